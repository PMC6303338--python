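"""Fossil calibration priors and calibration-node placement.

Three prior families are supported for node ages:

* :class:`LognormalOffsetPrior` — a lognormal on the amount by which the
  node age exceeds a hard fossil minimum (the offset), parameterized so
  the expected exceedance is a fixed fraction of the fossil age.
* :class:`TruncatedNormalPrior` — a normal renormalized over ages above
  a hard minimum.
* :class:`UniformPrior` — a boxcar between two bounds.

Minimum-age arithmetic is done on decimal 0.1-My units so that values
like ``407.0 - 2.8 = 404.2`` come out exact rather than carrying binary
round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Union

import numpy as np
from scipy import stats

from .tree_io import Chronogram, CladeDefinition

__all__ = [
    "FossilCalibration",
    "LognormalOffsetPrior",
    "TruncatedNormalPrior",
    "UniformPrior",
    "CalibrationPrior",
    "fossil_min_age",
    "make_lognormal_prior",
    "prior_density",
    "sample_prior",
    "place_calibration",
    "annotate_support",
]

DEFAULT_SIGMA = 0.75
DEFAULT_EXPECTED_FRACTION = 0.05


def fossil_min_age(stage_lower_bound: float, margin: float) -> float:
    """Minimum node age from a stratigraphic lower bound and its margin.

    Returns ``stage_lower_bound - margin`` computed on decimal 0.1-My
    units, so the result is exact at that resolution (e.g.
    ``fossil_min_age(407.0, 2.8) == 404.2``).
    """
    if margin < 0:
        raise ValueError("margin of error must be non-negative")
    if stage_lower_bound <= 0:
        raise ValueError("stage lower bound must be positive")
    if margin >= stage_lower_bound:
        raise ValueError("margin must be smaller than the stage lower bound")
    return float(Decimal(repr(float(stage_lower_bound))) - Decimal(repr(float(margin))))


@dataclass(frozen=True)
class FossilCalibration:
    """A fossil record anchoring a minimum age on a clade."""

    fossil_name: str
    stage_lower_bound: float
    margin: float
    clade: CladeDefinition

    def __post_init__(self) -> None:
        if self.stage_lower_bound <= 0:
            raise ValueError("stage_lower_bound must be > 0")
        if not (0 <= self.margin < self.stage_lower_bound):
            raise ValueError("margin must satisfy 0 <= margin < stage_lower_bound")

    @property
    def min_age(self) -> float:
        return fossil_min_age(self.stage_lower_bound, self.margin)


@dataclass(frozen=True)
class LognormalOffsetPrior:
    """Lognormal prior on the exceedance of a node age over a fossil minimum.

    The node age is ``offset + X`` with ``X ~ LogNormal(mu, sigma)``;
    the analytic mean of X, ``exp(mu + sigma^2/2)``, equals
    ``expected_fraction * offset`` by construction.
    """

    offset: float
    mu: float
    sigma: float = DEFAULT_SIGMA
    expected_fraction: float = DEFAULT_EXPECTED_FRACTION

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        expected = math.exp(self.mu + self.sigma**2 / 2.0)
        target = self.expected_fraction * self.offset
        if target > 0 and not math.isclose(expected, target, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent parameterization: exp(mu + sigma^2/2) = "
                f"{expected:.9g} but expected_fraction * offset = {target:.9g}"
            )

    @property
    def mean_exceedance(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2.0)

    def density(self, age):
        age = np.asarray(age, dtype=float)
        out = np.zeros_like(age)
        above = age > self.offset
        out[above] = stats.lognorm.pdf(
            age[above] - self.offset, s=self.sigma, scale=math.exp(self.mu)
        )
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.offset + rng.lognormal(self.mu, self.sigma, size=n)

    @property
    def support(self) -> tuple[float, float]:
        return (self.offset, math.inf)


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """Normal prior renormalized over ages above a hard minimum."""

    mean: float
    sd: float
    min_age: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    def _dist(self):
        a = (self.min_age - self.mean) / self.sd
        return stats.truncnorm(a, math.inf, loc=self.mean, scale=self.sd)

    def density(self, age):
        age = np.asarray(age, dtype=float)
        out = self._dist().pdf(age)
        out = np.where(age < self.min_age, 0.0, out)
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._dist().rvs(size=n, random_state=rng)

    @property
    def support(self) -> tuple[float, float]:
        return (self.min_age, math.inf)


@dataclass(frozen=True)
class UniformPrior:
    """Boxcar prior between a young and an old bound (Ma)."""

    young_bound: float
    old_bound: float

    def __post_init__(self) -> None:
        if not self.young_bound < self.old_bound:
            raise ValueError("young_bound must be < old_bound")

    def density(self, age):
        age = np.asarray(age, dtype=float)
        inside = (age >= self.young_bound) & (age <= self.old_bound)
        out = np.where(inside, 1.0 / (self.old_bound - self.young_bound), 0.0)
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.young_bound, self.old_bound, size=n)

    @property
    def support(self) -> tuple[float, float]:
        return (self.young_bound, self.old_bound)


CalibrationPrior = Union[LognormalOffsetPrior, TruncatedNormalPrior, UniformPrior]


def make_lognormal_prior(
    fossil_age: float,
    sigma: float = DEFAULT_SIGMA,
    expected_fraction: float = DEFAULT_EXPECTED_FRACTION,
) -> LognormalOffsetPrior:
    """Offset-lognormal prior with mu = ln(f * fossil_age) - sigma^2 / 2."""
    if fossil_age <= 0:
        raise ValueError("fossil_age must be > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if expected_fraction <= 0:
        raise ValueError("expected_fraction must be > 0")
    mu = math.log(expected_fraction * fossil_age) - sigma**2 / 2.0
    return LognormalOffsetPrior(
        offset=float(fossil_age),
        mu=mu,
        sigma=float(sigma),
        expected_fraction=float(expected_fraction),
    )


def prior_density(prior: CalibrationPrior, age) -> float | np.ndarray:
    """Density of the prior at ``age`` (per My); 0 outside the support."""
    return prior.density(age)


def sample_prior(prior: CalibrationPrior, n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. draws from the prior, reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return prior.sample(int(n), rng)


# ----------------------------------------------------------------------
# calibration placement on a support-annotated tree
# ----------------------------------------------------------------------
def annotate_support(
    tree: Chronogram,
    support: Mapping[frozenset, tuple[float, float]],
) -> None:
    """Attach (posterior probability, bootstrap) to internal nodes.

    ``support`` maps a frozenset of descendant tip labels to a
    ``(pp, bootstrap)`` pair; unknown clades are ignored.
    """
    for node in tree.tree.preorder_internal_node_iter():
        key = tree.leaf_labels_under(node)
        if key in support:
            pp, bs = support[key]
            node.posterior_probability = float(pp)
            node.bootstrap = float(bs)


def _node_support(node) -> tuple[float | None, float | None]:
    return (
        getattr(node, "posterior_probability", None),
        getattr(node, "bootstrap", None),
    )


def place_calibration(
    tree: Chronogram,
    clade: CladeDefinition | Iterable[str],
    pp_min: float = 0.95,
    bs_min: float = 0.70,
):
    """Find the node to which a fossil constraint should be attached.

    Returns the MRCA of the clade's taxa if its posterior probability is
    at least ``pp_min`` and its bootstrap proportion at least ``bs_min``;
    otherwise walks rootward and returns the first (next deeper) node
    meeting both thresholds.  Nodes lacking support values are treated
    as unsupported.  Raises if no qualifying node exists up to and
    including the root.
    """
    taxa = clade.taxa if isinstance(clade, CladeDefinition) else frozenset(clade)
    node = tree.mrca(taxa)
    cur = node
    while cur is not None:
        pp, bs = _node_support(cur)
        if pp is not None and bs is not None and pp >= pp_min and bs >= bs_min:
            return cur
        cur = cur.parent_node
    raise ValueError(
        f"no ancestor of {sorted(taxa)[:4]} meets pp >= {pp_min} and "
        f"bootstrap >= {bs_min} (root included)"
    )
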