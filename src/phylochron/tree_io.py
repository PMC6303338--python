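"""Reading tree samples and extracting per-clade node-age posteriors.

Trees are rooted chronograms with branch lengths in millions of years
(My); node ages are measured backward from the present, so extant tips
sit at age 0 and the root carries the oldest age.  Posterior samples of
such trees (e.g. the output of a Bayesian dating run, thinned and
concatenated across chains) are handled by :class:`TreeSample`, with
burn-in removed per input file before concatenation.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Chronogram",
    "TreeSample",
    "CladeDefinition",
    "AgePosterior",
    "NonUltrametricError",
    "read_trees",
    "mrca",
    "crown_age",
    "stem_age",
    "is_monophyletic",
    "extract_age_posterior",
    "check_ultrametric",
    "write_age_table",
    "read_age_table",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class NonUltrametricError(ValueError):
    """Raised when root-to-tip path lengths disagree beyond tolerance."""


class Chronogram:
    """A rooted, time-calibrated tree with tips at age 0.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree` with branch lengths in My.
    ultrametric_rtol:
        Maximum allowed spread of root-to-tip path lengths, relative to
        the root age.
    relax_ultrametric:
        If True, trees whose paths disagree beyond ``ultrametric_rtol``
        are accepted and node ages are computed as the mean root-to-tip
        path length minus node depth.  If False (default) such trees
        raise :class:`NonUltrametricError` when ages are requested.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
        relax_ultrametric: bool = False,
    ) -> None:
        if not tree.is_rooted:
            raise ValueError("chronograms must be rooted trees")
        self.tree = tree
        self.ultrametric_rtol = float(ultrametric_rtol)
        self.relax_ultrametric = bool(relax_ultrametric)
        self._depths: dict[int, float] | None = None
        self._root_age: float | None = None
        self._tip_depth_spread: float | None = None

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "Chronogram":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="default-rooted",
        )
        return cls(tree, **kwargs)

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def _compute_depths(self) -> None:
        depths: dict[int, float] = {}
        tip_depths: list[float] = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[id(node)] = 0.0
            else:
                el = node.edge.length if node.edge.length is not None else 0.0
                if el < 0:
                    raise ValueError(
                        f"negative branch length {el} on edge above "
                        f"{_node_repr(node)}"
                    )
                depths[id(node)] = depths[id(node.parent_node)] + el
            if node.is_leaf():
                tip_depths.append(depths[id(node)])
        self._depths = depths
        self._root_age = float(np.mean(tip_depths))
        self._tip_depth_spread = float(max(tip_depths) - min(tip_depths))

    @property
    def root_age(self) -> float:
        """Age of the root: mean root-to-tip path length (Ma)."""
        if self._root_age is None:
            self._compute_depths()
        return self._root_age  # type: ignore[return-value]

    def is_ultrametric(self, rtol: float | None = None) -> bool:
        if self._tip_depth_spread is None:
            self._compute_depths()
        rtol = self.ultrametric_rtol if rtol is None else rtol
        root_age = self.root_age
        if root_age == 0.0:
            return True
        return self._tip_depth_spread <= rtol * root_age  # type: ignore[operator]

    def _require_ultrametric(self) -> None:
        if not self.relax_ultrametric and not self.is_ultrametric():
            raise NonUltrametricError(
                "root-to-tip path lengths differ by "
                f"{self._tip_depth_spread:.6g} My (> rtol "
                f"{self.ultrametric_rtol:g} x root age {self.root_age:.6g}); "
                "enable relax_ultrametric to normalize by the mean path"
            )

    def node_age(self, node: dendropy.Node) -> float:
        """Age of ``node`` in Ma, measured backward from the present."""
        self._require_ultrametric()
        if self._depths is None:
            self._compute_depths()
        age = self.root_age - self._depths[id(node)]  # type: ignore[index]
        # tips are age 0 by definition; clear float dust near the present
        if abs(age) <= self.ultrametric_rtol * max(self.root_age, 1.0):
            return 0.0
        return age

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of ``taxa`` (a tip for singletons)."""
        taxa = set(taxa)
        if not taxa:
            raise ValueError("taxon set must be non-empty")
        known = self.tip_labels
        unknown = sorted(taxa - known)
        if unknown:
            raise KeyError(f"unknown tip labels: {', '.join(unknown)}")
        if len(taxa) == 1:
            (label,) = taxa
            for lf in self.tree.leaf_node_iter():
                if lf.taxon.label == label:
                    return lf
        node = self.tree.mrca(taxon_labels=sorted(taxa))
        if node is None:  # pragma: no cover - dendropy returns root at worst
            raise ValueError(f"no MRCA found for {sorted(taxa)}")
        return node

    def leaf_labels_under(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _node_repr(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    tips = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "{" + ",".join(tips[:4]) + (",..." if len(tips) > 4 else "") + "}"


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade given by a taxon set and an age mode (crown/stem)."""

    name: str
    taxa: frozenset[str]
    mode: str = "crown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        if not self.taxa:
            raise ValueError(f"clade {self.name!r}: taxon set must be non-empty")
        if self.mode not in ("crown", "stem"):
            raise ValueError(f"clade {self.name!r}: mode must be 'crown' or 'stem'")


@dataclass
class TreeSample:
    """An ordered posterior sample of chronograms sharing one taxon set."""

    trees: list[Chronogram]
    source: str = ""
    burnin_fraction: float = 0.0

    @property
    def n_retained(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        if not self.trees:
            return frozenset()
        return self.trees[0].tip_labels


@dataclass
class AgePosterior:
    """Crown or stem ages (Ma) of one clade across a tree sample."""

    clade: CladeDefinition
    ages: np.ndarray
    monophyly_policy: str = "mrca"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.ndim != 1:
            raise ValueError("ages must be a 1-D vector")
        if not np.all(np.isfinite(self.ages)):
            raise ValueError("ages must all be finite")
        if np.any(self.ages < 0):
            raise ValueError("ages must be non-negative")

    @property
    def n(self) -> int:
        return int(self.ages.size)

    @property
    def label(self) -> str:
        return self.clade.name


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def read_trees(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    format: str = "newick",
    burnin_fraction: float = 0.0,
    *,
    ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    relax_ultrametric: bool = False,
) -> TreeSample:
    """Read one or more tree files into a :class:`TreeSample`.

    The first ``floor(burnin_fraction * n_file)`` trees of EACH file are
    discarded before the files are concatenated, mirroring per-run
    burn-in removal followed by run combination.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported format {format!r}")
    if not (0.0 <= burnin_fraction < 1.0):
        raise ValueError("burnin_fraction must satisfy 0 <= f < 1")
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]

    retained: list[Chronogram] = []
    ref_taxa: frozenset[str] | None = None
    global_index = 0
    for path in paths:
        tl = dendropy.TreeList.get(
            path=str(path),
            schema=format,
            preserve_underscores=True,
            rooting="default-rooted",
        )
        if len(tl) == 0:
            raise ValueError(f"no trees parsed from {path}")
        n_discard = math.floor(burnin_fraction * len(tl))
        for i, t in enumerate(tl):
            if not t.is_rooted:
                raise ValueError(f"tree {global_index + i} in {path} is unrooted")
            chrono = Chronogram(
                t,
                ultrametric_rtol=ultrametric_rtol,
                relax_ultrametric=relax_ultrametric,
            )
            tips = chrono.tip_labels
            if ref_taxa is None:
                ref_taxa = tips
            elif tips != ref_taxa:
                extra = sorted(tips ^ ref_taxa)
                raise ValueError(
                    f"tree {global_index + i} (file {path}) has a different "
                    f"taxon set; symmetric difference: {extra[:6]}"
                )
            if i >= n_discard:
                retained.append(chrono)
        global_index += len(tl)

    return TreeSample(
        trees=retained,
        source=";".join(str(p) for p in paths),
        burnin_fraction=burnin_fraction,
    )


def mrca(tree: Chronogram, taxa: Iterable[str]) -> dendropy.Node:
    return tree.mrca(taxa)


def crown_age(tree: Chronogram, clade: CladeDefinition | Iterable[str]) -> float:
    """Age of the MRCA of the clade's taxa (tips are age 0)."""
    taxa = clade.taxa if isinstance(clade, CladeDefinition) else set(clade)
    return tree.node_age(tree.mrca(taxa))


def stem_age(tree: Chronogram, clade: CladeDefinition | Iterable[str]) -> float:
    """Age of the parent of the clade's MRCA."""
    taxa = clade.taxa if isinstance(clade, CladeDefinition) else set(clade)
    node = tree.mrca(taxa)
    if node.parent_node is None:
        raise ValueError("stem age undefined for root")
    return tree.node_age(node.parent_node)


def is_monophyletic(tree: Chronogram, taxa: Iterable[str]) -> bool:
    taxa = frozenset(taxa)
    node = tree.mrca(taxa)
    return tree.leaf_labels_under(node) == taxa


def check_ultrametric(tree: Chronogram, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> bool:
    return tree.is_ultrametric(rtol)


def extract_age_posterior(
    sample: TreeSample,
    clade: CladeDefinition,
    policy: str = "mrca",
) -> AgePosterior:
    """Record the clade's (crown|stem) age in every retained tree.

    ``policy='mrca'`` uses the MRCA in every tree; ``policy='strict'``
    skips trees in which the clade is not monophyletic and records the
    skip count.
    """
    if policy not in ("mrca", "strict"):
        raise ValueError("policy must be 'mrca' or 'strict'")
    if not sample.trees:
        raise ValueError("tree sample is empty")
    unknown = clade.taxa - sample.tip_labels
    if unknown:
        raise KeyError(
            f"clade {clade.name!r}: unknown tip labels {sorted(unknown)[:6]}"
        )
    age_fn = crown_age if clade.mode == "crown" else stem_age
    ages: list[float] = []
    skipped = 0
    for tree in sample.trees:
        if policy == "strict" and not is_monophyletic(tree, clade.taxa):
            skipped += 1
            continue
        ages.append(age_fn(tree, clade))
    if not ages:
        raise ValueError(
            f"clade {clade.name!r} monophyletic in 0 of "
            f"{sample.n_retained} trees under strict policy"
        )
    return AgePosterior(
        clade=clade,
        ages=np.asarray(ages, dtype=float),
        monophyly_policy=policy,
        n_skipped=skipped,
    )


# ----------------------------------------------------------------------
# age tables
# ----------------------------------------------------------------------
AGE_TABLE_COLUMNS = ["clade", "mode", "draw_index", "age_ma"]


def write_age_table(
    posteriors: Sequence[AgePosterior], path: str | os.PathLike
) -> None:
    """Write posteriors to a TSV (clade, mode, draw_index, age_ma)."""
    if not posteriors:
        raise ValueError("no posteriors to write")
    frames = []
    for post in posteriors:
        frames.append(
            pd.DataFrame(
                {
                    "clade": post.clade.name,
                    "mode": post.clade.mode,
                    "draw_index": np.arange(post.n),
                    "age_ma": post.ages,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=lambda x: format(x, ".17g")
    )


def read_age_table(path: str | os.PathLike) -> dict[tuple[str, str], AgePosterior]:
    """Read an age table TSV back into posteriors keyed by (clade, mode)."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = set(AGE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"age table {path} missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], AgePosterior] = {}
    for (name, mode), grp in df.groupby(["clade", "mode"], sort=False):
        grp = grp.sort_values("draw_index")
        clade = CladeDefinition(name=str(name), taxa=frozenset({str(name)}), mode=str(mode))
        out[(str(name), str(mode))] = AgePosterior(
            clade=clade, ages=grp["age_ma"].to_numpy(dtype=float)
        )
    return out
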