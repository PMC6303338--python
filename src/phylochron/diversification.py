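"""Richness-aware birth-death diversification-rate-shift detection.

The likelihood combines two ingredients:

* a constant-rate birth-death likelihood of the backbone's internal
  branching times, conditioned on survival of the two root lineages
  (Nee et al. 1994 reconstructed-process likelihood, written as a
  product of per-edge factors so that edges can be partitioned into
  rate classes), and
* for each terminal (unresolved) clade of known extant richness ``n``
  with stem age ``t``, the conditional geometric probability
  ``P(n | survival) = (1 - beta) * beta^(n-1)`` with
  ``beta = (exp(r t) - 1) / (exp(r t) - eps)`` (Magallon & Sanderson).

With all tip richness equal to 1 on a fully resolved binary tree the
combined likelihood is exactly the Nee backbone likelihood.

Rate shifts are placed on edges; a shift re-parameterizes the whole
subtree below its edge until overridden by a more tipward shift.
Models are compared by AICc, with a greedy forward search adding one
shift at a time while the score improves by at least a threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .tree_io import Chronogram

__all__ = [
    "BDParams",
    "RichnessTree",
    "FitResult",
    "ShiftModel",
    "clade_richness_logprob",
    "backbone_loglik",
    "combined_loglik",
    "fit_bd",
    "aicc",
    "stepwise_shift_search",
]

_EPS_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class BDParams:
    """Net diversification rate r = lambda - mu and relative extinction
    eps = mu / lambda."""

    r: float
    eps: float = 0.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("net diversification rate r must be > 0")
        if not (0.0 <= self.eps < 1.0):
            raise ValueError("relative extinction eps must be in [0, 1)")

    @property
    def lam(self) -> float:
        return self.r / (1.0 - self.eps)

    @property
    def mu(self) -> float:
        return self.lam * self.eps


@dataclass
class RichnessTree:
    """A chronogram backbone whose tips carry extant species counts."""

    backbone: Chronogram
    richness: dict[str, int]

    def __post_init__(self) -> None:
        tips = self.backbone.tip_labels
        missing = tips - set(self.richness)
        if missing:
            raise ValueError(f"tips without richness: {sorted(missing)[:6]}")
        extra = set(self.richness) - tips
        if extra:
            raise ValueError(f"richness entries without tips: {sorted(extra)[:6]}")
        bad = [t for t, n in self.richness.items() if int(n) < 1]
        if bad:
            raise ValueError(f"richness must be >= 1; offending tips: {bad[:6]}")
        self.richness = {t: int(n) for t, n in self.richness.items()}

    @property
    def total_richness(self) -> int:
        return sum(self.richness.values())


# ----------------------------------------------------------------------
# elementary birth-death probabilities (numerically stable forms)
# ----------------------------------------------------------------------
def _log_survival(t: float, r: float, eps: float) -> float:
    """log P(>=1 descendant at present | one lineage at age t)."""
    # P(t) = (1 - eps) / (1 - eps * exp(-r t))
    return math.log1p(-eps) - math.log1p(-eps * math.exp(-r * t))

def _log_p1(t: float, r: float, eps: float) -> float:
    """log P(exactly 1 reconstructed descendant | one lineage at age t)."""
    # p1(t) = (1 - eps)^2 exp(-r t) / (1 - eps exp(-r t))^2
    return 2.0 * math.log1p(-eps) - r * t - 2.0 * math.log1p(-eps * math.exp(-r * t))


def clade_richness_logprob(n: int, t: float, params: BDParams) -> float:
    """log P(clade of stem age ``t`` has exactly ``n`` extant species),
    conditioned on its survival to the present.

    Geometric law with ``beta = (exp(r t) - 1) / (exp(r t) - eps)``:
    ``log[(1 - beta) beta^(n-1)]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1 (probability is conditioned on survival)")
    if t <= 0:
        raise ValueError("stem age t must be > 0")
    r, eps = params.r, params.eps
    emrt = math.exp(-r * t)
    log_beta = math.log1p(-emrt) - math.log1p(-eps * emrt)
    log_1mbeta = math.log1p(-eps) - r * t - math.log1p(-eps * emrt)
    return log_1mbeta + (n - 1) * log_beta


# ----------------------------------------------------------------------
# edge tables and class assignment
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class _Edge:
    """One backbone edge, identified by the node below it."""

    node_id: int
    label: str               # tip label, or sorted-tip-set digest for internal
    t_top: float             # age of the parent node (older end)
    t_bot: float             # age of the node below (0 for tips)
    is_tip: bool
    richness: int            # valid for tip edges
    is_root_child: bool
    parent_id: int


def _edge_table(rtree: RichnessTree) -> tuple[list[_Edge], float, int]:
    """Flatten the backbone into per-edge records.

    Returns (edges, root_age, n_internal_nodes).  Requires a binary
    backbone (the Nee factorization assigns one speciation event per
    non-root internal node).
    """
    tree = rtree.backbone
    root = tree.tree.seed_node
    root_age = tree.root_age
    edges: list[_Edge] = []
    n_internal = 0
    for node in tree.tree.preorder_node_iter():
        children = node.child_nodes()
        if children:
            n_internal += 1
            if len(children) != 2:
                raise ValueError(
                    "diversification likelihood requires a binary backbone; "
                    f"found a node with {len(children)} children"
                )
        if node is root:
            continue
        t_top = tree.node_age(node.parent_node)
        t_bot = tree.node_age(node)
        if node.is_leaf():
            label = node.taxon.label
            rich = rtree.richness[label]
            is_tip = True
        else:
            tips = sorted(lf.taxon.label for lf in node.leaf_iter())
            label = "|".join(tips)
            rich = 0
            is_tip = False
        edges.append(
            _Edge(
                node_id=id(node),
                label=label,
                t_top=t_top,
                t_bot=t_bot,
                is_tip=is_tip,
                richness=rich,
                is_root_child=node.parent_node is root,
                parent_id=id(node.parent_node),
            )
        )
    return edges, root_age, n_internal


def _assign_classes(
    edges: Sequence[_Edge], shift_edges: Sequence[int]
) -> dict[int, int]:
    """Map each edge (by node id) to a rate class.

    Class 0 is the base (root) class; class ``i`` (1-based) is the
    subtree below the ``i``-th shift edge, until overridden by a more
    tipward shift.
    """
    shift_class = {nid: i + 1 for i, nid in enumerate(shift_edges)}
    assignment: dict[int, int] = {}
    by_id = {e.node_id: e for e in edges}
    for e in edges:
        if e.node_id in shift_class:
            assignment[e.node_id] = shift_class[e.node_id]
            continue
        # inherit from parent edge (root itself has no edge -> base class)
        cur = e
        chain = [e.node_id]
        while True:
            parent = by_id.get(cur.parent_id)
            if parent is None:
                cls = 0
                break
            if parent.node_id in assignment:
                cls = assignment[parent.node_id]
                break
            if parent.node_id in shift_class:
                cls = shift_class[parent.node_id]
                break
            chain.append(parent.node_id)
            cur = parent
        for nid in chain:
            assignment[nid] = cls
    return assignment


# ----------------------------------------------------------------------
# log-likelihood
# ----------------------------------------------------------------------
def _class_loglik(
    edges: Sequence[_Edge],
    root_age: float,
    n_root_children_in_class: int,
    params: BDParams,
    *,
    with_richness: bool = True,
) -> float:
    """Log-likelihood contribution of one rate class.

    Internal edge: log p1(t_top) - log p1(t_bot), plus log(lambda) for
    the speciation event closing the edge.  Tip edge: log of the
    unconditional probability of ``n`` extant species from one lineage
    of age t_top (survival times the conditional geometric).  Root
    conditioning: -log P(root_age) per root-child edge in the class.
    """
    r, eps, lam = params.r, params.eps, params.lam
    ll = 0.0
    for e in edges:
        if e.is_tip:
            n = e.richness if with_richness else 1
            ll += _log_survival(e.t_top, r, eps)
            ll += clade_richness_logprob(n, e.t_top, params)
        else:
            ll += _log_p1(e.t_top, r, eps) - _log_p1(e.t_bot, r, eps)
            ll += math.log(lam)
    ll -= n_root_children_in_class * _log_survival(root_age, r, eps)
    return ll


def backbone_loglik(tree: Chronogram, params: BDParams) -> float:
    """Nee-style constant-rate BD log-likelihood of a resolved backbone,
    conditioned on survival of the two root lineages (richness ignored:
    every tip counts as one extant species)."""
    if len(tree.tip_labels) < 2:
        raise ValueError("need at least 2 tips")
    rtree = RichnessTree(backbone=tree, richness={t: 1 for t in tree.tip_labels})
    edges, root_age, _ = _edge_table(rtree)
    n_root_children = sum(e.is_root_child for e in edges)
    return _class_loglik(edges, root_age, n_root_children, params, with_richness=False)


def combined_loglik(
    rtree: RichnessTree,
    class_params: Sequence[BDParams],
    assignment: Mapping[int, int] | None = None,
    shift_edges: Sequence[int] | None = None,
) -> float:
    """Backbone + richness log-likelihood under a per-edge class map."""
    edges, root_age, _ = _edge_table(rtree)
    if assignment is None:
        assignment = _assign_classes(edges, shift_edges or [])
    ll = 0.0
    for cls, params in enumerate(class_params):
        cls_edges = [e for e in edges if assignment[e.node_id] == cls]
        n_rc = sum(e.is_root_child for e in cls_edges)
        if not cls_edges:
            continue
        ll += _class_loglik(cls_edges, root_age, n_rc, params)
    return ll


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Per-class maximum-likelihood fit."""

    class_id: int
    params: BDParams
    logL: float
    k: int                 # free parameters in this class (1 Yule, 2 BD)
    model: str             # "yule" or "bd"
    converged: bool


def _neg_ll_factory(edges, root_age, n_rc, yule: bool):
    def neg_ll(x):
        r = math.exp(x[0])
        eps = 0.0 if yule else 1.0 / (1.0 + math.exp(-x[1]))
        eps = min(eps, _EPS_MAX)
        try:
            params = BDParams(r=r, eps=eps)
            return -_class_loglik(edges, root_age, n_rc, params)
        except (OverflowError, ValueError):
            return 1e12

    return neg_ll


def _fit_one_class(
    edges: Sequence[_Edge],
    root_age: float,
    n_rc: int,
    *,
    n_starts: int = 5,
    seed: int = 0,
    init: BDParams | None = None,
) -> FitResult:
    """MLE of (r, eps) for one class; fits Yule (eps=0) and full BD,
    keeps whichever wins on per-class AIC."""
    rng = np.random.default_rng(seed)
    # heuristic rate scale from total richness vs oldest time in the class
    n_total = max(sum(e.richness for e in edges if e.is_tip), 2)
    t_max = max(e.t_top for e in edges)
    r0 = max(math.log(max(n_total, 2)) / t_max, 1e-4)

    best: dict[str, tuple[float, np.ndarray, bool]] = {}
    for yule in (True, False):
        starts: list[np.ndarray] = []
        if init is not None:
            if yule:
                starts.append(np.array([math.log(init.r)]))
            else:
                e0 = min(max(init.eps, 1e-6), 1 - 1e-6)
                starts.append(np.array([math.log(init.r), math.log(e0 / (1 - e0))]))
        base = np.array([math.log(r0)] if yule else [math.log(r0), 0.0])
        starts.append(base)
        while len(starts) < n_starts:
            jitter = rng.normal(scale=1.0, size=base.size)
            starts.append(base + jitter)
        neg_ll = _neg_ll_factory(edges, root_age, n_rc, yule)
        key = "yule" if yule else "bd"
        for x0 in starts:
            res = minimize(
                neg_ll,
                x0,
                method="L-BFGS-B",
                bounds=[(-20.0, 10.0)] + ([] if yule else [(-20.0, 20.0)]),
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            val = float(res.fun)
            if key not in best or val < best[key][0]:
                best[key] = (val, res.x, bool(res.success))

    ll_yule, x_yule, ok_yule = best["yule"]
    ll_bd, x_bd, ok_bd = best["bd"]
    # per-class AIC: 2k - 2 logL
    aic_yule = 2 * 1 + 2 * ll_yule
    aic_bd = 2 * 2 + 2 * ll_bd
    if aic_yule <= aic_bd:
        params = BDParams(r=math.exp(x_yule[0]), eps=0.0)
        return FitResult(0, params, -ll_yule, 1, "yule", ok_yule)
    eps = 1.0 / (1.0 + math.exp(-x_bd[1]))
    params = BDParams(r=math.exp(x_bd[0]), eps=min(eps, _EPS_MAX))
    return FitResult(0, params, -ll_bd, 2, "bd", ok_bd)


def fit_bd(
    rtree: RichnessTree,
    shift_edges: Sequence[int] | None = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
    inits: Sequence[BDParams | None] | None = None,
) -> list[FitResult]:
    """Per-class MLEs for the partition induced by ``shift_edges``
    (node ids of edges carrying a shift; empty = constant-rate model)."""
    edges, root_age, _ = _edge_table(rtree)
    shift_edges = list(shift_edges or [])
    assignment = _assign_classes(edges, shift_edges)
    n_classes = 1 + len(shift_edges)
    results: list[FitResult] = []
    for cls in range(n_classes):
        cls_edges = [e for e in edges if assignment[e.node_id] == cls]
        n_rc = sum(e.is_root_child for e in cls_edges)
        init = inits[cls] if inits is not None else None
        if not cls_edges:
            results.append(
                FitResult(cls, BDParams(r=1e-3), 0.0, 1, "empty", True)
            )
            continue
        fr = _fit_one_class(
            cls_edges, root_age, n_rc, n_starts=n_starts, seed=seed + cls, init=init
        )
        fr.class_id = cls
        results.append(fr)
    return results


def aicc(logL: float, k: int, n_obs: int) -> float:
    """AICc = AIC + 2k(k+1)/(n-k-1); falls back to AIC (with a warning)
    when n_obs <= k + 1."""
    aic = 2.0 * k - 2.0 * logL
    if n_obs > k + 1:
        return aic + 2.0 * k * (k + 1) / (n_obs - k - 1)
    warnings.warn(
        f"n_obs={n_obs} too small for AICc with k={k}; falling back to AIC",
        RuntimeWarning,
        stacklevel=2,
    )
    return aic


# ----------------------------------------------------------------------
# stepwise search
# ----------------------------------------------------------------------
@dataclass
class ShiftModel:
    """A fitted shift configuration on a richness tree."""

    shift_labels: list[str]          # tip-set labels of shift edges
    shift_node_ids: list[int]
    fits: list[FitResult]            # index 0 = base class
    logL: float
    k: int
    aicc: float
    n_obs: int
    trace: list[dict] = field(default_factory=list)

    @property
    def n_shifts(self) -> int:
        return len(self.shift_node_ids)

    @property
    def class_params(self) -> list[BDParams]:
        return [f.params for f in self.fits]


def _model_score(
    rtree: RichnessTree,
    shift_edges: list[int],
    n_obs: int,
    *,
    n_starts: int,
    seed: int,
    inits=None,
) -> tuple[list[FitResult], float, int, float]:
    fits = fit_bd(rtree, shift_edges, n_starts=n_starts, seed=seed, inits=inits)
    logL = sum(f.logL for f in fits)
    k = sum(f.k for f in fits) + len(shift_edges)  # + shift placements
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = aicc(logL, k, n_obs)
    return fits, logL, k, score


def stepwise_shift_search(
    rtree: RichnessTree,
    max_shifts: int = 5,
    threshold: float = 4.0,
    *,
    n_starts: int = 3,
    seed: int = 0,
) -> ShiftModel:
    """Greedy forward search for diversification-rate shifts.

    Starts from the constant-rate model; at each step tries a shift on
    every eligible edge (all edges except those already carrying a
    shift), refits, and accepts the best candidate while the AICc
    improves by at least ``threshold``.
    """
    if max_shifts < 0:
        raise ValueError("max_shifts must be >= 0")
    edges, root_age, n_internal = _edge_table(rtree)
    n_tips = sum(e.is_tip for e in edges)
    n_obs = n_internal + n_tips
    label_of = {e.node_id: e.label for e in edges}

    shift_edges: list[int] = []
    fits, logL, k, score = _model_score(
        rtree, shift_edges, n_obs, n_starts=n_starts, seed=seed
    )
    trace = [
        {
            "step": 0,
            "edge": None,
            "logL": logL,
            "k": k,
            "aicc": score,
            "accepted": True,
        }
    ]

    while len(shift_edges) < max_shifts:
        if not math.isfinite(threshold):
            break
        best_candidate = None
        for e in edges:
            if e.node_id in shift_edges:
                continue
            cand = shift_edges + [e.node_id]
            # warm-start every class at the current best params
            inits = [f.params for f in fits] + [fits[0].params]
            c_fits, c_logL, c_k, c_score = _model_score(
                rtree,
                cand,
                n_obs,
                n_starts=n_starts,
                seed=seed + len(cand),
                inits=inits,
            )
            if best_candidate is None or c_score < best_candidate[3]:
                best_candidate = (e, c_fits, c_logL, c_score, c_k)
        if best_candidate is None:
            break
        e, c_fits, c_logL, c_score, c_k = best_candidate
        improved = score - c_score >= threshold
        trace.append(
            {
                "step": len(shift_edges) + 1,
                "edge": e.label,
                "logL": c_logL,
                "k": c_k,
                "aicc": c_score,
                "accepted": bool(improved),
            }
        )
        if not improved:
            break
        shift_edges.append(e.node_id)
        fits, logL, k, score = c_fits, c_logL, c_k, c_score

    return ShiftModel(
        shift_labels=[label_of[nid] for nid in shift_edges],
        shift_node_ids=shift_edges,
        fits=fits,
        logL=logL,
        k=k,
        aicc=score,
        n_obs=n_obs,
        trace=trace,
    )
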