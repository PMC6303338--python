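"""Simulators for every input the other modules consume.

* birth-death chronograms (Gillespie, conditioned on the stop state by
  rejection, so the simulator stays independent of the likelihoods it
  is used to test),
* single-clade extant-size draws (Monte Carlo oracle for the richness
  probability),
* terminally unresolved richness trees built by collapsing clades of a
  resolved tree,
* pseudo-posterior samples of chronograms around a base tree (a
  hierarchical scale-plus-jitter stand-in for a real MCMC sample),
* direct Gaussian age posteriors with known truth.

All draws come from ``numpy.random.default_rng`` streams seeded
explicitly; identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .diversification import BDParams, RichnessTree
from .tree_io import AgePosterior, Chronogram, CladeDefinition, TreeSample

__all__ = [
    "BDSimConfig",
    "PseudoPosteriorConfig",
    "simulate_bd_tree",
    "simulate_clade_size",
    "simulate_clade_sizes",
    "make_richness_tree",
    "simulate_pseudo_posterior",
    "make_gaussian_age_posteriors",
]

MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class BDSimConfig:
    """Settings for one birth-death tree simulation."""

    birth_rate: float
    death_rate: float = 0.0
    n_tips: int | None = None
    time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if (self.n_tips is None) == (self.time is None):
            raise ValueError("exactly one of n_tips or time must be set")
        if self.n_tips is not None:
            if self.n_tips < 2:
                raise ValueError("n_tips must be >= 2")
            if self.birth_rate <= self.death_rate:
                raise ValueError("n-tip stopping requires birth_rate > death_rate")
        if self.time is not None and self.time <= 0:
            raise ValueError("time must be > 0")


class _Lineage:
    __slots__ = ("parent", "birth_time", "end_time", "children", "label")

    def __init__(self, parent, birth_time):
        self.parent = parent
        self.birth_time = birth_time
        self.end_time = None   # death or present
        self.children = []
        self.label = None


def _gillespie(config: BDSimConfig, rng: np.random.Generator):
    """One forward simulation from 2 root lineages.

    Returns (root_lineages, extant, present_time) or None if the
    process died out (or never reached n_tips where applicable).
    """
    lam, mu = config.birth_rate, config.death_rate
    roots = [_Lineage(None, 0.0), _Lineage(None, 0.0)]
    active = list(roots)
    t = 0.0
    while True:
        k = len(active)
        if k == 0:
            return None
        rate = (lam + mu) * k
        dt = rng.exponential(1.0 / rate)
        if config.n_tips is not None and k == config.n_tips:
            # stop just before the next event so pendant edges are positive
            present = t + dt
            break
        if config.time is not None and t + dt >= config.time:
            present = config.time
            break
        t += dt
        idx = rng.integers(0, k)
        lineage = active.pop(idx)
        lineage.end_time = t
        if rng.random() < lam / (lam + mu):
            c1, c2 = _Lineage(lineage, t), _Lineage(lineage, t)
            lineage.children = [c1, c2]
            active.extend([c1, c2])
        # else: death, no children
    for lin in active:
        lin.end_time = present
    return roots, active, present


def _build_tree(roots, extant, present) -> Chronogram:
    """Prune extinct lineages and emit an ultrametric chronogram."""
    keep = set()
    for lin in extant:
        cur = lin
        while cur is not None and id(cur) not in keep:
            keep.add(id(cur))
            cur = cur.parent

    taxon_ns = dendropy.TaxonNamespace()
    counter = [0]

    def convert(lin) -> dendropy.Node | None:
        if id(lin) not in keep:
            return None
        node = dendropy.Node()
        node.edge.length = lin.end_time - lin.birth_time
        kids = [convert(c) for c in lin.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            counter[0] += 1
            taxon = taxon_ns.new_taxon(label=f"t{counter[0]}")
            node.taxon = taxon
            return node
        if len(kids) == 1:  # suppress unifurcation from a pruned sister
            child = kids[0]
            child.edge.length += node.edge.length
            return child
        for k in kids:
            node.add_child(k)
        return node

    subtrees = [convert(r) for r in roots]
    subtrees = [s for s in subtrees if s is not None]
    if len(subtrees) == 2:
        root = dendropy.Node()
        for s in subtrees:
            root.add_child(s)
    else:
        root = subtrees[0]
        root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    return Chronogram(tree)


def simulate_bd_tree(config: BDSimConfig) -> Chronogram:
    """Simulate a birth-death chronogram from 2 root lineages.

    Conditioned on reaching the stop state (for n-tip stopping: exactly
    ``n_tips`` extant lineages; for time stopping: >= 2 survivors) by
    rejection, with an attempt cap of 10^4.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(MAX_ATTEMPTS):
        out = _gillespie(config, rng)
        if out is None:
            continue
        roots, extant, present = out
        if len(extant) < 2:
            continue
        return _build_tree(roots, extant, present)
    raise RuntimeError(
        f"no surviving simulation in {MAX_ATTEMPTS} attempts; "
        "check birth/death rates and stop condition"
    )


def simulate_clade_size(
    t: float,
    params: BDParams,
    seed: int | np.random.Generator = 0,
) -> int:
    """Extant descendants of one lineage after time ``t``, conditioned
    on at least one survivor (resimulated on extinction)."""
    if t <= 0:
        raise ValueError("t must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, mu = params.lam, params.mu
    total = lam + mu
    p_birth = lam / total
    while True:
        n = 1
        elapsed = 0.0
        while True:
            dt = rng.exponential(1.0 / (total * n))
            if elapsed + dt >= t:
                break
            elapsed += dt
            if rng.random() < p_birth:
                n += 1
            else:
                n -= 1
                if n == 0:
                    break
        if n >= 1:
            return n


def simulate_clade_sizes(
    t: float, params: BDParams, n_reps: int, seed: int = 0
) -> np.ndarray:
    """Vector of ``n_reps`` independent conditioned clade sizes."""
    rng = np.random.default_rng(seed)
    return np.array([simulate_clade_size(t, params, rng) for _ in range(n_reps)])


def draw_clade_richness(
    t: float, params: BDParams, rng: np.random.Generator
) -> int:
    """One clade size from the conditional geometric law (fast path).

    Equivalent in distribution to :func:`simulate_clade_size` but drawn
    via the closed-form geometric success probability ``1 - beta``;
    used to build large engineered richness scenarios where explicit
    event simulation would be quadratic in clade size.
    """
    emrt = math.exp(-params.r * t)
    beta = (1.0 - emrt) / (1.0 - params.eps * emrt)
    return int(rng.geometric(1.0 - beta))


def engineer_shift_scenario(
    seed: int,
    *,
    n_tips: int = 12,
    r_background: float = 0.03,
    shift_fold: float = 10.0,
    min_contrast: float = 10.0,
    max_draws: int = 500,
):
    """A richness tree with one known diversification-rate shift.

    Simulates a pure-birth backbone at ``r_background``, places a shift
    of ``shift_fold`` times the background net rate on a random internal
    non-root-child edge subtending 3-5 tips, and draws every tip's
    richness from its class's conditional geometric law.  Richness
    vectors are redrawn until every shifted tip has at least
    ``min_contrast`` times the mean background richness, so the
    engineered contrast is guaranteed.

    Returns ``(rtree, true_edge_label, parent_edge_label)`` or ``None``
    when the backbone has no eligible shift edge or the contrast is not
    reached within ``max_draws`` redraws.
    """
    from .diversification import _assign_classes, _edge_table

    rng = np.random.default_rng(seed)
    config = BDSimConfig(
        birth_rate=r_background, death_rate=0.0, n_tips=n_tips, seed=seed
    )
    tree = simulate_bd_tree(config)
    rt0 = RichnessTree(backbone=tree, richness={t: 1 for t in tree.tip_labels})
    edges, _, _ = _edge_table(rt0)
    candidates = [
        e
        for e in edges
        if not e.is_tip
        and not e.is_root_child
        and 3 <= len(e.label.split("|")) <= 5
    ]
    if not candidates:
        return None
    true_edge = candidates[rng.integers(len(candidates))]
    assignment = _assign_classes(edges, [true_edge.node_id])
    p_bg = BDParams(r=r_background)
    p_hi = BDParams(r=r_background * shift_fold)
    for _ in range(max_draws):
        richness: dict[str, int] = {}
        shifted_sizes, background_sizes = [], []
        for e in edges:
            if not e.is_tip:
                continue
            shifted = assignment[e.node_id] == 1
            n = draw_clade_richness(e.t_top, p_hi if shifted else p_bg, rng)
            richness[e.label] = n
            (shifted_sizes if shifted else background_sizes).append(n)
        if min(shifted_sizes) >= min_contrast * float(np.mean(background_sizes)):
            parent_label = next(
                (e.label for e in edges if e.node_id == true_edge.parent_id), None
            )
            return (
                RichnessTree(backbone=tree, richness=richness),
                true_edge.label,
                parent_label,
            )
    return None


def make_richness_tree(
    full_tree: Chronogram,
    clade_map: Mapping[str, Iterable[str]] | None = None,
) -> RichnessTree:
    """Collapse mapped clades of a resolved tree into richness tips.

    ``clade_map`` maps a representative tip label to the full set of
    tip labels it will stand for (the representative included).  The
    mapped sets must be disjoint; unmapped tips keep richness 1.  Total
    species count is preserved exactly.
    """
    clade_map = {rep: frozenset(s) for rep, s in (clade_map or {}).items()}
    all_tips = full_tree.tip_labels
    seen: set[str] = set()
    for rep, taxa in clade_map.items():
        if rep not in taxa:
            raise ValueError(f"representative {rep!r} not inside its own clade set")
        missing = taxa - all_tips
        if missing:
            raise KeyError(f"clade of {rep!r}: unknown tips {sorted(missing)[:6]}")
        overlap = taxa & seen
        if overlap:
            raise ValueError(f"overlapping clade sets at {sorted(overlap)[:6]}")
        seen |= taxa

    collapsed = set().union(*clade_map.values()) if clade_map else set()
    keep = (all_tips - collapsed) | set(clade_map)

    tree = dendropy.Tree(full_tree.tree)  # deep copy via taxon-sharing clone
    tree.retain_taxa_with_labels(sorted(keep))
    backbone = Chronogram(tree)

    richness = {t: 1 for t in backbone.tip_labels}
    for rep, taxa in clade_map.items():
        richness[rep] = len(taxa)
    return RichnessTree(backbone=backbone, richness=richness)


@dataclass(frozen=True)
class PseudoPosteriorConfig:
    """Settings for a pseudo-posterior sample around a base chronogram."""

    base_tree: Chronogram
    age_cv: float
    n_trees: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_cv < 0:
            raise ValueError("age_cv must be >= 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def simulate_pseudo_posterior(config: PseudoPosteriorConfig) -> TreeSample:
    """Emulate a posterior sample of chronograms around a base tree.

    Each replicate applies (1) a tree-wide scale factor
    ``s ~ LogNormal(-cv^2/2, cv)`` (unit mean) and (2) independent
    node-age jitter: visiting internal nodes root-to-tip, the age is
    resampled uniformly in a ``+/- cv * age`` window clipped by the
    (already jittered) parent age above and the oldest scaled child age
    below, preserving parent-older-than-child everywhere.  Topology is
    unchanged.

    Stream order per replicate: one scale draw, then one uniform per
    internal node in preorder.
    """
    base = config.base_tree
    cv = config.age_cv
    rng = np.random.default_rng(config.seed)

    # cache base ages in preorder
    base_nodes = list(base.tree.preorder_node_iter())
    base_ages = [base.node_age(n) for n in base_nodes]
    base_index = {id(n): i for i, n in enumerate(base_nodes)}

    trees: list[Chronogram] = []
    for _ in range(config.n_trees):
        if cv == 0.0:
            trees.append(Chronogram(dendropy.Tree(base.tree)))
            continue
        s = float(rng.lognormal(-cv * cv / 2.0, cv))
        scaled = [a * s for a in base_ages]
        new_age: dict[int, float] = {}
        clone = dendropy.Tree(base.tree)
        clone_nodes = list(clone.preorder_node_iter())
        # preorder of the clone parallels preorder of the base
        for i, (bnode, cnode) in enumerate(zip(base_nodes, clone_nodes)):
            a = scaled[i]
            if bnode.is_leaf():
                new_age[id(cnode)] = 0.0
                continue
            half = cv * a
            children_scaled = [
                scaled[base_index[id(ch)]] for ch in bnode.child_nodes()
            ]
            lo = max(a - half, max(children_scaled))
            if cnode.parent_node is None:
                hi = a + half
            else:
                hi = min(a + half, new_age[id(cnode.parent_node)])
            if hi <= lo:
                new_age[id(cnode)] = lo
            else:
                new_age[id(cnode)] = float(rng.uniform(lo, hi))
        for cnode in clone_nodes:
            if cnode.parent_node is not None:
                cnode.edge.length = new_age[id(cnode.parent_node)] - new_age[id(cnode)]
        trees.append(Chronogram(clone))
    return TreeSample(trees=trees, source="pseudo-posterior", burnin_fraction=0.0)


def make_gaussian_age_posteriors(
    specs: Sequence[tuple[str, float, float, int, int]],
) -> list[AgePosterior]:
    """Direct age posteriors with known truth: i.i.d. normal draws
    truncated at 0 (negative draws rejected and redrawn).

    Each spec is ``(label, mean_ma, sd_my, n, seed)``.
    """
    out: list[AgePosterior] = []
    for label, mean, sd, n, seed in specs:
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if n < 2:
            raise ValueError("n must be >= 2")
        rng = np.random.default_rng(seed)
        if sd == 0.0:
            ages = np.full(n, float(mean))
        else:
            ages = rng.normal(mean, sd, size=n)
            bad = ages < 0
            while bad.any():
                ages[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = ages < 0
        clade = CladeDefinition(name=label, taxa=frozenset({label}), mode="crown")
        out.append(AgePosterior(clade=clade, ages=ages))
    return out
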