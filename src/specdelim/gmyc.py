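"""Single-threshold GMYC (generalized mixed Yule-coalescent) delimitation.

The model views an ultrametric gene tree as the outcome of two branching
regimes separated by a threshold time T: older than T, branching reflects
speciation (a Yule-type process over species-level lineages); younger than
T, branching reflects within-species coalescence.  Writing k for the number
of species-level lineages and n_j for the number of lineages within
putative species j during an inter-node interval, the total branching rate
during the interval is

    b = lambda_yule * k**p_yule + lambda_coal * (sum_j n_j (n_j - 1))**p_coal

and the likelihood of the tree's waiting times x_i between successive
branching events is  prod_i b_i * exp(-b_i * x_i)  (the final interval,
which ends at the present without an event, contributes survival only).
The null model is the single-regime special case (one coalescent class
across the whole tree).  The threshold is scanned exhaustively over the
observed node heights; rate parameters are profiled by bounded numerical
optimization from deterministic multistarts.  Because the null
configuration (threshold at the root) is always among the candidates,
lnL_alt >= lnL_null by construction and the likelihood-ratio statistic
LR = 2 (lnL_alt - lnL_null) is non-negative.

Putative species ("GMYC entities") are the maximal subtrees whose internal
nodes all lie below the fitted threshold.  Per-node support is the
Akaike-weighted fraction of a small ensemble of model variants (exponents
free or fixed at 1) whose maximum-likelihood delimitation places a
speciation event on that node; entities can be re-formed by merging at a
support cutoff (0.9 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import average
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.stats import chi2

__all__ = [
    "GmycError",
    "UltrametricTree",
    "GmycFit",
    "GmycSupport",
    "read_tree",
    "upgma_tree",
    "gmyc_fit",
    "gmyc_support",
    "entities_from_nodes",
]

_P_BOUNDS = (0.01, 3.0)
_LOGL_BOUNDS = (-30.0, 10.0)


class GmycError(ValueError):
    pass


@dataclass
class UltrametricTree:
    """Rooted binary clock-like tree in node-height form.

    Nodes are indexed 0..2n-2: tips first (0..n-1, with ``labels``), then
    internal nodes in preorder.  ``height`` is the time above the present
    (tips at 0); ``children``/``parent`` give the topology.
    """

    labels: list[str]
    parent: np.ndarray
    children: list[tuple[int, int] | None]
    height: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return int(np.argmax(self.height))

    def internal_nodes(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if ch is not None]

    def tipset(self, node: int) -> frozenset[str]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            ch = self.children[v]
            if ch is None:
                out.append(self.labels[v])
            else:
                stack.extend(ch)
        return frozenset(out)

    def scaled(self, factor: float) -> "UltrametricTree":
        return UltrametricTree(
            list(self.labels), self.parent.copy(), list(self.children),
            self.height * factor,
        )


def _from_dendropy(tree: dendropy.Tree, tolerance: float) -> UltrametricTree:
    tree = tree.clone(depth=1)
    n_poly = sum(1 for nd in tree if len(nd.child_nodes()) > 2)
    if n_poly:
        warnings.warn(f"resolving {n_poly} polytomies with zero-length branches")
        tree.resolve_polytomies()
    tips = [lf for lf in tree.leaf_node_iter()]
    n = len(tips)
    if n < 2:
        raise GmycError("need >= 2 tips")
    # depths from root
    depth = {}
    for nd in tree.preorder_node_iter():
        depth[nd] = (0.0 if nd.parent_node is None
                     else depth[nd.parent_node] + (nd.edge.length or 0.0))
    tip_depths = np.array([depth[lf] for lf in tips])
    span = tip_depths.max()
    if span <= 0:
        raise GmycError("tree has zero height")
    if (tip_depths.max() - tip_depths.min()) > tolerance * span:
        raise GmycError(
            "tree is not ultrametric within tolerance "
            f"(tip depth spread {tip_depths.max() - tip_depths.min():.4g})"
        )
    labels = [lf.taxon.label if lf.taxon else f"t{i}" for i, lf in enumerate(tips)]
    index = {id(lf): i for i, lf in enumerate(tips)}
    internals = [nd for nd in tree.preorder_node_iter() if nd.child_nodes()]
    for k, nd in enumerate(internals):
        index[id(nd)] = n + k
    total = n + len(internals)
    parent = np.full(total, -1, dtype=int)
    children: list[tuple[int, int] | None] = [None] * total
    height = np.zeros(total)
    for nd in tree.preorder_node_iter():
        i = index[id(nd)]
        height[i] = max(span - depth[nd], 0.0)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        ch = nd.child_nodes()
        if ch:
            children[i] = (index[id(ch[0])], index[id(ch[1])])
    height[:n] = 0.0  # tips at the present exactly
    return UltrametricTree(labels, parent, children, height)


def read_tree(path, fmt: str = "newick", tolerance: float = 1e-3) -> UltrametricTree:
    """Read a rooted ultrametric tree from newick or NEXUS."""
    schema = "nexus" if fmt.lower() == "nexus" else "newick"
    tree = dendropy.Tree.get(path=str(path), schema=schema, preserve_underscores=True)
    return _from_dendropy(tree, tolerance)


def tree_from_string(newick: str, tolerance: float = 1e-3) -> UltrametricTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _from_dendropy(tree, tolerance)


def upgma_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> UltrametricTree:
    """UPGMA clock tree from a symmetric distance matrix; node heights are
    half the merge distance (distance units)."""
    dm = np.asarray(distance_matrix, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise GmycError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise GmycError("distance matrix must be symmetric")
    n = dm.shape[0]
    if n != len(labels):
        raise GmycError("labels do not match matrix size")
    if n == 1:
        return UltrametricTree([labels[0]], np.array([-1]), [None], np.zeros(1))
    link = average(squareform(dm, checks=False))
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    children: list[tuple[int, int] | None] = [None] * total
    height = np.zeros(total)
    for k, (a, b, dist, _) in enumerate(link):
        node = n + k
        a, b = int(a), int(b)
        children[node] = (a, b)
        parent[a] = parent[b] = node
        height[node] = dist / 2.0
    return UltrametricTree(list(labels), parent, children, height)


@dataclass
class GmycFit:
    lnL_null: float
    lnL_alt: float
    threshold_time: float
    lambda_yule: float
    p_yule: float
    lambda_coal: float
    p_coal: float
    entities: list[frozenset[str]]
    speciation_nodes: list[frozenset[str]]  # identified by their tip sets
    df: int = 3
    n_free_exponents: int = 2

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def LR(self) -> float:
        return 2.0 * (self.lnL_alt - self.lnL_null)

    @property
    def p_value(self) -> float:
        return float(chi2.sf(self.LR, self.df))

    @property
    def n_parameters(self) -> int:
        # lambda_yule, lambda_coal, free exponents, threshold
        return 3 + self.n_free_exponents


@dataclass
class GmycSupport:
    support: dict[frozenset[str], float]  # per speciation node (by tip set)
    cutoff: float
    entities: list[frozenset[str]]

    @property
    def n_entities(self) -> int:
        return len(self.entities)


# -- interval bookkeeping -----------------------------------------------------


def _interval_profile(tree: UltrametricTree, threshold: float):
    """Per inter-event interval: length x_i, species-level lineage count k_i,
    and S_i = sum_j n_j (n_j - 1) over putative species, for the species
    configuration implied by ``threshold`` (speciation nodes: height > T)."""
    internal = tree.internal_nodes()
    events = sorted(internal, key=lambda v: -tree.height[v])
    spec = {v for v in internal if tree.height[v] > threshold}

    # species root of every node (nearest ancestor-or-self not under a
    # speciation chain); species roots are children of speciation nodes
    # (or the root itself) that are not speciation nodes themselves.
    root = tree.root
    species_root: dict[int, int] = {}

    def assign(v: int, sp_root: int | None) -> None:
        stack = [(v, sp_root)]
        while stack:
            u, sr = stack.pop()
            if sr is None and u not in spec:
                sr = u
            if sr is not None:
                species_root[u] = sr
            ch = tree.children[u]
            if ch:
                stack.extend((c, sr) for c in ch)

    assign(root, None)

    heights = [tree.height[v] for v in events]
    n_events = len(events)
    x = np.empty(n_events)
    k = np.empty(n_events)
    S = np.empty(n_events)
    n_per_species: dict[int, int] = {}
    s_running = 0
    k_running = 1  # species-level lineages after processing events so far
    for i, v in enumerate(events):
        if v in spec:
            k_running += 1
        else:
            sr = species_root[v]
            prev = n_per_species.get(sr, 1)  # stem counts as one lineage
            s_running += (prev + 1) * prev - prev * (prev - 1)
            n_per_species[sr] = prev + 1
        x[i] = heights[i] - (heights[i + 1] if i + 1 < n_events else 0.0)
        k[i] = k_running
        S[i] = s_running
    return x, k, S


def _profile_lnl(x, k, S, log_ly, p_y, log_lc, p_c) -> float:
    ly, lc = np.exp(log_ly), np.exp(log_lc)
    yule = ly * np.power(k, p_y)
    coal = np.where(S > 0, lc * np.power(np.maximum(S, 1e-300), p_c), 0.0)
    b = yule + coal
    # events end every interval except the last
    if np.any(b[:-1] <= 0):
        return -np.inf
    lnl = float(np.sum(np.log(b[:-1]))) - float(np.sum(b * x))
    return lnl


def _fit_candidate(x, k, S, free_p: tuple[bool, bool]) -> tuple[float, np.ndarray]:
    """Maximize lnL over (log lambda_yule, p_yule, log lambda_coal, p_coal)."""
    n_events = len(x) - 0  # intervals; events = len(x) - 1
    exp_y = float(np.sum(k * x))
    exp_c = float(np.sum(S * x))
    e_total = max(len(x) - 1, 1)
    ly0 = np.log(max(e_total / max(exp_y, 1e-12), 1e-10))
    lc0 = np.log(max(e_total / max(exp_c, 1e-12), 1e-10)) if exp_c > 0 else -20.0
    free_y, free_c = free_p

    def unpack(theta):
        idx = 0
        log_ly = theta[idx]; idx += 1
        p_y = theta[idx] if free_y else 1.0
        idx += int(free_y)
        log_lc = theta[idx]; idx += 1
        p_c = theta[idx] if free_c else 1.0
        return log_ly, p_y, log_lc, p_c

    def neg(theta):
        val = _profile_lnl(x, k, S, *unpack(theta))
        return -val if np.isfinite(val) else 1e12

    bounds = [_LOGL_BOUNDS]
    if free_y:
        bounds.append(_P_BOUNDS)
    bounds.append(_LOGL_BOUNDS)
    if free_c:
        bounds.append(_P_BOUNDS)

    best = (-np.inf, None)
    for scale in (0.0, np.log(5.0), -np.log(5.0)):
        theta0 = []
        theta0.append(np.clip(ly0 + scale, *_LOGL_BOUNDS))
        if free_y:
            theta0.append(1.0)
        theta0.append(np.clip(lc0 + scale, *_LOGL_BOUNDS))
        if free_c:
            theta0.append(1.0)
        res = minimize(neg, np.array(theta0), method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "maxiter": 200})
        if -res.fun > best[0]:
            best = (-res.fun, res.x)
    lnl, theta = best
    if theta is None:
        raise GmycError("optimizer failed to converge")
    return lnl, np.array(unpack(theta))


def _candidate_thresholds(tree: UltrametricTree) -> list[float]:
    heights = sorted({float(tree.height[v]) for v in tree.internal_nodes()})
    return [0.0] + heights  # 0.0: all-singleton; max height: null (single species)


def entities_from_nodes(
    tree: UltrametricTree, speciation: set[int]
) -> list[frozenset[str]]:
    """Maximal subtrees containing no speciation node, as tip sets."""
    out: list[frozenset[str]] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if v in speciation and tree.children[v] is not None:
            stack.extend(tree.children[v])
        else:
            out.append(tree.tipset(v))
    return sorted(out, key=lambda s: sorted(s))


def gmyc_fit(
    tree: UltrametricTree,
    free_p: tuple[bool, bool] = (True, True),
    df: int = 3,
    candidate_thresholds: Sequence[float] | None = None,
) -> GmycFit:
    """Single-threshold GMYC fit with exhaustive threshold scan.

    ``free_p`` controls whether the Yule and coalescent rate exponents are
    estimated (True) or fixed at 1.  ``df`` is the degrees of freedom used
    for the chi-square likelihood-ratio test (the extra rate, exponent and
    threshold parameters of the mixed model; not prescribed by the model
    itself, hence configurable).
    """
    if tree.n_tips < 3:
        raise GmycError("need >= 3 tips")
    root_h = float(tree.height[tree.root])
    candidates = (
        sorted(set(candidate_thresholds))
        if candidate_thresholds is not None
        else _candidate_thresholds(tree)
    )

    # null: threshold at the root (single species, one coalescent class)
    xn, kn, Sn = _interval_profile(tree, root_h)
    lnl_null, _ = _fit_candidate(xn, kn, Sn, (False, free_p[1]))

    best = (-np.inf, None, None)
    for t in candidates:
        x, k, S = _interval_profile(tree, t)
        lnl, params = _fit_candidate(x, k, S, free_p)
        if lnl > best[0] + 1e-12:
            best = (lnl, t, params)
    lnl_alt, t_hat, params = best
    lnl_alt = max(lnl_alt, lnl_null)  # root candidate nests the null
    log_ly, p_y, log_lc, p_c = params
    spec_nodes = {v for v in tree.internal_nodes() if tree.height[v] > t_hat}
    entities = entities_from_nodes(tree, spec_nodes)
    return GmycFit(
        lnL_null=lnl_null,
        lnL_alt=lnl_alt,
        threshold_time=float(t_hat),
        lambda_yule=float(np.exp(log_ly)),
        p_yule=float(p_y),
        lambda_coal=float(np.exp(log_lc)),
        p_coal=float(p_c),
        entities=entities,
        speciation_nodes=[tree.tipset(v) for v in sorted(spec_nodes)],
        df=df,
        n_free_exponents=int(free_p[0]) + int(free_p[1]),
    )


DEFAULT_VARIANTS: tuple[tuple[bool, bool], ...] = (
    (True, True),
    (False, False),
    (True, False),
    (False, True),
)


def gmyc_support(
    tree: UltrametricTree,
    variants: Sequence[tuple[bool, bool]] = DEFAULT_VARIANTS,
    cutoff: float = 0.9,
    fits: Sequence[GmycFit] | None = None,
) -> GmycSupport:
    """Akaike-weighted per-node speciation support across model variants,
    with entities merged wherever support falls below ``cutoff``."""
    if not 0.0 < cutoff <= 1.0:
        raise GmycError("cutoff must be in (0, 1]")
    if fits is None:
        fits = [gmyc_fit(tree, free_p=v) for v in variants]
    if len(fits) < 2:
        raise GmycError("need >= 2 model variants")
    aic = np.array([2 * f.n_parameters - 2 * f.lnL_alt for f in fits])
    w = np.exp(-(aic - aic.min()) / 2.0)
    w /= w.sum()
    internal = tree.internal_nodes()
    support: dict[frozenset[str], float] = {}
    node_by_tipset = {tree.tipset(v): v for v in internal}
    for v in internal:
        ts = tree.tipset(v)
        s = sum(
            float(wi)
            for wi, f in zip(w, fits)
            if ts in set(f.speciation_nodes)
        )
        support[ts] = s
    supported = {
        node_by_tipset[ts] for ts, s in support.items() if s >= cutoff
    }
    entities = entities_from_nodes(tree, supported)
    return GmycSupport(support=support, cutoff=cutoff, entities=entities)
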