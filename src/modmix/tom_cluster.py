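"""Topological-overlap clustering of the partial-correlation network.

The adjacency is the unsigned partial correlation a_ij = |rho_ij|.  The
topological overlap between features i and j,

    t_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

measures how much of the network neighbourhood the pair shares; 1 - TOM
is the dissimilarity fed to average-linkage hierarchical clustering, and
the dendrogram is cut with the dynamic hybrid method (static height cut,
branch-shape criteria, optional PAM-like reassignment of leftovers).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .ggm import GlassoConfig, PartialCorrelationMatrix, estimate_ggm
from .io import AbundanceMatrix

logger = logging.getLogger("modmix")


@dataclass
class Adjacency:
    feature_ids: list[str]
    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (len(self.feature_ids),) * 2:
            raise ValueError("adjacency shape does not match feature_ids")
        if a.min(initial=0.0) < -1e-12 or a.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        if np.abs(np.diag(a)).max(initial=0.0) > 1e-12:
            raise ValueError("adjacency diagonal must be zero")
        self.a = a


@dataclass
class TOMatrix:
    feature_ids: list[str]
    t: np.ndarray


@dataclass
class Dendrogram:
    """Average-linkage merge tree (scipy linkage encoding)."""

    feature_ids: list[str]
    linkage: np.ndarray

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.feature_ids[node.id]
            left, right = node.get_left(), node.get_right()
            lh = node.dist - (0.0 if left.is_leaf() else left.dist)
            rh = node.dist - (0.0 if right.is_leaf() else right.dist)
            return f"({rec(left)}:{lh:g},{rec(right)}:{rh:g})"

        return rec(tree) + ";"


@dataclass
class ModuleAssignment:
    """feature -> module label; 0 means unassigned, labels 1..M are sorted
    by decreasing module size."""

    feature_ids: list[str]
    labels: np.ndarray
    module_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.feature_ids),):
            raise ValueError("labels length does not match feature_ids")
        if (self.labels < 0).any():
            raise ValueError("labels must be nonnegative")
        if not self.module_sizes:
            uniq, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
            self.module_sizes = {int(u): int(c) for u, c in zip(uniq, counts)}

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def members(self, label: int) -> list[str]:
        return [f for f, l in zip(self.feature_ids, self.labels) if l == label]


@dataclass
class CutConfig:
    """Dynamic hybrid tree-cut settings.

    min_module_size : smallest branch accepted as a module (default 10).
    deep_split : 0..4; higher values split more aggressively by relaxing
        the core-scatter ceiling and gap floor.
    cut_height : static cut height on the 1-TOM dendrogram (default 0.99).
    pam_stage : whether leftover features are joined to their nearest
        module by average dissimilarity.
    """

    min_module_size: int = 10
    deep_split: int = 2
    cut_height: float = 0.99
    pam_stage: bool = True

    def __post_init__(self) -> None:
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be an integer in 0..4")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must be in (0, 1]")


def adjacency_from_partial_corr(rho: PartialCorrelationMatrix) -> Adjacency:
    """Unsigned network: a_ij = |rho_ij| clipped to [0, 1], zero diagonal."""
    a = np.clip(np.abs(rho.rho), 0.0, 1.0)
    np.fill_diagonal(a, 0.0)
    return Adjacency(list(rho.feature_ids), a)


def correlation_adjacency(m: AbundanceMatrix, soft_power: int = 1) -> Adjacency:
    """Marginal-correlation baseline: a_ij = |cor(x_i, x_j)|^soft_power.

    Unlike the partial-correlation network this adjacency carries both
    direct and indirect associations, so it serves as the comparison mode
    for benchmarking module structure against the sparse network.
    """
    if soft_power < 1:
        raise ValueError("soft_power must be a positive integer")
    c = np.corrcoef(m.values)
    a = np.abs(np.clip(c, -1.0, 1.0)) ** soft_power
    np.fill_diagonal(a, 0.0)
    return Adjacency(list(m.feature_ids), a)


def compute_tom(adj: Adjacency) -> TOMatrix:
    """Topological overlap matrix; unit diagonal, entries in [0, 1]."""
    a = adj.a
    n = a.shape[0]
    if n == 1:
        return TOMatrix(list(adj.feature_ids), np.ones((1, 1)))
    # With a zero diagonal, (A @ A)_ij already equals sum_{u != i,j} a_iu a_uj.
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (L + a) / denom
    np.fill_diagonal(t, 1.0)
    t = (t + t.T) / 2.0
    return TOMatrix(list(adj.feature_ids), t)


def tom_dissimilarity(tom: TOMatrix) -> np.ndarray:
    d = 1.0 - tom.t
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def hierarchical_cluster(d: np.ndarray, feature_ids: list[str]) -> Dendrogram:
    """Average-linkage clustering of a dissimilarity matrix."""
    d = np.asarray(d, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    z = sch.linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    return Dendrogram(list(feature_ids), z)


# deep_split -> maximum normalized core scatter of an accepted branch;
# the minimum gap is (1 - maxCoreScatter) * 3/4 on the same scale.
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


def _subtree_members(z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf sets of each internal node, as sorted index arrays."""
    members: list[np.ndarray] = []
    for a, b in z[:, :2].astype(int):
        left = members[a - n] if a >= n else np.array([a])
        right = members[b - n] if b >= n else np.array([b])
        members.append(np.sort(np.concatenate([left, right])))
    return members


def cutree_hybrid(dend: Dendrogram, d: np.ndarray, cfg: CutConfig | None = None) -> ModuleAssignment:
    """Dynamic hybrid cut of the dendrogram into modules.

    Candidate branches come from a static cut at ``cut_height``; each is
    kept only if it has at least ``min_module_size`` members, its core is
    tight (core scatter below a deep_split-dependent ceiling) and it is
    separated from the rest of the tree (merge gap above a floor).  With
    ``pam_stage`` the leftovers are joined to the module with the smallest
    average dissimilarity, provided that module is a unique nearest one
    and no farther than the cut height.  Surviving modules are labelled
    1..M by decreasing size; everything else is 0.
    """
    cfg = cfg or CutConfig()
    n = len(dend.feature_ids)
    if cfg.min_module_size > n:
        logger.warning("cutree_hybrid: min_module_size %d exceeds feature count %d; "
                       "all features unassigned", cfg.min_module_size, n)
        return ModuleAssignment(list(dend.feature_ids), np.zeros(n, dtype=int))

    z = dend.linkage
    static = sch.fcluster(z, t=cfg.cut_height, criterion="distance")
    members = _subtree_members(z, n)
    heights = z[:, 2]
    # Reference height anchoring the shape criteria.  The median merge
    # height below the cut is used rather than a low quantile: sparse
    # partial-correlation networks put most merges close to the cut
    # height, and a single unusually tight branch would otherwise drag
    # the core-scatter ceiling below every genuine module.
    below = heights[heights < cfg.cut_height]
    h_base = float(np.median(below)) if below.size else float(heights.min(initial=0.0))
    h_ref = max(cfg.cut_height - h_base, 1e-12)
    max_scatter = h_base + _MAX_CORE_SCATTER[cfg.deep_split] * h_ref
    min_gap = (1.0 - _MAX_CORE_SCATTER[cfg.deep_split]) * 0.75 * h_ref

    # Height at which each static branch (a maximal subtree below the cut)
    # attaches to the rest of the tree.
    subtree_height: dict[frozenset, float] = {}
    for i, idx in enumerate(members):
        subtree_height[frozenset(idx.tolist())] = float(heights[i])

    labels = np.zeros(n, dtype=int)
    accepted: list[np.ndarray] = []
    for cl in np.unique(static):
        idx = np.flatnonzero(static == cl)
        if idx.size < cfg.min_module_size:
            continue
        sub = d[np.ix_(idx, idx)]
        # Core = tightest min_module_size members (lowest average intra-branch
        # dissimilarity); its mean pairwise dissimilarity is the core scatter.
        avg_intra = sub.sum(axis=1) / max(idx.size - 1, 1)
        core_size = min(idx.size, cfg.min_module_size)
        core = np.argsort(avg_intra, kind="stable")[:core_size]
        if core_size > 1:
            core_sub = sub[np.ix_(core, core)]
            core_scatter = core_sub.sum() / (core_size * (core_size - 1))
        else:
            core_scatter = 0.0
        key = frozenset(idx.tolist())
        if key in subtree_height:
            # Attach height = height of the smallest internal node strictly
            # containing this branch (linkage heights are monotone).
            parent = [i for i, mem in enumerate(members)
                      if mem.size > idx.size and idx[0] in mem and np.isin(idx, mem).all()]
            attach = float(heights[min(parent)]) if parent else max(
                float(heights.max(initial=cfg.cut_height)), cfg.cut_height)
        else:  # branch is a single leaf; treat the cut height as its attach point
            attach = cfg.cut_height
        gap = attach - core_scatter
        if core_scatter <= max_scatter and gap >= min_gap:
            accepted.append(idx)

    if cfg.pam_stage and accepted:
        assigned = np.concatenate(accepted)
        left = np.setdiff1d(np.arange(n), assigned)
        if left.size:
            avg_d = np.stack([d[np.ix_(left, idx)].mean(axis=1) for idx in accepted], axis=1)
            order = np.argsort(avg_d, axis=1, kind="stable")
            best = order[:, 0]
            best_d = avg_d[np.arange(left.size), best]
            if avg_d.shape[1] > 1:
                second_d = avg_d[np.arange(left.size), order[:, 1]]
            else:
                second_d = np.full(left.size, np.inf)
            join = (best_d < second_d) & (best_d <= cfg.cut_height)
            extras: list[list[int]] = [[] for _ in accepted]
            for pos in np.flatnonzero(join):
                extras[best[pos]].append(int(left[pos]))
            accepted = [np.sort(np.concatenate([idx, np.array(ex, dtype=int)])) if ex else idx
                        for idx, ex in zip(accepted, extras)]

    # Label modules by decreasing size (stable for ties).
    accepted.sort(key=lambda idx: -idx.size)
    for label, idx in enumerate(accepted, start=1):
        labels[idx] = label
    return ModuleAssignment(list(dend.feature_ids), labels)


def modules_from_adjacency(adj: Adjacency, cut_cfg: CutConfig | None = None
                           ) -> tuple[ModuleAssignment, Dendrogram, TOMatrix]:
    """Adjacency -> TOM -> average-linkage tree -> hybrid cut."""
    tom = compute_tom(adj)
    d = tom_dissimilarity(tom)
    dend = hierarchical_cluster(d, list(adj.feature_ids))
    assign = cutree_hybrid(dend, d, cut_cfg)
    return assign, dend, tom


def modules_from_matrix(m: AbundanceMatrix, glasso_cfg: GlassoConfig | None = None,
                        cut_cfg: CutConfig | None = None,
                        precomputed: PartialCorrelationMatrix | None = None
                        ) -> tuple[ModuleAssignment, Dendrogram, TOMatrix, PartialCorrelationMatrix]:
    """Full per-dataset chain: GGM -> |rho| adjacency -> TOM -> modules."""
    rho = estimate_ggm(m, glasso_cfg, precomputed=precomputed)
    assign, dend, tom = modules_from_adjacency(adjacency_from_partial_corr(rho), cut_cfg)
    return assign, dend, tom, rho


def module_size_stats(assign: ModuleAssignment) -> tuple[int, float, float, float]:
    """(n_modules, mean size, SD of sizes, fraction unassigned)."""
    sizes = np.array(sorted(assign.module_sizes.values()), dtype=float)
    n = len(assign.feature_ids)
    frac_unassigned = float((assign.labels == 0).mean()) if n else 0.0
    if sizes.size == 0:
        return 0, 0.0, 0.0, frac_unassigned
    sd = float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0
    return int(sizes.size), float(sizes.mean()), sd, frac_unassigned


def lambda_grid_scan(m: AbundanceMatrix, lambdas: list[float],
                     cut_cfg: CutConfig | None = None,
                     glasso_base: GlassoConfig | None = None) -> pd.DataFrame:
    """Run the GGM->TOM->cut chain per lambda and tabulate module statistics."""
    if not lambdas:
        raise ValueError("need at least one lambda value")
    base = glasso_base or GlassoConfig()
    rows = []
    for lam in lambdas:
        t0 = time.perf_counter()
        cfg = GlassoConfig(lam=lam, max_iter=base.max_iter, tol=base.tol)
        assign, _, _, _ = modules_from_matrix(m, cfg, cut_cfg)
        n_mod, mean_size, sd_size, frac_un = module_size_stats(assign)
        rows.append({"lam": lam, "n_modules": n_mod, "mean_size": mean_size,
                     "sd_size": sd_size, "frac_unassigned": frac_un,
                     "runtime_s": time.perf_counter() - t0})
    return pd.DataFrame(rows)
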