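"""Horizontal multi-omics integration: Spearman correlation of module
eigenfeatures across datasets, ranking of module pairs, and per-pair
feature reports.

All module pairs between two datasets are correlated (rank transform with
average ranks, Pearson on ranks, two-sided t-approximation p-value);
Benjamini-Hochberg q-values are computed over the full pair list because
the all-pairs scan inflates false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .eigenfeatures import EigenfeatureSet
from .io import AbundanceMatrix, FeatureAnnotation, SampleMetadata
from .tom_cluster import ModuleAssignment

logger = logging.getLogger("modmix")


@dataclass
class CrossOmicsEdge:
    dataset_a: str
    module_a: int
    dataset_b: str
    module_b: int
    rho: float
    p_value: float
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.dataset_a == self.dataset_b:
            raise ValueError("cross-omics edges must link different datasets")
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")


def _spearman_all_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every row pair of a (Ma x n) vs b (Mb x n)."""
    n = a.shape[1]
    ra = np.apply_along_axis(stats.rankdata, 1, a)
    rb = np.apply_along_axis(stats.rankdata, 1, b)
    ra = (ra - ra.mean(axis=1, keepdims=True))
    rb = (rb - rb.mean(axis=1, keepdims=True))
    na = np.linalg.norm(ra, axis=1)
    nb = np.linalg.norm(rb, axis=1)
    rho = (ra @ rb.T) / np.outer(na, nb)
    np.clip(rho, -1.0, 1.0, out=rho)
    # t-approximation, matching the standard two-sided Spearman test
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 0.0, p)  # |rho| == 1 -> p = 0
    return rho, p


def correlate_eigenfeatures(e1: EigenfeatureSet, e2: EigenfeatureSet) -> list[CrossOmicsEdge]:
    """All M1 x M2 Spearman correlations between two datasets' eigenfeatures.

    Requires identical sample sets in identical order (use io.align_samples
    upstream); fewer than 4 shared samples is an error because the Spearman
    p-value is unstable there.
    """
    if list(e1.sample_ids) != list(e2.sample_ids):
        raise ValueError("eigenfeature sets have different samples/order; align first")
    if len(e1.sample_ids) < 4:
        raise ValueError("need at least 4 shared samples for Spearman correlation")
    rho, p = _spearman_all_pairs(e1.scores, e2.scores)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    edges = []
    for i, la in enumerate(e1.module_labels):
        for j, lb in enumerate(e2.module_labels):
            edges.append(CrossOmicsEdge(e1.dataset_name, la, e2.dataset_name, lb,
                                        float(rho[i, j]), float(p[i, j]), float(q[i, j])))
    return edges


def integrate_all(eigensets: list[EigenfeatureSet]) -> list[CrossOmicsEdge]:
    """All pairwise dataset blocks in one edge list (q-values recomputed
    jointly across every block)."""
    edges: list[CrossOmicsEdge] = []
    for ea, eb in combinations(eigensets, 2):
        edges.extend(correlate_eigenfeatures(ea, eb))
    if edges:
        q = multipletests(np.array([e.p_value for e in edges]), method="fdr_bh")[1]
        for e, qv in zip(edges, q):
            e.q_value = float(qv)
    return edges


def top_correlations(edges: list[CrossOmicsEdge], k: int) -> list[CrossOmicsEdge]:
    """The K strongest module pairs by |rho| (ties broken lexicographically)."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > len(edges):
        logger.warning("top_correlations: K=%d exceeds %d edges; returning all", k, len(edges))
        k = len(edges)
    ordered = sorted(edges, key=lambda e: (-abs(e.rho), e.dataset_a, e.module_a, e.module_b))
    return ordered[:k]


def edges_to_frame(edges: list[CrossOmicsEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"dataset_a": e.dataset_a, "module_a": e.module_a,
          "dataset_b": e.dataset_b, "module_b": e.module_b,
          "rho": e.rho, "p": e.p_value, "q": e.q_value} for e in edges],
        columns=["dataset_a", "module_a", "dataset_b", "module_b", "rho", "p", "q"],
    )


def _module_feature_table(m: AbundanceMatrix, assign: ModuleAssignment, label: int,
                          annotation: FeatureAnnotation | None,
                          metadata: SampleMetadata | None,
                          grouping: str | None) -> pd.DataFrame:
    from .phenotype import feature_level_tests  # local import to avoid a cycle

    features = assign.members(label)
    df = pd.DataFrame({"feature_id": features})
    if annotation is not None:
        ann = annotation.lookup(features)
        ann.index = df.index
        df = pd.concat([df, ann], axis=1)
    if metadata is not None and grouping is not None:
        tests = feature_level_tests(m, assign, label, metadata, grouping)
        df = df.merge(tests, on="feature_id", how="left")
    return df


def module_pair_report(
    edge: CrossOmicsEdge,
    matrices: dict[str, AbundanceMatrix],
    assignments: dict[str, ModuleAssignment],
    annotations: dict[str, FeatureAnnotation] | None = None,
    metadata: SampleMetadata | None = None,
    grouping: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Feature listings (with annotation and optional per-feature Welch
    tests) for both modules of a correlated cross-omics pair."""
    annotations = annotations or {}
    out = {}
    for ds, label in ((edge.dataset_a, edge.module_a), (edge.dataset_b, edge.module_b)):
        out[ds] = _module_feature_table(
            matrices[ds], assignments[ds], label,
            annotations.get(ds), metadata, grouping,
        )
    return out
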