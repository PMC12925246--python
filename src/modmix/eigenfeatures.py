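"""Module eigenfeatures: each module is summarized by the first principal
component of its (standardized) member features across samples.

The eigenfeature is rescaled to mean 0 / SD 1 so that cross-omics
correlations are scale-free, and its sign is fixed so that it correlates
non-negatively with the per-sample mean profile of the module (PC sign is
otherwise arbitrary).  Per-feature loadings (left singular-vector weights)
and module memberships (kME, the Pearson correlation of a feature with
its module eigenfeature) are both reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix
from .tom_cluster import ModuleAssignment

logger = logging.getLogger("modmix")


@dataclass
class EigenfeatureSet:
    """First-PC summaries for every module of one dataset."""

    dataset_name: str
    module_labels: list[int]
    sample_ids: list[str]
    scores: np.ndarray  # modules x samples, each row mean 0 / SD 1
    var_explained: dict[int, float]
    loadings: pd.DataFrame     # columns: module, feature_id, loading
    memberships: pd.DataFrame  # columns: module, feature_id, kME

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores,
                            index=[f"M{l}" for l in self.module_labels],
                            columns=self.sample_ids)

    def module_scores(self, label: int) -> np.ndarray:
        return self.scores[self.module_labels.index(label)]


def _standardize_vector(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant eigenfeature (degenerate module)")
    return (v - v.mean()) / sd


def compute_eigenfeature(submatrix: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """First PC of a module's features x samples block.

    Returns (scores, var_explained, loadings): scores is the first right
    singular direction rescaled to mean 0 / SD 1; var_explained is
    sigma_1^2 / sum_k sigma_k^2; loadings are the first left singular
    vector entries.  The sign is flipped so the scores correlate
    non-negatively with the per-sample mean of the module (falling back
    to a non-negative first loading on exact ties).
    """
    x = np.asarray(submatrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 3:
        raise ValueError("need a 2-D block with >=1 feature and >=3 samples")
    if np.allclose(x, x[:, :1]):
        raise ValueError("constant module submatrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = vt[0]
    loadings = u[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    mean_profile = x.mean(axis=0)
    orient = float(np.dot(scores - scores.mean(), mean_profile - mean_profile.mean()))
    if orient < 0 or (orient == 0 and loadings[0] < 0):
        scores = -scores
        loadings = -loadings
    return _standardize_vector(scores), var_explained, loadings


def eigenfeatures_for_all(m: AbundanceMatrix, assign: ModuleAssignment,
                          dataset_name: str | None = None) -> EigenfeatureSet:
    """Eigenfeatures for every module label >= 1 (label 0 is skipped).

    Modules whose features are all constant are dropped with a warning.
    kME is the Pearson correlation of each member feature with the module
    eigenfeature.
    """
    if list(m.feature_ids) != list(assign.feature_ids):
        raise ValueError("assignment features do not match the matrix")
    labels_out: list[int] = []
    scores_rows: list[np.ndarray] = []
    var_explained: dict[int, float] = {}
    load_rows: list[dict] = []
    kme_rows: list[dict] = []
    for label in sorted(assign.module_sizes):
        idx = np.flatnonzero(assign.labels == label)
        sub = m.values[idx]
        try:
            scores, ve, loadings = compute_eigenfeature(sub)
        except ValueError as exc:
            logger.warning("module %d dropped: %s", label, exc)
            continue
        labels_out.append(label)
        scores_rows.append(scores)
        var_explained[label] = ve
        centered = sub - sub.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        sc_centered = scores - scores.mean()
        sc_norm = np.linalg.norm(sc_centered)
        for j, fi in enumerate(idx):
            fid = m.feature_ids[fi]
            load_rows.append({"module": label, "feature_id": fid, "loading": float(loadings[j])})
            kme = float(centered[j] @ sc_centered / (norms[j] * sc_norm)) if norms[j] > 0 else 0.0
            kme_rows.append({"module": label, "feature_id": fid, "kME": max(-1.0, min(1.0, kme))})
    if not labels_out:
        raise ValueError("no usable modules (all empty or constant)")
    return EigenfeatureSet(
        dataset_name=dataset_name or m.omics_name,
        module_labels=labels_out,
        sample_ids=list(m.sample_ids),
        scores=np.vstack(scores_rows),
        var_explained=var_explained,
        loadings=pd.DataFrame(load_rows, columns=["module", "feature_id", "loading"]),
        memberships=pd.DataFrame(kme_rows, columns=["module", "feature_id", "kME"]),
    )


def write_eigenfeatures(es: EigenfeatureSet, scores_path, loadings_path=None) -> None:
    """Scores as modules x samples TSV; loadings/kME as long-format TSV."""
    with open(scores_path, "w", encoding="utf-8", newline="\n") as fh:
        es.scores_frame().to_csv(fh, sep="\t", index_label="module")
    if loadings_path is not None:
        merged = es.loadings.merge(es.memberships, on=["module", "feature_id"])
        with open(loadings_path, "w", encoding="utf-8", newline="\n") as fh:
            merged.to_csv(fh, sep="\t", index=False)
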