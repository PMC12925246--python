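"""Association of module eigenfeatures (and member features) with sample
groupings.

Two-level groupings use Welch's unequal-variance t-test; groupings with
more than two levels use the Kruskal-Wallis test, avoiding a normality
assumption on eigenfeature scores.  Benjamini-Hochberg adjustment is
applied across modules within one grouping (each grouping is treated as
its own hypothesis family); a module is flagged significant when its
q-value (or raw p with ``use_raw_p``) falls at or below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .eigenfeatures import EigenfeatureSet
from .io import AbundanceMatrix, SampleMetadata
from .tom_cluster import ModuleAssignment

logger = logging.getLogger("modmix")


@dataclass
class ModulePhenotypeResult:
    module_label: int
    grouping_name: str
    test_name: str  # "welch_t" or "kruskal_wallis"
    statistic: float
    p_value: float
    q_value: float
    group_means: dict[str, float]
    significant: bool
    zero_variance: bool = False


def _split_by_group(values: np.ndarray, groups: pd.Series) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    g = np.asarray(groups.astype(str))
    for level in pd.unique(g):
        out[level] = values[g == level]
    return out


def _test_one(values: np.ndarray, groups: pd.Series) -> tuple[str, float, float, dict[str, float], bool]:
    by_group = _split_by_group(values, groups)
    levels = list(by_group)
    for level, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"grouping level {level!r} has fewer than 2 samples")
    means = {level: float(v.mean()) for level, v in by_group.items()}
    if all(np.ptp(v) == 0 for v in by_group.values()) and len({v[0] for v in by_group.values()}) == 1:
        # no variance anywhere: the test statistic is undefined
        return ("welch_t" if len(levels) == 2 else "kruskal_wallis"), 0.0, 1.0, means, True
    if len(levels) == 2:
        stat, p = stats.ttest_ind(by_group[levels[0]], by_group[levels[1]], equal_var=False)
        name = "welch_t"
    else:
        stat, p = stats.kruskal(*by_group.values())
        name = "kruskal_wallis"
    if np.isnan(p):
        return name, 0.0, 1.0, means, True
    return name, float(stat), float(p), means, False


def associate_modules(
    e: EigenfeatureSet,
    meta: SampleMetadata,
    grouping: str,
    alpha: float = 0.05,
    use_raw_p: bool = False,
) -> list[ModulePhenotypeResult]:
    """Test every module eigenfeature against one sample grouping."""
    groups = meta.group_values(grouping, e.sample_ids)
    if groups.astype(str).nunique() < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than 2 levels")
    rows = []
    for label, scores in zip(e.module_labels, e.scores):
        name, stat, p, means, zero_var = _test_one(scores, groups)
        rows.append((label, name, stat, p, means, zero_var))
    q = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = []
    for (label, name, stat, p, means, zero_var), qv in zip(rows, q):
        crit = p if use_raw_p else qv
        results.append(ModulePhenotypeResult(
            module_label=label, grouping_name=grouping, test_name=name,
            statistic=stat, p_value=p, q_value=float(qv), group_means=means,
            significant=bool(crit <= alpha), zero_variance=zero_var))
    return results


def feature_level_tests(
    m: AbundanceMatrix,
    assign: ModuleAssignment,
    module_label: int,
    meta: SampleMetadata,
    grouping: str,
) -> pd.DataFrame:
    """Welch t-test per member feature of one module, BH within the module.

    Constant features get p = 1 with a zero-variance flag.  The grouping
    must have exactly 2 levels.
    """
    if module_label not in assign.module_sizes and module_label != 0:
        raise ValueError(f"module {module_label} does not exist")
    groups = meta.group_values(grouping, m.sample_ids)
    if groups.astype(str).nunique() != 2:
        raise ValueError("feature-level t-tests require a 2-level grouping")
    idx = np.flatnonzero(assign.labels == module_label)
    rows = []
    for fi in idx:
        name, stat, p, means, zero_var = _test_one(m.values[fi], groups)
        rows.append({"feature_id": m.feature_ids[fi], "t": stat, "p": p,
                     "zero_variance": zero_var, **{f"mean_{k}": v for k, v in means.items()}})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def results_to_frame(results: list[ModulePhenotypeResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "module": r.module_label, "grouping": r.grouping_name, "test": r.test_name,
        "statistic": r.statistic, "p": r.p_value, "q": r.q_value,
        "significant": r.significant, "zero_variance": r.zero_variance,
        **{f"mean_{k}": v for k, v in r.group_means.items()},
    } for r in results])


def boxplot_export(scores: np.ndarray, sample_ids: list[str], meta: SampleMetadata,
                   grouping: str, path, image_path=None) -> pd.DataFrame:
    """Write the long-format (sample, group, value) table behind a boxplot.

    The TSV is the contract; the static image is produced only if
    matplotlib is importable, and failures there are non-fatal.
    """
    groups = meta.group_values(grouping, sample_ids)
    df = pd.DataFrame({"sample": sample_ids,
                       "group": groups.astype(str).to_numpy(),
                       "value": np.asarray(scores, dtype=float)})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False)
    if image_path is not None:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 3))
            df.boxplot(column="value", by="group", ax=ax)
            ax.set_ylabel("eigenfeature score")
            fig.suptitle("")
            fig.tight_layout()
            fig.savefig(image_path)
            plt.close(fig)
        except Exception as exc:  # pragma: no cover - best-effort plotting
            logger.warning("boxplot image skipped: %s", exc)
    return df
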