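"""Reading and writing abundance matrices, metadata, annotations and networks.

All tabular I/O is CSV/TSV (delimiter inferred from the file extension,
overridable); networks are exported as edge-list TSV or GraphML.  The
canonical in-memory orientation of an abundance matrix is features x
samples; both file orientations are accepted via a flag.  Writers emit
UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("modmix")

#: Cell contents (case-insensitive, surrounding whitespace ignored) parsed
#: as missing values.  Covers both R ("NA") and Python ("nan") CSV dialects.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Node styling per dataset index (1-based) used in network exports.
DATASET_STYLES = {1: ("diamond", "yellow"), 2: ("triangle", "green"), 3: ("circle", "blue")}


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".txt", ".tab"} else ","


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what} IDs: {', '.join(map(str, dups.index[:10]))}")


@dataclass
class AbundanceMatrix:
    """A quantitative omics table: features x samples, NaN marks missing."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    omics_name: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def select_features(self, keep: np.ndarray) -> "AbundanceMatrix":
        """Return a copy restricted to the boolean/index mask ``keep`` (row order kept)."""
        idx = np.arange(self.n_features)[keep] if np.asarray(keep).dtype == bool else np.asarray(keep)
        return AbundanceMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx].copy(),
            self.omics_name,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx].copy(), self.omics_name)


@dataclass
class SampleMetadata:
    """Sample IDs plus one or more categorical grouping columns."""

    sample_ids: list[str]
    groupings: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        if self.groupings.shape[1] < 1:
            raise ValueError("metadata has no grouping column")

    def group_values(self, grouping: str, sample_ids: Sequence[str] | None = None) -> pd.Series:
        if grouping not in self.groupings.columns:
            raise KeyError(f"unknown grouping column {grouping!r}")
        col = self.groupings[grouping]
        return col.loc[list(sample_ids)] if sample_ids is not None else col

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(list(sample_ids), self.groupings.loc[list(sample_ids)].copy())


@dataclass
class FeatureAnnotation:
    """Optional per-feature annotations; unidentified features simply lack rows."""

    table: pd.DataFrame  # indexed by feature_id; all columns optional strings

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "feature")

    def lookup(self, feature_ids: Sequence[str]) -> pd.DataFrame:
        """Annotation rows aligned to ``feature_ids``; blanks where unannotated."""
        out = self.table.reindex(feature_ids)
        return out.fillna("")


def _parse_numeric(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    """Convert a string-valued frame to float with strict missing-token handling."""
    raw = df.to_numpy(dtype=object)
    flat = pd.Series(raw.ravel(), dtype=object).astype(str).str.strip()
    missing = flat.str.lower().isin(MISSING_TOKENS).to_numpy()
    cleaned = flat.to_numpy(dtype=object)
    cleaned[missing] = "nan"
    try:
        # numpy's string->float conversion is correctly rounded, so written
        # values round-trip bit-for-bit
        numeric = cleaned.astype(np.float64)
    except ValueError:
        for pos, token in enumerate(cleaned):
            if missing[pos]:
                continue
            try:
                float(token)
            except ValueError:
                i, j = divmod(pos, df.shape[1])
                raise ValueError(
                    f"{path}: non-numeric value {token!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
        raise
    return numeric.reshape(raw.shape)


def read_abundance_matrix(
    path: str | Path,
    orientation: str = "features_in_rows",
    delimiter: str | None = None,
    omics_name: str | None = None,
) -> AbundanceMatrix:
    """Read a feature x sample (or sample x feature) table into canonical form.

    The first column holds row IDs; empty cells and the tokens NA/NaN
    (any case) are parsed as missing.  Duplicate IDs or non-numeric cells
    are hard errors.
    """
    if orientation not in {"features_in_rows", "samples_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    values = _parse_numeric(df, path)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "samples_in_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    name = omics_name if omics_name is not None else Path(path).stem
    return AbundanceMatrix(row_ids, col_ids, values, name)


def write_abundance_matrix(m: AbundanceMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        # %.17g guarantees bit-exact float round-trips
        m.to_frame().to_csv(fh, sep=sep, index_label="Feature_ID", na_rep="NA",
                            float_format="%.17g")


def read_metadata(path: str | Path, delimiter: str | None = None, sample_col: str | None = None) -> SampleMetadata:
    """Read the sample metadata table (sample-ID column plus >=1 grouping column)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: no grouping column (need a sample-ID column plus >=1 grouping)")
    id_col = sample_col if sample_col is not None else df.columns[0]
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing sample-ID column {id_col!r}")
    sample_ids = [str(s) for s in df[id_col]]
    _check_unique(sample_ids, "sample")
    groupings = df.drop(columns=[id_col]).astype("category")
    groupings.index = pd.Index(sample_ids)
    return SampleMetadata(sample_ids, groupings)


def read_annotation(path: str | Path, delimiter: str | None = None) -> FeatureAnnotation:
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.map(str)
    return FeatureAnnotation(df)


def align_samples(
    matrices: Sequence[AbundanceMatrix], metadata: SampleMetadata
) -> tuple[list[AbundanceMatrix], SampleMetadata]:
    """Restrict matrices and metadata to shared samples, in metadata order.

    The intersection of all sample-ID sets defines the analysis samples;
    their order follows the metadata file, which anchors the integration.
    Idempotent.  An empty intersection is a hard error.
    """
    if not matrices:
        raise ValueError("align_samples requires at least one matrix")
    shared = set(metadata.sample_ids)
    for m in matrices:
        shared &= set(m.sample_ids)
    if not shared:
        raise ValueError("no samples shared across all matrices and the metadata")
    order = [s for s in metadata.sample_ids if s in shared]
    for m in matrices:
        dropped = sorted(set(m.sample_ids) - shared)
        if dropped:
            logger.warning("align_samples: dropping %d sample(s) from %s: %s",
                           len(dropped), m.omics_name, ", ".join(dropped[:10]))
    meta_dropped = sorted(set(metadata.sample_ids) - shared)
    if meta_dropped:
        logger.warning("align_samples: dropping %d sample(s) from metadata: %s",
                       len(meta_dropped), ", ".join(meta_dropped[:10]))
    return [m.select_samples(order) for m in matrices], metadata.select_samples(order)


def write_module_table(
    assignment,  # ModuleAssignment (tom_cluster); duck-typed to avoid a cycle
    annotation: FeatureAnnotation | None,
    path: str | Path,
) -> None:
    """Write a TSV of feature -> module label, deterministically ordered.

    Rows sorted by module label then feature ID; unassigned features carry
    label 0; annotation columns are blank for unidentified features.
    """
    df = pd.DataFrame({"feature_id": assignment.feature_ids, "module_label": assignment.labels})
    if annotation is not None:
        ann = annotation.lookup(df["feature_id"])
        ann.index = df.index
        df = pd.concat([df, ann], axis=1)
    df = df.sort_values(["module_label", "feature_id"], kind="mergesort").reset_index(drop=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_square_matrix(path: str | Path, delimiter: str | None = None) -> tuple[list[str], np.ndarray]:
    """Read a square feature x feature CSV (header row/column of feature IDs)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column feature IDs differ")
    return [str(x) for x in df.index], df.to_numpy(dtype=float)


def write_square_matrix(feature_ids: Sequence[str], mat: np.ndarray, path: str | Path,
                        delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        pd.DataFrame(mat, index=feature_ids, columns=feature_ids).to_csv(fh, sep=sep)


def _node_name(dataset: str, module: int) -> str:
    return f"{dataset}:M{module}"


def write_network(
    edges: Iterable,  # CrossOmicsEdge (integrate)
    node_attrs: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
    format: str = "graphml",
    dataset_order: Sequence[str] | None = None,
) -> None:
    """Export the cross-omics module network.

    Nodes are styled by dataset index: dataset 1 yellow diamonds, dataset 2
    green triangles, dataset 3 blue circles (later datasets reuse the last
    style).  Edges carry Spearman rho and its p-value.
    """
    if format not in {"tsv", "graphml"}:
        raise ValueError(f"unknown network format {format!r}")
    edges = list(edges)
    if dataset_order is None:
        seen: dict[str, None] = {}
        for e in edges:
            seen.setdefault(e.dataset_a)
            seen.setdefault(e.dataset_b)
        dataset_order = list(seen)
    ds_index = {name: i + 1 for i, name in enumerate(dataset_order)}

    g = nx.Graph()
    for e in edges:
        for ds, mod in ((e.dataset_a, e.module_a), (e.dataset_b, e.module_b)):
            node = _node_name(ds, mod)
            if node not in g:
                idx = ds_index.get(ds, len(ds_index))
                shape, color = DATASET_STYLES.get(min(idx, 3), DATASET_STYLES[3])
                attrs = {"dataset_name": ds, "module": int(mod), "shape": shape, "color": color}
                if node_attrs and node in node_attrs:
                    attrs.update(node_attrs[node])
                g.add_node(node, **attrs)
        g.add_edge(_node_name(e.dataset_a, e.module_a), _node_name(e.dataset_b, e.module_b),
                   rho=float(e.rho), p_value=float(e.p_value), q_value=float(e.q_value))

    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        rows = [
            {"source": u, "target": v, **{k: d[k] for k in ("rho", "p_value", "q_value")}}
            for u, v, d in g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "rho", "p_value", "q_value"])
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index=False)
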