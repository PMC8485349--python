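"""Abundance-matrix containers, TSV input/output, autoscaling and
comparison-design subsetting.

The universal input of the pipeline is a samples x proteins abundance
matrix with per-sample metadata (animal, gender, timepoint, technical
replicate).  Everything downstream — univariate screening, PCA, the
self-organizing map and PLS-DA — consumes either the raw matrix or its
autoscaled form.

File dialect: tab-separated UTF-8, samples as rows, a ``sample_id``
header cell naming the identifier column.  Values are written at full
``repr`` precision so a write/read cycle is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceDataset",
    "ComparisonDesign",
    "ScaledMatrix",
    "read_dataset",
    "write_dataset",
    "read_phenotypes",
    "write_phenotypes",
    "autoscale",
    "subset_for_design",
]

METADATA_COLUMNS = ("animal_id", "gender", "timepoint", "tech_rep")


@dataclass
class AbundanceDataset:
    """A samples x proteins abundance matrix with per-sample metadata.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample labels, one per row (technical-replicate level).
    metadata : pandas.DataFrame
        Indexed by sample id with columns ``animal_id``, ``gender``,
        ``timepoint`` and ``tech_rep``.
    protein_ids : list of str
        Unique protein/gene identifiers, one per column.
    values : numpy.ndarray
        Positive abundances, shape ``(n_samples, n_proteins)``.
    """

    sample_ids: list[str]
    metadata: pd.DataFrame
    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample_ids: {dupes}")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = sorted({p for p in self.protein_ids if self.protein_ids.count(p) > 1})
            raise ValueError(f"duplicate protein_ids: {dupes}")
        if self.values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.protein_ids)} proteins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if len(self.metadata) != len(self.sample_ids):
            raise ValueError(
                f"metadata has {len(self.metadata)} rows for {len(self.sample_ids)} samples"
            )
        missing = set(self.sample_ids) - set(self.metadata.index.astype(str))
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)}")
        # align metadata row order with the matrix
        self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def timepoints(self) -> pd.Series:
        return self.metadata["timepoint"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.protein_ids)

    def select_samples(self, mask_or_ids: Sequence) -> "AbundanceDataset":
        """Row-subset by boolean mask or explicit sample-id list."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in mask_or_ids], dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        return AbundanceDataset(
            sample_ids=ids,
            metadata=self.metadata.iloc[idx].copy(),
            protein_ids=list(self.protein_ids),
            values=self.values[idx],
        )


@dataclass(frozen=True)
class ComparisonDesign:
    """A two-class contrast defined on timepoint labels.

    ``class_a`` is the earlier condition and ``class_b`` the later one,
    so that fold changes and PLS-DA coefficient signs read as
    "up/down with aging".
    """

    name: str
    class_a: frozenset[str]
    class_b: frozenset[str]

    def __init__(self, name: str, class_a, class_b):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "class_a", frozenset(class_a))
        object.__setattr__(self, "class_b", frozenset(class_b))
        if not self.class_a or not self.class_b:
            raise ValueError("both classes must be nonempty")
        if self.class_a & self.class_b:
            raise ValueError(f"classes overlap: {sorted(self.class_a & self.class_b)}")


#: The four contrasts studied in the beef-maturation design.
DEFAULT_DESIGNS = (
    ComparisonDesign("early", {"t0"}, {"t12"}),
    ComparisonDesign("late", {"t12"}, {"t26"}),
    ComparisonDesign("long", {"t0"}, {"t26"}),
    ComparisonDesign("general", {"t0"}, {"t12", "t26"}),
)


@dataclass
class ScaledMatrix:
    """An autoscaled matrix together with the column statistics used.

    Each column of ``values`` has mean 0 and sample standard deviation 1
    (n-1 denominator).  ``column_means``/``column_sds`` let new samples be
    projected into the same space and the transform be inverted exactly.
    """

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        return (matrix - self.column_means) / self.column_sds

    def invert(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.column_sds + self.column_means


def autoscale(matrix: np.ndarray, protein_ids: Sequence[str] | None = None) -> ScaledMatrix:
    """Center each column to mean 0 and scale to unit sample standard deviation.

    Autoscaling puts every protein on an equal footing before
    multivariate modelling, so that high-abundance proteins do not
    dominate the decomposition.

    Raises
    ------
    ValueError
        If the matrix has fewer than 2 rows or any column is constant
        (named in the message).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("autoscale requires a 2-D matrix with at least 2 rows")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        names = (
            [protein_ids[i] for i in bad[:10]]
            if protein_ids is not None
            else bad[:10].tolist()
        )
        raise ValueError(f"cannot autoscale constant column(s): {names}")
    return ScaledMatrix(values=(matrix - means) / sds, column_means=means, column_sds=sds)


def subset_for_design(
    dataset: AbundanceDataset, design: ComparisonDesign
) -> tuple[AbundanceDataset, np.ndarray]:
    """Restrict a dataset to the samples of a two-class contrast.

    Returns the row-subset dataset and a binary label vector
    (0 = class_a, 1 = class_b) aligned with its rows.
    """
    present = set(dataset.timepoints.unique())
    unknown = (design.class_a | design.class_b) - present
    if unknown:
        raise ValueError(
            f"design {design.name!r} references timepoint(s) {sorted(unknown)} "
            f"absent from the dataset (has {sorted(present)})"
        )
    tp = dataset.timepoints
    mask = tp.isin(design.class_a | design.class_b).to_numpy()
    sub = dataset.select_samples(mask)
    labels = sub.timepoints.isin(design.class_b).to_numpy().astype(int)
    return sub, labels


# ---------------------------------------------------------------------------
# TSV input/output


def write_dataset(dataset: AbundanceDataset, matrix_path, metadata_path) -> None:
    """Write the matrix and metadata as TSV at full float precision."""
    frame = dataset.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(matrix_path, sep="\t", float_format=None)
    meta = dataset.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_dataset(matrix_path, metadata_path) -> AbundanceDataset:
    """Read a TSV abundance matrix plus TSV metadata into a dataset.

    The two files must describe exactly the same samples; mismatches and
    non-numeric abundance cells are reported explicitly.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = [c for c in header if c != "sample_id"]
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate protein column(s): {dupes}")
    frame = pd.read_csv(matrix_path, sep="\t", index_col="sample_id", dtype=str)
    try:
        values = frame.astype(float)
    except ValueError:
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric abundance in column {col!r}, row {bad[0]!r}: "
                    f"{frame.loc[bad[0], col]!r}"
                ) from None
        raise
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id", dtype=str)
    matrix_samples, meta_samples = set(frame.index), set(meta.index)
    if matrix_samples != meta_samples:
        only_matrix = sorted(matrix_samples - meta_samples)
        only_meta = sorted(meta_samples - matrix_samples)
        raise ValueError(
            "sample sets differ between matrix and metadata: "
            f"matrix-only={only_matrix} metadata-only={only_meta}"
        )
    if frame.columns.duplicated().any():
        dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ValueError(f"duplicate protein column(s): {dupes}")
    if "tech_rep" in meta.columns:
        meta["tech_rep"] = meta["tech_rep"].astype(int)
    return AbundanceDataset(
        sample_ids=list(frame.index),
        metadata=meta,
        protein_ids=list(frame.columns),
        values=values.to_numpy(),
    )


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    out = phenotypes.copy()
    out.index.name = "biological_sample"
    out.to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="biological_sample")
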