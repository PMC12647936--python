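"""Omics matrices, label tables, and sample alignment.

Matrices follow the Xena convention: rows are features, columns are samples,
tab-separated, first header cell is an id column name. Missing entries are
permitted (methylation beta values before imputation) and are encoded as NaN
in memory and as ``NA`` on disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ParseError

__all__ = [
    "Modality",
    "OmicsMatrix",
    "LabelTable",
    "MultiOmicsDataset",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_label_table",
    "write_label_table",
    "align_samples",
]

#: tokens accepted (case-insensitively) as missing values in TSV input
NA_TOKENS = frozenset({"na", "nan", ""})

#: significant digits preserved by a write/read round trip
WRITE_PRECISION = 10


class Modality(str, Enum):
    """One omics data layer."""

    EXON = "exon"
    MRNA = "mrna"
    MIRNA = "mirna"
    METHYLATION = "methylation"
    FUSED = "fused"

    @property
    def is_expression(self) -> bool:
        """Expression layers carry non-negative counts/RPKM and may be zero-inflated."""
        return self in (Modality.EXON, Modality.MRNA, Modality.MIRNA)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """A feature x sample value grid for one modality.

    Parameters
    ----------
    modality
        Which omics layer the values come from.
    feature_ids, sample_ids
        Ordered, unique row and column identifiers.
    values
        ``(n_features, n_samples)`` float array; NaN marks a missing entry.
    """

    modality: Modality
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
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

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: Sequence[str] | np.ndarray) -> "OmicsMatrix":
        """Restrict to the given features (bool mask or id list), preserving order."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            idx = np.array([pos[f] for f in keep], dtype=int)
        return OmicsMatrix(
            self.modality,
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Restrict/reorder columns to the given sample ids."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as e:
            raise AlignmentError(f"sample {e.args[0]!r} absent from {self.modality.value} matrix")
        return OmicsMatrix(self.modality, list(self.feature_ids), list(sample_ids), self.values[:, idx])

    def equals(self, other: "OmicsMatrix", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.modality == other.modality
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol, equal_nan=True)
        )


@dataclass
class LabelTable:
    """Binary labels per sample: 1 = tumor (positive class), 0 = normal."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise FormatError("one label per sample id required")
        _check_unique(self.sample_ids, "sample")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise FormatError(f"labels must be binary 0/1, found {sorted(bad)}")

    def subset(self, sample_ids: Sequence[str]) -> "LabelTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return LabelTable(list(sample_ids), self.labels[idx])

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.labels.tolist()))


@dataclass
class MultiOmicsDataset:
    """Sample-aligned modalities plus binary labels.

    Every modality's columns are in the same order as ``sample_ids``, which
    also orders ``labels``.
    """

    modalities: dict[Modality, OmicsMatrix]
    labels: LabelTable
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = list(self.labels.sample_ids)
        for mod, mat in self.modalities.items():
            if mat.sample_ids != self.sample_ids:
                raise AlignmentError(f"{Modality(mod).value} sample order differs from dataset order")
        if self.labels.sample_ids != self.sample_ids:
            raise AlignmentError("label sample order differs from dataset order")
        if len(self.sample_ids) < 2:
            raise AlignmentError("need at least 2 samples")
        if len(set(self.labels.labels.tolist())) < 2:
            raise AlignmentError("both classes must be present after alignment")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def y(self) -> np.ndarray:
        return self.labels.labels

    def subset_samples(self, sample_ids: Sequence[str]) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            {m: mat.subset_samples(sample_ids) for m, mat in self.modalities.items()},
            self.labels.subset(sample_ids),
            list(sample_ids),
        )


def _parse_matrix_text(text: str, modality: Modality, source: str) -> OmicsMatrix:
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{source}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{source}: header must contain an id cell plus sample ids")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    feature_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise FormatError(
                f"{source}: line {lineno} has {len(cells) - 1} values, expected {len(sample_ids)}"
            )
        feature_ids.append(cells[0])
        row = np.empty(len(sample_ids))
        for j, cell in enumerate(cells[1:]):
            token = cell.strip()
            if token.lower() in NA_TOKENS:
                row[j] = np.nan
                continue
            try:
                row[j] = float(token)
            except ValueError:
                raise ParseError(
                    f"{source}: non-numeric value {cell!r} at feature {cells[0]!r}, "
                    f"sample {sample_ids[j]!r} (line {lineno}, column {j + 2})"
                )
        rows.append(row)
    _check_unique(feature_ids, "feature")
    if not feature_ids:
        raise FormatError(f"{source}: no feature rows")
    return OmicsMatrix(modality, feature_ids, sample_ids, np.vstack(rows))


def read_omics_matrix(
    path: str | Path, modality: Modality | str, transpose: bool = False
) -> OmicsMatrix:
    """Read a Xena-style TSV matrix.

    ``transpose=True`` accepts sample-major files (rows = samples) and
    transposes them into the canonical feature x sample orientation.
    """
    path = Path(path)
    mat = _parse_matrix_text(path.read_text(), Modality(modality), str(path))
    if transpose:
        mat = OmicsMatrix(mat.modality, mat.sample_ids, mat.feature_ids, mat.values.T)
    return mat


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> Path:
    """Write a matrix as Xena-style TSV; NaN becomes ``NA``.

    Values are written with :data:`WRITE_PRECISION` significant digits, so
    write-then-read reproduces the matrix to that precision.
    """
    if matrix.n_features == 0:
        raise FormatError("refusing to write a matrix with no features")
    path = Path(path)
    buf = io.StringIO()
    buf.write("sample\t" + "\t".join(matrix.sample_ids) + "\n")
    fmt = f"%.{WRITE_PRECISION - 1}e"
    for i, fid in enumerate(matrix.feature_ids):
        cells = [
            "NA" if np.isnan(v) else fmt % v
            for v in matrix.values[i]
        ]
        buf.write(fid + "\t" + "\t".join(cells) + "\n")
    path.write_text(buf.getvalue())
    return path


def read_label_table(path: str | Path) -> LabelTable:
    """Read a 2-column TSV ``sample_id<TAB>label`` with labels {tumor,normal} or {1,0}."""
    path = Path(path)
    mapping = {"tumor": 1, "normal": 0, "1": 1, "0": 0, "sc": 1}
    sample_ids: list[str] = []
    labels: list[int] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if lineno == 1 and cells[0].lower() in ("sample", "sample_id"):
            continue
        if len(cells) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
        token = cells[1].strip().lower()
        if token not in mapping:
            raise ParseError(f"{path}: line {lineno}: unknown label {cells[1]!r}")
        sample_ids.append(cells[0])
        labels.append(mapping[token])
    return LabelTable(sample_ids, np.array(labels))


def write_label_table(labels: LabelTable, path: str | Path) -> Path:
    path = Path(path)
    out = ["sample_id\tlabel"]
    out += [f"{s}\t{y}" for s, y in zip(labels.sample_ids, labels.labels)]
    path.write_text("\n".join(out) + "\n")
    return path


def align_samples(
    matrices: Sequence[OmicsMatrix], labels: LabelTable
) -> tuple[MultiOmicsDataset, dict[str, dict[str, int]]]:
    """Restrict all modalities and the labels to their shared samples.

    Only subjects with complete measurements across every layer (and a label)
    are retained; columns are reordered to the lexicographically sorted shared
    ids so results do not depend on input column order.

    Returns the aligned dataset and a per-input report of kept/dropped counts.
    """
    if not matrices:
        raise AlignmentError("no matrices to align")
    if len(labels.sample_ids) == 0:
        raise AlignmentError("empty label table")
    shared = set(labels.sample_ids)
    for m in matrices:
        shared &= set(m.sample_ids)
    if not shared:
        raise AlignmentError("no sample id is present in every modality and the label table")
    order = sorted(shared)
    report: dict[str, dict[str, int]] = {}
    mods: dict[Modality, OmicsMatrix] = {}
    for m in matrices:
        if m.modality in mods:
            raise AlignmentError(f"two matrices share modality {m.modality.value!r}")
        mods[m.modality] = m.subset_samples(order)
        report[m.modality.value] = {"kept": len(order), "dropped": m.n_samples - len(order)}
    sub_labels = labels.subset(order)
    report["labels"] = {"kept": len(order), "dropped": len(labels.sample_ids) - len(order)}
    if len(set(sub_labels.labels.tolist())) < 2:
        raise AlignmentError("aligned samples contain only one class")
    return MultiOmicsDataset(mods, sub_labels, order), report
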