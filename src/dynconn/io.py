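"""Reading and writing ROI time series, cohort manifests and connectivity matrices.

On-disk conventions
-------------------
* Time series: delimited text (TSV/CSV picked by extension), rows = time
  volumes, columns = ROIs, optional single header row of ROI names.
  Orientation is never auto-detected: rows are always time.
* Manifest: CSV with header ``subject_id,path,label``.  Labels may be the
  integers +1/-1 or strings mapped through ``label_map`` (default
  ``{"ASD": +1, "NC": -1}``); +1 is the patient class.
* Matrices: TSV, full float precision, symmetric (checked on read).

ROI indices are 0-based everywhere in memory; reports use 1-based indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CohortError, DimensionError, FormatError, SymmetryError

__all__ = [
    "SubjectTimeSeries",
    "Cohort",
    "PairIndexMap",
    "read_timeseries",
    "write_timeseries",
    "read_cohort",
    "make_pair_index",
    "read_matrix",
    "write_matrix",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class SubjectTimeSeries:
    """One subject's ROI-averaged rs-fMRI time series.

    ``data`` has M rows (time volumes) and N columns (ROIs).  ``label`` is +1
    for patients, -1 for controls, or None for unlabeled subjects.
    """

    subject_id: str
    data: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError("time series must be a 2-D matrix")
        m, n = self.data.shape
        if m < 2 or n < 3:
            raise DimensionError(
                f"time series needs >=2 rows and >=3 columns, got {m}x{n}"
            )
        if not np.isfinite(self.data).all():
            raise FormatError(f"subject {self.subject_id!r}: non-finite values")
        if self.label is not None and self.label not in (-1, 1):
            raise ValueError("label must be +1, -1 or None")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class Cohort:
    """An ordered collection of subjects sharing one ROI parcellation."""

    subjects: list[SubjectTimeSeries]
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate subject ids in cohort")
        if self.subjects:
            n = self.subjects[0].n_roi
            for s in self.subjects:
                if s.n_roi != n:
                    raise CohortError(
                        f"subject {s.subject_id!r} has N={s.n_roi}, expected {n}"
                    )
            if self.roi_names is not None and len(self.roi_names) != n:
                raise CohortError("roi_names length does not match N")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_roi(self) -> int:
        if not self.subjects:
            raise CohortError("empty cohort has no ROI count")
        return self.subjects[0].n_roi

    def labels(self) -> np.ndarray:
        labs = [s.label for s in self.subjects]
        if any(l is None for l in labs):
            raise CohortError("cohort contains unlabeled subjects")
        return np.asarray(labs, dtype=int)

    def data_list(self) -> list[np.ndarray]:
        return [s.data for s in self.subjects]


@dataclass(frozen=True)
class PairIndexMap:
    """Canonical ordering of the strictly lower triangle of an NxN matrix.

    Pairs (i, j) with i > j, i ascending then j ascending within i — i.e. the
    row-major traversal of the lower off-diagonal triangle.  This single map
    defines feature order for every vectorized matrix downstream.
    """

    n_roi: int
    pairs: tuple = field(default=())

    def __len__(self) -> int:
        return len(self.pairs)

    def index_of(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("diagonal entries are not part of the pair map")
        if i < j:
            i, j = j, i
        return i * (i - 1) // 2 + j


def make_pair_index(n_roi: int) -> PairIndexMap:
    """Build the lower-triangle pair map for ``n_roi`` ROIs.

    Length is exactly n_roi(n_roi-1)/2 (6670 for the 116-ROI AAL atlas).
    """
    if n_roi < 2:
        raise DimensionError("need at least 2 ROIs for a pair index")
    rows, cols = np.tril_indices(n_roi, k=-1)
    return PairIndexMap(n_roi=n_roi, pairs=tuple(zip(rows.tolist(), cols.tolist())))


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _parse_numeric_table(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Parse a delimited numeric table, tolerating one header row of names."""
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim) if any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path}: empty file")
    header: list[str] | None = None

    def try_float(cell: str) -> float | None:
        try:
            v = float(cell)
        except ValueError:
            return None
        return v if np.isfinite(v) else None

    first_numeric = [try_float(c) for c in rows[0]]
    if any(v is None for v in first_numeric):
        header = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: header but no data rows")
    data = np.empty((len(rows), len(rows[0])), dtype=float)
    for r, row in enumerate(rows):
        if len(row) != data.shape[1]:
            raise FormatError(f"{path}: ragged row {r + 1}")
        for c, cell in enumerate(row):
            v = try_float(cell)
            if v is None:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {r + 1}, column {c + 1}"
                )
            data[r, c] = v
    return data, header


def read_timeseries(
    path: str | Path, subject_id: str | None = None, label: int | None = None
) -> SubjectTimeSeries:
    """Read one subject's MxN ROI time-series table (rows are always time)."""
    path = Path(path)
    data, _ = _parse_numeric_table(path)
    if data.shape[0] < 2 or data.shape[1] < 3:
        raise DimensionError(
            f"{path}: need >=2 time points and >=3 ROIs, got {data.shape}"
        )
    sid = subject_id if subject_id is not None else path.stem
    return SubjectTimeSeries(subject_id=sid, data=data, label=label)


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, ts.data, delimiter=_delimiter_for(path), fmt="%.17g")


_DEFAULT_LABEL_MAP = {"ASD": 1, "NC": -1, "1": 1, "+1": 1, "-1": -1}


def read_cohort(
    manifest_path: str | Path, label_map: dict[str, int] | None = None
) -> Cohort:
    """Read a cohort manifest (CSV: subject_id, path, label) and all its files.

    Relative time-series paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    mapping = dict(_DEFAULT_LABEL_MAP)
    if label_map:
        mapping.update({str(k): int(v) for k, v in label_map.items()})
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "subject_id",
            "path",
            "label",
        }.issubset(set(reader.fieldnames)):
            raise CohortError(
                f"{manifest_path}: manifest needs columns subject_id,path,label"
            )
        records = list(reader)
    if not records:
        raise CohortError(f"{manifest_path}: empty manifest")
    subjects: list[SubjectTimeSeries] = []
    seen: set[str] = set()
    for rec in records:
        sid = rec["subject_id"].strip()
        if sid in seen:
            raise CohortError(f"duplicate subject_id {sid!r} in manifest")
        seen.add(sid)
        raw_label = rec["label"].strip()
        if raw_label not in mapping:
            raise CohortError(f"subject {sid!r}: unknown label {raw_label!r}")
        ts_path = Path(rec["path"].strip())
        if not ts_path.is_absolute():
            ts_path = manifest_path.parent / ts_path
        if not ts_path.exists():
            raise CohortError(f"subject {sid!r}: missing file {ts_path}")
        subjects.append(read_timeseries(ts_path, sid, mapping[raw_label]))
    return Cohort(subjects=subjects)


def write_matrix(
    values: np.ndarray, path: str | Path, roi_names: list[str] | None = None
) -> None:
    """Write a symmetric matrix as TSV at full float precision."""
    values = np.asarray(getattr(values, "values", values), dtype=float)
    path = Path(path)
    header = "\t".join(roi_names) if roi_names else ""
    np.savetxt(path, values, delimiter="\t", fmt="%.17g", header=header, comments="")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a symmetric matrix written by :func:`write_matrix`.

    Raises :class:`SymmetryError` if the table is not square-symmetric to
    within 1e-10.
    """
    path = Path(path)
    data, _ = _parse_numeric_table(path)
    if data.shape[0] != data.shape[1]:
        raise SymmetryError(f"{path}: matrix is not square: {data.shape}")
    if not np.allclose(data, data.T, atol=_SYMMETRY_TOL, rtol=0):
        raise SymmetryError(f"{path}: matrix is not symmetric")
    return data
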