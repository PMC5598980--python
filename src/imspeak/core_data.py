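"""Domain types and text-format I/O for MCC-IMS data.

A *measurement* is one breath sample recorded as a dense intensity grid:
rows are retention times (seconds, from the multi-capillary column),
columns are inverse reduced mobility 1/K0 (Vs/cm², from the ion drift
tube).  Peaks picked from single measurements and consensus peaks
aggregated across a cohort are carried in small typed containers, and
everything round-trips through headered delimited text so intermediate
results can be inspected, diffed and versioned.

All public coordinates are physical units (seconds, Vs/cm²); grid indices
never escape the algorithms that use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "Peak",
    "PeakList",
    "ConsensusPeak",
    "FeatureMatrix",
    "FormatError",
    "read_measurement",
    "write_measurement",
    "read_peaklist",
    "write_peaklist",
    "read_feature_matrix",
    "write_feature_matrix",
]

CASE, CONTROL = "case", "control"


class FormatError(ValueError):
    """Raised when a delimited-text input violates the expected layout."""


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(axis)):
        raise ValueError(f"{name} contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        raise ValueError(f"{name} must be strictly ascending")
    return axis


@dataclass
class Measurement:
    """One sample's dense intensity grid with physical axes.

    Parameters
    ----------
    sample_id
        Identifier of the breath sample.
    rt_axis
        Retention times in seconds, strictly ascending.
    ik0_axis
        Inverse reduced mobility 1/K0 in Vs/cm², strictly ascending.
    intensity
        Signal intensities, shape ``(len(rt_axis), len(ik0_axis))``,
        arbitrary units, all finite.
    label
        Optional class label, ``"case"`` or ``"control"``.
    """

    sample_id: str
    rt_axis: np.ndarray
    ik0_axis: np.ndarray
    intensity: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.rt_axis = _check_axis("rt_axis", self.rt_axis)
        self.ik0_axis = _check_axis("ik0_axis", self.ik0_axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.rt_axis.size, self.ik0_axis.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.rt_axis.size}, {self.ik0_axis.size})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if self.label is not None and self.label not in (CASE, CONTROL):
            raise ValueError(f"label must be {CASE!r} or {CONTROL!r}, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def with_intensity(self, intensity: np.ndarray) -> "Measurement":
        """Copy of this measurement with a replacement intensity grid."""
        return replace(self, intensity=intensity)


@dataclass(frozen=True)
class Peak:
    """A detected analyte signal inside one measurement.

    ``bbox`` is an optional bounding region ``(rt_lo, rt_hi, ik0_lo,
    ik0_hi)`` in physical units enclosing the peak position.
    """

    measurement_id: str
    rt: float
    ik0: float
    intensity: float
    bbox: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.intensity > 0):
            raise ValueError(f"peak intensity must be > 0, got {self.intensity}")
        if self.bbox is not None:
            rt_lo, rt_hi, ik0_lo, ik0_hi = self.bbox
            if not (rt_lo <= self.rt <= rt_hi and ik0_lo <= self.ik0 <= ik0_hi):
                raise ValueError("bbox does not contain the peak position")


@dataclass
class PeakList:
    """Ordered collection of peaks from a single measurement."""

    measurement_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[float, float]] = set()
        for p in self.peaks:
            if p.measurement_id != self.measurement_id:
                raise ValueError(
                    f"peak belongs to {p.measurement_id!r}, list to {self.measurement_id!r}"
                )
            key = (p.rt, p.ik0)
            if key in seen:
                raise ValueError(f"duplicate peak position {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (rt, ik0) positions."""
        return np.array([(p.rt, p.ik0) for p in self.peaks], dtype=float).reshape(-1, 2)


@dataclass
class ConsensusPeak:
    """Representative of a cross-measurement cluster of peaks (a feature).

    ``members`` are ``(measurement_id, peak_index)`` references into the
    per-measurement peak lists that formed the cluster.
    """

    feature_id: str
    rt: float
    ik0: float
    members: list[tuple[str, int]] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("consensus peak needs at least one member")


@dataclass
class FeatureMatrix:
    """Measurements × consensus-peaks intensity table with binary labels.

    ``values[i, j]`` is the intensity assigned to measurement *i* for
    feature *j*; absence of a matching peak is encoded as 0.
    """

    measurement_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = len(self.measurement_ids), len(self.feature_ids)
        if self.values.shape != (n, p):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {p})")
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match measurements")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary 0/1")
        if len(set(self.feature_ids)) != p:
            raise FormatError("duplicate feature_id")
        if len(set(self.measurement_ids)) != n:
            raise ValueError("duplicate measurement_id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.measurement_ids, columns=self.feature_ids)
        df.insert(0, "label", self.labels)
        df.index.name = "measurement_id"
        return df


# ---------------------------------------------------------------------------
# Measurement grid files
#
# Layout: first row is the 1/K0 axis, first column the retention-time axis.
# Cell (0, 0) carries a free-form tag (written as "rt_s\ik0_Vs_cm2"); a tag
# starting with "ik0" followed by "rt" marks a transposed file, which is
# normalised on read so rows are always retention time.
# ---------------------------------------------------------------------------

_CORNER = r"rt_s\ik0_Vs_cm2"
_CORNER_T = r"ik0_Vs_cm2\rt_s"


def write_measurement(m: Measurement, path: str | Path, sep: str = ",") -> None:
    """Write a measurement as a headered dense grid (text).

    First row holds the 1/K0 axis, first column the retention-time axis;
    the corner cell carries the axis tag.  Values are printed with enough
    digits for a 1e-9-relative round trip.
    """
    if m.intensity.size == 0:
        raise ValueError("refusing to write a zero-sized grid")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join([_CORNER] + [f"{v:.17g}" for v in m.ik0_axis]) + "\n")
        for rt, row in zip(m.rt_axis, m.intensity):
            fh.write(sep.join([f"{rt:.17g}"] + [f"{v:.17g}" for v in row]) + "\n")


def _parse_cell(token: str, row: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"non-numeric cell {token!r} at row {row}, column {col}"
        ) from None


def read_measurement(
    path: str | Path,
    sep: str = ",",
    sample_id: str | None = None,
    label: str | None = None,
) -> Measurement:
    """Read a headered dense-grid measurement file.

    Orientation is normalised to rows = retention time; a descending axis
    in either dimension is reversed (together with the corresponding grid
    dimension) so the returned axes are strictly ascending.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split(sep)
    if len(header) < 2:
        raise FormatError(f"{path}: malformed header line 1: {lines[0]!r}")
    corner = header[0].strip()
    transposed = corner == _CORNER_T
    col_axis = np.array([_parse_cell(t, 0, j + 1) for j, t in enumerate(header[1:])])

    row_axis_vals: list[float] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        tokens = line.split(sep)
        if len(tokens) != len(header):
            raise FormatError(
                f"{path}: line {i + 1} has {len(tokens)} fields, expected {len(header)}"
            )
        row_axis_vals.append(_parse_cell(tokens[0], i, 0))
        rows.append([_parse_cell(t, i, j + 1) for j, t in enumerate(tokens[1:])])
    if not rows:
        raise FormatError(f"{path}: no data rows")

    row_axis = np.array(row_axis_vals)
    grid = np.array(rows)
    if transposed:
        row_axis, col_axis = col_axis, row_axis
        grid = grid.T

    # normalise descending axes
    for ax, flip in ((0, row_axis), (1, col_axis)):
        if flip.size > 1 and flip[0] > flip[-1]:
            if ax == 0:
                row_axis, grid = row_axis[::-1], grid[::-1, :]
            else:
                col_axis, grid = col_axis[::-1], grid[:, ::-1]

    return Measurement(
        sample_id=sample_id if sample_id is not None else path.stem,
        rt_axis=row_axis,
        ik0_axis=col_axis,
        intensity=grid,
        label=label,
    )


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

_PEAK_COLS = ["measurement_id", "rt_s", "ik0_Vs_cm2", "intensity"]
_BBOX_COLS = ["rt_lo", "rt_hi", "ik0_lo", "ik0_hi"]


def peaklist_to_frame(pl: PeakList) -> pd.DataFrame:
    rows = []
    for p in pl.peaks:
        row = {
            "measurement_id": p.measurement_id,
            "rt_s": p.rt,
            "ik0_Vs_cm2": p.ik0,
            "intensity": p.intensity,
        }
        if p.bbox is not None:
            row.update(dict(zip(_BBOX_COLS, p.bbox)))
        rows.append(row)
    cols = _PEAK_COLS + (_BBOX_COLS if any(p.bbox is not None for p in pl.peaks) else [])
    return pd.DataFrame(rows, columns=cols)


def write_peaklist(pl: PeakList, path: str | Path, sep: str = ",") -> None:
    """Write a peak list as typed delimited text (empty lists keep the header)."""
    df = peaklist_to_frame(pl)
    if df.empty:
        df = pd.DataFrame(columns=_PEAK_COLS)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_peaklist(path: str | Path, measurement_id: str | None = None, sep: str = ",") -> PeakList:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _PEAK_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        mid = measurement_id if measurement_id is not None else Path(path).stem
        return PeakList(measurement_id=mid, peaks=[])
    has_bbox = all(c in df.columns for c in _BBOX_COLS)
    peaks = []
    for _, r in df.iterrows():
        bbox = None
        if has_bbox and not any(pd.isna(r[c]) for c in _BBOX_COLS):
            bbox = tuple(float(r[c]) for c in _BBOX_COLS)
        peaks.append(
            Peak(
                measurement_id=str(r["measurement_id"]),
                rt=float(r["rt_s"]),
                ik0=float(r["ik0_Vs_cm2"]),
                intensity=float(r["intensity"]),
                bbox=bbox,
            )
        )
    mids = {p.measurement_id for p in peaks}
    if len(mids) != 1:
        raise FormatError(f"{path}: peak list spans multiple measurements: {sorted(mids)}")
    return PeakList(measurement_id=peaks[0].measurement_id, peaks=peaks)


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, sep: str = ",") -> None:
    fm.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_feature_matrix(path: str | Path, sep: str = ",") -> FeatureMatrix:
    # pandas mangles duplicate column names, so check them on the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    feat_cols = header[2:]
    if len(set(feat_cols)) != len(feat_cols):
        dupes = sorted({c for c in feat_cols if feat_cols.count(c) > 1})
        raise FormatError(f"{path}: duplicate feature_id {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing label column")
    return FeatureMatrix(
        measurement_ids=[str(i) for i in df.index],
        feature_ids=list(df.columns[1:]),
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
    )
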