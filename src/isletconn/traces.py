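"""Per-cell fluorescence time series: container, delimited-text I/O, preprocessing.

A recording is a matrix of mean-ROI fluorescence intensities, one column per
cell and one row per frame, sampled at a fixed interval.  Preprocessing
follows the standard Ca²⁺-imaging recipe: causal (retrospective) moving-average
smoothing, then normalisation of each trace to its baseline fluorescence F0,
so traces become dimensionless F/F0 and comparable across cells.

ROI coordinates (2-D Cartesian, arbitrary units) live here too because they
are an input of the connectivity line maps, whether measured or simulated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: variance below this is treated as zero (degenerate trace)
VARIANCE_TOL = 1e-12
#: |F0| below this cannot be used as a normalisation baseline
F0_TOL = 1e-12


class TraceParseError(ValueError):
    """Raised when a trace or coordinate file violates the expected layout."""


@dataclass
class PreprocFlags:
    """Record of which preprocessing steps have been applied."""

    smoothed: bool = False
    normalised: bool = False
    smooth_window: int | None = None
    f0_frames: int | None = None


@dataclass
class TraceMatrix:
    """Fluorescence time series for one imaged islet.

    Parameters
    ----------
    cell_ids
        Unique ROI/cell identifiers, one per column of ``values``.
    frame_times_s
        Frame acquisition times in seconds, uniformly spaced.
    values
        Array of shape ``(n_frames, n_cells)``, fluorescence in arbitrary
        units (or dimensionless F/F0 after normalisation).
    flags
        Which preprocessing steps have been applied.
    """

    cell_ids: list[str]
    frame_times_s: np.ndarray
    values: np.ndarray
    flags: PreprocFlags = field(default_factory=PreprocFlags)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = sorted({c for c in self.cell_ids if self.cell_ids.count(c) > 1})
            raise ValueError(f"duplicate cell ids: {dupes}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_frames, n_cells) array")
        if self.values.shape != (self.frame_times_s.size, len(self.cell_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{self.frame_times_s.size} frames x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not np.all(np.isfinite(self.frame_times_s)):
            raise ValueError("frame times must be finite")
        if self.n_frames >= 2:
            dt = np.diff(self.frame_times_s)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
                raise ValueError("frame spacing must be uniform (rtol 1e-9)")

    @property
    def n_frames(self) -> int:
        return self.frame_times_s.size

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def frame_interval_s(self) -> float:
        if self.n_frames < 2:
            raise ValueError("frame interval undefined for a single frame")
        return float(self.frame_times_s[1] - self.frame_times_s[0])

    def series(self, cell_id: str) -> np.ndarray:
        """Return the trace of one cell as a 1-D array."""
        return self.values[:, self.cell_ids.index(cell_id)]

    def equals(self, other: "TraceMatrix") -> bool:
        return (
            self.cell_ids == other.cell_ids
            and np.array_equal(self.frame_times_s, other.frame_times_s)
            and np.array_equal(self.values, other.values)
            and dataclasses.asdict(self.flags) == dataclasses.asdict(other.flags)
        )


@dataclass
class CellCoordinates:
    """2-D Cartesian ROI positions (arbitrary units) for one islet."""

    cell_ids: list[str]
    xy: np.ndarray  # shape (n_cells, 2)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.cell_ids), 2)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in coordinates")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")

    def position(self, cell_id: str) -> tuple[float, float]:
        i = self.cell_ids.index(cell_id)
        return float(self.xy[i, 0]), float(self.xy[i, 1])


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Trace file: comma-delimited, header ``time_s,<cell ids...>``, one row/frame.
# Coordinate file: comma-delimited, header ``cell_id,x,y``.
# ---------------------------------------------------------------------------

def read_traces(path) -> TraceMatrix:
    """Read a trace matrix from comma-delimited text.

    Raises :class:`TraceParseError` naming the offending row/column for
    ragged rows, duplicate cell ids, non-numeric entries or non-uniform
    frame spacing.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if not header or header[0] != "time_s":
        raise TraceParseError(
            f"{path}: first header field must be 'time_s', got {header[:1]}"
        )
    ids = header[1:]
    if not ids:
        raise TraceParseError(f"{path}: no cell columns in header")
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise TraceParseError(f"{path}: duplicate cell ids in header: {dupes}")
    try:
        df = pd.read_csv(path, header=0, names=["time_s", *ids], dtype=str)
    except pd.errors.ParserError as exc:
        raise TraceParseError(f"{path}: ragged row ({exc})") from exc
    try:
        # numpy's string->float conversion is correctly rounded, so the
        # write/read roundtrip is exact
        numeric = df.astype(float)
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere((coerced.isna() & df.notna()).to_numpy())[0]
        raise TraceParseError(
            f"{path}: non-numeric value at data row {r + 1}, "
            f"column '{df.columns[c]}'"
        ) from None
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TraceParseError(
            f"{path}: missing value at data row {r + 1}, "
            f"column '{numeric.columns[c]}' (ragged row?)"
        )
    try:
        return TraceMatrix(
            cell_ids=ids,
            frame_times_s=numeric["time_s"].to_numpy(),
            values=numeric[ids].to_numpy(),
        )
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def write_traces(t: TraceMatrix, path) -> None:
    """Write a trace matrix as comma-delimited text (full float precision)."""
    df = pd.DataFrame(t.values, columns=t.cell_ids)
    df.insert(0, "time_s", t.frame_times_s)
    df.to_csv(path, index=False)


def read_coordinates(path) -> CellCoordinates:
    df = pd.read_csv(path, dtype={"cell_id": str})
    expected = ["cell_id", "x", "y"]
    if list(df.columns) != expected:
        raise TraceParseError(f"{path}: header must be {expected}, got {list(df.columns)}")
    return CellCoordinates(df["cell_id"].tolist(), df[["x", "y"]].to_numpy(dtype=float))


def write_coordinates(coords: CellCoordinates, path) -> None:
    pd.DataFrame(
        {"cell_id": coords.cell_ids, "x": coords.xy[:, 0], "y": coords.xy[:, 1]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def smooth_retrospective(
    t: TraceMatrix, window: int = 10, include_current: bool = True
) -> TraceMatrix:
    """Causal trailing-window moving average (default window 10 frames).

    Each sample is replaced by the mean of the trailing window ending at that
    sample; the first ``window − 1`` samples use all samples available so far
    (no look-ahead, output length equals input length).

    With ``include_current=False`` the window strictly excludes the current
    sample (mean of the *previous* ``window`` values); the first sample,
    which has no history, is left unchanged.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window >= t.n_frames:
        raise ValueError(f"window {window} must be < n_frames {t.n_frames}")
    if t.flags.smoothed:
        raise ValueError("trace matrix is already smoothed")
    df = pd.DataFrame(t.values)
    if include_current:
        out = df.rolling(window, min_periods=1).mean().to_numpy()
    else:
        out = df.shift(1).rolling(window, min_periods=1).mean().to_numpy()
        out[0, :] = t.values[0, :]
    flags = dataclasses.replace(t.flags, smoothed=True, smooth_window=window)
    return TraceMatrix(list(t.cell_ids), t.frame_times_s.copy(), out, flags)


def normalise_f0(t: TraceMatrix, f0_frames: int = 30) -> TraceMatrix:
    """Divide each trace by its baseline F0 = mean of its first ``f0_frames``.

    After the call the mean of each cell's first ``f0_frames`` samples is 1
    (up to floating tolerance).  Raises if any cell's F0 is (numerically)
    zero, naming the cell.
    """
    if not 1 <= f0_frames < t.n_frames:
        raise ValueError(
            f"f0_frames must be in [1, n_frames), got {f0_frames} with "
            f"{t.n_frames} frames"
        )
    f0 = t.values[:f0_frames].mean(axis=0)
    zero = np.abs(f0) < F0_TOL
    if zero.any():
        bad = [c for c, z in zip(t.cell_ids, zero) if z]
        raise ValueError(f"cells with zero baseline F0: {bad}")
    flags = dataclasses.replace(t.flags, normalised=True, f0_frames=f0_frames)
    return TraceMatrix(list(t.cell_ids), t.frame_times_s.copy(), t.values / f0, flags)


def drop_degenerate_cells(t: TraceMatrix) -> tuple[TraceMatrix, list[str]]:
    """Remove cells whose trace has (numerically) zero variance.

    Pearson correlation is undefined for constant traces, so they must be
    removed before connectivity analysis.  Survivor order is preserved; each
    removal is logged.  Raises if every cell is degenerate.
    """
    var = t.values.var(axis=0)
    keep = var > VARIANCE_TOL
    removed = [c for c, k in zip(t.cell_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all cells have zero-variance traces")
    for c in removed:
        log.info("dropping degenerate (zero-variance) cell %s", c)
    if not removed:
        return t, []
    kept_ids = [c for c, k in zip(t.cell_ids, keep) if k]
    return (
        TraceMatrix(
            kept_ids,
            t.frame_times_s.copy(),
            t.values[:, keep],
            dataclasses.replace(t.flags),
        ),
        removed,
    )


def preprocess(
    t: TraceMatrix,
    smooth_window: int | None = 10,
    f0_frames: int = 30,
    drop_degenerate: bool = True,
) -> tuple[TraceMatrix, list[str]]:
    """Standard pipeline: smooth → normalise to F0 → drop degenerate cells.

    ``smooth_window=None`` skips smoothing (useful when downstream
    significance assumes exchangeable frames; see the block bootstrap).
    Returns the preprocessed matrix and the list of removed cell ids.
    """
    removed: list[str] = []
    if drop_degenerate:
        t, removed = drop_degenerate_cells(t)
    if smooth_window is not None:
        t = smooth_retrospective(t, smooth_window)
    t = normalise_f0(t, f0_frames)
    return t, removed
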