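"""Synthetic islet Ca²⁺ recordings and ranked gene lists with known ground truth.

The simulator emulates a field of ~50 β-cell ROIs imaged at 0.5 Hz in which a
subpopulation of cells shares a glucose-driven oscillatory Ca²⁺ signal while
every cell carries independent shot/readout noise.  The trace of cell *i* is

    F_i(t) = f0_i · (1 + a_i · s(t − τ_i) · 1[t ≥ t_stim]) + drift · t + ε_it

with ``s`` a zero-mean unit-variance periodic waveform shared by coupled
cells, ``a_i`` the fractional-fluorescence modulation amplitude (0 for
uncoupled cells), ``τ_i`` a per-cell constant phase offset, and
``ε_it ~ N(0, noise_sd²)``.  Every simulation returns the planted coupling
structure so downstream edge discovery can be scored against a known answer.

Under a homogeneous specification (no jitter, no drift, common baseline f0)
the population Pearson correlation between two coupled cells over the
post-stimulus window has the closed form

    ρ = a²v / (a²v + σ²),          v = f0² · Var(s) = f0²

which :func:`expected_pairwise_r` exposes as the calibration oracle, and
:func:`amplitude_for_expected_r` inverts to plant a target correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import CellCoordinates, TraceMatrix

WAVEFORMS = ("square", "sine")


@dataclass(frozen=True)
class IsletSimSpec:
    """Parameters of one simulated islet recording.

    Defaults emulate the acquisition used for real recordings: ~50 ROIs per
    islet imaged at 0.5 Hz (2 s frame interval), a 1-minute pre-stimulus
    baseline, and slow glucose-driven Ca²⁺ oscillations (period ~60 s).
    """

    n_cells: int = 50
    field_radius: float = 100.0
    min_spacing: float = 8.0
    n_frames: int = 300
    frame_interval_s: float = 2.0
    baseline_frames: int = 30
    coupled_fraction: float = 0.4
    coupled_mask: tuple[bool, ...] | None = None
    coupling_amplitude: float = 0.12
    oscillation_period_s: float = 60.0
    waveform: str = "square"
    phase_jitter_s: float = 0.0
    noise_sd: float = 10.0
    drift_slope: float = 0.0
    f0_mean: float = 100.0
    f0_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not self.n_frames > self.baseline_frames >= 1:
            raise ValueError("need n_frames > baseline_frames >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must be in [0, 1]")
        if self.coupling_amplitude < 0:
            raise ValueError("coupling_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.phase_jitter_s < 0:
            raise ValueError("phase_jitter_s must be >= 0")
        if self.oscillation_period_s <= 0:
            raise ValueError("oscillation_period_s must be > 0")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"waveform must be one of {WAVEFORMS}")
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be > 0")
        if self.coupled_mask is not None:
            object.__setattr__(self, "coupled_mask", tuple(bool(b) for b in self.coupled_mask))
            if len(self.coupled_mask) != self.n_cells:
                raise ValueError("coupled_mask length must equal n_cells")


@dataclass
class GroundTruth:
    """Planted coupling structure of a simulated islet."""

    cell_ids: list[str]
    coupled_mask: np.ndarray  # per-cell bool
    true_edges: set[tuple[str, str]]  # unordered pairs, lexicographically sorted
    expected_r: float | None  # identical for all true edges under a homogeneous spec

    def write(self, edges_path, mask_path) -> None:
        """Write the edge list and per-cell mask as TSV."""
        pd.DataFrame(sorted(self.true_edges), columns=["cell_a", "cell_b"]).to_csv(
            edges_path, sep="\t", index=False
        )
        pd.DataFrame(
            {"cell_id": self.cell_ids, "coupled": self.coupled_mask.astype(int)}
        ).to_csv(mask_path, sep="\t", index=False)


class PackingError(RuntimeError):
    """Raised when ROI placement cannot satisfy the minimum spacing."""


def _cell_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"cell_{i + 1:0{width}d}" for i in range(n)]


def generate_coordinates(
    n: int,
    field_radius: float = 100.0,
    min_spacing: float = 8.0,
    seed: int = 0,
    max_attempts_per_cell: int = 2000,
) -> CellCoordinates:
    """Rejection-sample ``n`` ROI centres uniformly in a disc.

    All points lie within ``field_radius`` of the origin and all pairwise
    distances are >= ``min_spacing``.  Deterministic for a fixed seed.
    Raises :class:`PackingError` naming the densest feasible count reached
    when the spacing constraint cannot be met.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if field_radius <= 0:
        raise ValueError("field_radius must be > 0")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    min_sq = min_spacing * min_spacing
    for _ in range(n):
        for _attempt in range(max_attempts_per_cell):
            r = field_radius * math.sqrt(rng.random())
            theta = 2 * math.pi * rng.random()
            p = np.array([r * math.cos(theta), r * math.sin(theta)])
            if all(np.sum((p - q) ** 2) >= min_sq for q in pts):
                pts.append(p)
                break
        else:
            raise PackingError(
                f"could not place {n} cells with min_spacing={min_spacing} in a "
                f"disc of radius {field_radius}; densest feasible n tried: {len(pts)}"
            )
    return CellCoordinates(_cell_ids(n), np.array(pts))


def _shared_waveform(spec: IsletSimSpec) -> "callable":
    """Continuous-time shared signal s(t), zero-mean unit-variance by design."""
    period = spec.oscillation_period_s
    if spec.waveform == "square":
        return lambda t: np.where(np.mod(t, period) < period / 2, 1.0, -1.0)
    return lambda t: math.sqrt(2.0) * np.sin(2 * math.pi * np.asarray(t) / period)


def simulate_islet(spec: IsletSimSpec) -> tuple[TraceMatrix, CellCoordinates, GroundTruth]:
    """Simulate one islet recording.

    Returns the raw (unpreprocessed) trace matrix, the ROI coordinates, and
    the planted :class:`GroundTruth`.  Bit-identical output for an identical
    spec (including seed): the top-level seed is split into independent
    substreams for coordinates, the coupled-mask draw, baselines, and one
    stream per cell for its phase offset and noise.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_coords, ss_mask, ss_f0, *ss_cells = root.spawn(3 + spec.n_cells)

    coords = generate_coordinates(
        spec.n_cells,
        spec.field_radius,
        spec.min_spacing,
        seed=ss_coords,
    )
    ids = coords.cell_ids

    if spec.coupled_mask is not None:
        mask = np.asarray(spec.coupled_mask, dtype=bool)
    else:
        mask = np.random.default_rng(ss_mask).random(spec.n_cells) < spec.coupled_fraction

    f0 = np.random.default_rng(ss_f0).normal(spec.f0_mean, spec.f0_sd, spec.n_cells)
    f0 = np.clip(f0, 0.05 * spec.f0_mean, None)  # keep baselines positive

    t = np.arange(spec.n_frames) * spec.frame_interval_s
    t_stim = spec.baseline_frames * spec.frame_interval_s
    post = t >= t_stim
    wave = _shared_waveform(spec)

    values = np.empty((spec.n_frames, spec.n_cells))
    for i in range(spec.n_cells):
        rng = np.random.default_rng(ss_cells[i])
        tau = rng.normal(0.0, spec.phase_jitter_s) if spec.phase_jitter_s > 0 else 0.0
        noise = rng.normal(0.0, spec.noise_sd, spec.n_frames)
        signal = np.zeros(spec.n_frames)
        if mask[i] and spec.coupling_amplitude > 0:
            s = wave(t[post] - t_stim - tau)
            sd = s.std()
            if sd < 1e-12:
                raise ValueError(
                    "shared signal is constant over the post-stimulus window; "
                    "check oscillation_period_s vs recording length"
                )
            signal[post] = spec.coupling_amplitude * (s - s.mean()) / sd
        values[:, i] = f0[i] * (1.0 + signal) + spec.drift_slope * np.arange(spec.n_frames) + noise

    traces = TraceMatrix(ids, t, values)
    coupled_ids = [c for c, m in zip(ids, mask) if m]
    true_edges = {
        tuple(sorted((a, b)))
        for k, a in enumerate(coupled_ids)
        for b in coupled_ids[k + 1 :]
    }
    try:
        exp_r = expected_pairwise_r(spec)
    except ValueError:
        exp_r = None
    truth = GroundTruth(ids, mask, true_edges, exp_r)
    return traces, coords, truth


def expected_pairwise_r(spec: IsletSimSpec) -> float:
    """Closed-form Pearson R between two coupled cells: a²v / (a²v + σ²).

    ``v = f0_mean²`` is the variance of the post-stimulus shared-signal term
    at a cell's baseline fluorescence (the waveform has unit variance).
    Valid only for the homogeneous case: zero phase jitter and zero drift;
    called otherwise it raises, since the closed form no longer holds.
    """
    if spec.phase_jitter_s != 0:
        raise ValueError("closed form invalid with phase jitter != 0")
    if spec.drift_slope != 0:
        raise ValueError("closed form invalid with drift_slope != 0")
    a2v = (spec.coupling_amplitude * spec.f0_mean) ** 2
    denom = a2v + spec.noise_sd**2
    if denom == 0:
        return 0.0
    return a2v / denom


def amplitude_for_expected_r(r: float, noise_sd: float, f0_mean: float) -> float:
    """Coupling amplitude that plants a target coupled-pair correlation ``r``."""
    if not 0 <= r < 1:
        raise ValueError("target r must be in [0, 1)")
    if f0_mean <= 0:
        raise ValueError("f0_mean must be > 0")
    return math.sqrt(r / (1.0 - r)) * noise_sd / f0_mean


# ---------------------------------------------------------------------------
# ranked gene lists with planted enrichment
# ---------------------------------------------------------------------------

def simulate_ranked_list(
    n_genes: int, set_size: int, shift: float, seed: int = 0
) -> tuple["RankedGeneList", "GeneSet"]:
    """Gene statistics ~ N(0,1); planted set members ~ N(shift, 1).

    Returns the list sorted by statistic descending (ties broken by gene id)
    together with the planted gene set.  Deterministic per seed.
    """
    from .enrichment import GeneSet, RankedGeneList

    if not 1 <= set_size < n_genes:
        raise ValueError("need 1 <= set_size < n_genes")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    stats = rng.normal(0.0, 1.0, n_genes)
    members = rng.choice(n_genes, size=set_size, replace=False)
    stats[members] += shift
    ranked = RankedGeneList.from_unsorted(genes, stats)
    gene_set = GeneSet("planted", frozenset(genes[i] for i in members))
    return ranked, gene_set


def write_simulation(
    out_dir,
    traces: TraceMatrix,
    coords: CellCoordinates,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write traces (CSV), coordinates (CSV) and ground truth (TSV) files."""
    from .traces import write_coordinates, write_traces

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "traces.csv",
        "coordinates": out / "coordinates.csv",
        "true_edges": out / "true_edges.tsv",
        "coupled_mask": out / "coupled_mask.tsv",
    }
    write_traces(traces, paths["traces"])
    write_coordinates(coords, paths["coordinates"])
    truth.write(paths["true_edges"], paths["coupled_mask"])
    return paths
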