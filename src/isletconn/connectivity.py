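"""All-pairs Pearson correlation with bootstrap/permutation significance.

Functional connectivity between two cells is read off the Pearson correlation
R of their (preprocessed) fluorescence traces.  Because a single R carries no
significance, each unordered pair is also assigned a p-value by resampling
frames:

``pairs_bootstrap`` (default)
    Frame indices are drawn with replacement and applied identically to both
    traces of a pair; R is recomputed per replicate.  The one-sided
    ``p = (1 + #{replicate R <= 0}) / (n_boot + 1)`` asks whether the
    bootstrap confidence interval for R excludes zero — connectivity is
    positive coupling.

``block_bootstrap``
    As above but contiguous blocks of ``block_len`` frames are resampled,
    which respects short-range temporal autocorrelation (e.g. after
    smoothing).

``permutation``
    One trace's frames are permuted per replicate; the p-value is the
    null-based ``(1 + #{replicate R >= observed}) / (n_boot + 1)``.

Every pair draws its replicates from its own RNG substream derived from the
top-level seed, so results are reproducible and independent of evaluation
order.  The plus-one smoothing means p is never exactly 0; the minimum
attainable value is ``1 / (n_boot + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .traces import TraceMatrix, VARIANCE_TOL

METHODS = ("pairs_bootstrap", "block_bootstrap", "permutation")

#: fraction of degenerate (zero-variance) replicates above which a pair errors
MAX_DISCARD_FRACTION = 0.10


class DegenerateReplicatesError(RuntimeError):
    """Raised when too many bootstrap replicates of a pair are degenerate."""


@dataclass
class CorrelationResult:
    """Pairwise Pearson R matrix with per-pair resampling p-values.

    ``R`` and ``P`` are symmetric ``(n, n)`` arrays whose diagonal is NaN:
    the autocorrelation of a cell with itself is excluded from the analysis,
    not reported as 1.
    """

    cell_ids: list[str]
    R: np.ndarray
    P: np.ndarray
    n_boot: int
    method: str
    block_len: int | None
    seed: int
    n_discarded: np.ndarray | None = None  # degenerate replicates per pair

    def pair_table(self):
        """Long-format table ``cell_a, cell_b, r, p`` over unordered pairs."""
        import pandas as pd

        rows = []
        n = len(self.cell_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (self.cell_ids[i], self.cell_ids[j], self.R[i, j], self.P[i, j])
                )
        return pd.DataFrame(rows, columns=["cell_a", "cell_b", "r", "p"])

    def write_matrices(self, r_path, p_path) -> None:
        """Write R and P as tab-delimited square tables, diagonal as NA."""
        import pandas as pd

        for mat, path in ((self.R, r_path), (self.P, p_path)):
            pd.DataFrame(mat, index=self.cell_ids, columns=self.cell_ids).to_csv(
                path, sep="\t", na_rep="NA"
            )


def pearson_matrix(t: TraceMatrix) -> np.ndarray:
    """Pearson R for all unordered cell pairs; diagonal set to NaN.

    Warns if the traces have not been smoothed and normalised (the intended
    inputs); errors on zero-variance cells, which should be removed with
    :func:`isletconn.traces.drop_degenerate_cells` first.
    """
    if t.n_frames < 3:
        raise ValueError("need at least 3 frames for a meaningful correlation")
    if not (t.flags.smoothed and t.flags.normalised):
        warnings.warn(
            "computing Pearson matrix on traces that are not both smoothed "
            "and normalised",
            stacklevel=2,
        )
    var = t.values.var(axis=0)
    if np.any(var <= VARIANCE_TOL):
        bad = [c for c, v in zip(t.cell_ids, var) if v <= VARIANCE_TOL]
        raise ValueError(
            f"zero-variance cells {bad}: remove with drop_degenerate_cells first"
        )
    r = np.corrcoef(t.values.T)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.nan)
    return r


def pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    """Deterministic per-pair RNG substream (i, j are column indices, i < j)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, j)))


def replicate_indices(
    rng: np.random.Generator,
    n_frames: int,
    n_boot: int,
    method: str = "pairs_bootstrap",
    block_len: int | None = None,
) -> np.ndarray:
    """Draw the ``(n_boot, n_frames)`` frame-index array for one pair.

    This is the exact resampling used by :func:`bootstrap_pvalues`; exposing
    it lets an independent reference implementation replay identical
    replicates.
    """
    if method == "pairs_bootstrap":
        return rng.integers(0, n_frames, size=(n_boot, n_frames))
    if method == "block_bootstrap":
        if block_len is None or not 1 <= block_len <= n_frames:
            raise ValueError(f"block_len must be in [1, n_frames], got {block_len}")
        n_blocks = -(-n_frames // block_len)  # ceil
        starts = rng.integers(0, n_frames - block_len + 1, size=(n_boot, n_blocks))
        idx = starts[:, :, None] + np.arange(block_len)
        return idx.reshape(n_boot, -1)[:, :n_frames]
    if method == "permutation":
        return rng.permuted(
            np.tile(np.arange(n_frames), (n_boot, 1)), axis=1
        )
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _rowwise_pearson(
    x: np.ndarray, y: np.ndarray, idx: np.ndarray, permute_y_only: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """R per replicate row of ``idx`` plus centred sums of squares (for QC)."""
    n = x.size
    yb = y[idx]
    xb = x[idx] if not permute_y_only else np.broadcast_to(x, idx.shape)
    sx = xb.sum(axis=1)
    sy = yb.sum(axis=1)
    sxx = np.einsum("ij,ij->i", xb, xb) - sx * sx / n
    syy = np.einsum("ij,ij->i", yb, yb) - sy * sy / n
    sxy = np.einsum("ij,ij->i", xb, yb) - sx * sy / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    return r, sxx, syy


def _pair_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    r_obs: float,
    rng: np.random.Generator,
    n_boot: int,
    method: str,
    block_len: int | None,
    pair_name: str,
) -> tuple[float, int]:
    """One pair's resampling p-value; returns (p, n degenerate discards)."""
    n = x.size
    permute_y = method == "permutation"
    idx = replicate_indices(rng, n, n_boot, method, block_len)
    r, sxx, syy = _rowwise_pearson(x, y, idx, permute_y)
    # scale-aware zero-variance test for resampled series
    tol = VARIANCE_TOL * n
    bad = (sxx <= tol) | (syy <= tol)
    n_discarded = 0
    while bad.any():
        n_discarded += int(bad.sum())
        if n_discarded > MAX_DISCARD_FRACTION * n_boot:
            raise DegenerateReplicatesError(
                f"pair {pair_name}: >{MAX_DISCARD_FRACTION:.0%} of replicates "
                f"degenerate ({n_discarded}/{n_boot} discarded)"
            )
        redraw = replicate_indices(rng, n, int(bad.sum()), method, block_len)
        r_new, sxx_new, syy_new = _rowwise_pearson(x, y, redraw, permute_y)
        r[bad] = r_new
        where = np.flatnonzero(bad)
        bad = np.zeros_like(bad)
        bad[where] = (sxx_new <= tol) | (syy_new <= tol)
    if permute_y:
        extreme = int(np.count_nonzero(r >= r_obs))
    else:
        extreme = int(np.count_nonzero(r <= 0.0))
    return (1 + extreme) / (n_boot + 1), n_discarded


def bootstrap_pvalues(
    t: TraceMatrix,
    n_boot: int = 10_000,
    method: str = "pairs_bootstrap",
    block_len: int | None = None,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson R for all pairs plus a resampling p-value per pair.

    Parameters
    ----------
    t
        Preprocessed trace matrix (>= 10 frames, no zero-variance cells).
    n_boot
        Replicates per pair; below 1000 the p < 0.001 threshold cannot be
        resolved and a warning is issued.
    method
        One of ``pairs_bootstrap``, ``block_bootstrap``, ``permutation``.
    block_len
        Block length for the block bootstrap; defaults to the smoothing
        window recorded on ``t`` (or 10).
    seed
        Top-level seed; each pair uses the substream ``spawn_key=(i, j)``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if t.n_frames < 10:
        raise ValueError("need at least 10 frames for resampling significance")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 1000:
        warnings.warn(
            f"n_boot={n_boot} cannot resolve p < 0.001 "
            f"(minimum attainable p is {1 / (n_boot + 1):.2g})",
            stacklevel=2,
        )
    if method == "block_bootstrap" and block_len is None:
        block_len = t.flags.smooth_window or 10
    R = pearson_matrix(t)
    n = t.n_cells
    P = np.full((n, n), np.nan)
    n_disc = np.zeros((n, n), dtype=int)
    for i in range(n):
        x = np.ascontiguousarray(t.values[:, i])
        for j in range(i + 1, n):
            y = np.ascontiguousarray(t.values[:, j])
            p, d = _pair_pvalue(
                x,
                y,
                R[i, j],
                pair_rng(seed, i, j),
                n_boot,
                method,
                block_len,
                f"({t.cell_ids[i]}, {t.cell_ids[j]})",
            )
            P[i, j] = P[j, i] = p
            n_disc[i, j] = n_disc[j, i] = d
    return CorrelationResult(
        cell_ids=list(t.cell_ids),
        R=R,
        P=P,
        n_boot=n_boot,
        method=method,
        block_len=block_len if method == "block_bootstrap" else None,
        seed=seed,
        n_discarded=n_disc,
    )
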