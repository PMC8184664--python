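"""Shared fixtures and independent reference (oracle) implementations.

The oracles here are deliberately naive — explicit loops and textbook
formulas — so they stay independent of the vectorised library code paths
they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from isletconn.traces import PreprocFlags, TraceMatrix


@pytest.fixture
def small_traces() -> TraceMatrix:
    """3 cells x 5 frames, plain numbers, raw flags."""
    return TraceMatrix(
        cell_ids=["a", "b", "c"],
        frame_times_s=np.arange(5) * 2.0,
        values=np.array(
            [
                [1.0, 2.0, 5.0],
                [2.0, 4.0, 4.0],
                [3.0, 6.0, 3.0],
                [4.0, 8.0, 2.0],
                [5.0, 10.0, 1.0],
            ]
        ),
    )


def make_traces(values: np.ndarray, dt: float = 2.0, **flags) -> TraceMatrix:
    """TraceMatrix from a (n_frames, n_cells) array with generated ids."""
    values = np.asarray(values, dtype=float)
    n_frames, n_cells = values.shape
    return TraceMatrix(
        cell_ids=[f"c{i + 1}" for i in range(n_cells)],
        frame_times_s=np.arange(n_frames) * dt,
        values=values,
        flags=PreprocFlags(**flags),
    )


def pearson_oracle(x, y) -> float:
    """Textbook product-moment correlation, computed with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def pearson_matrix_oracle(values: np.ndarray) -> np.ndarray:
    """Naive two-pass all-pairs Pearson matrix (diagonal NaN)."""
    n_cells = values.shape[1]
    out = np.full((n_cells, n_cells), np.nan)
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            out[i, j] = out[j, i] = pearson_oracle(values[:, i], values[:, j])
    return out


def running_sum_oracle(genes, stats, members, weight):
    """Step-by-step enrichment running sum executed with a plain loop."""
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    w = [abs(s) ** weight if weight != 0 else 1.0 for s in stats]
    denom = sum(wi for wi, h in zip(w, hits) if h)
    running = []
    total = 0.0
    for wi, h in zip(w, hits):
        total += wi / denom if h else -1.0 / (n - n_hit)
        running.append(total)
    es = max(running, key=abs)
    return es, running
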