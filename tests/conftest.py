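"""Shared fixtures and independent per-base oracles.

The oracle helpers deliberately re-derive results with naive bitmap /
scan / enumeration logic, independent of the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cneqc.intervals import Interval, IntervalSet
from cneqc.simulate import SimulationConfig, simulate_clade

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# bitmap oracles over a small coordinate universe
# ---------------------------------------------------------------------------

def bitmap_of(intervals, universe: int, seq_id: str = "chr") -> np.ndarray:
    bits = np.zeros(universe, dtype=bool)
    for iv in intervals:
        if iv.seq_id == seq_id:
            bits[iv.start : iv.end] = True
    return bits


def bitmap_close_gaps(bits: np.ndarray, join_gap: int) -> np.ndarray:
    """Naive gap closing: fill any 0-run of length <= join_gap flanked by 1s."""
    out = bits.copy()
    n = len(bits)
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            left = i > 0 and out[i - 1]
            right = j < n and (j < n and out[j])
            if left and right and (j - i) <= join_gap:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def bitmap_to_intervals(bits: np.ndarray, seq_id: str = "chr") -> list[Interval]:
    out = []
    n = len(bits)
    i = 0
    while i < n:
        if bits[i]:
            j = i
            while j < n and bits[j]:
                j += 1
            out.append(Interval(seq_id, i, j))
            i = j
        else:
            i += 1
    return out


def random_interval_set(rng: np.random.Generator, universe: int, n: int, seq_id: str = "chr") -> IntervalSet:
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, universe - 1))
        end = int(rng.integers(start + 1, min(universe, start + 1 + int(rng.integers(1, 200)))) + 1)
        end = min(end, universe)
        if end > start:
            ivs.append(Interval(seq_id, start, end))
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# simulation fixtures (module-scoped: each simulation is deterministic)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic clade (seed 1): 200 kb, 50 elements, 9+3 species."""
    return simulate_clade(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast clade for I/O-heavy tests."""
    return simulate_clade(
        SimulationConfig(seed=3, genome_len=40_000, n_elements=10)
    )
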