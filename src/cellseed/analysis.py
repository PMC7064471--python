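"""Aggregation of seeding simulations into reported quantities.

Seeding efficiency is the percentage of injected cells that end up
attached to the scaffold, ``Phi = 100 * N_a / N_i``; attached cells are
also histogrammed into lateral bins measured from the injection-side face
of the scaffold (six 1.3-mm bins spanning the 7.8-mm footprint by
default), separately for live and dead cells. Replicate bin counts can be
compared with Welch's two-sample t test.

Live attached cells are those in the stick or spread regimes; splash
products (fragments and their parents) are tracked as a parallel dead
series and excluded from the live efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeedingResult",
    "seeding_efficiency",
    "lateral_bin_counts",
    "compare_bins",
    "efficiency_curve",
    "DEFAULT_BIN_EDGES_MM",
]

#: Lateral bins (mm from the injection-side scaffold face): 0-1.3 ... 6.5-7.8.
DEFAULT_BIN_EDGES_MM = np.arange(0.0, 7.8 + 1e-9, 1.3)


def seeding_efficiency(n_attached: int, n_injected: int) -> float:
    """Phi = 100 * N_a / N_i (percent)."""
    if n_injected <= 0:
        raise ValueError("n_injected must be > 0")
    return 100.0 * n_attached / n_injected


def lateral_bin_counts(
    distances_mm: np.ndarray,
    bin_edges_mm: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, int]:
    """Histogram of attachment distances from the injection-side face.

    Bins are half-open ``[a, b)``; a particle at exactly an interior edge
    falls into the higher bin. Returns ``(counts, n_overflow)`` where the
    overflow bucket collects particles outside all bins.
    """
    edges = np.asarray(DEFAULT_BIN_EDGES_MM if bin_edges_mm is None else bin_edges_mm,
                       dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    d = np.asarray(distances_mm, dtype=float)
    idx = np.searchsorted(edges, d, side="right") - 1
    inside = (idx >= 0) & (idx < len(edges) - 1) & (d < edges[-1])
    counts = np.bincount(idx[inside], minlength=len(edges) - 1)
    return counts.astype(int), int((~inside).sum())


def compare_bins(replicate_counts_a: Sequence, replicate_counts_b: Sequence) -> tuple:
    """Welch two-sample t test between replicate groups.

    Returns ``(t_statistic, p_two_sided)``. Requires at least two
    replicates per group and nonzero variance in at least one group.
    """
    a = np.asarray(replicate_counts_a, dtype=float).ravel()
    b = np.asarray(replicate_counts_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class SeedingResult:
    """Time series and spatial distribution of one seeding run."""

    times: np.ndarray  # s
    injected_count: np.ndarray
    attached_count: np.ndarray  # live (stick + spread)
    dead_count: np.ndarray  # splash products deposited on the scaffold
    attached_mass: np.ndarray  # kg, live
    bin_edges_mm: np.ndarray = field(
        default_factory=lambda: DEFAULT_BIN_EDGES_MM.copy())
    bin_counts_live: Optional[np.ndarray] = None  # final-time per-bin live
    bin_counts_dead: Optional[np.ndarray] = None
    overflow_live: int = 0
    overflow_dead: int = 0
    design: str = ""
    seed: Optional[int] = None

    @property
    def efficiency(self) -> np.ndarray:
        """Phi(t) in percent (0 where nothing is injected yet)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = 100.0 * self.attached_count / self.injected_count
        return np.where(self.injected_count > 0, phi, 0.0)

    @property
    def final_efficiency(self) -> float:
        n_i = int(self.injected_count[-1])
        if n_i == 0:
            return 0.0
        return seeding_efficiency(int(self.attached_count[-1]), n_i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times,
            "N_i": self.injected_count,
            "N_a": self.attached_count,
            "Phi_pct": self.efficiency,
            "dead": self.dead_count,
        })

    def bins_frame(self) -> pd.DataFrame:
        edges = self.bin_edges_mm
        return pd.DataFrame({
            "bin_lo_mm": edges[:-1],
            "bin_hi_mm": edges[1:],
            "live": self.bin_counts_live,
            "dead": self.bin_counts_dead,
        })


def efficiency_curve(result: SeedingResult, slope_threshold_pct_per_s: float = 1.0,
                     window_s: float = 0.2) -> dict:
    """Phi(t) summary: plateau onset and steady (final) value.

    The plateau onset is the first time the efficiency slope, measured
    over a trailing ``window_s`` window, falls below
    ``slope_threshold_pct_per_s`` after attachment has begun.
    """
    t = result.times
    phi = result.efficiency
    steady = float(phi[-1])
    onset = None
    if np.any(result.attached_count > 0):
        started = np.flatnonzero(result.attached_count > 0)[0]
        for i in range(started, len(t)):
            t0 = t[i] - window_s
            j = np.searchsorted(t, t0)
            if j >= i:
                continue
            slope = (phi[i] - phi[j]) / (t[i] - t[j])
            if slope < slope_threshold_pct_per_s:
                onset = float(t[i])
                break
    return {
        "steady_efficiency_pct": steady,
        "plateau_onset_s": onset,
        "final_attached": int(result.attached_count[-1]),
        "final_injected": int(result.injected_count[-1]),
        "final_dead": int(result.dead_count[-1]),
    }
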