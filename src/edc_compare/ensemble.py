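"""Ensemble-level analysis: pairwise RMSD matrix, central structure,
spread statistics, and time-series scoring/smoothing.

The "central structure" of a conformational ensemble is the member with the
minimum average RMSD to all other members — the standard representative of
an NMR bundle or a simulation cluster.  Trajectory scoring aligns each
frame to the reference anchor and scores its compliance with the density,
turning an MD trajectory into an EDC-versus-time curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import DensityGrid
from .errors import PairingError
from .metrics import edc_score_detail, rmsd_calpha
from .structures import ComplexModel, StructureModel, pair_calpha, select_calpha
from .superpose import align_complex_to_reference

__all__ = [
    "Ensemble",
    "TimeSeries",
    "rmsd_matrix",
    "central_structure",
    "spread_stats",
    "analyze_ensemble",
    "moving_average_series",
    "score_trajectory",
]


def _member_coords(member) -> np.ndarray | None:
    """Members may be raw (n,3) coordinate arrays, StructureModels or
    ComplexModels (mobile-protein Cα are then compared)."""
    if isinstance(member, np.ndarray):
        return np.asarray(member, dtype=np.float64)
    return None


def _pair(member_a, member_b, pairing_mode: str) -> tuple[np.ndarray, np.ndarray]:
    ca = _member_coords(member_a)
    cb = _member_coords(member_b)
    if ca is not None and cb is not None:
        if ca.shape != cb.shape:
            raise PairingError(f"coordinate members differ in shape: {ca.shape} vs {cb.shape}")
        return ca, cb
    ma = member_a.mobile if isinstance(member_a, ComplexModel) else member_a
    mb = member_b.mobile if isinstance(member_b, ComplexModel) else member_b
    return pair_calpha(ma, mb, mode=pairing_mode)


def rmsd_matrix(members, pairing_mode: str = "auto") -> np.ndarray:
    """Symmetric matrix of in-frame Cα RMSDs between all member pairs."""
    n = len(members)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pa, pb = _pair(members[i], members[j], pairing_mode)
            except PairingError as exc:
                raise PairingError(f"members {i} and {j}: {exc}") from exc
            mat[i, j] = mat[j, i] = rmsd_calpha(pa, pb)
    return mat


def central_structure(matrix: np.ndarray) -> int:
    """Index of the member with minimum average RMSD to all the others
    (self-distance excluded; ties broken by lowest index; n = 1 -> 0)."""
    mat = np.asarray(matrix, dtype=np.float64)
    n = mat.shape[0]
    if n == 0:
        raise ValueError("empty ensemble")
    if n == 1:
        return 0
    means = (mat.sum(axis=1)) / (n - 1)  # diagonal is zero
    return int(np.argmin(means))


@dataclass
class SpreadStats:
    max_pairwise_rmsd: float
    max_rmsd_to_central: float
    mean_rmsd_to_central: float


def spread_stats(matrix: np.ndarray, central_index: int | None = None) -> SpreadStats:
    """Ensemble spread read off the RMSD matrix: the overall maximum
    pairwise RMSD plus the max/mean RMSD from the central structure to the
    other members."""
    mat = np.asarray(matrix, dtype=np.float64)
    n = mat.shape[0]
    if central_index is None:
        central_index = central_structure(mat)
    if n == 1:
        return SpreadStats(0.0, 0.0, 0.0)
    row = np.delete(mat[central_index], central_index)
    return SpreadStats(
        max_pairwise_rmsd=float(mat.max()),
        max_rmsd_to_central=float(row.max()),
        mean_rmsd_to_central=float(row.mean()),
    )


@dataclass
class Ensemble:
    """An ordered pose set with its pairwise RMSD matrix and representative."""

    members: list
    rmsd_matrix: np.ndarray
    central_index: int
    max_rmsd: float
    mean_rmsd_to_central: float
    max_rmsd_to_central: float

    def central(self):
        return self.members[self.central_index]


def analyze_ensemble(members, pairing_mode: str = "auto") -> Ensemble:
    mat = rmsd_matrix(members, pairing_mode=pairing_mode)
    idx = central_structure(mat)
    stats = spread_stats(mat, idx)
    return Ensemble(
        members=list(members),
        rmsd_matrix=mat,
        central_index=idx,
        max_rmsd=stats.max_pairwise_rmsd,
        mean_rmsd_to_central=stats.mean_rmsd_to_central,
        max_rmsd_to_central=stats.max_rmsd_to_central,
    )


@dataclass
class TimeSeries:
    """A labelled (time, value) series; times in ns, strictly increasing."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ns": self.times, "value": self.values}).to_csv(path, index=False)


def moving_average_series(series: TimeSeries, window: int) -> TimeSeries:
    """Centered moving average with truncated windows at the ends; times
    unchanged.  A 20-sample window on a 1 ns-sampled series reproduces the
    20 ns smoothing used for trajectory curves."""
    n = series.values.size
    if not isinstance(window, (int, np.integer)) or window < 1 or window > n:
        raise ValueError(f"window must be an integer in [1, {n}], got {window!r}")
    if window == 1:
        return TimeSeries(series.times.copy(), series.values.copy(), series.label)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return TimeSeries(times=series.times.copy(), values=smoothed, label=series.label)


def score_trajectory(
    frames: list[ComplexModel],
    smoothed: DensityGrid,
    reference: StructureModel,
    reference_chain: str,
    heme_radius: float = 8.0,
    times: np.ndarray | None = None,
    dt_ns: float = 1.0,
    sampling_mode: str = "nearest",
) -> TimeSeries:
    """Align every frame to the reference anchor, score its EDC, and return
    the EDC-versus-time series (default time base: frame index x 1 ns)."""
    if not frames:
        raise ValueError("no frames supplied")
    if times is None:
        times = np.arange(len(frames), dtype=np.float64) * dt_ns
    values = []
    for k, frame in enumerate(frames):
        try:
            aligned = align_complex_to_reference(
                frame, reference, reference_chain, heme_radius=heme_radius
            )
        except Exception as exc:
            raise type(exc)(f"frame {k} ({frame.label or 'unlabelled'}): {exc}") from exc
        edc, _ = edc_score_detail(select_calpha(aligned.mobile), smoothed, mode=sampling_mode)
        values.append(edc)
    return TimeSeries(times=np.asarray(times, dtype=np.float64), values=np.array(values),
                      label="edc")
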