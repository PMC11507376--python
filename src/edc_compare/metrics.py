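"""Per-pose and pairwise scores: EDC, Cu–Fe distance, CoM distance, Cα RMSD,
and the comparison table that summarizes a set of poses.

The electron-density compliance (EDC) score of a pose is the mean of the
moving-average-smoothed experimental density sampled at the mobile
protein's Cα positions.  It deliberately ignores atom-scale detail (the
smoothing window removes it) and asks only whether the protein *as a whole*
sits inside density.  It inherits the arbitrary units of the deposited map.

Pairwise distances (CoM shift, Cα RMSD) are computed in the common
reference frame WITHOUT per-pair refitting: after every pose is anchored to
the same reference cytochrome f, a large RMSD between two poses means the
mobile protein sits elsewhere, not that it is internally different.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import DensityGrid, sample_points
from .errors import PairingError, UsageError
from .structures import ComplexModel, center_of_mass, pair_calpha, select_calpha

__all__ = [
    "PoseScore",
    "ComparisonTable",
    "edc_score",
    "edc_score_detail",
    "cofactor_distance",
    "com_distance",
    "rmsd_calpha",
    "build_comparison_table",
]


@dataclass
class PoseScore:
    """Diagonal entry of the comparison table: one pose's own numbers."""

    label: str
    edc: float
    cu_fe_distance: float
    out_of_bounds_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.cu_fe_distance < 0:
            raise ValueError("cu_fe_distance must be >= 0")
        if not 0.0 <= self.out_of_bounds_fraction <= 1.0:
            raise ValueError("out_of_bounds_fraction must lie in [0, 1]")


def edc_score_detail(
    calpha_coords: np.ndarray, smoothed: DensityGrid, mode: str = "nearest"
) -> tuple[float, float]:
    """EDC score plus the fraction of Cα positions falling outside the map.

    Out-of-bounds atoms contribute 0.0 to the average (a pose fully outside
    the box scores exactly 0), and the fraction lets callers flag scores
    that are meaningless because the pose left the map.
    """
    if not smoothed.smoothed:
        raise UsageError(
            "EDC scoring requires a smoothed grid; call smooth_map first "
            "(scoring raw maps reintroduces atom-scale sensitivity)"
        )
    coords = np.atleast_2d(np.asarray(calpha_coords, dtype=np.float64))
    if coords.size == 0:
        raise ValueError("empty coordinate list")
    vals, oob = sample_points(smoothed, coords, mode=mode)
    return float(vals.mean()), float(oob.mean())


def edc_score(calpha_coords: np.ndarray, smoothed: DensityGrid, mode: str = "nearest") -> float:
    """Mean smoothed density over the Cα positions (map units)."""
    return edc_score_detail(calpha_coords, smoothed, mode=mode)[0]


def cofactor_distance(complex_model: ComplexModel) -> float:
    """Cu–Fe distance in Å — the electron-tunneling proxy (functional
    complexes sit below ~15 Å)."""
    return float(np.linalg.norm(complex_model.cu_atom.coord - complex_model.fe_atom.coord))


def com_distance(mobile_a, mobile_b, mass_weighted: bool = True) -> float:
    """Distance between the two mobile-protein centers of mass (Å); both
    poses must already be in the common frame."""
    return float(
        np.linalg.norm(
            center_of_mass(mobile_a, mass_weighted) - center_of_mass(mobile_b, mass_weighted)
        )
    )


def rmsd_calpha(paired_a: np.ndarray, paired_b: np.ndarray) -> float:
    """Root-mean-square distance between paired coordinates (Å), computed
    in place — no refitting."""
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise PairingError(f"paired coordinate lists must match in shape, got {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def score_pose(
    complex_model: ComplexModel, smoothed: DensityGrid, mode: str = "nearest"
) -> PoseScore:
    """Diagonal numbers for one pose: EDC over mobile Cα + Cu–Fe distance."""
    edc, oob = edc_score_detail(select_calpha(complex_model.mobile), smoothed, mode=mode)
    return PoseScore(
        label=complex_model.label,
        edc=edc,
        cu_fe_distance=cofactor_distance(complex_model),
        out_of_bounds_fraction=oob,
    )


@dataclass
class ComparisonTable:
    """Square pose-comparison table.

    Diagonal: per-pose Cu–Fe distance | EDC score.  Upper triangle: distance
    between mobile-protein centers of mass (Å).  Lower triangle: Cα RMSD
    (Å).  All values full precision internally; rounding (1 decimal for
    distances, 3 for EDC) happens only in the formatters.
    """

    labels: list[str]
    diagonal: list[PoseScore]
    com_matrix: np.ndarray
    rmsd_matrix: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.diagonal) != n:
            raise ValueError("one PoseScore per label required")
        for name, m in (("com_matrix", self.com_matrix), ("rmsd_matrix", self.rmsd_matrix)):
            m = np.asarray(m, dtype=np.float64)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if np.any(m < 0) or not np.allclose(m, m.T, atol=1e-9):
                raise ValueError(f"{name} must be symmetric and non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper(self, i: int, j: int) -> float:
        """CoM distance for the unordered pair (i, j)."""
        return float(self.com_matrix[i, j])

    def lower(self, i: int, j: int) -> float:
        """Cα RMSD for the unordered pair (i, j)."""
        return float(self.rmsd_matrix[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        """Formatted table: diagonal 'd|edc', upper CoM, lower RMSD."""
        cells = []
        for i in range(self.n):
            row = []
            for j in range(self.n):
                if i == j:
                    d = self.diagonal[i]
                    row.append(f"{d.cu_fe_distance:.1f}|{d.edc:.3f}")
                elif i < j:
                    row.append(f"{self.com_matrix[i, j]:.1f}")
                else:
                    row.append(f"{self.rmsd_matrix[i, j]:.1f}")
            cells.append(row)
        return pd.DataFrame(cells, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="structure")

    def to_json(self, path=None):
        payload = {
            "labels": self.labels,
            "diagonal": [
                {
                    "label": d.label,
                    "cu_fe_distance": d.cu_fe_distance,
                    "edc": d.edc,
                    "out_of_bounds_fraction": d.out_of_bounds_fraction,
                }
                for d in self.diagonal
            ],
            "com_distance": self.com_matrix.tolist(),
            "rmsd_calpha": self.rmsd_matrix.tolist(),
            "metadata": self.metadata,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return payload


def build_comparison_table(
    complexes: list[ComplexModel],
    smoothed: DensityGrid,
    pairing_mode: str = "auto",
    mass_weighted_com: bool = True,
    sampling_mode: str = "nearest",
) -> ComparisonTable:
    """Assemble the full comparison table from poses already aligned to a
    common reference.

    Diagonal entries come from :func:`score_pose`; the upper triangle holds
    mobile-protein CoM distances and the lower triangle mobile Cα RMSDs,
    both measured directly in the common frame.
    """
    if not complexes:
        raise ValueError("need at least one complex")
    labels = [c.label or f"pose{i}" for i, c in enumerate(complexes)]
    diagonal = [score_pose(c, smoothed, mode=sampling_mode) for c in complexes]
    n = len(complexes)
    com = np.zeros((n, n))
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            com[i, j] = com[j, i] = com_distance(
                complexes[i].mobile, complexes[j].mobile, mass_weighted=mass_weighted_com
            )
            try:
                pa, pb = pair_calpha(complexes[i].mobile, complexes[j].mobile, mode=pairing_mode)
            except PairingError as exc:
                raise PairingError(f"pairing {labels[i]} vs {labels[j]}: {exc}") from exc
            rmsd[i, j] = rmsd[j, i] = rmsd_calpha(pa, pb)
    return ComparisonTable(
        labels=labels,
        diagonal=diagonal,
        com_matrix=com,
        rmsd_matrix=rmsd,
        metadata={"pairing_mode": pairing_mode, "mass_weighted_com": mass_weighted_com,
                  "sampling_mode": sampling_mode},
    )
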