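"""Least-squares rigid superposition and the common reference frame.

All pairwise pose metrics in this package are computed *after* every pose
has been placed in one common frame — the frame of a reference structure's
cytochrome f chain, fitted on the anchor residues surrounding the heme.
Fitting on the anchor only (never on the mobile protein) is what makes the
subsequent mobile-protein distances measure pose differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CofactorError, GeometryError, SelectionError
from .structures import ComplexModel, StructureModel, pair_calpha

__all__ = ["Transform", "kabsch", "align_complex_to_reference"]

_HEME_NAMES = {"HEC", "HEM", "HEB", "HEA", "HEO"}


@dataclass
class Transform:
    """A proper rigid transform x -> R x + t with its fit quality."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float
    n_fit_atoms: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise GeometryError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64)
        return coords @ self.rotation.T + self.translation

    def is_identity(self, atol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def kabsch(mobile_coords: np.ndarray, ref_coords: np.ndarray) -> Transform:
    """Optimal proper-rotation least-squares superposition (Kabsch).

    Returns the transform minimizing the RMSD of ``R @ mobile + t`` to the
    reference over the paired points.  Reflections are excluded by the
    usual determinant sign correction on the SVD.
    """
    mob = np.asarray(mobile_coords, dtype=np.float64)
    ref = np.asarray(ref_coords, dtype=np.float64)
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape != ref.shape:
        raise GeometryError(f"need matching (n,3) arrays, got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 point pairs, got {n}")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    m0, r0 = mob - cm, ref - cr
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise GeometryError("point set is collinear; rotation is underdetermined")
    h = m0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return Transform(rotation=rot, translation=trans, fit_rmsd=rmsd, n_fit_atoms=n)


def _reference_heme_fe(reference: StructureModel, reference_chain: str):
    chain_atoms = [a for a in reference.atoms if a.chain_id == reference_chain]
    if not chain_atoms:
        raise SelectionError(
            f"chain {reference_chain!r} not in reference "
            f"(has {sorted(set(a.chain_id for a in reference.atoms))})"
        )
    fes = [a for a in chain_atoms if a.element.upper() == "FE"]
    if not fes:
        raise CofactorError(f"no heme Fe in reference chain {reference_chain!r}")
    if len(fes) > 1:
        heme_fes = [a for a in fes if a.residue_name in _HEME_NAMES]
        if len(heme_fes) == 1:
            return heme_fes[0], chain_atoms
        raise CofactorError(
            f"{len(fes)} Fe atoms in reference chain {reference_chain!r}; cannot choose"
        )
    return fes[0], chain_atoms


def _fit_pairs(
    anchor: StructureModel,
    ref_atoms: list,
    fe_coord: np.ndarray,
    heme_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair anchor atoms to reference atoms over reference residues that
    have any heavy atom within ``heme_radius`` of the heme Fe.

    Pairing key is (residue number, atom name); when the anchor and the
    reference share too few residue numbers the residue correspondence is
    rebuilt from a Cα sequence alignment first.
    """
    near_res = {
        (a.chain_id, a.residue_number)
        for a in ref_atoms
        if a.element.upper() != "H" and float(np.linalg.norm(a.coord - fe_coord)) <= heme_radius
    }
    ref_sel = {
        (a.residue_number, a.name): a.coord
        for a in ref_atoms
        if (a.chain_id, a.residue_number) in near_res and a.element.upper() != "H"
    }
    anchor_by_key = {
        (a.residue_number, a.name): a.coord for a in anchor.atoms if a.element.upper() != "H"
    }
    keys = sorted(set(ref_sel) & set(anchor_by_key))
    if len(keys) < 3:
        # numbering schemes differ: remap anchor residue numbers onto the
        # reference numbering through a Cα sequence alignment
        ref_model = StructureModel(1, list(ref_atoms), "reference-chain")
        try:
            ca_a, ca_r = pair_calpha(anchor, ref_model, mode="sequence")
        except Exception as exc:  # no CA / unalignable -> geometry error below
            raise GeometryError(
                f"cannot establish residue correspondence with reference: {exc}"
            ) from exc
        # map each anchor Cα to its partner's residue number via coordinates
        coord_to_num = {tuple(np.round(a.coord, 4)): a.residue_number for a in ref_model.atoms}
        num_map = {}
        anchor_ca = {tuple(np.round(a.coord, 4)): a.residue_number for a in anchor.atoms}
        for pa, pr in zip(ca_a, ca_r):
            na = anchor_ca.get(tuple(np.round(pa, 4)))
            nr = coord_to_num.get(tuple(np.round(pr, 4)))
            if na is not None and nr is not None:
                num_map[na] = nr
        anchor_by_key = {
            (num_map[a.residue_number], a.name): a.coord
            for a in anchor.atoms
            if a.residue_number in num_map and a.element.upper() != "H"
        }
        keys = sorted(set(ref_sel) & set(anchor_by_key))
    if len(keys) < 3:
        raise GeometryError(
            f"only {len(keys)} anchor/reference atom pairs within "
            f"{heme_radius} Å of the heme Fe; alignment is underdetermined"
        )
    mob = np.array([anchor_by_key[k] for k in keys])
    ref = np.array([ref_sel[k] for k in keys])
    return mob, ref


def align_complex_to_reference(
    complex_model: ComplexModel,
    reference: StructureModel,
    reference_chain: str,
    heme_radius: float = 8.0,
) -> ComplexModel:
    """Rigidly place a whole complex into the reference frame.

    A single transform is fitted (Kabsch) on the anchor-protein heavy atoms
    paired to the reference-chain residues surrounding the heme Fe (any
    heavy atom within ``heme_radius`` Å of the Fe), then applied to both
    proteins and the cofactors.  The transform and its fit RMSD are stored
    in the returned complex's provenance.
    """
    if not heme_radius > 0:
        raise ValueError("heme_radius must be positive")
    fe, chain_atoms = _reference_heme_fe(reference, reference_chain)
    mob, ref = _fit_pairs(complex_model.anchor, chain_atoms, fe.coord, heme_radius)
    tr = kabsch(mob, ref)
    aligned = complex_model.transformed(tr.rotation, tr.translation)
    aligned.provenance["alignment"] = {
        "fit_rmsd": tr.fit_rmsd,
        "n_fit_atoms": tr.n_fit_atoms,
        "heme_radius": heme_radius,
        "reference_chain": reference_chain,
    }
    aligned.provenance["transform"] = tr
    return aligned
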