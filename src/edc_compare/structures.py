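"""Atomic models: PDB/mmCIF reading, atom selections, the two-body complex.

The data model is deliberately flat: a :class:`StructureModel` is an ordered
list of :class:`Atom` records, and a :class:`ComplexModel` groups the two
protein subsets of a pose — the anchored heme protein (cytochrome f role)
and the mobile copper protein (plastocyanin role) — together with the two
redox cofactor atoms whose separation gauges electron-tunneling feasibility.

Parsing is delegated to gemmi (PDB and mmCIF, multi-model NMR entries);
waters and hydrogens are excluded by default since no metric in the
pipeline uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import CofactorError, SelectionError, PairingError

__all__ = [
    "Atom",
    "StructureModel",
    "ComplexModel",
    "read_structure",
    "write_pdb",
    "split_complex",
    "select_calpha",
    "calpha_records",
    "pair_calpha",
    "select_within_radius",
    "center_of_mass",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Atom:
    """One atom: name, element, Cartesian Å coordinate, residue context, mass."""

    name: str
    element: str
    coord: np.ndarray
    residue_number: int
    residue_name: str
    chain_id: str
    mass: float
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=np.float64)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if not self.mass > 0:
            raise ValueError(f"atom {self.name}: mass must be positive")

    def moved_to(self, coord: np.ndarray) -> "Atom":
        return replace(self, coord=np.asarray(coord, dtype=np.float64))


@dataclass
class StructureModel:
    """One coordinate set (model) of a structure file."""

    model_index: int
    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a StructureModel needs at least one atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def subset(self, predicate) -> "StructureModel":
        picked = [a for a in self.atoms if predicate(a)]
        if not picked:
            raise SelectionError(f"empty selection from {self.source_id or 'model'}")
        return StructureModel(self.model_index, picked, self.source_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        new_coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, new_coords)]
        return StructureModel(self.model_index, atoms, self.source_id)


@dataclass
class ComplexModel:
    """One pose of the two-protein complex.

    ``anchor`` plays the cytochrome f role (carries the heme Fe), ``mobile``
    the plastocyanin role (carries the Cu).  The two atom subsets are
    disjoint by construction of :func:`split_complex`.
    """

    anchor: StructureModel
    mobile: StructureModel
    cu_atom: Atom
    fe_atom: Atom
    label: str = ""
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.cu_atom.element.upper() != "CU":
            raise CofactorError(f"cu_atom element is {self.cu_atom.element!r}, expected Cu")
        if self.fe_atom.element.upper() != "FE":
            raise CofactorError(f"fe_atom element is {self.fe_atom.element!r}, expected Fe")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexModel":
        r = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        return ComplexModel(
            anchor=self.anchor.transformed(r, t),
            mobile=self.mobile.transformed(r, t),
            cu_atom=self.cu_atom.moved_to(r @ self.cu_atom.coord + t),
            fe_atom=self.fe_atom.moved_to(r @ self.fe_atom.coord + t),
            label=self.label,
            provenance=dict(self.provenance),
        )


def _element_of(gatom: gemmi.Atom) -> gemmi.Element:
    el = gatom.element
    if el.name and el.name not in ("X", ""):
        return el
    # element column absent: infer from the atom name (strip digits/spaces)
    guess = "".join(c for c in gatom.name if c.isalpha())
    for cand in (guess[:2].capitalize(), guess[:1].upper()):
        el2 = gemmi.Element(cand)
        if el2.name not in ("X", ""):
            return el2
    return gemmi.Element("C")


def _convert_model(
    gmodel, model_index: int, source_id: str, include_waters: bool, include_hydrogens: bool
) -> StructureModel:
    atoms: list[Atom] = []
    for chain in gmodel:
        for res in chain:
            if not include_waters and res.name.strip() in _WATER_NAMES:
                continue
            for ga in res:
                el = _element_of(ga)
                if not include_hydrogens and el.is_hydrogen:
                    continue
                if ga.altloc not in ("", "\0", "A"):
                    continue  # keep a single conformer
                atoms.append(
                    Atom(
                        name=ga.name.strip(),
                        element=el.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        residue_number=res.seqid.num,
                        residue_name=res.name.strip(),
                        chain_id=chain.name,
                        mass=float(el.weight),
                        hetero=res.het_flag == "H",
                    )
                )
    return StructureModel(model_index, atoms, source_id)


def read_structure(
    path,
    model_index: int | None = None,
    include_waters: bool = False,
    include_hydrogens: bool = False,
):
    """Read a PDB or mmCIF file.

    Returns a list of :class:`StructureModel` (one per model, in file order)
    or, when ``model_index`` is given, the single model with that 1-based
    index.  Hetero atoms (Cu, hemes) are retained; waters and hydrogens are
    dropped unless requested.
    """
    st = gemmi.read_structure(str(path))
    models = []
    for i, gmodel in enumerate(st):
        try:
            num = int(gmodel.num)
        except (AttributeError, TypeError, ValueError):
            num = i + 1
        models.append(
            _convert_model(
                gmodel, num, f"{st.name or path} model {num}", include_waters, include_hydrogens
            )
        )
    if model_index is None:
        return models
    for m in models:
        if m.model_index == model_index:
            return m
    raise LookupError(
        f"model {model_index} not in {path}; available: {[m.model_index for m in models]}"
    )


def write_pdb(models, path) -> None:
    """Write one model or a list of models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    st.name = "edc"
    for sm in models:
        gm = gemmi.Model(int(sm.model_index))
        # gemmi containers copy on add: group atoms first, then assemble
        # bottom-up (atoms -> residue -> chain -> model).
        chain_order: list[str] = []
        grouped: dict[str, list[tuple[tuple, list]]] = {}
        for atom in sm.atoms:
            if atom.chain_id not in grouped:
                grouped[atom.chain_id] = []
                chain_order.append(atom.chain_id)
            residues = grouped[atom.chain_id]
            key = (atom.residue_number, atom.residue_name)
            if not residues or residues[-1][0] != key:
                residues.append((key, []))
            residues[-1][1].append(atom)
        for chain_id in chain_order:
            chain = gemmi.Chain(chain_id)
            for (resnum, resname), atoms in grouped[chain_id]:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                res.het_flag = "H" if atoms[0].hetero else "A"
                for atom in atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coord)
                    ga.occ = 1.0
                    res.add_atom(ga)
                chain.add_residue(res)
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def _find_cofactor(atoms: list[Atom], element: str, role: str) -> Atom:
    cands = [a for a in atoms if a.element.upper() == element.upper()]
    if len(cands) != 1:
        desc = [
            f"{a.chain_id}/{a.residue_name}{a.residue_number}/{a.name}" for a in cands
        ]
        raise CofactorError(
            f"expected exactly one {element} in the {role} subset, found {len(cands)}: {desc}"
        )
    return cands[0]


def split_complex(
    model: StructureModel,
    mobile_chains,
    anchor_chains,
    label: str = "",
    multi_heme: str = "error",
) -> ComplexModel:
    """Partition a model into the mobile (Cu-bearing) and anchor (heme Fe)
    subsets by chain id and resolve the two cofactor atoms.

    ``multi_heme="nearest"`` accepts a multi-heme anchor (a whole cytochrome
    bf, say) by picking the Fe nearest the Cu; the default is strict.
    """
    mobile_chains = set(mobile_chains)
    anchor_chains = set(anchor_chains)
    if not mobile_chains or not anchor_chains:
        raise ValueError("mobile_chains and anchor_chains must both be non-empty")
    if mobile_chains & anchor_chains:
        raise ValueError("mobile and anchor chain sets must be disjoint")
    present = set(model.chain_ids())
    for name, wanted in (("mobile", mobile_chains), ("anchor", anchor_chains)):
        missing = wanted - present
        if missing:
            raise SelectionError(
                f"{name} chains {sorted(missing)} not in model (has {sorted(present)})"
            )
    mobile = model.subset(lambda a: a.chain_id in mobile_chains)
    anchor = model.subset(lambda a: a.chain_id in anchor_chains)
    cu = _find_cofactor(mobile.atoms, "Cu", "mobile")
    fes = [a for a in anchor.atoms if a.element.upper() == "FE"]
    if len(fes) == 1:
        fe = fes[0]
    elif len(fes) > 1 and multi_heme == "nearest":
        fe = min(fes, key=lambda a: float(np.linalg.norm(a.coord - cu.coord)))
    else:
        fe = _find_cofactor(anchor.atoms, "Fe", "anchor")
    return ComplexModel(
        anchor=anchor,
        mobile=mobile,
        cu_atom=cu,
        fe_atom=fe,
        label=label or model.source_id,
    )


def calpha_records(model: StructureModel) -> list[Atom]:
    """Cα atoms (name CA, element C), one per residue, in (chain,
    residue-number) order."""
    seen: dict[tuple[str, int], Atom] = {}
    for a in model.atoms:
        if a.name == "CA" and a.element.upper() == "C":
            seen.setdefault((a.chain_id, a.residue_number), a)
    records = [seen[k] for k in sorted(seen)]
    if not records:
        raise SelectionError(f"no Cα atoms in {model.source_id or 'model'}")
    return records


def select_calpha(model: StructureModel) -> np.ndarray:
    """Ordered (n, 3) array of Cα coordinates; residues lacking a CA atom
    are skipped."""
    return np.array([a.coord for a in calpha_records(model)])


_THREE_TO_ONE = None


def _one_letter(resname: str) -> str:
    global _THREE_TO_ONE
    if _THREE_TO_ONE is None:
        _THREE_TO_ONE = {}
    code = _THREE_TO_ONE.get(resname)
    if code is None:
        info = gemmi.find_tabulated_residue(resname)
        code = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
        if not code.isalpha():
            code = "X"
        _THREE_TO_ONE[resname] = code
    return code


def pair_calpha(
    model_a: StructureModel, model_b: StructureModel, mode: str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Put the Cα atoms of two (possibly homologous) proteins into
    correspondence and return two equal-length coordinate arrays.

    Modes: ``"number"`` pairs by (chain-position, residue number);
    ``"sequence"`` pairs by a global identity-scored sequence alignment
    (used across homologs whose numbering differs, e.g. spinach vs poplar
    plastocyanin); ``"auto"`` uses numbers when at least half of the
    residues share a number, else falls back to the alignment.  Unpaired
    residues are dropped.
    """
    rec_a = calpha_records(model_a)
    rec_b = calpha_records(model_b)
    by_num_a = {a.residue_number: a for a in rec_a}
    by_num_b = {b.residue_number: b for b in rec_b}
    shared = sorted(set(by_num_a) & set(by_num_b))
    if mode not in ("auto", "number", "sequence"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    use_number = mode == "number" or (
        mode == "auto" and len(shared) >= 0.5 * max(len(rec_a), len(rec_b))
    )
    if use_number:
        if not shared:
            raise PairingError(
                f"no shared residue numbers between {model_a.source_id} and {model_b.source_id}"
            )
        pairs = [(by_num_a[n], by_num_b[n]) for n in shared]
    else:
        from Bio import Align

        seq_a = "".join(_one_letter(a.residue_name) for a in rec_a)
        seq_b = "".join(_one_letter(b.residue_name) for b in rec_b)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -1.0
        aligner.extend_gap_score = -0.5
        aln = aligner.align(seq_a, seq_b)[0]
        pairs = []
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            for off in range(ea - sa):
                pairs.append((rec_a[sa + off], rec_b[sb + off]))
        if not pairs:
            raise PairingError(
                f"sequence alignment paired no residues between "
                f"{model_a.source_id} and {model_b.source_id}"
            )
    ca = np.array([p[0].coord for p in pairs])
    cb = np.array([p[1].coord for p in pairs])
    return ca, cb


def select_within_radius(model: StructureModel, center, radius: float, atom_filter=None):
    """All atoms passing ``atom_filter`` within ``radius`` Å of ``center``,
    in deterministic (chain, residue number, atom name) order."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=np.float64)
    picked = [
        a
        for a in model.atoms
        if (atom_filter is None or atom_filter(a))
        and float(np.linalg.norm(a.coord - center)) <= radius
    ]
    if not picked:
        raise SelectionError(f"no atoms within {radius} Å of {center.tolist()}")
    picked.sort(key=lambda a: (a.chain_id, a.residue_number, a.name))
    return picked


def center_of_mass(atoms, mass_weighted: bool = True) -> np.ndarray:
    """Mass-weighted (default) or geometric mean coordinate of an atom set
    or :class:`StructureModel`."""
    if isinstance(atoms, StructureModel):
        atoms = atoms.atoms
    atoms = list(atoms)
    if not atoms:
        raise SelectionError("center of mass of an empty atom set")
    coords = np.array([a.coord for a in atoms])
    if mass_weighted:
        masses = np.array([a.mass for a in atoms])
        return coords.T @ masses / masses.sum()
    return coords.mean(axis=0)
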