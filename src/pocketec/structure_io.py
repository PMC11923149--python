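"""Reading, filtering, writing and perturbing protein structures (PDB format).

Only ATOM-record protein content is kept: HETATM entries (waters, ligands,
ions) are discarded, nucleic-acid chains are removed, only the first model of
a multi-model (e.g. NMR) file is used, and alternate locations are resolved to
the highest-occupancy conformer.  All chains of a file stay together in one
:class:`Structure`, so a pocket descriptor can see chemistry from neighbouring
chains.  Coordinates are Ångström throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Optional, Sequence

import gemmi
import numpy as np

from .eclabel import ECLabel

__all__ = [
    "Atom",
    "Structure",
    "EmptyStructureError",
    "MalformedRecordError",
    "read_structure",
    "read_structure_file",
    "write_structure",
    "mutate_to_alanine",
    "perturb_coordinates",
]

#: Residue names treated as nucleic acids when deciding to drop a chain.
NUCLEIC_RESIDUES = frozenset({"DA", "DC", "DG", "DT", "A", "C", "G", "U"})

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

#: Atoms kept by an alanine mutation (glycine simply stays backbone-only).
_ALANINE_ATOMS = frozenset({"N", "CA", "C", "O", "CB", "OXT"})


class EmptyStructureError(ValueError):
    """No protein ATOM records survive parsing/filtering."""


class MalformedRecordError(ValueError):
    """A coordinate field could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        super().__init__(message)
        self.line_number = line_number


@dataclasses.dataclass(frozen=True)
class Atom:
    """One heavy atom (or hydrogen) of a protein structure."""

    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    coord: np.ndarray  # shape (3,), Å
    is_hydrogen: bool = False

    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclasses.dataclass
class Structure:
    """An ordered list of atoms with provenance and an optional EC label."""

    atoms: list[Atom]
    source_id: str = ""
    label: Optional[ECLabel] = None
    deposition_date: Optional[str] = None
    #: free-form provenance (e.g. planted-motif positions of synthetic data)
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.source_id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=np.float64)

    def residue_keys(self) -> list[tuple]:
        """Unique residue keys in file order."""
        seen: dict[tuple, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key(), None)
        return list(seen)

    def residues(self) -> dict[tuple, list[Atom]]:
        """Residue key -> atoms, preserving file order."""
        out: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key(), []).append(a)
        return out

    def ca_positions(self) -> tuple[list[tuple], np.ndarray]:
        """Residue keys that have a Cα and the corresponding positions."""
        keys, pos = [], []
        for key, atoms in self.residues().items():
            for a in atoms:
                if a.atom_name == "CA" and not a.is_hydrogen:
                    keys.append(key)
                    pos.append(a.coord)
                    break
        return keys, (
            np.array(pos, dtype=np.float64) if pos else np.zeros((0, 3))
        )


def _chain_is_nucleic(residue_names: Sequence[str]) -> bool:
    if not residue_names:
        return False
    n_nuc = sum(1 for r in residue_names if r in NUCLEIC_RESIDUES)
    return n_nuc / len(residue_names) > 0.5


def read_structure(
    pdb_text: str,
    keep_hydrogens: bool = False,
    source_id: str = "",
    label: Optional[ECLabel] = None,
) -> Structure:
    """Parse PDB text into a filtered :class:`Structure`.

    Keeps ATOM records of protein chains only; first model; highest-occupancy
    alternate location (ties resolved to the first occurrence); hydrogens are
    dropped unless ``keep_hydrogens``.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise MalformedRecordError(f"malformed record: {exc}", _guess_bad_line(pdb_text)) from exc

    _date_key = "_pdbx_database_status.recvd_initial_deposition_date"
    deposition_date = st.info[_date_key] if _date_key in st.info else None

    atoms: list[Atom] = []
    if len(st) > 0:
        model = st[0]  # first model only
        for chain in model:
            res_names = [r.name for r in chain]
            if _chain_is_nucleic(res_names):
                continue
            for res in chain:
                if res.het_flag != "A":  # ATOM records only
                    continue
                if res.name in WATER_RESIDUES:
                    continue
                chosen: dict[str, int] = {}  # atom name -> index of best altloc
                occ_best: dict[str, float] = {}
                for idx, at in enumerate(res):
                    if at.name not in chosen or at.occ > occ_best[at.name]:
                        chosen[at.name] = idx
                        occ_best[at.name] = at.occ
                for idx, at in enumerate(res):  # file order among chosen conformers
                    if chosen[at.name] != idx:
                        continue
                    is_h = at.element.is_hydrogen
                    if is_h and not keep_hydrogens:
                        continue
                    coord = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=np.float64)
                    if not np.all(np.isfinite(coord)):
                        raise MalformedRecordError(
                            f"non-finite coordinate for atom {at.name} in {res.name} {res.seqid.num}"
                        )
                    atoms.append(
                        Atom(
                            atom_name=at.name,
                            element=at.element.name,
                            residue_name=res.name,
                            residue_seq=res.seqid.num,
                            insertion_code=(res.seqid.icode or " ").strip() or "",
                            chain_id=chain.name,
                            coord=coord,
                            is_hydrogen=is_h,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(
            f"no protein ATOM records in {source_id!r} after filtering"
        )
    return Structure(atoms=atoms, source_id=source_id, label=label, deposition_date=deposition_date)


def _guess_bad_line(pdb_text: str) -> Optional[int]:
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for field in (line[30:38], line[38:46], line[46:54]):
                try:
                    float(field)
                except ValueError:
                    return i
    return None


def read_structure_file(path, keep_hydrogens: bool = False, label: Optional[ECLabel] = None) -> Structure:
    with open(path) as fh:
        text = fh.read()
    import os

    sid = os.path.splitext(os.path.basename(str(path)))[0]
    return read_structure(text, keep_hydrogens=keep_hydrogens, source_id=sid, label=label)


def write_structure(s: Structure, path) -> None:
    """Write a Structure back out as minimal PDB ATOM records (via gemmi)."""
    # gemmi's add_* methods copy their argument, so assemble bottom-up.
    by_chain: dict[str, dict[tuple, list[Atom]]] = {}
    for a in s.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(a.residue_key(), []).append(a)

    st = gemmi.Structure()
    st.name = s.source_id or "pocketec"
    model = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        ch = gemmi.Chain(chain_id)
        for key, res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(res_atoms[0].residue_seq, res_atoms[0].insertion_code or " ")
            res.het_flag = "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coord)
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def mutate_to_alanine(s: Structure, selector: Callable[[Atom], bool] | Iterable[tuple] | None = None) -> Structure:
    """Rename selected residues to ALA and drop side-chain atoms beyond Cβ.

    ``selector`` is either a predicate over one atom of the residue (applied to
    the residue's first atom), an iterable of residue keys, or None (= all
    residues).  Backbone (N, Cα, C, O) and Cβ coordinates are untouched;
    glycine gains no atoms.
    """
    residues = s.residues()
    if selector is None:
        selected = set(residues)
    elif callable(selector):
        selected = {key for key, atoms in residues.items() if selector(atoms[0])}
    else:
        selected = set(selector)

    new_atoms: list[Atom] = []
    for a in s.atoms:
        if a.residue_key() in selected:
            if a.atom_name not in _ALANINE_ATOMS or a.is_hydrogen:
                continue
            new_atoms.append(dataclasses.replace(a, residue_name="ALA"))
        else:
            new_atoms.append(a)
    return Structure(
        atoms=new_atoms, source_id=s.source_id, label=s.label,
        deposition_date=s.deposition_date, metadata=dict(s.metadata),
    )


def perturb_coordinates(s: Structure, amplitude: float, seed: int) -> Structure:
    """Displace every atom by an independent random vector of norm ≤ amplitude.

    Direction uniform on the sphere, radius uniform in [0, amplitude]; the same
    seed reproduces the same output bit-for-bit.
    """
    if amplitude < 0:
        raise ValueError(f"invalid amplitude {amplitude!r}: must be >= 0")
    if amplitude == 0.0:
        return Structure(
            atoms=list(s.atoms), source_id=s.source_id, label=s.label,
            deposition_date=s.deposition_date, metadata=dict(s.metadata),
        )
    rng = np.random.default_rng(seed)
    n = len(s.atoms)
    direction = rng.normal(size=(n, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    direction /= norms
    radius = rng.uniform(0.0, amplitude, size=(n, 1))
    disp = direction * radius
    new_atoms = [
        dataclasses.replace(a, coord=a.coord + disp[i]) for i, a in enumerate(s.atoms)
    ]
    return Structure(
        atoms=new_atoms, source_id=s.source_id, label=s.label,
        deposition_date=s.deposition_date, metadata=dict(s.metadata),
    )
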