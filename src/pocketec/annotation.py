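"""Chemical-environment typing of residues and heavy atoms (graph node types).

Nodes are typed by local chemical environment rather than by element, in the
spirit of the ff19SB force-field atom types: a backbone carbonyl carbon, an
aromatic ring carbon and a methyl carbon are different classes even though all
three are carbon.  The default scheme has exactly 21 residue classes (20
standard amino acids + "other"), 31 heavy-atom classes and 20 hydrogen
classes.  The heavy-atom table here is a documented reconstruction from
force-field atom-type groupings, not a copy of any published table; users can
load their own tab-separated mapping instead.

The hydrogen vocabulary is implemented but unused by the default models
(hydrogen nodes multiply graph size for little classification signal).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

__all__ = [
    "AnnotationScheme",
    "default_scheme",
    "load_scheme",
    "STANDARD_RESIDUES",
    "RESIDUE_HEAVY_ATOMS",
    "WrongVocabularyError",
]

SCHEME_VERSION = "pocketec-ff-like-1"

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Standard heavy-atom names per residue (backbone N/CA/C/O plus side chain).
RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

# ---------------------------------------------------------------------------
# Heavy-atom classes (exactly 31, catch-all included).

HEAVY_ATOM_CLASSES = (
    "C_ALPHA",              # 0  backbone sp3 α-carbon, all residues
    "C_CARBONYL",           # 1  backbone C; side-chain amide C (ASN CG, GLN CD)
    "C_CARBOXYLATE",        # 2  ASP CG, GLU CD
    "C_SP3_CH3",            # 3  methyl carbons
    "C_SP3_CH2",            # 4  aliphatic methylene carbons
    "C_SP3_CH",             # 5  branched aliphatic CH (VAL CB, LEU CG, ILE CB)
    "C_SP3_O",              # 6  sp3 C bonded to hydroxyl O (SER CB, THR CB)
    "C_SP3_S",              # 7  sp3 C bonded to S (CYS CB, MET CG)
    "C_SP3_N",              # 8  sp3 C bonded to side-chain/ring N (LYS CE, ARG CD, PRO CD)
    "C_AROMATIC_CH",        # 9  aromatic CH (PHE/TYR/TRP benzene-like)
    "C_AROMATIC_JUNCTION",  # 10 ring C without H at the Cβ attachment (CG of PHE/TYR/TRP/HIS)
    "C_INDOLE_JUNCTION",    # 11 TRP fused-ring junction (CD2, CE2)
    "C_PYRROLE_CH",         # 12 TRP CD1 (N-adjacent five-ring CH)
    "C_IMIDAZOLE_CH",       # 13 HIS CD2, CE1
    "C_PHENOL",             # 14 TYR CZ (carries the OH)
    "C_GUANIDINIUM",        # 15 ARG CZ
    "N_BACKBONE_AMIDE",     # 16 backbone N (except proline)
    "N_PROLINE",            # 17 PRO backbone N (tertiary)
    "N_AMIDE_SIDE",         # 18 ASN ND2, GLN NE2
    "N_AMMONIUM",           # 19 LYS NZ
    "N_GUANIDINIUM",        # 20 ARG NE, NH1, NH2
    "N_IMIDAZOLE",          # 21 HIS ND1, NE2
    "N_INDOLE",             # 22 TRP NE1
    "O_CARBONYL",           # 23 backbone O; ASN OD1, GLN OE1
    "O_CARBOXYLATE",        # 24 ASP OD1/OD2, GLU OE1/OE2, C-terminal OXT
    "O_HYDROXYL_PRI",       # 25 SER OG
    "O_HYDROXYL_SEC",       # 26 THR OG1
    "O_PHENOL",             # 27 TYR OH
    "S_THIOL",              # 28 CYS SG
    "S_THIOETHER",          # 29 MET SD
    "OTHER_HEAVY",          # 30 catch-all (non-standard residues/atoms)
)

_METHYL = {
    ("ALA", "CB"), ("VAL", "CG1"), ("VAL", "CG2"), ("LEU", "CD1"), ("LEU", "CD2"),
    ("ILE", "CG2"), ("ILE", "CD1"), ("THR", "CG2"), ("MET", "CE"),
}
_BRANCH_CH = {("VAL", "CB"), ("LEU", "CG"), ("ILE", "CB")}
_SP3_O = {("SER", "CB"), ("THR", "CB")}
_SP3_S = {("CYS", "CB"), ("MET", "CG")}
_SP3_N = {("LYS", "CE"), ("ARG", "CD"), ("PRO", "CD")}
_AROM_CH = {
    ("PHE", "CD1"), ("PHE", "CD2"), ("PHE", "CE1"), ("PHE", "CE2"), ("PHE", "CZ"),
    ("TYR", "CD1"), ("TYR", "CD2"), ("TYR", "CE1"), ("TYR", "CE2"),
    ("TRP", "CE3"), ("TRP", "CZ2"), ("TRP", "CZ3"), ("TRP", "CH2"),
}
_AROM_JUNCTION = {("PHE", "CG"), ("TYR", "CG"), ("TRP", "CG"), ("HIS", "CG")}


def _classify_heavy(residue_name: str, atom_name: str) -> str:
    """Rule-based (residue, heavy atom) -> class name for standard residues."""
    res, at = residue_name, atom_name
    if at == "CA":
        return "C_ALPHA"
    if at == "N":
        return "N_PROLINE" if res == "PRO" else "N_BACKBONE_AMIDE"
    if at == "C":
        return "C_CARBONYL"
    if at == "O":
        return "O_CARBONYL"
    if at == "OXT":
        return "O_CARBOXYLATE"
    pair = (res, at)
    if pair in {("ASN", "CG"), ("GLN", "CD")}:
        return "C_CARBONYL"
    if pair in {("ASP", "CG"), ("GLU", "CD")}:
        return "C_CARBOXYLATE"
    if pair in _METHYL:
        return "C_SP3_CH3"
    if pair in _BRANCH_CH:
        return "C_SP3_CH"
    if pair in _SP3_O:
        return "C_SP3_O"
    if pair in _SP3_S:
        return "C_SP3_S"
    if pair in _SP3_N:
        return "C_SP3_N"
    if pair in _AROM_CH:
        return "C_AROMATIC_CH"
    if pair in _AROM_JUNCTION:
        return "C_AROMATIC_JUNCTION"
    if pair in {("TRP", "CD2"), ("TRP", "CE2")}:
        return "C_INDOLE_JUNCTION"
    if pair == ("TRP", "CD1"):
        return "C_PYRROLE_CH"
    if pair in {("HIS", "CD2"), ("HIS", "CE1")}:
        return "C_IMIDAZOLE_CH"
    if pair == ("TYR", "CZ"):
        return "C_PHENOL"
    if pair == ("ARG", "CZ"):
        return "C_GUANIDINIUM"
    if pair in {("ASN", "ND2"), ("GLN", "NE2")}:
        return "N_AMIDE_SIDE"
    if pair == ("LYS", "NZ"):
        return "N_AMMONIUM"
    if pair in {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}:
        return "N_GUANIDINIUM"
    if pair in {("HIS", "ND1"), ("HIS", "NE2")}:
        return "N_IMIDAZOLE"
    if pair == ("TRP", "NE1"):
        return "N_INDOLE"
    if pair in {("ASN", "OD1"), ("GLN", "OE1")}:
        return "O_CARBONYL"
    if pair in {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}:
        return "O_CARBOXYLATE"
    if pair == ("SER", "OG"):
        return "O_HYDROXYL_PRI"
    if pair == ("THR", "OG1"):
        return "O_HYDROXYL_SEC"
    if pair == ("TYR", "OH"):
        return "O_PHENOL"
    if pair == ("CYS", "SG"):
        return "S_THIOL"
    if pair == ("MET", "SD"):
        return "S_THIOETHER"
    # generic aliphatic CH2 (LYS CG/CD, ARG CG, GLU/GLN CG, ILE CG1, PRO CG,
    # every remaining CB, ...)
    if at.startswith("C"):
        return "C_SP3_CH2"
    return "OTHER_HEAVY"


# ---------------------------------------------------------------------------
# Hydrogen classes (exactly 20; available but unused by the default models).

HYDROGEN_CLASSES = (
    "H_BACKBONE_N",    # amide H on backbone N
    "H_ALPHA",         # Hα on CA
    "H_SP3_CH3",       # methyl hydrogens
    "H_SP3_CH2",       # methylene hydrogens
    "H_SP3_CH",        # methine hydrogens
    "H_AROMATIC",      # benzene-like ring H
    "H_IMIDAZOLE_C",   # HIS ring-carbon H
    "H_PYRROLE_C",     # TRP CD1 H
    "H_HYDROXYL",      # SER/THR O-H
    "H_PHENOL",        # TYR O-H
    "H_THIOL",         # CYS S-H
    "H_AMIDE_SIDE",    # ASN/GLN side-chain amide H
    "H_AMMONIUM",      # LYS N-H3+
    "H_GUANIDINIUM",   # ARG N-H
    "H_IMIDAZOLE_N",   # HIS N-H
    "H_INDOLE_N",      # TRP NE1-H
    "H_TERMINAL_N",    # N-terminal H3+
    "H_CB",            # Hβ on CB
    "H_POLAR_OTHER",   # other heteroatom-bound H
    "OTHER_H",         # catch-all
)


class WrongVocabularyError(ValueError):
    """A hydrogen was passed to the heavy-atom lookup (or vice versa)."""


@dataclasses.dataclass(frozen=True)
class AnnotationScheme:
    """Total mappings from residue/atom names to node-type indices."""

    residue_vocab: tuple[str, ...]
    heavy_atom_vocab: tuple[str, ...]
    hydrogen_vocab: tuple[str, ...]
    lookup: Mapping[tuple[str, str], int]        # (residue, atom) -> heavy class idx
    residue_lookup: Mapping[str, int]            # residue -> residue class idx
    version: str = SCHEME_VERSION

    def __post_init__(self):
        if len(self.residue_vocab) != 21:
            raise ValueError(f"residue vocabulary must have 21 classes, got {len(self.residue_vocab)}")
        if len(self.heavy_atom_vocab) != 31:
            raise ValueError(f"heavy-atom vocabulary must have 31 classes, got {len(self.heavy_atom_vocab)}")
        if len(self.hydrogen_vocab) != 20:
            raise ValueError(f"hydrogen vocabulary must have 20 classes, got {len(self.hydrogen_vocab)}")

    @property
    def n_residue_classes(self) -> int:
        return len(self.residue_vocab)

    @property
    def n_heavy_classes(self) -> int:
        return len(self.heavy_atom_vocab)

    def annotate_residue(self, residue_name: str) -> int:
        """Residue class index: one of the 20 standard types or 'other' (20)."""
        return self.residue_lookup.get(residue_name.upper(), len(self.residue_vocab) - 1)

    def annotate_atom(self, residue_name: str, atom_name: str) -> int:
        """Heavy-atom class index; total via the catch-all class."""
        atom_name = atom_name.upper().strip()
        if _looks_like_hydrogen(atom_name):
            raise WrongVocabularyError(
                f"{atom_name!r} is a hydrogen name; use the hydrogen vocabulary"
            )
        key = (residue_name.upper(), atom_name)
        if key in self.lookup:
            return self.lookup[key]
        # unknown residue but standard backbone atom name: type by backbone rule
        if atom_name in ("N", "CA", "C", "O", "OXT"):
            return self.lookup[("ALA", atom_name)] if atom_name != "OXT" else \
                self.heavy_atom_vocab.index("O_CARBOXYLATE")
        return len(self.heavy_atom_vocab) - 1  # OTHER_HEAVY

    def annotate_hydrogen(self, residue_name: str, atom_name: str) -> int:
        atom_name = atom_name.upper().strip()
        if not _looks_like_hydrogen(atom_name):
            raise WrongVocabularyError(f"{atom_name!r} is not a hydrogen name")
        if atom_name in ("H", "H1", "H2", "H3", "HN"):
            return self.hydrogen_vocab.index(
                "H_TERMINAL_N" if atom_name in ("H1", "H2", "H3") else "H_BACKBONE_N"
            )
        if atom_name.startswith("HA"):
            return self.hydrogen_vocab.index("H_ALPHA")
        if atom_name.startswith("HB"):
            return self.hydrogen_vocab.index("H_CB")
        if residue_name.upper() in ("SER", "THR") and atom_name.startswith("HG"):
            return self.hydrogen_vocab.index("H_HYDROXYL")
        if residue_name.upper() == "TYR" and atom_name == "HH":
            return self.hydrogen_vocab.index("H_PHENOL")
        if residue_name.upper() == "CYS" and atom_name == "HG":
            return self.hydrogen_vocab.index("H_THIOL")
        if residue_name.upper() == "LYS" and atom_name.startswith("HZ"):
            return self.hydrogen_vocab.index("H_AMMONIUM")
        if residue_name.upper() == "ARG" and atom_name.startswith("HH"):
            return self.hydrogen_vocab.index("H_GUANIDINIUM")
        if residue_name.upper() in ("ASN", "GLN") and atom_name.endswith(("21", "22", "1", "2")):
            return self.hydrogen_vocab.index("H_AMIDE_SIDE")
        if residue_name.upper() in ("PHE", "TYR", "TRP"):
            return self.hydrogen_vocab.index("H_AROMATIC")
        return self.hydrogen_vocab.index("OTHER_H")


def _looks_like_hydrogen(atom_name: str) -> bool:
    # PDB hydrogen names start with H after any leading digit ("1HB", "HG1").
    stripped = atom_name.lstrip("0123456789")
    return stripped.startswith(("H", "D"))


def default_scheme() -> AnnotationScheme:
    """The package's built-in 21/31/20 annotation scheme."""
    residue_vocab = STANDARD_RESIDUES + ("OTHER",)
    residue_lookup = {name: i for i, name in enumerate(STANDARD_RESIDUES)}
    class_index = {name: i for i, name in enumerate(HEAVY_ATOM_CLASSES)}
    lookup: dict[tuple[str, str], int] = {}
    for res, atom_names in RESIDUE_HEAVY_ATOMS.items():
        for at in atom_names + ("OXT",):
            lookup[(res, at)] = class_index[_classify_heavy(res, at)]
    return AnnotationScheme(
        residue_vocab=residue_vocab,
        heavy_atom_vocab=HEAVY_ATOM_CLASSES,
        hydrogen_vocab=HYDROGEN_CLASSES,
        lookup=lookup,
        residue_lookup=residue_lookup,
    )


def load_scheme(path, version: str = "user") -> AnnotationScheme:
    """Load a heavy-atom mapping from a TSV (residue, atom, class_name) file.

    The class-name column defines the heavy-atom vocabulary (order of first
    appearance, padded with a final catch-all if the file does not provide
    one); the residue and hydrogen vocabularies stay at the defaults.
    Class counts are validated to 31.
    """
    classes: list[str] = []
    lookup: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated columns")
            res, at, cls = (p.strip().upper() for p in parts)
            if cls not in classes:
                classes.append(cls)
            lookup[(res, at)] = classes.index(cls)
    if not any(c in ("OTHER", "OTHER_HEAVY") for c in classes):
        classes.append("OTHER_HEAVY")
    if len(classes) != 31:
        raise ValueError(
            f"heavy-atom table must define exactly 31 classes, got {len(classes)}"
        )
    residue_vocab = STANDARD_RESIDUES + ("OTHER",)
    residue_lookup = {name: i for i, name in enumerate(STANDARD_RESIDUES)}
    return AnnotationScheme(
        residue_vocab=residue_vocab,
        heavy_atom_vocab=tuple(classes),
        hydrogen_vocab=HYDROGEN_CLASSES,
        lookup=lookup,
        residue_lookup=residue_lookup,
        version=version,
    )
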