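"""PDB structure model and I/O.

Reads and writes PDB-format coordinate files into a light hierarchical
model (Structure -> chains -> Residue -> Atom) that preserves insertion-code
residue numbering (e.g. 53A sorts between 53 and 54) and supports
multi-model files, altloc resolution, water/hetero filtering, per-atom van
der Waals radius assignment, and chain/residue-range sub-selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import total_ordering
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import ConfigError, EmptyStructureError, SelectionError

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = frozenset(ONE_TO_THREE)

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}

#: element-based fallback radii, Angstrom
ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
DEFAULT_RADIUS = 1.80  # unknown elements

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}
DEFAULT_MASS = 12.011

# ProtOr-style united-atom-class radii (carbonyl/trigonal C, aromatic CH,
# aliphatic C, N, carbonyl O, hydroxyl O, S).
_PROTOR = {
    "C=O": 1.61, "C_aro_junction": 1.61, "C_aroH": 1.76, "C_ali": 1.88,
    "N": 1.64, "O=C": 1.42, "O-H": 1.46, "S": 1.77,
}

_AROMATIC_CH = {
    "PHE": {"CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CD1", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CD2", "CE1"},
}
_AROMATIC_JUNCTION = {
    "PHE": {"CG"},
    "TYR": {"CG", "CZ"},
    "TRP": {"CG", "CD2", "CE2"},
    "HIS": {"CG"},
}
_TRIGONAL_SIDECHAIN_C = {
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"},
    "ARG": {"CZ"},
}
_HYDROXYL_O = {"OG", "OG1", "OH"}


@dataclass
class Atom:
    """A single atom record."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    vdw_radius: Optional[float] = None
    is_hetero: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


@total_ordering
@dataclass(frozen=True)
class ResidueKey:
    """Chain + sequence number + insertion code; orders 53 < 53A < 54."""

    chain_id: str
    resseq: int
    icode: str = ""

    def _cmp_key(self):
        return (self.chain_id, self.resseq, self.icode)

    def __lt__(self, other: "ResidueKey") -> bool:
        return self._cmp_key() < other._cmp_key()

    def __str__(self) -> str:
        return f"{self.chain_id}{self.resseq}{self.icode}"


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


class Structure:
    """Hierarchy of models -> chains -> residues.

    ``models`` is a list of ``(model_id, chains)`` pairs where ``chains``
    maps chain id to a list of residues sorted by :class:`ResidueKey`.
    All models are expected to share chain/residue topology.
    """

    def __init__(self, models: Sequence[tuple[int, dict[str, list[Residue]]]]):
        if not models:
            raise EmptyStructureError("structure has no models")
        self.models = list(models)
        for _, chains in self.models:
            for cid, residues in chains.items():
                residues.sort(key=lambda r: r.key)

    @property
    def chains(self) -> dict[str, list[Residue]]:
        """Chains of the first model."""
        return self.models[0][1]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self, model: int = 0) -> Iterator[Residue]:
        for cid in self.models[model][1]:
            yield from self.models[model][1][cid]

    def atoms(self, model: int = 0) -> Iterator[Atom]:
        for res in self.residues(model):
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coordinates(self, model: int = 0) -> np.ndarray:
        arr = [a.coords for a in self.atoms(model)]
        return np.array(arr, dtype=float).reshape(-1, 3)

    def set_coordinates(self, coords: np.ndarray, model: int = 0) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = list(self.atoms(model))
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(atoms)} atoms"
            )
        for atom, xyz in zip(atoms, coords):
            atom.coords = xyz.copy()

    def residue_map(self, model: int = 0) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues(model)}

    def copy(self) -> "Structure":
        models = []
        for mid, chains in self.models:
            new_chains: dict[str, list[Residue]] = {}
            for cid, residues in chains.items():
                new_chains[cid] = [
                    Residue(r.key, r.name, [replace(a, coords=a.coords.copy())
                                            for a in r.atoms])
                    for r in residues
                ]
            models.append((mid, new_chains))
        return Structure(models)

    def sequence(self, chain_id: str, model: int = 0) -> str:
        chains = self.models[model][1]
        if chain_id not in chains:
            raise SelectionError(f"chain '{chain_id}' not present")
        return "".join(r.one_letter for r in chains[chain_id])


def infer_element(atom_name: str, resname: str = "") -> str:
    """Best-effort element from a PDB atom name (protein atoms)."""
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():  # e.g. 1HB2
        return "H"
    two = name[:2].upper()
    if two in ("FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE"):
        return two[0] + two[1].lower()
    return name[0].upper()


def _parse_atom_line(line: str) -> tuple[Atom, str, str, int, str, str]:
    """Parse one ATOM/HETATM record; returns (atom, altloc, resname, resseq,
    icode, chain)."""
    serial = int(line[6:11])
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain_id = line[21]
    resseq = int(line[22:26])
    icode = line[26].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, resname)
    atom = Atom(
        serial=serial, name=name, element=element,
        coords=np.array([x, y, z]), occupancy=occupancy,
        is_hetero=line.startswith("HETATM"),
    )
    return atom, altloc, resname, resseq, icode, chain_id


def read_pdb(path, keep_waters: bool = False, keep_hetero: bool = False) -> Structure:
    """Read a (possibly multi-model) PDB file.

    Waters (HOH/WAT) and HETATM records are dropped unless the corresponding
    flag is set.  Insertion codes are preserved.  Alternate locations are
    resolved to the highest-occupancy conformer (ties broken by altloc
    letter, blank first).
    """
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc

    models: list[tuple[int, dict]] = []
    # chain -> key -> (resname, atom-name -> list of (altloc, atom))
    current: dict[str, dict] = {}
    model_id = 0
    seen_model_record = False

    def flush():
        nonlocal current
        chains: dict[str, list[Residue]] = {}
        for cid, resmap in current.items():
            residues = []
            for key, (resname, atom_variants) in resmap.items():
                atoms = []
                for aname, variants in atom_variants.items():
                    # highest occupancy wins; ties -> first altloc letter
                    variants.sort(key=lambda v: (-v[1].occupancy, v[0]))
                    atoms.append(variants[0][1])
                residues.append(Residue(key, resname, atoms))
            if residues:
                chains[cid] = residues
        if any(chains.values()):
            models.append((model_id, chains))
        current = {}

    for line in lines:
        rec = line[:6]
        if rec == "MODEL ":
            if seen_model_record:
                flush()
            seen_model_record = True
            model_id = int(line.split()[1])
        elif rec == "ENDMDL":
            flush()
            seen_model_record = False
        elif rec in ("ATOM  ", "HETATM"):
            atom, altloc, resname, resseq, icode, chain_id = _parse_atom_line(line)
            if resname in WATER_RESNAMES:
                if not keep_waters:
                    continue
            elif atom.is_hetero and not keep_hetero:
                continue
            key = ResidueKey(chain_id, resseq, icode)
            resmap = current.setdefault(chain_id, {})
            _, atom_variants = resmap.setdefault(key, (resname, {}))
            atom_variants.setdefault(atom.name, []).append((altloc, atom))
    flush()

    if not models:
        raise EmptyStructureError(
            f"no ATOM records remain in {path} after filtering"
        )
    return Structure(models)


def write_pdb(s: Structure, path) -> None:
    """Write ``s`` as PDB text; round-trips through :func:`read_pdb`."""
    multi = s.n_models > 1
    try:
        with open(path, "w") as fh:
            for mid, chains in s.models:
                if multi:
                    fh.write(f"MODEL     {mid:4d}\n")
                serial = 1
                for cid, residues in chains.items():
                    for res in residues:
                        for a in res.atoms:
                            name = a.name
                            # column-13 convention: 1-3 char names start at 14
                            fmt_name = name if len(name) == 4 else f" {name:<3s}"
                            record = "HETATM" if a.is_hetero else "ATOM  "
                            fh.write(
                                f"{record}{serial:5d} {fmt_name}{'':1s}{res.name:>3s} "
                                f"{res.key.chain_id}{res.key.resseq:4d}"
                                f"{res.key.icode or ' '}   "
                                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                                f"{a.occupancy:6.2f}{0.0:6.2f}          "
                                f"{a.element:>2s}\n"
                            )
                            serial += 1
                    fh.write("TER\n")
                if multi:
                    fh.write("ENDMDL\n")
            fh.write("END\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


def _protor_radius(resname: str, atom: Atom) -> Optional[float]:
    if resname not in THREE_TO_ONE:  # class table covers standard residues only
        return None
    name, el = atom.name, atom.element.upper()
    if el == "N":
        return _PROTOR["N"]
    if el == "S":
        return _PROTOR["S"]
    if el == "O":
        return _PROTOR["O-H"] if name in _HYDROXYL_O else _PROTOR["O=C"]
    if el == "C":
        if name == "C":
            return _PROTOR["C=O"]
        if name in _TRIGONAL_SIDECHAIN_C.get(resname, ()):
            return _PROTOR["C=O"]
        if name in _AROMATIC_JUNCTION.get(resname, ()):
            return _PROTOR["C_aro_junction"]
        if name in _AROMATIC_CH.get(resname, ()):
            return _PROTOR["C_aroH"]
        return _PROTOR["C_ali"]
    return None


def assign_radii(s: Structure, radius_set: str = "protor") -> Structure:
    """Assign van der Waals radii in place (and return ``s``).

    ``radius_set`` is ``"protor"`` (atom-class radii with element fallback)
    or ``"element"`` (element radii only).  Unknown elements get 1.80 A
    with a warning.
    """
    if radius_set not in ("protor", "element"):
        raise ConfigError(f"unknown radius set '{radius_set}'")
    for _, chains in s.models:
        for residues in chains.values():
            for res in residues:
                for atom in res.atoms:
                    r = None
                    if radius_set == "protor":
                        r = _protor_radius(res.name, atom)
                    if r is None:
                        el = atom.element.upper()
                        r = ELEMENT_RADII.get(el)
                    if r is None:
                        r = DEFAULT_RADIUS
                        warnings.warn(
                            f"unknown element '{atom.element}' for atom "
                            f"{atom.name}; using fallback radius {DEFAULT_RADIUS} A"
                        )
                    atom.vdw_radius = r
    return s


def select(
    s: Structure,
    chains: Iterable[str],
    residue_range: Optional[tuple[ResidueKey, ResidueKey]] = None,
) -> Structure:
    """Sub-structure containing ``chains``, optionally restricted to the
    closed ResidueKey interval ``residue_range`` (applied per chain)."""
    chains = list(chains)
    models = []
    for mid, model_chains in s.models:
        missing = [c for c in chains if c not in model_chains]
        if missing:
            raise SelectionError(f"chain '{missing[0]}' not present in structure")
        new_chains: dict[str, list[Residue]] = {}
        for cid in chains:
            residues = model_chains[cid]
            if residue_range is not None:
                lo, hi = residue_range
                lo = ResidueKey(cid, lo.resseq, lo.icode)
                hi = ResidueKey(cid, hi.resseq, hi.icode)
                residues = [r for r in residues if lo <= r.key <= hi]
            new_chains[cid] = [
                Residue(r.key, r.name,
                        [replace(a, coords=a.coords.copy()) for a in r.atoms])
                for r in residues
            ]
        models.append((mid, new_chains))
    return Structure(models)


def merge(a: Structure, b: Structure) -> Structure:
    """Combine the first models of two structures into one complex.

    Chain ids must be disjoint.
    """
    overlap = set(a.chains) & set(b.chains)
    if overlap:
        raise SelectionError(f"chain id collision on merge: {sorted(overlap)}")
    chains: dict[str, list[Residue]] = {}
    for src in (a, b):
        for cid, residues in src.chains.items():
            chains[cid] = [
                Residue(r.key, r.name,
                        [replace(at, coords=at.coords.copy()) for at in r.atoms])
                for r in residues
            ]
    return Structure([(1, chains)])


def atom_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)
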