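"""PDB structure I/O and per-atom parameter assignment.

Reads and writes fixed-width PDB coordinate records, resolves altlocs,
applies chain / residue selections, and attaches the per-atom radii,
partial charges and coarse atom types that the grid builders and the
off-grid minimizer consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

log = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

ATYPES = ("C_aliph", "C_arom", "N_don", "O_acc", "S", "P", "other")

#: element fallback radii (Å) used when an atom is absent from the table
ELEMENT_RADII = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "H": 1.0, "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2,
}
DEFAULT_RADIUS = 1.8


class PdbFormatError(ValueError):
    """A PDB record could not be parsed; message names the line number."""


class NoAtomsError(ValueError):
    """No atoms survived parsing/filters."""


class ParamError(KeyError):
    """Strict parameter assignment hit atoms missing from the table."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    chain: str
    res_seq: int
    icode: str
    xyz: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    altloc: str = ""

    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)


@dataclass
class Structure:
    atoms: list[Atom]
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, id=self.id)

    def select(self, chains=None, res_range=None) -> "Structure":
        """Subset by chain ids and/or an inclusive (start, end) res_seq range."""
        picked = []
        for a in self.atoms:
            if chains is not None and a.chain not in chains:
                continue
            if res_range is not None:
                lo, hi = res_range
                if not (lo <= a.res_seq <= hi):
                    continue
            picked.append(a)
        if not picked:
            raise NoAtomsError(
                f"selection chains={chains} res_range={res_range} matched no atoms")
        return Structure(picked, id=self.id)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Residues in order of first appearance -> atom indices."""
        order: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            order.setdefault(a.residue_id(), []).append(i)
        return list(order.items())


@dataclass
class ParamStructure:
    structure: Structure
    radius: np.ndarray
    charge: np.ndarray
    atype: list[str]

    def __post_init__(self):
        n = len(self.structure)
        self.radius = np.asarray(self.radius, dtype=float).reshape(n)
        self.charge = np.asarray(self.charge, dtype=float).reshape(n)
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        if len(self.atype) != n:
            raise ValueError("atype length mismatch")

    def __len__(self) -> int:
        return len(self.structure)

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords

    def with_coords(self, coords: np.ndarray) -> "ParamStructure":
        return ParamStructure(self.structure.with_coords(coords),
                              self.radius.copy(), self.charge.copy(),
                              list(self.atype))

    def subset(self, indices) -> "ParamStructure":
        indices = list(indices)
        return ParamStructure(
            Structure([self.structure.atoms[i] for i in indices],
                      id=self.structure.id),
            self.radius[indices], self.charge[indices],
            [self.atype[i] for i in indices])


def _infer_element(name: str, raw_element: str) -> str:
    el = raw_element.strip().upper()
    if el:
        return el
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ELEMENT_RADII:
        return stripped[:2].upper()
    return stripped[:1].upper() if stripped else "C"


def read_pdb(text: str, *, id: str = "", keep_waters: bool = False,
             keep_hydrogens: bool = False, keep_hetero: bool = True,
             chains=None) -> Structure:
    """Parse ATOM/HETATM records from PDB-format text.

    Default filters drop waters and hydrogens; when alternate locations
    are present, the highest-occupancy altloc is kept (ties favour 'A').
    """
    raw: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PdbFormatError(f"line {lineno}: record too short for coordinates")
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip() or " "
            res_seq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
        except ValueError as e:
            raise PdbFormatError(f"line {lineno}: malformed fixed-width record ({e})")
        element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
        if not np.all(np.isfinite([x, y, z])):
            raise PdbFormatError(f"line {lineno}: non-finite coordinate")
        a = Atom(serial=serial, name=name, element=element, res_name=res_name,
                 chain=chain, res_seq=res_seq, icode=icode,
                 xyz=np.array([x, y, z]), occupancy=occ,
                 is_hetero=(rec == "HETATM"), altloc=altloc)
        if not keep_waters and a.res_name in WATER_RESNAMES:
            continue
        if not keep_hydrogens and a.element in ("H", "D"):
            continue
        if not keep_hetero and a.is_hetero:
            continue
        if chains is not None and a.chain not in chains:
            continue
        raw.append(a)

    # altloc resolution: highest occupancy wins, ties resolved towards 'A'
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in raw:
        key = (a.chain, a.res_seq, a.icode, a.res_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, -ord(a.altloc or "Z")) > (b.occupancy, -ord(b.altloc or "Z")):
                best[key] = a
    atoms = [best[k] for k in order]
    if not atoms:
        raise NoAtomsError("no atoms after parsing and filters")
    return Structure(atoms, id=id)


def write_pdb(s: Structure) -> str:
    """Serialize to fixed-width PDB text (ATOM/HETATM + TER + END)."""
    if not len(s):
        raise NoAtomsError("cannot write an empty structure")
    lines = []
    prev_chain = None
    for i, a in enumerate(s.atoms):
        if prev_chain is not None and a.chain != prev_chain:
            lines.append("TER")
        prev_chain = a.chain
        if np.any(np.abs(a.xyz) >= 10000.0):
            raise ValueError(
                f"coordinate overflow for atom {a.name} {a.chain}{a.res_seq}: "
                f"{a.xyz} exceeds PDB fixed-width field")
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{(i + 1) % 100000:5d} {name:<4.4s}{'':1s}{a.res_name:>3.3s} "
            f"{a.chain:1.1s}{a.res_seq:4d}{a.icode:<1.1s}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}")
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def load_param_table(path=None) -> dict:
    """Load the (res_name, atom_name) -> (radius, charge, atype) table.

    '*' residue entries act as wildcards for any residue name.
    """
    if path is None:
        text = resources.files("dockmap.data").joinpath("atom_params.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[tuple[str, str], tuple[float, float, str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, name, radius, charge, atype = line.split("\t")
        if atype not in ATYPES:
            raise ValueError(f"unknown atom type {atype!r} in parameter table")
        table[(res, name)] = (float(radius), float(charge), atype)
    return table


def _element_fallback(element: str) -> tuple[float, float, str]:
    return (ELEMENT_RADII.get(element.upper(), DEFAULT_RADIUS), 0.0, "other")


def assign_params(s: Structure, table: dict | None = None, *,
                  strict: bool = False) -> ParamStructure:
    """Attach radius/charge/atype per atom.

    Lookup order: exact (res_name, atom_name), wildcard ('*', atom_name),
    then element fallback (type "other", zero charge). In strict mode the
    fallback is an error that lists the offending atoms.
    """
    if table is None:
        table = load_param_table()
    radii, charges, atypes = [], [], []
    missing = []
    for a in s.atoms:
        hit = table.get((a.res_name, a.name)) or table.get(("*", a.name))
        if hit is None:
            if strict:
                missing.append(f"{a.res_name} {a.chain}{a.res_seq} {a.name}")
                hit = _element_fallback(a.element)
            else:
                hit = _element_fallback(a.element)
                log.debug("parameter fallback for %s %s%d %s",
                          a.res_name, a.chain, a.res_seq, a.name)
        radii.append(hit[0])
        charges.append(hit[1])
        atypes.append(hit[2])
    if missing:
        raise ParamError(
            "atoms missing from parameter table: " + ", ".join(missing))
    return ParamStructure(s, np.array(radii), np.array(charges), atypes)
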