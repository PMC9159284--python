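"""Pairwise distance restraints with k-of-n group semantics.

A restraint bounds the distance between one receptor atom and one
ligand atom (default CB, CA for glycine).  Restraints live in groups;
a group holds when at least `required` of its members hold, and a set
holds when every group holds (AND across groups).  JSON dialect::

    {"groups": [{"required": 1,
                 "restraints": [{"rec": "A.85.CB", "lig": "C.119.CB",
                                 "dmin": 2.0, "dmax": 10.0}]}]}

The atom field of a selection string is optional ("A.85" applies the
CB/CA default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structio import ParamStructure, Structure


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class Selection:
    chain: str
    res_seq: int
    atom: str | None = None  # None -> CB (CA for GLY)

    @classmethod
    def parse(cls, text: str) -> "Selection":
        parts = text.split(".")
        if len(parts) not in (2, 3) or not parts[0]:
            raise RestraintError(f"bad selection syntax: {text!r} "
                                 "(expected CHAIN.RESSEQ[.ATOM])")
        try:
            res_seq = int(parts[1])
        except ValueError:
            raise RestraintError(f"bad residue number in selection {text!r}")
        atom = parts[2] if len(parts) == 3 else None
        return cls(chain=parts[0], res_seq=res_seq, atom=atom)

    def render(self) -> str:
        base = f"{self.chain}.{self.res_seq}"
        return f"{base}.{self.atom}" if self.atom else base

    def resolve(self, s: Structure) -> int:
        """Atom index in `s`, applying the CB / CA-for-GLY default."""
        cand = {}
        for i, a in enumerate(s.atoms):
            if a.chain == self.chain and a.res_seq == self.res_seq:
                cand[a.name] = i
        if not cand:
            raise RestraintError(f"selection {self.render()} matches no residue")
        if self.atom is not None:
            if self.atom not in cand:
                raise RestraintError(
                    f"selection {self.render()} matches no atom")
            return cand[self.atom]
        for name in ("CB", "CA"):
            if name in cand:
                return cand[name]
        raise RestraintError(
            f"selection {self.render()}: residue has neither CB nor CA")


@dataclass(frozen=True)
class Restraint:
    rec_sel: Selection
    lig_sel: Selection
    dmin: float
    dmax: float

    def __post_init__(self):
        if not (0 <= self.dmin < self.dmax):
            raise RestraintError(
                f"invalid bounds dmin={self.dmin}, dmax={self.dmax}")


@dataclass(frozen=True)
class RestraintGroup:
    restraints: tuple
    required: int

    def __post_init__(self):
        if not self.restraints:
            raise RestraintError("empty restraint group")
        if not (1 <= self.required <= len(self.restraints)):
            raise RestraintError(
                f"required={self.required} outside [1, {len(self.restraints)}]")


@dataclass(frozen=True)
class RestraintSet:
    groups: tuple

    def __post_init__(self):
        if not self.groups:
            raise RestraintError("restraint set has no groups")

    def all_restraints(self):
        return [r for g in self.groups for r in g.restraints]


def parse_restraints(text: str) -> RestraintSet:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        raise RestraintError(f"restraint file is not valid JSON: {e}")
    if "groups" not in obj:
        raise RestraintError("restraint file missing 'groups'")
    groups = []
    for g in obj["groups"]:
        members = tuple(
            Restraint(rec_sel=Selection.parse(r["rec"]),
                      lig_sel=Selection.parse(r["lig"]),
                      dmin=float(r["dmin"]), dmax=float(r["dmax"]))
            for r in g.get("restraints", []))
        groups.append(RestraintGroup(restraints=members,
                                     required=int(g.get("required", len(members)))))
    return RestraintSet(groups=tuple(groups))


def serialize_restraints(rs: RestraintSet) -> str:
    obj = {"groups": [
        {"required": g.required,
         "restraints": [
             {"rec": r.rec_sel.render(), "lig": r.lig_sel.render(),
              "dmin": r.dmin, "dmax": r.dmax}
             for r in g.restraints]}
        for g in rs.groups]}
    return json.dumps(obj, indent=1)


def generate_restraints(pairs, dmin: float, dmax: float,
                        required: int) -> RestraintSet:
    """One group over residue pairs [(rec_sel_str, lig_sel_str), ...]."""
    if not pairs:
        raise RestraintError("no residue pairs given")
    members = tuple(
        Restraint(rec_sel=Selection.parse(rec), lig_sel=Selection.parse(lig),
                  dmin=float(dmin), dmax=float(dmax))
        for rec, lig in pairs)
    return RestraintSet(groups=(RestraintGroup(restraints=members,
                                               required=required),))


def satisfied(rec: ParamStructure | Structure, lig_coords: np.ndarray,
              lig: ParamStructure | Structure, rs: RestraintSet):
    """Evaluate a posed ligand against the restraint set.

    Returns (ok, tallies): per-group count of satisfied members; the set
    holds iff every group reaches its `required` count.
    """
    rec_s = rec.structure if isinstance(rec, ParamStructure) else rec
    lig_s = lig.structure if isinstance(lig, ParamStructure) else lig
    rec_xyz = rec_s.coords
    tallies = []
    ok = True
    for g in rs.groups:
        n_sat = 0
        for r in g.restraints:
            ri = r.rec_sel.resolve(rec_s)
            li = r.lig_sel.resolve(lig_s)
            d = float(np.linalg.norm(rec_xyz[ri] - lig_coords[li]))
            if r.dmin <= d <= r.dmax:
                n_sat += 1
        tallies.append(n_sat)
        if n_sat < g.required:
            ok = False
    return ok, tallies


def filter_poses(poses, rec: ParamStructure, lig: ParamStructure,
                 rs: RestraintSet):
    """Poses whose transformed ligand satisfies the restraint set."""
    kept = []
    for p in poses:
        coords = p.apply(lig.coords)
        if satisfied(rec, coords, lig, rs)[0]:
            kept.append(p)
    return kept
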