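"""Interface utilities for predicted complexes.

Extracts interface residues between two chain groups and computes the
average interface predicted-aligned-error (PAE) used to rank candidate
models of a complex (lower is better).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure


@dataclass
class PaeMatrix:
    values: np.ndarray       # (n, n) predicted aligned error, Å
    chains: list             # chain id per residue index

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("PAE matrix must be square")
        if np.any(self.values < 0):
            raise ValueError("PAE values must be non-negative")
        if self.chains and len(self.chains) != n:
            raise ValueError("chain map length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def parse_pae_json(text: str) -> PaeMatrix:
    """JSON dialect: {"pae": [[...]], "chains": "AAABB..."} (list also ok)."""
    obj = json.loads(text)
    if "pae" not in obj:
        raise ValueError("PAE file missing 'pae'")
    return PaeMatrix(values=np.array(obj["pae"], dtype=float),
                     chains=list(obj.get("chains", [])))


def _residue_order(model: Structure) -> list:
    return [rid for rid, _ in model.residues()]


def interface_residues(model: Structure, chains_a, chains_b,
                       cutoff: float = 10.0):
    """Residues of each side with any heavy atom within `cutoff` of the
    other side.  Returns (side_a_set, side_b_set) of residue ids."""
    chains_a, chains_b = set(chains_a), set(chains_b)
    present = {a.chain for a in model.atoms}
    for c in chains_a | chains_b:
        if c not in present:
            raise ValueError(f"chain {c!r} not present in model")
    ia = [i for i, a in enumerate(model.atoms) if a.chain in chains_a]
    ib = [i for i, a in enumerate(model.atoms) if a.chain in chains_b]
    coords = model.coords
    ta, tb = cKDTree(coords[ia]), cKDTree(coords[ib])
    hits = ta.query_ball_tree(tb, cutoff)
    side_a, side_b = set(), set()
    for k, js in enumerate(hits):
        if js:
            side_a.add(model.atoms[ia[k]].residue_id())
            for j in js:
                side_b.add(model.atoms[ib[j]].residue_id())
    return side_a, side_b


def interface_pae(model: Structure, pae: PaeMatrix, chains_a, chains_b,
                  cutoff: float = 10.0) -> float:
    """Mean symmetrized PAE over cross-chain interface residue pairs."""
    order = _residue_order(model)
    if pae.n != len(order):
        raise ValueError(
            f"PAE matrix size {pae.n} != model residue count {len(order)}")
    index = {rid: i for i, rid in enumerate(order)}
    side_a, side_b = interface_residues(model, chains_a, chains_b, cutoff)
    if not side_a or not side_b:
        raise ValueError("empty interface: no residue contact at this cutoff")
    ia = np.array(sorted(index[r] for r in side_a))
    ib = np.array(sorted(index[r] for r in side_b))
    block = 0.5 * (pae.values[np.ix_(ia, ib)] + pae.values[np.ix_(ib, ia)].T)
    return float(np.mean(block))
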