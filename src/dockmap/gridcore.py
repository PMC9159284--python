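"""Multi-channel grid construction and FFT translational correlation.

A structure is discretized into named scalar fields (core, surface,
charge and per-atom-type pair channels) on a common lattice.  For a
fixed ligand rotation, the score at every integer translation of the
ligand lattice relative to the receptor lattice is a weighted sum of
channel-wise cross-correlations, evaluated either with zero-padded FFTs
or by direct summation (the verification oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import fft as sfft
from scipy.spatial.transform import Rotation as _SciRot

from .structio import ATYPES, ParamStructure

#: core indicator shrink tolerance (Å) — allowed atomic overlap
DELTA_CORE = 0.5
#: attractive surface shell width (Å) beyond the van der Waals radius
SIGMA_SURFACE = 2.0
#: receptor interior penalty amplitude: the receptor core channel carries
#: this value (ligand core stays 1) so that w_rep=1 still forbids burial
CORE_AMPLITUDE = 400.0

PAIR_CHANNELS = tuple(f"pair_{t}" for t in ATYPES)


@dataclass(frozen=True)
class Rotation:
    """Unit quaternion (x, y, z, w ordering as in scipy)."""

    q: tuple

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"non-unit quaternion (|q|={n})")
        # canonical sign so q and -q compare equal
        for v in q[::-1]:
            if abs(v) > 1e-12:
                if v < 0:
                    q = -q
                break
        object.__setattr__(self, "q", tuple(q))

    @classmethod
    def identity(cls) -> "Rotation":
        return cls((0.0, 0.0, 0.0, 1.0))

    @classmethod
    def from_quaternion(cls, q) -> "Rotation":
        q = np.asarray(q, dtype=float)
        return cls(tuple(q / np.linalg.norm(q)))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float) -> "Rotation":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return cls(tuple(_SciRot.from_rotvec(axis * angle_rad).as_quat()))

    @property
    def matrix(self) -> np.ndarray:
        return _SciRot.from_quat(self.q).as_matrix()

    def compose(self, other: "Rotation") -> "Rotation":
        """self ∘ other (apply `other` first)."""
        return Rotation.from_quaternion(
            (_SciRot.from_quat(self.q) * _SciRot.from_quat(other.q)).as_quat())

    def angle_to(self, other: "Rotation") -> float:
        """Geodesic angle (radians) between the two rotations."""
        dot = abs(float(np.dot(self.q, other.q)))
        return 2.0 * np.arccos(min(1.0, dot))

    def apply(self, coords: np.ndarray, center) -> np.ndarray:
        center = np.asarray(center, dtype=float)
        return (coords - center) @ self.matrix.T + center


@dataclass(frozen=True)
class EnergyWeights:
    w_attr: float = 1.0
    w_rep: float = 1.0
    w_elec: float = 0.6
    w_pair: float = 1.0
    name: str = "balanced"

    def __post_init__(self):
        if self.w_rep <= 0:
            raise ValueError("w_rep must be positive (clashes always penalized)")


#: named coefficient sets selectable from the CLI
COEFF_SETS = {
    "balanced": EnergyWeights(),
    "electrostatic-favored": EnergyWeights(w_elec=1.8, name="electrostatic-favored"),
    "hydrophobic-favored": EnergyWeights(w_pair=2.0, w_elec=0.3,
                                         name="hydrophobic-favored"),
}


@dataclass
class GridSet:
    origin: np.ndarray
    spacing: float
    dims: tuple
    channels: dict

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        for name, arr in self.channels.items():
            if arr.shape != self.dims:
                raise ValueError(f"channel {name} shape {arr.shape} != dims {self.dims}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name} has non-finite values")
        core = self.channels.get("core")
        if core is not None and np.any(core < 0):
            raise ValueError("core channel must be non-negative")

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.spacing


@dataclass
class ScoreField:
    values: np.ndarray
    components: dict
    rotation: Rotation
    weights: EnergyWeights
    pair_matrix: np.ndarray | None = None

    def recombine(self) -> np.ndarray:
        w = self.weights
        return (w.w_rep * self.components["core"]
                - w.w_attr * self.components["surface"]
                + w.w_elec * self.components["charge"]
                + w.w_pair * self.components["pair"])


def load_contact_matrix(path=None) -> np.ndarray:
    """Symmetric atom-type contact-energy matrix over ATYPES order."""
    if path is None:
        text = resources.files("dockmap.data").joinpath("contact_matrix.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = {}
    header = None
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells[1:]
            continue
        rows[cells[0]] = [float(v) for v in cells[1:]]
    m = np.array([[rows[a][header.index(b)] for b in ATYPES] for a in ATYPES])
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix must be symmetric")
    return m


def rotate(ps: ParamStructure, rot: Rotation, center) -> ParamStructure:
    """Rigidly rotate coordinates about `center`; parameters untouched."""
    return ps.with_coords(rot.apply(ps.coords, center))


def _spread_indicator(grid: np.ndarray, origin: np.ndarray, h: float,
                      centers: np.ndarray, r_lo: np.ndarray, r_hi: np.ndarray):
    """Set 1 at voxels whose centers fall in [r_lo, r_hi] of any atom."""
    dims = grid.shape
    for c, lo, hi in zip(centers, r_lo, r_hi):
        i0 = np.maximum(np.floor((c - hi - origin) / h - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil((c + hi - origin) / h - 0.5).astype(int) + 1,
                        dims)
        if np.any(i0 >= i1):
            continue
        ax = [origin[k] + (np.arange(i0[k], i1[k]) + 0.5) * h - c[k] for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        mask = (d2 <= hi * hi) & (d2 >= lo * lo)
        sub = grid[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub[mask] = 1.0


def _spread_trilinear(grid: np.ndarray, origin: np.ndarray, h: float,
                      centers: np.ndarray, weights: np.ndarray):
    """Distribute point weights onto the 8 voxel centers around each point."""
    dims = np.array(grid.shape)
    # fractional position relative to voxel-center lattice
    f = (centers - origin) / h - 0.5
    base = np.floor(f).astype(int)
    frac = f - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + np.array([dx, dy, dz])
                wgt = (weights
                       * np.where(dx, frac[:, 0], 1 - frac[:, 0])
                       * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                       * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                ok = np.all((idx >= 0) & (idx < dims), axis=1)
                np.add.at(grid, (idx[ok, 0], idx[ok, 1], idx[ok, 2]), wgt[ok])


def _build_grids(ps: ParamStructure, h: float, margin: float,
                 pair_mode: str, origin=None, dims=None) -> GridSet:
    if len(ps) == 0:
        raise ValueError("empty structure")
    if h <= 0:
        raise ValueError("grid spacing must be positive")
    coords = ps.coords
    rmax = float(np.max(ps.radius)) + SIGMA_SURFACE
    if origin is None:
        origin = coords.min(axis=0) - margin - rmax
    else:
        origin = np.asarray(origin, dtype=float)
    if dims is None:
        top = coords.max(axis=0) + margin + rmax
        dims = tuple(int(np.ceil((top[k] - origin[k]) / h)) + 1
                     for k in range(3))
    z = lambda: np.zeros(dims)
    core, surface, charge = z(), z(), z()
    _spread_indicator(core, origin, h, coords,
                      np.zeros(len(ps)), np.maximum(ps.radius - DELTA_CORE, 0.0))
    if pair_mode == "shell":  # receptor side: penalize interior overlap hard
        core *= CORE_AMPLITUDE
    _spread_indicator(surface, origin, h, coords,
                      np.maximum(ps.radius - DELTA_CORE, 0.0),
                      ps.radius + SIGMA_SURFACE)
    _spread_trilinear(charge, origin, h, coords, ps.charge)
    channels = {"core": core, "surface": surface, "charge": charge}
    # pair channels: per-type contact-shell indicators on both sides, so the
    # contact matrix acts as a type-weighted surface complementarity term
    for t, name in zip(ATYPES, PAIR_CHANNELS):
        g = z()
        sel = np.array([a == t for a in ps.atype])
        if np.any(sel):
            _spread_indicator(g, origin, h, coords[sel],
                              np.maximum(ps.radius[sel] - DELTA_CORE, 0.0),
                              ps.radius[sel] + SIGMA_SURFACE)
        channels[name] = g
    return GridSet(origin=origin, spacing=h, dims=dims, channels=channels)


def build_receptor_grids(ps: ParamStructure, h: float = 1.0,
                         margin: float = 8.0, origin=None,
                         dims=None) -> GridSet:
    """Receptor fields, amplified core; lattice covers structure + margin."""
    return _build_grids(ps, h, margin, pair_mode="shell",
                        origin=origin, dims=dims)


def build_ligand_grids(ps: ParamStructure, h: float = 1.0, origin=None,
                       dims=None) -> GridSet:
    """Ligand fields on a tight box (unit-amplitude core)."""
    return _build_grids(ps, h, 0.0, pair_mode="density",
                        origin=origin, dims=dims)


def _check_compat(rec: GridSet, lig: GridSet):
    if abs(rec.spacing - lig.spacing) > 1e-12:
        raise ValueError(f"grid spacing mismatch: {rec.spacing} vs {lig.spacing}")
    if any(ld > rd for ld, rd in zip(lig.dims, rec.dims)):
        raise ValueError(f"ligand grid {lig.dims} larger than receptor {rec.dims}")


def _valid_dims(rec: GridSet, lig: GridSet) -> tuple:
    return tuple(rd - ld + 1 for rd, ld in zip(rec.dims, lig.dims))


class CorrelationEngine:
    """Caches receptor-channel FFTs so many rotations reuse one transform."""

    def __init__(self, rec: GridSet, weights: EnergyWeights,
                 pair_matrix: np.ndarray | None = None):
        self.rec = rec
        self.weights = weights
        self.pair_matrix = (load_contact_matrix() if pair_matrix is None
                            else np.asarray(pair_matrix, dtype=float))
        self._shape = rec.dims
        self._rfft = {name: sfft.rfftn(arr, s=self._shape)
                      for name, arr in rec.channels.items()}

    def score(self, lig: GridSet, rotation: Rotation | None = None) -> ScoreField:
        """One forward FFT per ligand channel; pair terms are accumulated in
        the spectral domain so a single inverse transform covers all types.
        Correlation padding: receptor dims suffice because only the
        non-wrapping valid region is returned."""
        _check_compat(self.rec, lig)
        out = _valid_dims(self.rec, lig)
        lf = {name: sfft.rfftn(arr, s=self._shape) if arr.any() else None
              for name, arr in lig.channels.items()}

        def inv(spec):
            full = sfft.irfftn(spec, s=self._shape)
            return full[:out[0], :out[1], :out[2]]

        comp = {}
        for name in ("core", "surface", "charge"):
            if lf[name] is None:
                comp[name] = np.zeros(out)
            else:
                comp[name] = inv(self._rfft[name] * np.conj(lf[name]))
        spec = None
        for i in range(len(ATYPES)):
            rf = self._rfft[PAIR_CHANNELS[i]]
            if not self.rec.channels[PAIR_CHANNELS[i]].any():
                continue
            for j in range(len(ATYPES)):
                eps = self.pair_matrix[i, j]
                ljf = lf[PAIR_CHANNELS[j]]
                if eps == 0.0 or ljf is None:
                    continue
                term = eps * (rf * np.conj(ljf))
                spec = term if spec is None else spec + term
        comp["pair"] = np.zeros(out) if spec is None else inv(spec)
        w = self.weights
        values = (w.w_rep * comp["core"] - w.w_attr * comp["surface"]
                  + w.w_elec * comp["charge"] + w.w_pair * comp["pair"])
        return ScoreField(values=values, components=comp,
                          rotation=rotation or Rotation.identity(),
                          weights=w, pair_matrix=self.pair_matrix)


def fft_correlate(rec: GridSet, lig: GridSet, weights: EnergyWeights,
                  pair_matrix: np.ndarray | None = None,
                  rotation: Rotation | None = None) -> ScoreField:
    """Score every integer translation of `lig` against `rec` via FFT."""
    return CorrelationEngine(rec, weights, pair_matrix).score(lig, rotation)


def brute_force_correlate(rec: GridSet, lig: GridSet, weights: EnergyWeights,
                          pair_matrix: np.ndarray | None = None,
                          rotation: Rotation | None = None) -> ScoreField:
    """Direct-summation oracle with the same contract as fft_correlate."""
    _check_compat(rec, lig)
    if pair_matrix is None:
        pair_matrix = load_contact_matrix()
    out = _valid_dims(rec, lig)
    ld = lig.dims

    def corr(ra: np.ndarray, la: np.ndarray) -> np.ndarray:
        res = np.zeros(out)
        for tx in range(out[0]):
            for ty in range(out[1]):
                for tz in range(out[2]):
                    block = ra[tx:tx + ld[0], ty:ty + ld[1], tz:tz + ld[2]]
                    res[tx, ty, tz] = np.sum(block * la)
        return res

    comp = {
        "core": corr(rec.channels["core"], lig.channels["core"]),
        "surface": corr(rec.channels["surface"], lig.channels["surface"]),
        "charge": corr(rec.channels["charge"], lig.channels["charge"]),
    }
    pair = np.zeros(out)
    for i in range(len(ATYPES)):
        for j in range(len(ATYPES)):
            eps = pair_matrix[i, j]
            ra = rec.channels[PAIR_CHANNELS[i]]
            la = lig.channels[PAIR_CHANNELS[j]]
            if eps == 0.0 or not la.any() or not ra.any():
                continue
            pair += eps * corr(ra, la)
    comp["pair"] = pair
    w = weights
    values = (w.w_rep * comp["core"] - w.w_attr * comp["surface"]
              + w.w_elec * comp["charge"] + w.w_pair * comp["pair"])
    return ScoreField(values=values, components=comp,
                      rotation=rotation or Rotation.identity(),
                      weights=w, pair_matrix=pair_matrix)


def dump_grid(gs: GridSet, channel: str) -> str:
    """Debug dump: documented text header + flat voxel values."""
    arr = gs.channels[channel]
    head = (f"# gridset channel={channel}\n"
            f"# origin {gs.origin[0]:.6f} {gs.origin[1]:.6f} {gs.origin[2]:.6f}\n"
            f"# spacing {gs.spacing:.6f}\n"
            f"# dims {gs.dims[0]} {gs.dims[1]} {gs.dims[2]}\n")
    body = "\n".join(f"{v:.9g}" for v in arr.ravel())
    return head + body + "\n"
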