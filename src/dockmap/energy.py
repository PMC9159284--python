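"""Continuous rigid-body interaction energy and local minimization.

Softened Lennard-Jones plus screened Coulomb between a fixed receptor
and one or many rigid mobile bodies (docked ligand or mapping probes).
The minimizer is gradient descent on (translation, rotation) with
per-body adaptive step sizes; steps are only accepted when the energy
decreases, so the returned energy never exceeds the input energy.
"""

from __future__ import annotations

import numpy as np

from .structio import ATYPES, ParamStructure

#: LJ well depth (arbitrary energy units) and distance softening (Å)
LJ_EPS = 0.1
SOFT2 = 0.25
#: Coulomb prefactor with distance-dependent dielectric ~4d, screening length (Å)
COULOMB_K = 83.0
SCREEN_LEN = 8.0
#: clash criterion: pair distance below this fraction of the radius sum
CLASH_FRAC = 0.75
#: pair cutoff (Å) beyond which interactions are neglected
CUTOFF = 12.0


def _pair_terms(d2: np.ndarray, rmin: np.ndarray, qq: np.ndarray,
                eps: np.ndarray | float):
    """Energy and dE/d(d^2) for softened LJ + screened Coulomb."""
    ds2 = d2 + SOFT2
    inv = rmin * rmin / ds2
    s6 = inv ** 3
    e_lj = eps * (s6 * s6 - 2.0 * s6)
    d = np.sqrt(ds2)
    scr = np.exp(-d / SCREEN_LEN)
    e_el = COULOMB_K * qq * scr / d
    # derivatives w.r.t. d^2
    de_lj = eps * (-12.0 * s6 * s6 + 12.0 * s6) / ds2
    de_el = -0.5 * e_el * (1.0 / d + 1.0 / SCREEN_LEN) / d
    mask = d2 < CUTOFF * CUTOFF
    return np.where(mask, e_lj + e_el, 0.0), np.where(mask, de_lj + de_el, 0.0)


def pair_well_depths(mob_types, rec_types) -> np.ndarray | float:
    """(n, m) LJ well-depth matrix from the atom-type contact energies.

    Complementary pairs (negative contact energy) get deeper wells than
    mismatched pairs, keeping the continuous score consistent with the
    grid pair term.  With either side untyped, the uniform depth is used.
    """
    if mob_types is None or rec_types is None:
        return LJ_EPS
    from .gridcore import load_contact_matrix
    contact = load_contact_matrix()
    idx = {t: i for i, t in enumerate(ATYPES)}
    mi = np.array([idx[t] for t in mob_types])
    ri = np.array([idx[t] for t in rec_types])
    return LJ_EPS * (1.0 - 2.0 * contact[np.ix_(mi, ri)])


def interaction_energy(rec: ParamStructure, mob_coords: np.ndarray,
                       mob_radius: np.ndarray, mob_charge: np.ndarray,
                       mob_types=None) -> float:
    """Total receptor–mobile energy for a single coordinate set."""
    eps = pair_well_depths(mob_types, rec.atype if mob_types else None)
    e, _ = _batch_energy(rec.coords, rec.radius, rec.charge,
                         mob_coords[None], mob_radius, mob_charge,
                         eps=eps, want_grad=False)
    return float(e[0])


def _batch_energy(rc: np.ndarray, rr: np.ndarray, rq: np.ndarray,
                  mc: np.ndarray, mr: np.ndarray, mq: np.ndarray,
                  eps=LJ_EPS, want_grad: bool = True):
    """Energies (and per-atom force) for a (B, n, 3) batch of mobile bodies."""
    diff = mc[:, :, None, :] - rc[None, None, :, :]        # (B, n, m, 3)
    d2 = np.sum(diff * diff, axis=-1)
    rmin = mr[None, :, None] + rr[None, None, :]
    qq = mq[None, :, None] * rq[None, None, :]
    e, de = _pair_terms(d2, rmin, qq, eps)
    energies = e.sum(axis=(1, 2))
    if not want_grad:
        return energies, None
    forces = -2.0 * de[..., None] * diff                   # -dE/dx per atom
    return energies, forces.sum(axis=2)                    # (B, n, 3)


def clash_count(rec: ParamStructure, mob_coords: np.ndarray,
                mob_radius: np.ndarray) -> int:
    """Heavy-atom pairs closer than CLASH_FRAC × radius sum."""
    diff = mob_coords[:, None, :] - rec.coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    lim = CLASH_FRAC * (mob_radius[:, None] + rec.radius[None, :])
    return int(np.sum(d < lim))


def _rotvec_matrices(w: np.ndarray) -> np.ndarray:
    """Rotation matrices for a (B, 3) batch of rotation vectors."""
    theta = np.linalg.norm(w, axis=1)
    out = np.empty((len(w), 3, 3))
    for b in range(len(w)):
        t = theta[b]
        if t < 1e-12:
            out[b] = np.eye(3)
            continue
        k = w[b] / t
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        out[b] = np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)
    return out


def minimize_rigid(rec: ParamStructure, coords: np.ndarray,
                   radius: np.ndarray, charge: np.ndarray, *,
                   mob_types=None, max_iter: int = 40, step0: float = 0.25,
                   max_rmsd: float = 3.0, chunk: int = 256):
    """Locally minimize a batch of rigid bodies against the receptor.

    Parameters
    ----------
    coords : (B, n, 3) starting coordinates of B rigid copies.
    max_rmsd : maximum allowed displacement (Å RMSD) from the start.

    Returns
    -------
    (coords, energies, start_energies, diverged) — energies never exceed
    the start energies; bodies whose line search collapses keep their
    input coordinates and are flagged.
    """
    coords = np.array(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    B = coords.shape[0]
    out_c = np.empty_like(coords)
    out_e = np.empty(B)
    out_e0 = np.empty(B)
    out_div = np.zeros(B, dtype=bool)
    rc, rr, rq = rec.coords, rec.radius, rec.charge
    eps = pair_well_depths(mob_types, rec.atype if mob_types else None)
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        c, e, e0, div = _minimize_chunk(rc, rr, rq, coords[lo:hi], radius,
                                        charge, eps, max_iter, step0,
                                        max_rmsd)
        out_c[lo:hi], out_e[lo:hi], out_e0[lo:hi], out_div[lo:hi] = c, e, e0, div
    return out_c, out_e, out_e0, out_div


def _minimize_chunk(rc, rr, rq, coords, radius, charge, eps,
                    max_iter, step0, max_rmsd):
    start = coords.copy()
    cur = coords.copy()
    e_cur, forces = _batch_energy(rc, rr, rq, cur, radius, charge, eps=eps)
    e0 = e_cur.copy()
    B, n = cur.shape[:2]
    step = np.full(B, step0)
    active = np.ones(B, dtype=bool)
    n_bad = np.zeros(B, dtype=int)
    for _ in range(max_iter):
        if not active.any():
            break
        cen = cur.mean(axis=1, keepdims=True)
        fnet = forces.mean(axis=1)                              # (B, 3)
        torque = np.cross(cur - cen, forces).sum(axis=1)        # (B, 3)
        fn = np.linalg.norm(fnet, axis=1, keepdims=True)
        tn = np.linalg.norm(torque, axis=1, keepdims=True)
        dt = step[:, None] * fnet / np.maximum(fn, 1e-9)
        # rotation step capped at 0.2 rad per iteration
        ang = np.minimum(step[:, None] * 0.15, 0.2)
        dw = ang * torque / np.maximum(tn, 1e-9)
        dw[tn[:, 0] < 1e-9] = 0.0
        rots = _rotvec_matrices(dw)
        prop = np.einsum("bij,bnj->bni", rots, cur - cen) + cen + dt[:, None, :]
        rmsd = np.sqrt(np.mean(np.sum((prop - start) ** 2, axis=-1), axis=-1))
        e_prop, f_prop = _batch_energy(rc, rr, rq, prop, radius, charge,
                                       eps=eps)
        ok = active & (e_prop < e_cur) & (rmsd <= max_rmsd)
        cur[ok] = prop[ok]
        e_cur[ok] = e_prop[ok]
        forces[ok] = f_prop[ok]
        step[ok] *= 1.2
        rej = active & ~ok
        step[rej] *= 0.4
        n_bad[rej] += 1
        active &= step > 1e-4
    diverged = (n_bad >= max_iter) & (e_cur >= e0)
    # a diverged body keeps its input pose (contract: never worsen)
    return cur, e_cur, e0, diverged
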