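"""Langevin dynamics of the heteromorphic chromatin model.

The polymer is a bead-spring chain (harmonic bonds, rest length 1 sigma)
with purely repulsive WCA excluded volume between all particle pairs.
Compact (non-open) chromatin additionally carries a cosine bending
potential and next-nearest-neighbor "crumpling" springs; open chromatin
carries neither, making it the thinner, more flexible fiber state.
Diffusing proteins switch stochastically between a binding and a
non-binding mode; binding-mode proteins feel a short-range attraction
(truncated-shifted Lennard-Jones well) to binding-site beads, which makes
them multivalent bridges.  Loop extruders are harmonic springs between two
anchor beads whose anchors step outward stochastically and stall at
convergently oriented CTCF beads.

Integration is BAOAB Langevin at kT=1; all pair interactions use the
minimum-image convention in a cubic periodic box, evaluated through a
cell-list neighbor list with a Verlet skin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from numba import njit

from .annotation_io import (BeadAnnotation, CopySpan, GenomicInterval,
                            CTCF_NONE, CTCF_FORWARD, CTCF_REVERSE, CTCF_BOTH)
from .calibration import UnitMapping
from .model_builder import (Extruder, SimulationParameters, SystemState,
                            build_system)

__all__ = [
    "ForceField",
    "Trajectory",
    "InstabilityError",
    "compute_forces",
    "potential_energy",
    "langevin_step",
    "advance",
    "switch_proteins",
    "step_extruders",
    "run_simulation",
]

_WCA_CUT = 2.0 ** (1.0 / 6.0)


class InstabilityError(RuntimeError):
    """A particle moved more than 0.5 sigma in one step; reduce dt."""


@dataclass
class ForceField:
    """Potential parameters, in reduced units (kT, sigma).

    All terms are continuous at their cutoffs and forces are exact
    negative gradients of the potentials.
    """

    k_bond: float = 100.0      # chain bond stiffness, kT/sigma^2 (rest 1.0)
    k_theta: float = 4.0       # bending stiffness on compact triples, kT
    k_nnn: float = 20.0        # crumpling NNN spring, kT/sigma^2 (rest 1.5)
    eps_bind: float = 6.0      # protein/binding-site well depth, kT
    r_attr: float = 1.8        # attraction cutoff, sigma
    k_extruder: float = 100.0  # extruder spring, kT/sigma^2 (rest 1.5)
    eps_weak: float = 0.0      # optional weak attraction to open beads, kT
    bond_rest: float = 1.0
    nnn_rest: float = 1.5
    extruder_rest: float = 1.5
    fixed_bond_rest: float = 1.0
    skin: float = 0.4          # Verlet-list skin, sigma

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(pos, L, rlist):
    """All particle pairs within ``rlist`` under minimum image -> (m, 2)."""
    n = pos.shape[0]
    ncell = int(L / rlist)
    cap = 64 * n + 1024
    pairs = np.empty((cap, 2), dtype=np.int64)
    m = 0
    r2cut = rlist * rlist
    if ncell < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                d2 = 0.0
                for d in range(3):
                    dx = pos[i, d] - pos[j, d]
                    dx -= L * np.round(dx / L)
                    d2 += dx * dx
                if d2 < r2cut:
                    if m >= cap:
                        new = np.empty((cap * 2, 2), dtype=np.int64)
                        new[:cap] = pairs
                        pairs = new
                        cap *= 2
                    pairs[m, 0] = i
                    pairs[m, 1] = j
                    m += 1
        return pairs[:m].copy()

    cell_sz = L / ncell
    nc3 = ncell * ncell * ncell
    head = np.full(nc3, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cix = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        for d in range(3):
            c = int((pos[i, d] % L) / cell_sz)
            if c >= ncell:
                c = ncell - 1
            cix[i, d] = c
        cid = (cix[i, 0] * ncell + cix[i, 1]) * ncell + cix[i, 2]
        nxt[i] = head[cid]
        head[cid] = i
    # half-shell of 13 neighbor offsets + self cell
    offs = np.array([
        (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, -1, 0),
        (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1), (1, 1, 1), (1, 1, -1),
        (1, -1, 1), (1, -1, -1)], dtype=np.int64)
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                cid = (cx * ncell + cy) * ncell + cz
                for k in range(offs.shape[0]):
                    ox = (cx + offs[k, 0]) % ncell
                    oy = (cy + offs[k, 1]) % ncell
                    oz = (cz + offs[k, 2]) % ncell
                    oid = (ox * ncell + oy) * ncell + oz
                    i = head[cid]
                    while i >= 0:
                        j = head[oid] if k > 0 else nxt[i]
                        while j >= 0:
                            d2 = 0.0
                            for d in range(3):
                                dx = pos[i, d] - pos[j, d]
                                dx -= L * np.round(dx / L)
                                d2 += dx * dx
                            if d2 < r2cut:
                                if m >= cap:
                                    new = np.empty((cap * 2, 2), dtype=np.int64)
                                    new[:cap] = pairs
                                    pairs = new
                                    cap *= 2
                                pairs[m, 0] = i
                                pairs[m, 1] = j
                                m += 1
                            j = nxt[j]
                        i = nxt[i]
    return pairs[:m].copy()


@njit(cache=True, fastmath=True)
def _forces(pos, L, nb, pairs, is_bind, is_open, prot_mode,
            nnn_pairs, angle_centers, ext_bonds, fixed_bonds, fixed_rests,
            k_bond, bond_rest, k_theta, k_nnn, nnn_rest,
            eps_bind, eps_weak, r_attr, k_ext, ext_rest,
            k_fix, forces):
    """Fill ``forces`` with -grad U; return total potential energy.

    ``is_bind``/``is_open`` are full-length (beads+proteins) masks, False on
    proteins; ``prot_mode`` is full-length, False on beads.
    """
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            forces[i, d] = 0.0
    energy = 0.0
    r_attr2 = r_attr * r_attr
    wca2 = _WCA_CUT * _WCA_CUT

    # --- nonbonded pairs ---------------------------------------------------
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if i < nb and j < nb and (i - j == 1 or j - i == 1):
            continue  # chain-bonded neighbors are excluded from nonbonded terms
        dx0 = pos[i, 0] - pos[j, 0]
        dx0 -= L * np.round(dx0 / L)
        dx1 = pos[i, 1] - pos[j, 1]
        dx1 -= L * np.round(dx1 / L)
        dx2 = pos[i, 2] - pos[j, 2]
        dx2 -= L * np.round(dx2 / L)
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        if r2 < 1e-12:
            continue
        eps_a = 0.0
        if (is_bind[i] and prot_mode[j]) or (is_bind[j] and prot_mode[i]):
            eps_a = eps_bind
        elif eps_weak > 0.0 and ((is_open[i] and prot_mode[j])
                                 or (is_open[j] and prot_mode[i])):
            eps_a = eps_weak
        if eps_a > 0.0:
            if r2 < r_attr2:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                inv12 = inv6 * inv6
                # truncated-shifted LJ: U = 4 eps (r^-12 - r^-6) - U(rc)
                rc2 = 1.0 / r_attr2
                rc6 = rc2 * rc2 * rc2
                shift = 4.0 * eps_a * (rc6 * rc6 - rc6)
                energy += 4.0 * eps_a * (inv12 - inv6) - shift
                fmag = 4.0 * eps_a * (12.0 * inv12 - 6.0 * inv6) * inv2
                forces[i, 0] += fmag * dx0
                forces[i, 1] += fmag * dx1
                forces[i, 2] += fmag * dx2
                forces[j, 0] -= fmag * dx0
                forces[j, 1] -= fmag * dx1
                forces[j, 2] -= fmag * dx2
        else:
            if r2 < wca2:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                inv12 = inv6 * inv6
                energy += 4.0 * (inv12 - inv6) + 1.0
                fmag = 4.0 * (12.0 * inv12 - 6.0 * inv6) * inv2
                forces[i, 0] += fmag * dx0
                forces[i, 1] += fmag * dx1
                forces[i, 2] += fmag * dx2
                forces[j, 0] -= fmag * dx0
                forces[j, 1] -= fmag * dx1
                forces[j, 2] -= fmag * dx2

    # --- harmonic bonds (chain, NNN, extruder, fixed) ----------------------
    for i in range(nb - 1):
        energy += _harmonic(pos, L, i, i + 1, k_bond, bond_rest, forces)
    for p in range(nnn_pairs.shape[0]):
        energy += _harmonic(pos, L, nnn_pairs[p, 0], nnn_pairs[p, 1],
                            k_nnn, nnn_rest, forces)
    for p in range(ext_bonds.shape[0]):
        energy += _harmonic(pos, L, ext_bonds[p, 0], ext_bonds[p, 1],
                            k_ext, ext_rest, forces)
    for p in range(fixed_bonds.shape[0]):
        energy += _harmonic(pos, L, fixed_bonds[p, 0], fixed_bonds[p, 1],
                            k_fix, fixed_rests[p], forces)

    # --- bending on compact triples ---------------------------------------
    for a in range(angle_centers.shape[0]):
        c = angle_centers[a]
        b1x = pos[c, 0] - pos[c - 1, 0]
        b1x -= L * np.round(b1x / L)
        b1y = pos[c, 1] - pos[c - 1, 1]
        b1y -= L * np.round(b1y / L)
        b1z = pos[c, 2] - pos[c - 1, 2]
        b1z -= L * np.round(b1z / L)
        b2x = pos[c + 1, 0] - pos[c, 0]
        b2x -= L * np.round(b2x / L)
        b2y = pos[c + 1, 1] - pos[c, 1]
        b2y -= L * np.round(b2y / L)
        b2z = pos[c + 1, 2] - pos[c, 2]
        b2z -= L * np.round(b2z / L)
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        ux, uy, uz = b1x / n1, b1y / n1, b1z / n1
        vx, vy, vz = b2x / n2, b2y / n2, b2z / n2
        cph = ux * vx + uy * vy + uz * vz
        # U = k_theta (1 - cos phi); F = k_theta * d(cos phi)/dr
        energy += k_theta * (1.0 - cph)
        gpx = (vx - cph * ux) / n1   # d cph / d r_{c-1} = -gp
        gpy = (vy - cph * uy) / n1
        gpz = (vz - cph * uz) / n1
        gnx = (ux - cph * vx) / n2   # d cph / d r_{c+1} = +gn
        gny = (uy - cph * vy) / n2
        gnz = (uz - cph * vz) / n2
        forces[c - 1, 0] -= k_theta * gpx
        forces[c - 1, 1] -= k_theta * gpy
        forces[c - 1, 2] -= k_theta * gpz
        forces[c, 0] += k_theta * (gpx - gnx)
        forces[c, 1] += k_theta * (gpy - gny)
        forces[c, 2] += k_theta * (gpz - gnz)
        forces[c + 1, 0] += k_theta * gnx
        forces[c + 1, 1] += k_theta * gny
        forces[c + 1, 2] += k_theta * gnz
    return energy


@njit(cache=True, inline="always")
def _harmonic(pos, L, i, j, k, r0, forces):
    dx0 = pos[i, 0] - pos[j, 0]
    dx0 -= L * np.round(dx0 / L)
    dx1 = pos[i, 1] - pos[j, 1]
    dx1 -= L * np.round(dx1 / L)
    dx2 = pos[i, 2] - pos[j, 2]
    dx2 -= L * np.round(dx2 / L)
    r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
    if r < 1e-12:
        return 0.5 * k * r0 * r0
    fmag = -k * (r - r0) / r
    forces[i, 0] += fmag * dx0
    forces[i, 1] += fmag * dx1
    forces[i, 2] += fmag * dx2
    forces[j, 0] -= fmag * dx0
    forces[j, 1] -= fmag * dx1
    forces[j, 2] -= fmag * dx2
    return 0.5 * k * (r - r0) ** 2


@njit(cache=True)
def _integrate(pos, vel, L, nb, is_bind, is_open, prot_mode,
               nnn_pairs, angle_centers, ext_bonds, fixed_bonds, fixed_rests,
               n_steps, dt, gamma, kT, seed, rlist, rebuild_every,
               k_bond, bond_rest, k_theta, k_nnn, nnn_rest,
               eps_bind, eps_weak, r_attr, k_ext, ext_rest,
               k_fix, clamp):
    """BAOAB Langevin integration for ``n_steps``; returns failing step
    index (displacement > 0.5 sigma in one step) or -1 on success."""
    np.random.seed(seed)
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    forces = np.empty((n, 3))
    pairs = _build_pairs(pos, L, rlist)
    _forces(pos, L, nb, pairs, is_bind, is_open, prot_mode, nnn_pairs,
            angle_centers, ext_bonds, fixed_bonds, fixed_rests, k_bond,
            bond_rest, k_theta, k_nnn, nnn_rest, eps_bind, eps_weak, r_attr,
            k_ext, ext_rest, k_fix, forces)
    old = np.empty((n, 3))
    acc_disp = 0.0
    half = 0.5 * dt
    for step in range(n_steps):
        max_d2 = 0.0
        for i in range(n):
            for d in range(3):
                old[i, d] = pos[i, d]
                vel[i, d] += half * forces[i, d]
                pos[i, d] += half * vel[i, d]
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
                pos[i, d] += half * vel[i, d]
        for i in range(n):
            d2 = 0.0
            for d in range(3):
                dx = pos[i, d] - old[i, d]
                d2 += dx * dx
            if clamp > 0.0 and d2 > clamp * clamp:
                # push-off phase: cap the displacement and damp the velocity
                scale = clamp / np.sqrt(d2)
                for d in range(3):
                    pos[i, d] = old[i, d] + (pos[i, d] - old[i, d]) * scale
                    vel[i, d] *= scale
                d2 = clamp * clamp
            if d2 > max_d2:
                max_d2 = d2
        if clamp <= 0.0 and max_d2 > 0.25:  # 0.5 sigma
            return step
        acc_disp += np.sqrt(max_d2)
        if acc_disp > 0.45 * (rlist - r_attr) or (step + 1) % rebuild_every == 0:
            pairs = _build_pairs(pos, L, rlist)
            acc_disp = 0.0
        _forces(pos, L, nb, pairs, is_bind, is_open, prot_mode, nnn_pairs,
                angle_centers, ext_bonds, fixed_bonds, fixed_rests, k_bond,
                bond_rest, k_theta, k_nnn, nnn_rest, eps_bind, eps_weak,
                r_attr, k_ext, ext_rest, k_fix, forces)
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
    return -1


# ---------------------------------------------------------------------------
# python assembly layer
# ---------------------------------------------------------------------------

def _topology(annotation: BeadAnnotation, n_proteins: int):
    """Derive NNN crumpling pairs, bending centers and full-length masks."""
    nb = annotation.n_beads
    compact = ~annotation.is_open
    # NNN spring (i, i+2) iff beads i, i+1, i+2 all compact
    tri = compact[:-2] & compact[1:-1] & compact[2:]
    idx = np.nonzero(tri)[0]
    nnn_pairs = np.column_stack([idx, idx + 2]).astype(np.int64)
    angle_centers = (idx + 1).astype(np.int64)  # same triples carry bending
    n = nb + n_proteins
    is_bind = np.zeros(n, dtype=np.bool_)
    is_bind[:nb] = annotation.is_binding_site
    is_open = np.zeros(n, dtype=np.bool_)
    is_open[:nb] = annotation.is_open
    return nnn_pairs, angle_centers, is_bind, is_open


def _kernel_arrays(state: SystemState, annotation: BeadAnnotation,
                   ff: ForceField):
    nb = state.n_beads
    nnn_pairs, angle_centers, is_bind, is_open = _topology(
        annotation, state.n_proteins)
    prot_mode = np.zeros(nb + state.n_proteins, dtype=np.bool_)
    prot_mode[nb:] = state.protein_binding_mode
    ext_bonds = np.array(
        [[e.left_anchor, e.right_anchor] for e in state.extruders],
        dtype=np.int64).reshape(-1, 2)
    fixed = state.fixed_bonds.copy()
    if fixed.size:
        fixed = np.column_stack([fixed[:, 0] + nb, fixed[:, 1]]).astype(np.int64)
        rests = state.fixed_bond_rests
        if len(rests) != len(fixed):
            rests = np.full(len(fixed), ff.fixed_bond_rest)
    else:
        fixed = np.empty((0, 2), dtype=np.int64)
        rests = np.empty(0, dtype=float)
    pos = np.vstack([state.bead_positions, state.protein_positions])
    vel = np.vstack([state.bead_velocities, state.protein_velocities])
    return pos, vel, is_bind, is_open, prot_mode, nnn_pairs, angle_centers, \
        ext_bonds, fixed, np.asarray(rests, dtype=float)


def _ff_scalars(ff: ForceField):
    return (ff.k_bond, ff.bond_rest, ff.k_theta, ff.k_nnn, ff.nnn_rest,
            ff.eps_bind, ff.eps_weak, ff.r_attr, ff.k_extruder,
            ff.extruder_rest, ff.k_bond)


def compute_forces(state: SystemState, annotation: BeadAnnotation,
                   ff: ForceField | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Forces = -grad U on every particle -> (bead forces, protein forces)."""
    ff = ff or ForceField()
    (pos, _vel, is_bind, is_open, prot_mode, nnn, angles, ext, fixed, rests
     ) = _kernel_arrays(state, annotation, ff)
    if not np.isfinite(pos).all():
        raise ValueError("non-finite coordinates")
    nb = state.n_beads
    forces = np.empty_like(pos)
    pairs = _build_pairs(pos, state.box, ff.r_attr)
    _forces(pos, state.box, nb, pairs, is_bind, is_open, prot_mode, nnn,
            angles, ext, fixed, rests, *_ff_scalars(ff), forces)
    return forces[:nb], forces[nb:]


def potential_energy(state: SystemState, annotation: BeadAnnotation,
                     ff: ForceField | None = None) -> float:
    """Total potential energy (kT units)."""
    ff = ff or ForceField()
    (pos, _vel, is_bind, is_open, prot_mode, nnn, angles, ext, fixed, rests
     ) = _kernel_arrays(state, annotation, ff)
    nb = state.n_beads
    forces = np.empty_like(pos)
    pairs = _build_pairs(pos, state.box, ff.r_attr)
    return float(_forces(pos, state.box, nb, pairs, is_bind, is_open,
                         prot_mode, nnn, angles, ext, fixed, rests,
                         *_ff_scalars(ff), forces))


def advance(state: SystemState, annotation: BeadAnnotation,
            params: SimulationParameters, ff: ForceField,
            n_steps: int, thermo_seed: int, clamp: float = 0.0) -> None:
    """Advance ``state`` in place by ``n_steps`` BAOAB steps.

    Raises :class:`InstabilityError` if any particle moves more than
    0.5 sigma in a single step.  A positive ``clamp`` instead caps the
    per-step displacement (push-off mode for resolving initial overlaps).
    """
    (pos, vel, is_bind, is_open, prot_mode, nnn, angles, ext, fixed, rests
     ) = _kernel_arrays(state, annotation, ff)
    rlist = ff.r_attr + ff.skin
    status = _integrate(
        pos, vel, state.box, state.n_beads, is_bind, is_open, prot_mode,
        nnn, angles, ext, fixed, rests, n_steps, params.dt, params.friction,
        params.temperature, int(thermo_seed) % (2 ** 31), rlist, 10,
        *_ff_scalars(ff), clamp)
    if status >= 0:
        raise InstabilityError(
            f"displacement exceeded 0.5 sigma at step {status}; "
            "reduce dt or stiffnesses")
    nb = state.n_beads
    state.bead_positions = pos[:nb]
    state.protein_positions = pos[nb:]
    state.bead_velocities = vel[:nb]
    state.protein_velocities = vel[nb:]
    state.time += n_steps * params.dt


def langevin_step(state: SystemState, annotation: BeadAnnotation,
                  params: SimulationParameters, ff: ForceField,
                  rng: np.random.Generator) -> SystemState:
    """Advance a copy of ``state`` by a single dt (BAOAB); returns it."""
    out = state.copy()
    advance(out, annotation, params, ff, 1,
            int(rng.integers(2 ** 31)))
    return out


# ---------------------------------------------------------------------------
# stochastic protein switching and loop extrusion
# ---------------------------------------------------------------------------

def switch_proteins(state: SystemState, k_sw: float, elapsed: float,
                    rng: np.random.Generator) -> None:
    """Flip each protein's binding mode with prob 1-exp(-k_sw*elapsed).

    Proteins participating in fixed (frozen) bonds never switch.
    """
    if k_sw < 0:
        raise ValueError("k_sw must be nonnegative")
    n = state.n_proteins
    if n == 0 or k_sw == 0.0:
        return
    p = 1.0 - np.exp(-k_sw * elapsed)
    flips = rng.random(n) < p
    if state.fixed_bonds.size:
        flips[np.unique(state.fixed_bonds[:, 0])] = False
    state.protein_binding_mode[flips] = ~state.protein_binding_mode[flips]


def _anchor_occupied(extruders, bead: int, skip=None) -> bool:
    for e in extruders:
        if e is skip:
            continue
        if e.left_anchor == bead or e.right_anchor == bead:
            return True
    return False


def _try_stall(side: str, bead: int, annotation: BeadAnnotation,
               rng: np.random.Generator) -> bool:
    """Does an anchor landing on ``bead`` stall there?

    The left anchor (extruding toward smaller indices) is blocked by
    forward-oriented CTCF, the right anchor by reverse-oriented CTCF, so a
    convergent pair traps extruders loaded between its sites.  Stalling is
    probabilistic with the site occupancy weight and permanent for the
    extruder's lifetime.
    """
    code = annotation.ctcf[bead]
    facing = (code == CTCF_BOTH
              or (side == "left" and code == CTCF_FORWARD)
              or (side == "right" and code == CTCF_REVERSE))
    if not facing:
        return False
    return bool(rng.random() < annotation.stall_weight[bead])


def step_extruders(state: SystemState, annotation: BeadAnnotation,
                   params: SimulationParameters, rng: np.random.Generator,
                   elapsed: float) -> None:
    """One loop-extrusion update covering ``elapsed`` tau.

    (i) each extruder unbinds with prob 1-exp(-k_off*elapsed) and is
    instantly re-loaded at a uniformly random adjacent bead pair (constant
    count once loaded); (ii) each non-stalled anchor advances one bead
    outward as a stochastic event at per-side rate k_ex/(2*bead_bp) per tau
    (or deterministically every inverse-rate interval when
    ``params.deterministic_extrusion``); (iii) an anchor landing on a CTCF
    bead facing it stalls with the site's occupancy weight, permanently for
    this binding event; (iv) anchors never cross chain ends or another
    extruder's anchors.
    """
    nb = annotation.n_beads
    target = params.resolve_n_extruders(nb, annotation.bead_bp)
    if nb < 2 or target == 0:
        return
    p_off = 1.0 - np.exp(-params.k_off * elapsed)
    side_rate = params.k_ex / (2.0 * annotation.bead_bp)

    survivors = [e for e in state.extruders if rng.random() >= p_off]
    state.extruders = survivors

    def load_one():
        for _ in range(200):
            i = int(rng.integers(0, nb - 1))
            if not (_anchor_occupied(state.extruders, i)
                    or _anchor_occupied(state.extruders, i + 1)):
                state.extruders.append(Extruder(i, i + 1))
                return
        # crowded chain: give up silently this round

    while len(state.extruders) < target:
        n_before = len(state.extruders)
        load_one()
        if len(state.extruders) == n_before:
            break

    if params.deterministic_extrusion:
        interval = np.inf if side_rate == 0 else 1.0 / side_rate
    for e in state.extruders:
        for side in ("left", "right"):
            stalled = e.left_stalled if side == "left" else e.right_stalled
            if stalled:
                continue
            if params.deterministic_extrusion:
                acc = getattr(e, "_acc_" + side, 0.0) + elapsed
                moves = int(acc // interval) if np.isfinite(interval) else 0
                setattr(e, "_acc_" + side, acc - moves * interval)
                moves = min(moves, 1)
            else:
                moves = 1 if rng.random() < 1.0 - np.exp(-side_rate * elapsed) else 0
            if not moves:
                continue
            if side == "left":
                nxt = e.left_anchor - 1
                if nxt < 0 or _anchor_occupied(state.extruders, nxt, skip=e):
                    continue
                e.left_anchor = nxt
                if _try_stall("left", nxt, annotation, rng):
                    e.left_stalled = True
            else:
                nxt = e.right_anchor + 1
                if nxt >= nb or _anchor_occupied(state.extruders, nxt, skip=e):
                    continue
                e.right_anchor = nxt
                if _try_stall("right", nxt, annotation, rng):
                    e.right_stalled = True


# ---------------------------------------------------------------------------
# trajectory container and the main driver
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Regularly sampled frames of a simulation plus event logs.

    Bead/protein positions are stored unwrapped (sigma units, float32);
    ``extruder_anchors`` is (frames, max_extruders, 2) with -1 padding;
    ``protein_bond_counts`` logs the number of attractive protein/binding
    -site contacts (within the attraction range) per frame.
    """

    times: np.ndarray                  # (F,), tau
    bead_positions: np.ndarray         # (F, nb, 3)
    protein_positions: np.ndarray      # (F, np, 3)
    protein_mode: np.ndarray           # (F, np) bool
    extruder_anchors: np.ndarray       # (F, K, 2) int32
    protein_bond_counts: np.ndarray    # (F,) int64
    box: float
    annotation: BeadAnnotation
    params: SimulationParameters
    forcefield: ForceField
    mapping: UnitMapping = field(default_factory=UnitMapping)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.bead_positions.shape[1]

    @property
    def frame_interval_tau(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval_tau * self.mapping.tau_s

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        import h5py

        ann = self.annotation
        with h5py.File(path, "w") as h5:
            h5.attrs["sigma_nm"] = self.mapping.sigma_nm
            h5.attrs["tau_s"] = self.mapping.tau_s
            h5.attrs["mapping_provenance"] = self.mapping.provenance
            h5.attrs["box"] = self.box
            h5.attrs["params_json"] = json.dumps(asdict(self.params))
            h5.attrs["forcefield_json"] = json.dumps(self.forcefield.as_dict())
            h5.attrs["annotation_hash"] = ann.content_hash()
            h5.create_dataset("times", data=self.times)
            h5.create_dataset("bead_positions", data=self.bead_positions,
                              compression="gzip", compression_opts=1)
            h5.create_dataset("protein_positions", data=self.protein_positions,
                              compression="gzip", compression_opts=1)
            h5.create_dataset("protein_mode", data=self.protein_mode)
            h5.create_dataset("extruder_anchors", data=self.extruder_anchors)
            h5.create_dataset("protein_bond_counts",
                              data=self.protein_bond_counts)
            g = h5.create_group("annotation")
            g.attrs["bead_bp"] = ann.bead_bp
            g.attrs["region"] = (f"{ann.region.chrom}:{ann.region.start}-"
                                 f"{ann.region.end}")
            g.create_dataset("is_binding_site", data=ann.is_binding_site)
            g.create_dataset("is_open", data=ann.is_open)
            g.create_dataset("ctcf", data=ann.ctcf)
            g.create_dataset("stall_weight", data=ann.stall_weight)
            g.create_dataset("copy_id", data=ann.copy_id)
            g.create_dataset("copies", data=np.array(
                [[c.copy_id, c.source_index, c.start_bead, c.n_beads]
                 for c in ann.copies], dtype=np.int64).reshape(-1, 4))

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as h5:
            g = h5["annotation"]
            chrom, span = g.attrs["region"].split(":")
            start, end = (int(x) for x in span.split("-"))
            ann = BeadAnnotation(
                bead_bp=int(g.attrs["bead_bp"]),
                region=GenomicInterval(chrom, start, end),
                is_binding_site=g["is_binding_site"][:],
                is_open=g["is_open"][:],
                ctcf=g["ctcf"][:],
                stall_weight=g["stall_weight"][:],
                copy_id=g["copy_id"][:],
                copies=[CopySpan(*row) for row in g["copies"][:]],
            )
            params = SimulationParameters(**json.loads(h5.attrs["params_json"]))
            ff = ForceField(**json.loads(h5.attrs["forcefield_json"]))
            mapping = UnitMapping(
                sigma_nm=float(h5.attrs["sigma_nm"]),
                tau_s=float(h5.attrs["tau_s"]),
                provenance=str(h5.attrs["mapping_provenance"]),
            )
            return cls(
                times=h5["times"][:],
                bead_positions=h5["bead_positions"][:],
                protein_positions=h5["protein_positions"][:],
                protein_mode=h5["protein_mode"][:],
                extruder_anchors=h5["extruder_anchors"][:],
                protein_bond_counts=h5["protein_bond_counts"][:],
                box=float(h5.attrs["box"]),
                annotation=ann,
                params=params,
                forcefield=ff,
                mapping=mapping,
            )


def _count_protein_bonds(state: SystemState, annotation: BeadAnnotation,
                         r_attr: float) -> int:
    """Attractive (binding protein, binding-site bead) contacts within range."""
    from scipy.spatial import cKDTree

    from .observables import wrap_coords

    bind_beads = wrap_coords(state.bead_positions[annotation.is_binding_site],
                             state.box)
    prots = wrap_coords(state.protein_positions[state.protein_binding_mode],
                        state.box)
    if len(bind_beads) == 0 or len(prots) == 0:
        return 0
    tree = cKDTree(bind_beads, boxsize=state.box)
    return int(sum(len(x) for x in
                   tree.query_ball_point(prots, r_attr)))


def equilibrate(annotation: BeadAnnotation,
                params: SimulationParameters,
                ff: ForceField | None = None,
                initial_state: SystemState | None = None) -> SystemState:
    """Build the system and run the t_equil relaxation phase only.

    Returns the relaxed state (with extruders loaded and proteins
    switched), e.g. as the treatment point for acute perturbations.
    """
    ff = ff or ForceField()
    state = initial_state.copy() if initial_state is not None \
        else build_system(annotation, params)
    ss = np.random.SeedSequence(params.seed)
    thermo_ss, switch_ss, extr_ss = ss.spawn(3)
    thermo_rng = np.random.default_rng(thermo_ss)
    switch_rng = np.random.default_rng(switch_ss)
    extr_rng = np.random.default_rng(extr_ss)
    if state.time == 0.0:
        # resolve random-placement overlaps with capped displacements
        advance(state, annotation, params, ff,
                int(round(5.0 / params.dt)),
                int(thermo_rng.integers(2 ** 31)), clamp=0.05)
        state.time = 0.0
    block_dt = min(params.event_interval, params.frame_interval)
    n_sub = max(1, int(round(block_dt / params.dt)))
    for _ in range(int(round(params.t_equil / block_dt))):
        advance(state, annotation, params, ff, n_sub,
                int(thermo_rng.integers(2 ** 31)))
        switch_proteins(state, params.k_sw, block_dt, switch_rng)
        step_extruders(state, annotation, params, extr_rng, block_dt)
    return state


def run_simulation(annotation: BeadAnnotation,
                   params: SimulationParameters,
                   ff: ForceField | None = None,
                   initial_state: SystemState | None = None,
                   mapping: UnitMapping | None = None) -> Trajectory:
    """Equilibrate, then sample ``n_frames`` frames evenly over t_sample.

    Fully reproducible from ``params.seed``: independent RNG streams drive
    the thermostat, protein switching, and extrusion so observables are
    stable under subsystem reordering.  An instability aborts with the
    frame index reached.
    """
    ff = ff or ForceField()
    mapping = mapping or UnitMapping(sigma_nm=params.bead_diameter_nm,
                                     tau_s=params.tau_s)
    state = initial_state.copy() if initial_state is not None \
        else build_system(annotation, params)

    ss = np.random.SeedSequence(params.seed)
    thermo_ss, switch_ss, extr_ss = ss.spawn(3)
    thermo_rng = np.random.default_rng(thermo_ss)
    switch_rng = np.random.default_rng(switch_ss)
    extr_rng = np.random.default_rng(extr_ss)

    if state.time == 0.0:
        advance(state, annotation, params, ff,
                int(round(5.0 / params.dt)),
                int(thermo_rng.integers(2 ** 31)), clamp=0.05)
        state.time = 0.0

    nb = annotation.n_beads
    n_ext = params.resolve_n_extruders(nb, annotation.bead_bp)
    frame_dt = params.frame_interval
    block_dt = min(params.event_interval, frame_dt)
    blocks_per_frame = max(1, int(round(frame_dt / block_dt)))
    block_dt = frame_dt / blocks_per_frame
    n_sub = max(1, int(round(block_dt / params.dt)))

    def one_block(frame_idx: int) -> None:
        try:
            advance(state, annotation, params, ff, n_sub,
                    int(thermo_rng.integers(2 ** 31)))
        except InstabilityError as err:
            raise InstabilityError(
                f"{err} (after frame {frame_idx})") from None
        switch_proteins(state, params.k_sw, block_dt, switch_rng)
        step_extruders(state, annotation, params, extr_rng, block_dt)

    n_equil_blocks = int(round(params.t_equil / block_dt))
    for _ in range(n_equil_blocks):
        one_block(-1)

    F = params.n_frames
    times = np.empty(F)
    bead_frames = np.empty((F, nb, 3), dtype=np.float32)
    prot_frames = np.empty((F, state.n_proteins, 3), dtype=np.float32)
    mode_frames = np.empty((F, state.n_proteins), dtype=bool)
    anchors = np.full((F, max(n_ext, 1), 2), -1, dtype=np.int32)
    bond_counts = np.zeros(F, dtype=np.int64)

    for f in range(F):
        for _ in range(blocks_per_frame):
            one_block(f)
        times[f] = state.time
        bead_frames[f] = state.bead_positions
        prot_frames[f] = state.protein_positions
        mode_frames[f] = state.protein_binding_mode
        for k, e in enumerate(state.extruders[:anchors.shape[1]]):
            anchors[f, k, 0] = e.left_anchor
            anchors[f, k, 1] = e.right_anchor
        bond_counts[f] = _count_protein_bonds(state, annotation, ff.r_attr)

    return Trajectory(
        times=times,
        bead_positions=bead_frames,
        protein_positions=prot_frames,
        protein_mode=mode_frames,
        extruder_anchors=anchors,
        protein_bond_counts=bond_counts,
        box=state.box,
        annotation=annotation,
        params=params,
        forcefield=ff,
        mapping=mapping,
    )
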