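"""In-silico perturbations of the model.

Two transcription-inhibition (alpha-amanitin) models:

* **Model A** — loss of polymerase-containing complexes: every
  protein-binding site is removed from the annotation and the system is
  re-equilibrated, so proteins no longer organize the locus.
* **Model B** — stabilization: at the moment of treatment every
  binding-mode protein within the attraction range of a binding-site bead
  is permanently bonded to it (bridges are frozen); such proteins stop
  switching, and the run continues from the treated state without
  re-equilibration (an acute treatment).

Plus parameter sweeps (protein switching rate, protein number, extrusion
rate, CTCF density, extruder count) and protein-cluster diagnostics.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .annotation_io import BeadAnnotation, CTCF_FORWARD, CTCF_NONE, CTCF_REVERSE
from .configuration_space import config_trajectory, variability
from .dynamics_engine import (ForceField, Trajectory, equilibrate,
                              run_simulation)
from .model_builder import SimulationParameters, SystemState
from .observables import (ProbeRegion, compute_msd, fit_subdiffusion_exponent,
                          mobility_profile, wrap_coords)

__all__ = [
    "alpha_amanitin_A",
    "alpha_amanitin_B",
    "add_random_ctcf",
    "sweep",
    "run_perturbation_experiment",
    "protein_cluster_sizes",
    "mean_largest_cluster",
]

SWEEP_AXES = ("k_sw", "n_proteins", "k_ex", "ctcf_density", "n_extruders")


def alpha_amanitin_A(annotation: BeadAnnotation) -> BeadAnnotation:
    """Model A: clear every protein-binding site; all else untouched."""
    out = annotation.copy()
    out.is_binding_site[:] = False
    return out


def alpha_amanitin_B(state: SystemState, annotation: BeadAnnotation,
                     capture_range: float = 1.8) -> SystemState:
    """Model B: freeze every current protein/binding-site contact.

    Every (binding-mode protein, binding-site bead) pair within
    ``capture_range`` sigma (minimum image) becomes a permanent harmonic
    bond; a protein may be fixed to several beads, freezing its bridges.
    Fixed proteins are exempt from switching thereafter.
    """
    out = state.copy()
    bind_idx = np.nonzero(annotation.is_binding_site)[0]
    prot_idx = np.nonzero(state.protein_binding_mode)[0]
    if len(bind_idx) == 0 or len(prot_idx) == 0:
        return out
    beads = wrap_coords(state.bead_positions[bind_idx], state.box)
    prots = wrap_coords(state.protein_positions[prot_idx], state.box)
    tree = cKDTree(beads, boxsize=state.box)
    new_bonds, new_rests = [], []
    for p, hits in enumerate(tree.query_ball_point(prots, capture_range)):
        for b in hits:
            new_bonds.append((int(prot_idx[p]), int(bind_idx[b])))
            # freeze the contact at its current separation: the new bond
            # is strain-free at the moment of treatment
            d = (state.protein_positions[prot_idx[p]]
                 - state.bead_positions[bind_idx[b]])
            d -= state.box * np.round(d / state.box)
            new_rests.append(float(np.sqrt((d ** 2).sum())))
    if new_bonds:
        out.fixed_bonds = np.vstack(
            [out.fixed_bonds.reshape(-1, 2),
             np.asarray(new_bonds, dtype=np.int64)])
        out.fixed_bond_rests = np.concatenate(
            [out.fixed_bond_rests, np.asarray(new_rests)])
    return out


def add_random_ctcf(annotation: BeadAnnotation, n_new: int,
                    seed: int = 0) -> BeadAnnotation:
    """Add ``n_new`` CTCF beads at random non-CTCF positions.

    Random orientation, stall weight 1.0 (fully occupied sites).
    """
    if n_new < 0:
        raise ValueError("n_new must be nonnegative")
    out = annotation.copy()
    free = np.nonzero(out.ctcf == CTCF_NONE)[0]
    if n_new > len(free):
        raise ValueError("not enough CTCF-free beads")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(free, size=n_new, replace=False)
    orientations = rng.choice([CTCF_FORWARD, CTCF_REVERSE], size=n_new)
    out.ctcf[chosen] = orientations
    out.stall_weight[chosen] = 1.0
    return out


def run_perturbation_experiment(annotation: BeadAnnotation,
                                params: SimulationParameters,
                                ff: ForceField | None = None,
                                model: str = "untreated",
                                capture_range: float = 1.8) -> Trajectory:
    """Run one arm of the alpha-amanitin experiment with matched seeds.

    ``model`` is ``"untreated"``, ``"A"`` or ``"B"``.  The untreated arm
    and model B share the equilibrated treatment state, so their
    production phases differ only by the frozen bonds; model A changes the
    annotation and therefore re-equilibrates.
    """
    ff = ff or ForceField()
    if model == "A":
        return run_simulation(alpha_amanitin_A(annotation), params, ff)
    if model not in ("untreated", "B"):
        raise ValueError(f"unknown model {model!r}")
    state = equilibrate(annotation, params, ff)
    if model == "B":
        state = alpha_amanitin_B(state, annotation, capture_range)
    prod = params.replace(t_equil=0.0, seed=params.seed + 1)
    return run_simulation(annotation, prod, ff, initial_state=state)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def _class_median_mobility(traj: Trajectory, lag_tau: float) -> dict:
    ann = traj.annotation
    m = mobility_profile(traj, lag_tau=lag_tau).values
    in_copy = ann.copy_id != 0
    classes = {
        "binding": ann.is_binding_site & in_copy,
        "open": ann.is_open & ~ann.is_binding_site & in_copy,
        "compact": ~ann.is_open & ~ann.is_binding_site & in_copy,
    }
    return {f"median_mobility_{k}": float(np.median(m[sel])) if sel.any()
            else np.nan for k, sel in classes.items()}


def sweep(annotation: BeadAnnotation, params: SimulationParameters,
          axis: str, values, seeds, probes: list[ProbeRegion] | None = None,
          ff: ForceField | None = None,
          mobility_lag_tau: float | None = None) -> pd.DataFrame:
    """Run the full pipeline across a parameter axis.

    ``axis`` is one of ``k_sw``, ``n_proteins``, ``k_ex``, ``ctcf_density``
    (value = number of random CTCF sites added) or ``n_extruders``.  Each
    (value, seed) row reports locus variability, the mean configuration
    -vector component, the subdiffusion exponent of the probe region, and
    per-chromatin-class median mobilities.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of "
                         f"{SWEEP_AXES}")
    ff = ff or ForceField()
    rows = []
    for value in values:
        for seed in seeds:
            ann = annotation
            p = params.replace(seed=int(seed))
            if axis == "ctcf_density":
                ann = add_random_ctcf(annotation, int(value), seed=int(seed))
            else:
                p = p.replace(**{axis: value})
            traj = run_simulation(ann, p, ff)
            span = traj.times[-1] - traj.times[0]
            lag = mobility_lag_tau or min(1e4, span / 4)
            row = {"axis": axis, "value": value, "seed": int(seed)}
            row.update(_class_median_mobility(traj, lag))
            if probes is not None:
                series = config_trajectory(traj, probes)
                row["variability_nm3"] = variability(series.vectors)
                row["mean_x_nm"] = float(series.vectors.mean())
                curve = compute_msd(traj, probes[0], use_com=False,
                                    lag_frames=range(1, traj.n_frames // 2))
                row["alpha"] = fit_subdiffusion_exponent(
                    curve, (curve.lags_tau[3], curve.lags_tau[-1]))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein cluster diagnostics
# ---------------------------------------------------------------------------

def protein_cluster_sizes(positions: np.ndarray, box: float,
                          linkage: float = 2.0) -> np.ndarray:
    """Single-linkage cluster sizes of protein positions at ``linkage`` sigma."""
    n = len(positions)
    if n == 0:
        return np.zeros(0, dtype=int)
    pts = wrap_coords(np.asarray(positions, dtype=float), box)
    tree = cKDTree(pts, boxsize=box)
    pairs = tree.query_pairs(linkage, output_type="ndarray")
    if len(pairs) == 0:
        return np.ones(n, dtype=int)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    _n_comp, labels = connected_components(adj, directed=False)
    return np.bincount(labels)


def mean_largest_cluster(traj: Trajectory, linkage: float = 2.0,
                         bound_only: bool = True) -> float:
    """Mean over frames of the largest protein cluster size."""
    largest = []
    for f in range(traj.n_frames):
        pos = traj.protein_positions[f]
        if bound_only:
            pos = pos[traj.protein_mode[f]]
        sizes = protein_cluster_sizes(pos, traj.box, linkage)
        largest.append(sizes.max() if len(sizes) else 0)
    return float(np.mean(largest))
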