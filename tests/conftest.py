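"""Shared fixtures: desk-scale simulations reused across the suite.

The heavy simulation fixtures are session-scoped so each trajectory is
computed once; the conditions (locus size, protein number, schedule) are
the desk-scale analogue of the full-scale study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

import hiphopsim as hh
from hiphopsim.dynamics_engine import Trajectory
from hiphopsim.model_builder import SimulationParameters


def make_synthetic_trajectory(bead_positions, annotation, frame_dt=10.0,
                              box=1000.0, protein_positions=None,
                              protein_mode=None, anchors=None):
    """Build a Trajectory from explicit coordinates (for geometry oracles)."""
    bead_positions = np.asarray(bead_positions, dtype=np.float32)
    F = bead_positions.shape[0]
    if protein_positions is None:
        protein_positions = np.zeros((F, 0, 3), dtype=np.float32)
        protein_mode = np.zeros((F, 0), dtype=bool)
    if anchors is None:
        anchors = np.full((F, 1, 2), -1, dtype=np.int32)
    params = SimulationParameters(
        n_proteins=protein_positions.shape[1], n_extruders=0,
        t_equil=0.0, t_sample=F * frame_dt, n_frames=max(F, 2))
    return Trajectory(
        times=np.arange(1, F + 1, dtype=float) * frame_dt,
        bead_positions=bead_positions,
        protein_positions=protein_positions,
        protein_mode=protein_mode,
        extruder_anchors=anchors,
        protein_bond_counts=np.zeros(F, dtype=np.int64),
        box=box,
        annotation=annotation,
        params=params,
        forcefield=hh.ForceField(),
    )


@pytest.fixture(scope="session")
def toy_locus():
    """400-kbp synthetic locus: open domains, embedded binding sites,
    two convergent CTCF pairs."""
    tracks, ann = hh.generate_toy_locus(
        n_beads=400, seed=1, n_open_domains=4,
        open_domain_len_bp=(20_000, 0.5), sites_per_domain=4.0,
        orphan_site_rate=0.05, n_ctcf_pairs=2)
    return tracks, ann


@pytest.fixture(scope="session")
def desk_params():
    return SimulationParameters(
        n_proteins=40, n_extruders=2, t_equil=600.0, t_sample=3000.0,
        n_frames=150, seed=7)


@pytest.fixture(scope="session")
def bridged_traj(toy_locus, desk_params):
    """Bridged, heterogeneous desk-scale trajectory of the toy locus."""
    _tracks, ann = toy_locus
    return hh.run_simulation(ann, desk_params)


@pytest.fixture(scope="session")
def toy_probes(toy_locus):
    _tracks, ann = toy_locus
    return hh.generate_three_probe_layout(ann, span_bp=200_000, seed=2)


@pytest.fixture(scope="session")
def perturbation_trio(toy_locus, desk_params):
    """Matched untreated / model A / model B trajectories.

    Untreated and model B continue from the same equilibrated state so
    the arms differ only by the intervention; model A re-equilibrates
    with the binding sites removed.
    """
    _tracks, ann = toy_locus
    params = desk_params.replace(t_sample=2000.0, n_frames=100, seed=17)
    state_eq = hh.equilibrate(ann, params)
    prod = params.replace(t_equil=0.0, seed=params.seed + 1)
    untreated = hh.run_simulation(ann, prod, initial_state=state_eq)
    state_fix = hh.alpha_amanitin_B(state_eq, ann)
    treated_b = hh.run_simulation(ann, prod, initial_state=state_fix)
    treated_a = hh.run_simulation(hh.alpha_amanitin_A(ann), params)
    return {"annotation": ann, "untreated": untreated, "A": treated_a,
            "B": treated_b}


@pytest.fixture(scope="session")
def hetero_chain_traj():
    """200-bead chain, central half compact (bending + crumpling), the
    rest open; no proteins or extruders — isolates fiber-structure
    effects on mobility."""
    ann = hh.BeadAnnotation.empty(200)
    ann.is_open[:] = True
    ann.is_open[50:150] = False
    params = SimulationParameters(
        n_proteins=0, n_extruders=0, k_sw=0.0, t_equil=300.0,
        t_sample=1500.0, n_frames=100, seed=9)
    return hh.run_simulation(ann, params)


@pytest.fixture(scope="session")
def rouse_result():
    """Homogeneous-chain subdiffusion benchmark (single trajectory)."""
    return hh.measure_rouse_exponent(n_beads=200, n_traj=1, seed=5)
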