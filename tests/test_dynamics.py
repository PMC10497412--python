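"""Force field correctness and stochastic dynamics statistics."""

import numpy as np
import pytest

import hiphopsim as hh
from hiphopsim.dynamics_engine import InstabilityError
from hiphopsim.model_builder import Extruder, SystemState


def random_test_system(seed=0, n_beads=12, n_prot=4, box=8.0):
    """Small mixed system exercising every force term."""
    rng = np.random.default_rng(seed)
    ann = hh.BeadAnnotation.empty(n_beads)
    ann.is_open[n_beads // 3: 2 * n_beads // 3] = True
    ann.is_binding_site[[1, n_beads - 2]] = True
    # near-straight chain with jitter, so all bonded terms are strained
    pos = np.cumsum(
        np.tile([0.95, 0.1, 0.0], (n_beads, 1))
        + rng.normal(0, 0.05, (n_beads, 3)), axis=0)
    prot = rng.uniform(0, box, (n_prot, 3))
    prot[0] = pos[1] + [0.0, 1.2, 0.0]  # protein near a binding site
    state = SystemState(
        bead_positions=pos, protein_positions=prot,
        protein_binding_mode=np.array([True, True, False, True]),
        box=box,
        extruders=[Extruder(2, n_beads - 3)],
        fixed_bonds=np.array([[1, n_beads - 2]]),
    )
    return state, ann


class TestForces:
    def test_bonded_pair_at_rest_length_zero_force(self):
        ann = hh.BeadAnnotation.empty(2)
        state = SystemState(
            bead_positions=[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
            protein_positions=np.zeros((0, 3)),
            protein_binding_mode=np.zeros(0, bool), box=20.0)
        fb, _fp = hh.compute_forces(state, ann)
        assert np.abs(fb).max() < 1e-12

    def test_internal_forces_sum_to_zero(self):
        state, ann = random_test_system(seed=3)
        fb, fp = hh.compute_forces(state, ann)
        total = fb.sum(axis=0) + fp.sum(axis=0)
        assert np.abs(total).max() < 1e-9

    def test_forces_match_finite_difference_of_energy(self):
        """Analytic forces vs central differences, 1e-6 relative."""
        state, ann = random_test_system(seed=4)
        fb, fp = hh.compute_forces(state, ann)
        analytic = np.vstack([fb, fp])
        h = 1e-6
        scale = max(1.0, np.abs(analytic).max())
        for which in ("bead", "protein"):
            arr = (state.bead_positions if which == "bead"
                   else state.protein_positions)
            for i in range(arr.shape[0]):
                for d in range(3):
                    orig = arr[i, d]
                    arr[i, d] = orig + h
                    up = hh.potential_energy(state, ann)
                    arr[i, d] = orig - h
                    dn = hh.potential_energy(state, ann)
                    arr[i, d] = orig
                    fd = -(up - dn) / (2 * h)
                    row = i if which == "bead" else state.n_beads + i
                    assert analytic[row, d] == pytest.approx(
                        fd, abs=2e-6 * scale)

    def test_nonfinite_coordinates_rejected(self):
        state, ann = random_test_system()
        state.bead_positions[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            hh.compute_forces(state, ann)

    def test_instability_error_advises_smaller_dt(self):
        state, ann = random_test_system(seed=5)
        # overlapping particles with a huge step blow up immediately
        state.protein_positions[1] = state.bead_positions[0] + 1e-4
        params = hh.SimulationParameters(n_proteins=4, dt=0.05)
        with pytest.raises(InstabilityError, match="dt"):
            hh.advance(state, ann, params, hh.ForceField(), 10, 1)


class TestLangevin:
    def test_rest_at_zero_temperature_and_zero_force(self):
        ann = hh.BeadAnnotation.empty(1)
        state = SystemState(
            bead_positions=[[5.0, 5.0, 5.0]],
            protein_positions=np.zeros((0, 3)),
            protein_binding_mode=np.zeros(0, bool), box=10.0)
        params = hh.SimulationParameters(n_proteins=0, temperature=0.0)
        hh.advance(state, ann, params, hh.ForceField(), 100, 0)
        assert state.bead_positions.ravel() == pytest.approx(
            [5.0, 5.0, 5.0])


class TestSwitching:
    def _state(self, n):
        return SystemState(
            bead_positions=[[0.0, 0.0, 0.0]],
            protein_positions=np.zeros((n, 3)),
            protein_binding_mode=np.zeros(n, bool), box=10.0)

    def test_zero_rate_never_flips(self):
        state = self._state(100)
        rng = np.random.default_rng(0)
        for _ in range(100):
            hh.switch_proteins(state, 0.0, 10.0, rng)
        assert not state.protein_binding_mode.any()

    def test_poisson_flip_counts(self):
        """k_sw=1e-3/tau over 1e4 tau -> ~10 flips per protein."""
        n, k_sw, block = 1000, 1e-3, 10.0
        state = self._state(n)
        rng = np.random.default_rng(42)
        flips = np.zeros(n)
        for _ in range(1000):  # 1e4 tau total
            before = state.protein_binding_mode.copy()
            hh.switch_proteins(state, k_sw, block, rng)
            flips += before != state.protein_binding_mode
        expected = 1000 * (1 - np.exp(-k_sw * block))  # ~9.95
        se = np.sqrt(expected) / np.sqrt(n)
        assert abs(flips.mean() - expected) < 3 * se
        assert flips.mean() == pytest.approx(10.0, abs=0.5)

    def test_mode_autocorrelation_time(self):
        """Two-state symmetric switching: correlation time 1/(2 k_sw)."""
        n, k_sw = 600, 0.02
        state = self._state(n)
        state.protein_binding_mode[: n // 2] = True
        rng = np.random.default_rng(7)
        modes = []
        for _ in range(1500):
            hh.switch_proteins(state, k_sw, 1.0, rng)
            modes.append(state.protein_binding_mode.copy())
        s = 2.0 * np.array(modes) - 1.0  # spins +-1
        lag = 25  # = 1/(2 k_sw)
        rho = np.mean(s[lag:] * s[:-lag])
        tau_fit = -lag / np.log(rho)
        assert tau_fit == pytest.approx(1.0 / (2 * k_sw), rel=0.1)


class TestExtruders:
    def _kinetic_state(self, n_beads):
        return SystemState(
            bead_positions=np.zeros((n_beads, 3)),
            protein_positions=np.zeros((0, 3)),
            protein_binding_mode=np.zeros(0, bool), box=100.0)

    def test_side_stepping_rate(self):
        """k_ex=2 bp/tau at 1 kbp/bead -> mean waiting 1000 tau per side."""
        # sparse extruders on a long chain: anchor collisions negligible
        ann = hh.BeadAnnotation.empty(20_000)
        state = self._kinetic_state(20_000)
        params = hh.SimulationParameters(
            n_proteins=0, n_extruders=5, k_off=0.0, k_ex=2.0)
        rng = np.random.default_rng(5)
        hh.step_extruders(state, ann, params, rng, 0.0)  # load
        moves, T, block = 0, 50_000.0, 10.0
        spans0 = [(e.left_anchor, e.right_anchor) for e in state.extruders]
        for _ in range(int(T / block)):
            hh.step_extruders(state, ann, params, rng, block)
        spans1 = [(e.left_anchor, e.right_anchor) for e in state.extruders]
        for (l0, r0), (l1, r1) in zip(spans0, spans1):
            moves += (l0 - l1) + (r1 - r0)
        mean_wait = 2 * len(spans0) * T / moves  # per side
        assert mean_wait == pytest.approx(1000.0, rel=0.1)

    def test_convergent_pair_traps_extruder(self):
        """stall_weight=1 convergent pair: anchors end at the pair and stay."""
        ann = hh.BeadAnnotation.empty(40)
        ann.ctcf[0], ann.ctcf[39] = 1, 2  # forward ... reverse (convergent)
        ann.stall_weight[[0, 39]] = 1.0
        state = self._kinetic_state(40)
        params = hh.SimulationParameters(
            n_proteins=0, n_extruders=1, k_off=0.0, k_ex=200.0)
        rng = np.random.default_rng(11)
        for _ in range(600):
            hh.step_extruders(state, ann, params, rng, 10.0)
        (e,) = state.extruders
        assert (e.left_anchor, e.right_anchor) == (0, 39)
        assert e.left_stalled and e.right_stalled
        for _ in range(50):
            hh.step_extruders(state, ann, params, rng, 10.0)
        assert (e.left_anchor, e.right_anchor) == (0, 39)


class TestRunSimulation:
    def test_tiny_run_frame_schedule(self):
        ann = hh.BeadAnnotation.empty(30)
        params = hh.SimulationParameters(
            n_proteins=5, n_extruders=1, t_equil=10.0, t_sample=40.0,
            n_frames=4, seed=2)
        traj = hh.run_simulation(ann, params)
        assert traj.n_frames == 4
        assert np.all(np.diff(traj.times) > 0)
        assert np.allclose(np.diff(traj.times), params.frame_interval)

    def test_seeded_reproducibility(self):
        ann = hh.BeadAnnotation.empty(30)
        params = hh.SimulationParameters(
            n_proteins=5, t_equil=5.0, t_sample=20.0, n_frames=3, seed=8)
        t1 = hh.run_simulation(ann, params)
        t2 = hh.run_simulation(ann, params)
        assert (t1.bead_positions == t2.bead_positions).all()
        assert (t1.protein_mode == t2.protein_mode).all()

    def test_chain_connectivity_throughout(self, bridged_traj):
        d = np.diff(bridged_traj.bead_positions.astype(float), axis=1)
        bond_lengths = np.sqrt((d ** 2).sum(-1))
        assert bond_lengths.max() < 1.5

    def test_extruder_count_constant_after_loading(self, bridged_traj):
        active = (bridged_traj.extruder_anchors[:, :, 0] >= 0).sum(axis=1)
        assert (active == 2).all()

    def test_steady_state_radius_of_gyration(self, bridged_traj):
        pos = bridged_traj.bead_positions.astype(float)
        com = pos.mean(axis=1, keepdims=True)
        rg = np.sqrt(((pos - com) ** 2).sum(-1).mean(axis=1))
        half = len(rg) // 2
        assert abs(rg[:half].mean() - rg[half:].mean()) \
            < 0.1 * rg[:half].mean()

    def test_bridging_induced_clustering(self, bridged_traj):
        """Bound proteins cluster more than uniformly placed controls."""
        observed = hh.mean_largest_cluster(bridged_traj, linkage=2.0)
        rng = np.random.default_rng(0)
        controls = []
        for f in range(0, bridged_traj.n_frames, 10):
            n = int(bridged_traj.protein_mode[f].sum())
            pts = rng.uniform(0, bridged_traj.box, (n, 3))
            sizes = hh.protein_cluster_sizes(pts, bridged_traj.box, 2.0)
            controls.append(sizes.max() if len(sizes) else 0)
        assert observed > np.mean(controls)

    def test_trajectory_save_load_round_trip(self, tmp_path, bridged_traj):
        path = tmp_path / "traj.h5"
        bridged_traj.save(path)
        back = hh.Trajectory.load(path)
        assert (back.bead_positions == bridged_traj.bead_positions).all()
        assert (back.extruder_anchors == bridged_traj.extruder_anchors).all()
        assert back.params == bridged_traj.params
        assert back.annotation.content_hash() \
            == bridged_traj.annotation.content_hash()
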