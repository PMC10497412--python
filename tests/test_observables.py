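"""Observable definitions: geometric oracles and simulation sign tests."""

import numpy as np
import pandas as pd
import pytest

import hiphopsim as hh
from hiphopsim.observables import (MSDCurve, ProbeRegion, contact_kinetics,
                                   fish_summary, probe_size_sweep, wrap_coords)

from conftest import make_synthetic_trajectory


def straight_chain_traj(n_beads=50, n_frames=3, spacing=1.0, box=1000.0):
    """Frozen straight chain along x at fixed spacing."""
    ann = hh.BeadAnnotation.empty(n_beads)
    pos = np.zeros((n_frames, n_beads, 3))
    pos[:, :, 0] = np.arange(n_beads) * spacing + 100.0
    pos[:, :, 1] = 100.0
    pos[:, :, 2] = 100.0
    return make_synthetic_trajectory(pos, ann, box=box)


class TestComputeMsd:
    def test_frozen_trajectory_msd_zero(self):
        traj = straight_chain_traj(n_frames=6)
        curve = hh.compute_msd(traj, 10)
        assert curve.msd_sigma2 == pytest.approx(np.zeros(5), abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        ann = hh.BeadAnnotation.empty(4)
        pos = rng.normal(0, 5, (20, 4, 3))
        traj = make_synthetic_trajectory(pos, ann)
        stored = traj.bead_positions.astype(float)  # float32 frame storage
        curve = hh.compute_msd(traj, 2)
        for k, got in zip(range(1, 20), curve.msd_sigma2):
            brute = np.mean([np.sum((stored[t + k, 2] - stored[t, 2]) ** 2)
                             for t in range(20 - k)])
            assert got == pytest.approx(brute, rel=1e-12)

    def test_random_walk_expectation(self):
        """Random walk with per-frame step variance s^2: MSD(k) = 3 s^2 k."""
        rng = np.random.default_rng(3)
        s = 0.5
        steps = rng.normal(0, s, (4000, 1, 3))
        pos = np.cumsum(steps, axis=0)
        traj = make_synthetic_trajectory(pos, hh.BeadAnnotation.empty(1))
        curve = hh.compute_msd(traj, 0, lag_frames=[1, 2, 5, 10])
        expected = 3 * s ** 2 * np.array([1, 2, 5, 10])
        assert curve.msd_sigma2 == pytest.approx(expected, rel=0.1)

    def test_probe_com_msd_below_mean_bead_msd(self, bridged_traj):
        probe = ProbeRegion("p", 100, 140)
        lags = [1, 5, 20, 60]
        com = hh.compute_msd(bridged_traj, probe, use_com=True,
                             lag_frames=lags)
        beads = hh.compute_msd(bridged_traj, probe, use_com=False,
                               lag_frames=lags)
        assert (com.msd_sigma2 <= beads.msd_sigma2 + 1e-9).all()


class TestFitSubdiffusion:
    def test_exact_power_laws(self):
        lags = np.logspace(0, 3, 30)
        half = MSDCurve(lags, lags ** 0.5, np.ones(30))
        lin = MSDCurve(lags, 2.5 * lags, np.ones(30))
        assert hh.fit_subdiffusion_exponent(half, (1, 1e3)) \
            == pytest.approx(0.5, abs=1e-12)
        assert hh.fit_subdiffusion_exponent(lin, (1, 1e3)) \
            == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_msd_rejected(self):
        lags = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        curve = MSDCurve(lags, np.array([1.0, 2.0, 0.0, 3.0, 4.0]),
                         np.ones(5))
        with pytest.raises(ValueError, match="nonpositive"):
            hh.fit_subdiffusion_exponent(curve, (1, 16))


class TestMobility:
    def test_lag_beyond_span_errors(self, bridged_traj):
        with pytest.raises(ValueError, match="exceeds"):
            hh.mobility_profile(bridged_traj, lag_tau=1e7)

    def test_homogeneous_chain_profile_flat(self):
        # interior of a homogeneous chain: no positional structure
        ann = hh.BeadAnnotation.empty(120)
        ann.is_open[:] = True
        params = hh.SimulationParameters(
            n_proteins=0, n_extruders=0, k_sw=0.0, t_equil=200.0,
            t_sample=1000.0, n_frames=100, seed=31)
        traj = hh.run_simulation(ann, params)
        m = hh.mobility_profile(traj, lag_tau=100.0).values[30:90]
        assert np.std(m) / np.mean(m) < 0.15

    def test_crumpled_block_less_mobile(self, hetero_chain_traj):
        """Compact (crumpled, stiff) chromatin moves less than open fiber."""
        m = hh.mobility_profile(hetero_chain_traj, lag_tau=150.0).values
        ann = hetero_chain_traj.annotation
        inside = np.median(m[~ann.is_open])
        outside = np.median(m[ann.is_open])
        assert inside < outside

    def test_mobility_lag_mapping(self, bridged_traj):
        track = hh.mobility_profile(bridged_traj, lag_tau=200.0)
        assert track.params["lag_s"] == pytest.approx(200 * 2.07e-3, rel=1e-9)


class TestLocalDensity:
    def test_isolated_bead_zero(self):
        traj = straight_chain_traj(n_beads=1)
        assert hh.local_density(traj).values == pytest.approx([0.0])

    def test_straight_chain_interior_counts_six(self):
        traj = straight_chain_traj(n_beads=50)
        rho = hh.local_density(traj, radius=3.0).values
        assert rho[10:40] == pytest.approx(np.full(30, 6.0))

    def test_radius_must_fit_in_box(self, bridged_traj):
        with pytest.raises(ValueError, match="half the box"):
            hh.local_density(bridged_traj, radius=bridged_traj.box)

    def test_default_radius_is_53_nm(self, bridged_traj):
        track = hh.local_density(bridged_traj)
        assert round(track.params["radius_nm"]) == 53

    def test_matches_brute_force_minimum_image(self):
        """KD-tree counting agrees with an all-pairs oracle (<=50 particles)."""
        rng = np.random.default_rng(8)
        box = 6.0
        ann = hh.BeadAnnotation.empty(30)
        pos = rng.uniform(-10, 20, (2, 30, 3))
        prot = rng.uniform(-10, 20, (2, 10, 3))
        traj = make_synthetic_trajectory(
            pos, ann, box=box, protein_positions=prot.astype(np.float32),
            protein_mode=np.zeros((2, 10), bool))
        got = hh.local_density(traj, radius=1.3).values
        expect = np.zeros(30)
        for f in range(2):
            pts = np.vstack([pos[f], prot[f]])
            for i in range(30):
                d = pts - pts[i]
                d -= box * np.round(d / box)
                r = np.sqrt((d ** 2).sum(1))
                expect[i] += (r < 1.3).sum() - 1
        assert got == pytest.approx(expect / 2)


class TestExtruderOccupancy:
    def test_no_extruders_all_zero(self):
        traj = straight_chain_traj()
        assert hh.extruder_occupancy(traj).values == pytest.approx(
            np.zeros(50))

    def test_permanent_anchor_vicinity_definition(self):
        ann = hh.BeadAnnotation.empty(30)
        pos = np.zeros((4, 30, 3))
        anchors = np.full((4, 1, 2), -1, dtype=np.int32)
        anchors[:, 0] = [10, 20]
        traj = make_synthetic_trajectory(pos, ann, anchors=anchors)
        phi = hh.extruder_occupancy(traj).values
        expected = np.zeros(30)
        expected[[9, 10, 11, 19, 20, 21]] = 1.0
        assert phi == pytest.approx(expected)

    def test_high_occupancy_ctcf_pair_gives_phi_maxima(self, toy_locus,
                                                       desk_params):
        """phi_e peaks at a fully occupied convergent anchor pair."""
        _tracks, ann = toy_locus
        ann2 = ann.copy()
        ann2.stall_weight[ann2.ctcf != 0] = 1.0
        state = hh.SystemState(
            bead_positions=np.zeros((ann2.n_beads, 3)),
            protein_positions=np.zeros((0, 3)),
            protein_binding_mode=np.zeros(0, bool), box=50.0)
        params = desk_params.replace(n_proteins=0, n_extruders=3,
                                     k_off=1e-4, k_ex=50.0)
        rng = np.random.default_rng(1)
        anchors = np.full((400, 3, 2), -1, dtype=np.int32)
        for f in range(400):
            for _ in range(5):
                hh.step_extruders(state, ann2, params, rng, 10.0)
            for k, e in enumerate(state.extruders[:3]):
                anchors[f, k] = (e.left_anchor, e.right_anchor)
        pos = np.zeros((400, ann2.n_beads, 3))
        traj = make_synthetic_trajectory(pos, ann2, anchors=anchors)
        phi = hh.extruder_occupancy(traj).values
        ctcf_beads = np.nonzero(ann2.ctcf != 0)[0]
        other = np.nonzero(ann2.ctcf == 0)[0]
        assert phi[ctcf_beads].mean() > phi[other].mean()
        assert phi.max() == phi[np.concatenate(
            [ctcf_beads - 1, ctcf_beads, ctcf_beads + 1])].max()


class TestLocalness:
    def test_straight_chain_all_contacts_local(self):
        n_frames = 3
        traj = straight_chain_traj(n_beads=50, n_frames=n_frames)
        track = hh.localness(traj)
        L = track.values
        # every contact within +-3 beads (3 kbp << 100 kbp): far = 0,
        # so L = pooled near contacts / pseudocount
        assert np.nanmin(L) > 0
        assert L[10] == pytest.approx(6.0 * n_frames)
        assert np.isfinite(track.params["log2_values"][10])

    def test_threshold_in_nm(self, bridged_traj):
        track = hh.localness(bridged_traj)
        assert round(track.params["contact_threshold_nm"]) == 62

    def test_binding_sites_less_local(self, bridged_traj):
        """Bridged binding sites trade local for distal contacts."""
        ann = bridged_traj.annotation
        L = hh.localness(bridged_traj).values
        unmarked = ~ann.is_binding_site & ~ann.is_open
        assert np.nanmedian(L[ann.is_binding_site]) \
            < np.nanmedian(L[unmarked])


class TestCaptureC:
    def test_frozen_straight_chain_indicator_profile(self):
        traj = straight_chain_traj(n_beads=50)
        (profile,) = hh.simulated_capturec(traj, [25]).values()
        d = np.abs(np.arange(50) - 25)
        expected = (d < 3.5).astype(float)
        mask = ~np.isnan(profile)
        assert profile[mask] == pytest.approx(expected[mask])
        assert np.isnan(profile[24:27]).all()   # viewpoint masked
        assert np.nanmax(profile) <= 1.0 and np.nanmin(profile) >= 0.0
        left = profile[:24][::-1]
        right = profile[27:]
        n = min(len(left), len(right))
        assert left[:n] == pytest.approx(right[:n])  # symmetric

    def test_viewpoint_in_spacer_rejected(self, toy_locus):
        _tracks, ann = toy_locus
        cat = hh.concatemerize([ann], [2], spacer_beads=50, order_seed=0)
        spacer = np.nonzero(cat.copy_id == 0)[0][0]
        pos = np.zeros((2, cat.n_beads, 3))
        traj = make_synthetic_trajectory(pos, cat)
        with pytest.raises(ValueError, match="spacer"):
            hh.simulated_capturec(traj, [int(spacer)])


class TestFish:
    def test_probe_with_itself_zero_distance(self):
        traj = straight_chain_traj()
        p = ProbeRegion("a", 10, 20)
        q = ProbeRegion("a2", 10, 20)
        df = hh.simulated_fish(traj, [p, q])
        assert df["separation_nm"].abs().max() < 1e-9

    def test_frozen_chain_separation_in_nm(self):
        traj = straight_chain_traj()
        df = hh.simulated_fish(traj, [ProbeRegion("a", 0, 10),
                                      ProbeRegion("b", 20, 30)])
        # COM separation is exactly 20 beads * 1 sigma * 17.6 nm
        assert df["separation_nm"].to_numpy() == pytest.approx(
            np.full(traj.n_frames, 20 * 17.6))
        summary = fish_summary(df)
        assert summary["median"].iloc[0] == pytest.approx(352.0)

    def test_observation_bookkeeping_across_copies(self, toy_locus):
        _tracks, ann = toy_locus
        cat = hh.concatemerize([ann], [3], spacer_beads=20, order_seed=0)
        pos = np.random.default_rng(0).normal(0, 1, (5, cat.n_beads, 3))
        traj = make_synthetic_trajectory(pos, cat)
        probes = [ProbeRegion("a", 10, 20), ProbeRegion("b", 100, 110)]
        pooled = hh.simulated_fish(traj, probes, all_copies=True)
        assert len(pooled) == 5 * 3  # frames x equivalent copies


class TestContactKinetics:
    def test_square_wave_durations(self):
        ann = hh.BeadAnnotation.empty(20)
        pos = np.zeros((12, 20, 3))
        # alternate the second probe every 3 frames between near and far
        for f in range(12):
            offset = 1.0 if (f // 3) % 2 == 0 else 50.0
            pos[f, 10:, 0] = offset
        traj = make_synthetic_trajectory(pos, ann)
        res = contact_kinetics(traj, (ProbeRegion("a", 0, 10),
                                      ProbeRegion("b", 10, 20)),
                               contact_threshold=3.5)
        dt = traj.frame_interval_s
        assert res.contact_durations_s == pytest.approx([3 * dt, 3 * dt])
        assert res.gap_durations_s == pytest.approx([3 * dt, 3 * dt])

    def test_frozen_contact_single_censored_episode(self):
        traj = straight_chain_traj(n_frames=8)
        res = contact_kinetics(traj, (ProbeRegion("a", 0, 3),
                                      ProbeRegion("b", 3, 6)))
        assert len(res.contact_durations_s) == 1
        assert len(res.gap_durations_s) == 0
        assert res.first_censored and res.last_censored


class TestProbeSizeSweep:
    def test_bead_size_reduces_to_per_bead_stats(self, bridged_traj):
        df = probe_size_sweep(bridged_traj, [1000], lag_tau=200.0)
        m = hh.mobility_profile(bridged_traj, lag_tau=200.0).values
        assert df["mean_mobility_sigma2"].iloc[0] == pytest.approx(
            m.mean(), rel=1e-6)

    def test_mean_and_sd_decrease_with_probe_size(self, bridged_traj):
        df = probe_size_sweep(bridged_traj, [1000, 10_000, 50_000],
                              lag_tau=200.0)
        means = df["mean_mobility_sigma2"].to_numpy()
        sds = df["sd_mobility_sigma2"].to_numpy()
        assert means[0] > means[-1]
        assert sds[0] > sds[-1]
        assert (np.diff(means) <= 0.05 * means[0]).all()  # monotone w/ noise

    def test_window_larger_than_copy_rejected(self, bridged_traj):
        with pytest.raises(ValueError, match="exceeds copy"):
            probe_size_sweep(bridged_traj, [10_000_000], lag_tau=200.0)


class TestCorrelations:
    def test_mobility_density_negative_correlation(self, bridged_traj):
        """Dense (clustered, bridged) chromatin is slow: r < 0."""
        m = hh.mobility_profile(bridged_traj, lag_tau=200.0).values
        rho = hh.local_density(bridged_traj).values
        r = np.corrcoef(m, rho)[0, 1]
        assert r < 0

    def test_windowed_mobility_vs_open_coverage_positive(self,
                                                         hetero_chain_traj):
        """20-kbp windowed mobility tracks open-chromatin coverage.

        Measured on the protein-free heteromorphic chain, which isolates
        the fiber-structure mechanism (flexible open fiber vs crumpled,
        stiff compact fiber); with strong bridging the collapse of the
        peak-bearing open domains overrides this contrast at desk scale.
        """
        ann = hetero_chain_traj.annotation
        m = hh.mobility_profile(hetero_chain_traj, lag_tau=150.0).values
        w = 20
        wins = np.arange(0, ann.n_beads - w + 1, w)
        wm = np.array([m[s:s + w].mean() for s in wins])
        cov = np.array([ann.is_open[s:s + w].mean() for s in wins])
        r = np.corrcoef(wm, cov)[0, 1]
        assert r > 0

    def test_bedgraph_round_trip_through_reader(self, tmp_path, bridged_traj):
        track = hh.local_density(bridged_traj)
        path = tmp_path / "rho.bedgraph"
        track.to_bedgraph(path, bridged_traj.annotation)
        from hiphopsim.annotation_io import read_bedgraph
        ivs, vals = read_bedgraph(path)
        rebuilt = np.empty(bridged_traj.n_beads)
        for iv, v in zip(ivs, vals):
            rebuilt[iv.start // 1000:iv.end // 1000] = v
        assert rebuilt == pytest.approx(track.values)
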