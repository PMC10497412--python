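"""Reference physics benchmarks run entirely inside the package.

These are small, self-contained protocols with known expected outcomes
(polymer scaling laws, Langevin statistics) used to validate the engine.
"""

from __future__ import annotations

import numpy as np

from .annotation_io import BeadAnnotation
from .dynamics_engine import run_simulation
from .model_builder import SimulationParameters
from .observables import MSDCurve, fit_subdiffusion_exponent

__all__ = ["rouse_time", "measure_rouse_exponent"]


def rouse_time(n_beads: int, k_entropic: float = 3.0, friction: float = 1.0
               ) -> float:
    """Slowest-mode relaxation time of an ideal discrete Rouse chain (tau).

    Long-wavelength modes of a rest-length-1 bead-spring chain are
    entropic with effective spring constant 3 kT/b^2 regardless of the
    microscopic bond stiffness.
    """
    return friction / (4.0 * k_entropic * np.sin(np.pi / (2 * n_beads)) ** 2)


def measure_rouse_exponent(n_beads: int = 200, n_traj: int = 3, seed: int = 0,
                           t_equil: float = 2000.0, t_sample: float = 1e4,
                           n_frames: int = 1000) -> dict:
    """Subdiffusion exponent of a homogeneous chain's internal motion.

    Protocol: simulate ``n_traj`` independent homogeneous chains (no
    proteins, extruders, bending or crumpling) with the Langevin engine;
    compute the interior-bead MSD in each chain's center-of-mass frame
    (the polymer g2, which isolates internal Rouse-mode motion from the
    finite chain's center-of-mass diffusion); pool the curves and fit the
    log-log slope over lags in [30 tau, tau_R / 2], i.e. well above the
    segmental time and below the Rouse time where the approach to the
    internal plateau would bend the fit.

    Returns a dict with the fitted ``alpha``, the pooled curve and the
    fit window.
    """
    ann = BeadAnnotation.empty(n_beads)
    ann.is_open[:] = True  # open chromatin: no bending, no crumpling springs
    lo, hi = n_beads // 4, n_beads - n_beads // 4  # interior half
    seeds = np.random.SeedSequence(seed).generate_state(n_traj) % (2 ** 31)
    curves = []
    lags = None
    frame_dt = None
    for s in seeds:
        params = SimulationParameters(
            n_proteins=0, n_extruders=0, k_sw=0.0,
            t_equil=t_equil, t_sample=t_sample, n_frames=n_frames,
            seed=int(s))
        traj = run_simulation(ann, params)
        pos = traj.bead_positions.astype(float)
        rel = pos - pos.mean(axis=1, keepdims=True)  # center-of-mass frame
        if lags is None:
            frame_dt = traj.frame_interval_tau
            lags = sorted(set(np.round(np.logspace(
                0, np.log10(n_frames - 1), 45)).astype(int)))
        msd = [float(np.mean(
            ((rel[k:, lo:hi] - rel[:-k, lo:hi]) ** 2).sum(axis=-1)))
            for k in lags]
        curves.append(msd)
    lag_tau = np.asarray(lags, dtype=float) * frame_dt
    pooled = MSDCurve(lag_tau, np.mean(curves, axis=0),
                      np.full(len(lags), n_traj))
    t_rouse = rouse_time(n_beads)
    window = (30.0, t_rouse / 2.0)
    alpha = fit_subdiffusion_exponent(pooled, window)
    return {"alpha": alpha, "curve": pooled, "fit_window_tau": window,
            "rouse_time_tau": t_rouse, "n_traj": n_traj}
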