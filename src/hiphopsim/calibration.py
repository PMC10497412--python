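"""Mapping between simulation units (sigma, tau) and physical units (nm, s).

The simulation is formulated in reduced units: lengths in multiples of the
bead diameter ``sigma`` and times in multiples of the Langevin time unit
``tau``.  Two independent fits pin these to physical units:

* ``sigma`` — a grid/golden-section search for the length scale that
  minimizes the mean two-sample Kolmogorov–Smirnov statistic between
  simulated and experimental FISH probe-separation distributions
  (nine pairings: three probe pairs in each of three cell states).
* ``tau`` — a least-squares fit of the time-axis scale aligning the
  bead-averaged simulated MSD curve with a reference motion-tracking
  MSD curve, after the length mapping has been fixed.

When no data are supplied the module ships the calibrated defaults
sigma = 17.6 nm and tau = 2.07e-3 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "UnitMapping",
    "DEFAULT_MAPPING",
    "calibrate_length",
    "calibrate_time",
    "to_physical",
    "from_physical",
]

#: Calibrated defaults for the unit mapping.
DEFAULT_SIGMA_NM = 17.6
DEFAULT_TAU_S = 2.07e-3


@dataclass(frozen=True)
class UnitMapping:
    """Length/time unit mapping with provenance.

    Parameters
    ----------
    sigma_nm:
        Physical size of one simulation length unit (bead diameter), nm.
    tau_s:
        Physical duration of one simulation time unit, seconds.
    provenance:
        ``"default_paper"`` for the shipped calibration constants,
        ``"fitted"`` when produced by :func:`calibrate_length` /
        :func:`calibrate_time`.
    """

    sigma_nm: float = DEFAULT_SIGMA_NM
    tau_s: float = DEFAULT_TAU_S
    provenance: str = "default_paper"

    def __post_init__(self) -> None:
        if not (self.sigma_nm > 0 and self.tau_s > 0):
            raise ValueError("sigma_nm and tau_s must both be positive")

    # -- convenience converters -------------------------------------------
    def length_to_nm(self, value_sigma):
        return np.asarray(value_sigma, dtype=float) * self.sigma_nm

    def time_to_s(self, value_tau):
        return np.asarray(value_tau, dtype=float) * self.tau_s

    def rate_to_per_s(self, value_per_tau):
        return np.asarray(value_per_tau, dtype=float) / self.tau_s

    def as_dict(self) -> dict:
        return {
            "sigma_nm": self.sigma_nm,
            "tau_s": self.tau_s,
            "provenance": self.provenance,
        }


DEFAULT_MAPPING = UnitMapping()

#: unit keys accepted by :func:`to_physical` -> (attribute, operation)
_UNIT_OPS = {
    "length_sigma": ("sigma_nm", "mul"),  # sigma -> nm
    "time_tau": ("tau_s", "mul"),  # tau -> s
    "rate_per_tau": ("tau_s", "div"),  # 1/tau -> 1/s
}


def to_physical(value, unit: str, mapping: UnitMapping = DEFAULT_MAPPING):
    """Convert a reduced-unit quantity to physical units.

    ``unit`` is one of ``"length_sigma"`` (-> nm), ``"time_tau"`` (-> s) or
    ``"rate_per_tau"`` (-> 1/s).  Pure arithmetic; no rounding.
    """
    try:
        attr, op = _UNIT_OPS[unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_OPS)}")
    factor = getattr(mapping, attr)
    value = np.asarray(value, dtype=float)
    out = value * factor if op == "mul" else value / factor
    return float(out) if out.ndim == 0 else out


def from_physical(value, unit: str, mapping: UnitMapping = DEFAULT_MAPPING):
    """Inverse of :func:`to_physical` (nm -> sigma, s -> tau, 1/s -> 1/tau)."""
    attr, op = _UNIT_OPS[unit]
    factor = getattr(mapping, attr)
    value = np.asarray(value, dtype=float)
    out = value / factor if op == "mul" else value * factor
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# length calibration: KS matching of probe-separation distributions
# ---------------------------------------------------------------------------

def _mean_ks(scale: float, sim_sets, exp_sets) -> float:
    ks = [
        stats.ks_2samp(np.asarray(s) * scale, np.asarray(e)).statistic
        for s, e in zip(sim_sets, exp_sets)
    ]
    return float(np.mean(ks))


def calibrate_length(sim_distance_sets, exp_distance_sets, scale_grid=None) -> float:
    """Fit sigma_nm by minimizing the mean two-sample KS statistic.

    Parameters
    ----------
    sim_distance_sets:
        Sequence of 1-D arrays of simulated separations, in sigma units.
    exp_distance_sets:
        Matched sequence of experimental separations, in nm.
    scale_grid:
        Candidate nm-per-sigma scales.  Default: 200 log-spaced values
        bracketing the ratio of pooled medians by a factor of 10 either way.

    Returns
    -------
    float
        The nm-per-sigma scale minimizing the mean KS statistic, refined
        by bounded golden-section search around the best grid point.
    """
    sim_sets = [np.asarray(s, dtype=float) for s in sim_distance_sets]
    exp_sets = [np.asarray(e, dtype=float) for e in exp_distance_sets]
    if len(sim_sets) != len(exp_sets) or not sim_sets:
        raise ValueError("need equal, non-empty collections of distance sets")
    for s, e in zip(sim_sets, exp_sets):
        if s.size == 0 or e.size == 0:
            raise ValueError("empty distance set")

    if scale_grid is None:
        med_sim = np.median(np.concatenate(sim_sets))
        med_exp = np.median(np.concatenate(exp_sets))
        center = med_exp / med_sim if med_sim > 0 else 1.0
        scale_grid = np.logspace(np.log10(center) - 1, np.log10(center) + 1, 200)
    scale_grid = np.asarray(scale_grid, dtype=float)
    if np.any(scale_grid <= 0):
        raise ValueError("scale grid must be positive")

    objective = [_mean_ks(s, sim_sets, exp_sets) for s in scale_grid]
    best = int(np.argmin(objective))
    lo = scale_grid[max(best - 1, 0)]
    hi = scale_grid[min(best + 1, len(scale_grid) - 1)]
    if lo == hi:
        return float(scale_grid[best])
    res = optimize.minimize_scalar(
        _mean_ks, args=(sim_sets, exp_sets), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4 * scale_grid[best]},
    )
    # The KS objective is piecewise constant; keep whichever point is better.
    if res.fun <= objective[best]:
        return float(res.x)
    return float(scale_grid[best])


# ---------------------------------------------------------------------------
# time calibration: aligning MSD curves
# ---------------------------------------------------------------------------

def calibrate_time(sim_lags_tau, sim_msd_sigma2, ref_lags_s, ref_msd_um2,
                   sigma_nm: float = DEFAULT_SIGMA_NM) -> float:
    """Fit tau_s by aligning a simulated MSD curve to a reference curve.

    The simulated curve (lags in tau, MSD in sigma^2) is converted to um^2
    using ``sigma_nm``; the time-axis scale s (seconds per tau) is then fit
    by least squares in log-log space: the scaled simulated curve is
    interpolated onto the reference lags and the squared log-difference is
    minimized over s.
    """
    lt = np.asarray(sim_lags_tau, dtype=float)
    ms = np.asarray(sim_msd_sigma2, dtype=float)
    lr = np.asarray(ref_lags_s, dtype=float)
    mr = np.asarray(ref_msd_um2, dtype=float)
    if np.any(lt <= 0) or np.any(ms <= 0) or np.any(lr <= 0) or np.any(mr <= 0):
        raise ValueError("MSD curves must be strictly positive for log-space fitting")
    sim_um2 = ms * (sigma_nm / 1000.0) ** 2

    def cost(log_s: float) -> float:
        s = np.exp(log_s)
        t_scaled = lt * s
        if t_scaled[-1] < lr[0] or t_scaled[0] > lr[-1]:
            return np.inf
        inside = (lr >= t_scaled[0]) & (lr <= t_scaled[-1])
        if inside.sum() < 2:
            return np.inf
        interp = np.interp(np.log(lr[inside]), np.log(t_scaled), np.log(sim_um2))
        return float(np.mean((interp - np.log(mr[inside])) ** 2))

    # coarse bracket over 8 decades around unity scaling of the medians
    center = np.median(lr) / np.median(lt)
    grid = np.log(center) + np.linspace(-4, 4, 161) * np.log(10) / 2
    vals = [cost(g) for g in grid]
    if not np.isfinite(vals).any():
        raise ValueError("simulated and reference MSD ranges do not overlap at any scale")
    best = int(np.nanargmin(vals))
    lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.exp(res.x))


def fitted_mapping(sigma_nm: float, tau_s: float) -> UnitMapping:
    """Bundle fitted scales into a :class:`UnitMapping` with provenance."""
    return UnitMapping(sigma_nm=sigma_nm, tau_s=tau_s, provenance="fitted")
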