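"""Whole-locus conformational dynamics in probe-separation space.

The configuration of a locus is summarized by the vector X of pairwise
separations of a small set of probe regions (for three probes: the
gene/upstream/downstream triplet, X = (x_UP, x_UD, x_PD)).  The cloud of
X points visited by an ensemble measures locus variability; the MSD of X
as it moves through this configuration space is the shape-change
parameter S(t), whose plateau marks the time needed to explore the
accessible configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import UnitMapping
from .dynamics_engine import Trajectory
from .observables import ProbeRegion, _probe_com

__all__ = [
    "ConfigSeries",
    "ShapeChangeCurve",
    "PlateauResult",
    "config_trajectory",
    "shape_change",
    "variability",
    "component_sd",
    "plateau_diagnostics",
]


@dataclass
class ConfigSeries:
    """Per-frame configuration vectors of one trajectory (nm units).

    ``vectors`` is (F, P*(P-1)/2) holding all pairwise probe separations in
    ``pair_names`` order; every row satisfies nonnegativity and (for three
    probes) the triangle inequality, being Euclidean distances.
    """

    times_s: np.ndarray
    vectors: np.ndarray
    pair_names: list[str]

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    def to_frame(self, **meta) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors, columns=self.pair_names)
        df.insert(0, "time_s", self.times_s)
        for k, v in meta.items():
            df[k] = v
        return df


@dataclass
class ShapeChangeCurve:
    """S(t): mean squared change of X over a lag, with sample counts."""

    lags_s: np.ndarray
    s_nm2: np.ndarray
    n_samples: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags_s, "S_nm2": self.s_nm2,
                             "n": self.n_samples})


@dataclass
class PlateauResult:
    reached: bool
    plateau_time_s: float | None
    plateau_value_nm2: float


def config_trajectory(traj: Trajectory, probes: Sequence[ProbeRegion]
                      ) -> ConfigSeries:
    """Pairwise probe-COM separations per frame, in nm."""
    if len(probes) < 3:
        raise ValueError("need at least 3 probes for a configuration vector")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    for p in probes:
        p.validate(traj.annotation)
    if len({p.copy_id for p in probes}) != 1:
        raise ValueError("probes must lie within one locus copy")
    coms = [_probe_com(traj, p) for p in probes]
    cols, names = [], []
    for a, b in combinations(range(len(probes)), 2):
        d = coms[a] - coms[b]
        cols.append(np.sqrt(np.sum(d * d, axis=-1)) * traj.mapping.sigma_nm)
        names.append(f"x_{probes[a].name}-{probes[b].name}")
    times_s = (traj.times - traj.times[0]) * traj.mapping.tau_s
    return ConfigSeries(times_s=times_s, vectors=np.column_stack(cols),
                        pair_names=names)


def shape_change(series: ConfigSeries | Sequence[ConfigSeries],
                 lag_frames: Sequence[int] | None = None) -> ShapeChangeCurve:
    """S(t) = mean over time origins (and trajectories) of |X(t0+t)-X(t0)|^2.

    Origin averaging never crosses trajectory boundaries; multiple
    trajectories contribute their origin-averaged sums at each lag.
    Lags beyond a trajectory's span are omitted with a warning.
    """
    many = list(series) if not isinstance(series, ConfigSeries) else [series]
    if not many:
        raise ValueError("no configuration series supplied")
    dt = float(many[0].times_s[1] - many[0].times_s[0])
    max_f = max(s.n_frames for s in many)
    if lag_frames is None:
        lag_frames = range(1, max_f)
    lags, s_vals, counts = [], [], []
    dropped = 0
    for k in lag_frames:
        tot, n = 0.0, 0
        for s in many:
            if k >= s.n_frames:
                continue
            d = s.vectors[k:] - s.vectors[:-k]
            tot += float(np.sum(d * d))
            n += s.n_frames - k
        if n == 0:
            dropped += 1
            continue
        lags.append(k * dt)
        s_vals.append(tot / n)
        counts.append(n)
    if dropped:
        warnings.warn(f"{dropped} lag(s) beyond trajectory span omitted")
    return ShapeChangeCurve(np.asarray(lags), np.asarray(s_vals),
                            np.asarray(counts, dtype=int))


def variability(vectors: np.ndarray) -> float:
    """Generalized s.d. volume of the configuration cloud: sqrt(det cov).

    For three probes this has units nm^3.  A singular covariance (e.g.
    a collinear cloud) yields 0.0 with a warning.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or len(X) < 4:
        raise ValueError("need at least 4 configuration vectors")
    det = float(np.linalg.det(np.cov(X.T)))
    if det <= 0:
        warnings.warn("singular configuration covariance; variability = 0")
        return 0.0
    return float(np.sqrt(det))


def component_sd(vectors: np.ndarray) -> np.ndarray:
    """Per-component standard deviations (alternative cloud-size metric)."""
    return np.std(np.asarray(vectors, dtype=float), axis=0, ddof=1)


def plateau_diagnostics(curve: ShapeChangeCurve,
                        tolerance: float = 0.1) -> PlateauResult:
    """Earliest lag from which S stays within ``tolerance`` of its late mean.

    The plateau value is the mean of S over the last quarter of lags; the
    plateau time is the smallest lag after which every S value lies within
    ``tolerance`` (relative) of it.  If that only happens inside the last
    quarter itself, the plateau is reported as not reached.
    """
    if len(curve.lags_s) < 5:
        raise ValueError("curve must span at least 5 lags")
    n = len(curve.s_nm2)
    tail_start = max(1, n - max(1, n // 4))
    plateau_value = float(np.mean(curve.s_nm2[tail_start:]))
    within = np.abs(curve.s_nm2 - plateau_value) <= tolerance * plateau_value
    idx = n
    for i in range(n - 1, -1, -1):
        if within[i]:
            idx = i
        else:
            break
    if idx >= tail_start:
        return PlateauResult(False, None, plateau_value)
    return PlateauResult(True, float(curve.lags_s[idx]), plateau_value)
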