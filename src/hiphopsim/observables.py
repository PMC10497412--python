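"""Dynamic and structural measurements on sampled trajectories.

Implements the per-bead and per-probe observables used to characterize
locus dynamics: mean squared displacement and subdiffusion exponents,
the fixed-lag mobility M, local density, extruder occupancy phi_e,
interaction localness L, simulated CaptureC contact profiles, simulated
FISH separation distributions, enhancer-promoter contact kinetics, and
the probe-size dependence of mobility.

Conventions: trajectory positions are stored unwrapped, so displacement
-based quantities need no boundary handling; all *contact* and *density*
quantities use minimum-image distances in the periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .annotation_io import BeadAnnotation, GenomicInterval, write_bedgraph
from .calibration import UnitMapping
from .dynamics_engine import Trajectory

__all__ = [
    "ProbeRegion",
    "ObservableTrack",
    "MSDCurve",
    "ContactKinetics",
    "wrap_coords",
    "compute_msd",
    "fit_subdiffusion_exponent",
    "mobility_profile",
    "local_density",
    "extruder_occupancy",
    "localness",
    "simulated_capturec",
    "simulated_fish",
    "contact_kinetics",
    "probe_size_sweep",
]


def wrap_coords(x: np.ndarray, box: float) -> np.ndarray:
    """Map coordinates into [0, box) for periodic KD-tree queries."""
    w = np.mod(np.asarray(x, dtype=float), box)
    w[w >= box] -= box  # guard against rounding to exactly `box`
    return w


@dataclass(frozen=True)
class ProbeRegion:
    """A named contiguous bead range (half-open) within one locus copy."""

    name: str
    start_bead: int
    stop_bead: int
    copy_id: int = 1

    def __post_init__(self) -> None:
        if self.start_bead < 0 or self.start_bead >= self.stop_bead:
            raise ValueError("probe bead range must be non-empty")

    @property
    def n_beads(self) -> int:
        return self.stop_bead - self.start_bead

    def validate(self, annotation: BeadAnnotation) -> None:
        ids = annotation.copy_id[self.start_bead:self.stop_bead]
        if len(ids) != self.n_beads:
            raise ValueError(f"probe {self.name} extends beyond the chain")
        if not (ids == self.copy_id).all() or self.copy_id == 0:
            raise ValueError(
                f"probe {self.name} must lie within a single locus copy")

    def shifted(self, offset: int, copy_id: int) -> "ProbeRegion":
        return ProbeRegion(self.name, self.start_bead + offset,
                           self.stop_bead + offset, copy_id)


@dataclass
class ObservableTrack:
    """A per-bead scalar profile; NaN marks beads where it is undefined."""

    name: str
    values: np.ndarray
    units: str
    params: dict = field(default_factory=dict)
    mapping: UnitMapping = field(default_factory=UnitMapping)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_bedgraph(self, path, annotation: BeadAnnotation) -> None:
        if len(self.values) != annotation.n_beads:
            raise ValueError("track length does not match annotation")
        write_bedgraph(self.values, annotation.region, annotation.bead_bp,
                       path, track_name=self.name)


@dataclass
class MSDCurve:
    """Time-and-origin-averaged MSD at multiples of the frame interval."""

    lags_tau: np.ndarray
    msd_sigma2: np.ndarray
    n_origins: np.ndarray
    mapping: UnitMapping = field(default_factory=UnitMapping)

    @property
    def lags_s(self) -> np.ndarray:
        return self.lags_tau * self.mapping.tau_s

    @property
    def msd_nm2(self) -> np.ndarray:
        return self.msd_sigma2 * self.mapping.sigma_nm ** 2


def _probe_com(traj: Trajectory, probe: ProbeRegion) -> np.ndarray:
    """(F, 3) unweighted center of mass of a probe's beads, unwrapped."""
    return traj.bead_positions[:, probe.start_bead:probe.stop_bead, :].mean(
        axis=1)


def _series_msd(series: np.ndarray, lag_frames: Iterable[int]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Origin-averaged MSD of one or many (F, ..., 3) series at given lags.

    Averages over time origins and over any middle axes.
    """
    series = np.asarray(series, dtype=float)
    msd, n = [], []
    F = series.shape[0]
    for k in lag_frames:
        if k <= 0 or k >= F:
            raise ValueError(f"lag of {k} frames outside trajectory span")
        d = series[k:] - series[:-k]
        msd.append(float(np.mean(np.sum(d * d, axis=-1))))
        n.append(F - k)
    return np.asarray(msd), np.asarray(n, dtype=int)


def compute_msd(traj: Trajectory, target, use_com: bool = False,
                lag_frames: Sequence[int] | None = None) -> MSDCurve:
    """MSD curve for a bead index or a :class:`ProbeRegion`.

    ``use_com=True`` tracks the probe's center of mass; otherwise single
    -bead MSDs are averaged over the probe's beads.  Lags are multiples of
    the frame interval (default: every available lag).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if lag_frames is None:
        lag_frames = range(1, traj.n_frames)
    if isinstance(target, (int, np.integer)):
        series = traj.bead_positions[:, int(target), :]
    elif isinstance(target, ProbeRegion):
        if use_com:
            series = _probe_com(traj, target)
        else:
            series = traj.bead_positions[:, target.start_bead:target.stop_bead, :]
    else:
        raise TypeError("target must be a bead index or ProbeRegion")
    msd, n = _series_msd(series, lag_frames)
    lags = np.asarray(list(lag_frames), dtype=float) * traj.frame_interval_tau
    return MSDCurve(lags, msd, n, traj.mapping)


def fit_subdiffusion_exponent(curve: MSDCurve,
                              fit_window: tuple[float, float]) -> float:
    """Least-squares slope of log MSD vs log lag over ``fit_window`` (tau)."""
    lo, hi = fit_window
    sel = (curve.lags_tau >= lo) & (curve.lags_tau <= hi)
    if sel.sum() < 4:
        raise ValueError("need at least 4 MSD points in the fit window")
    y = curve.msd_sigma2[sel]
    if np.any(y <= 0):
        raise ValueError("nonpositive MSD in fit window")
    return float(np.polyfit(np.log(curve.lags_tau[sel]), np.log(y), 1)[0])


def mobility_profile(traj: Trajectory, lag_tau: float = 1e4) -> ObservableTrack:
    """Per-bead mobility M = MSD at a fixed lag (default 1e4 tau ~ 20.7 s).

    If the lag is not a multiple of the frame interval the nearest
    available lag is used and recorded in the track parameters.
    """
    span = traj.times[-1] - traj.times[0]
    if lag_tau > span:
        raise ValueError(
            f"lag {lag_tau} tau exceeds production span {span:.3g} tau")
    k = max(1, int(round(lag_tau / traj.frame_interval_tau)))
    actual = k * traj.frame_interval_tau
    d = traj.bead_positions[k:].astype(float) - traj.bead_positions[:-k]
    m = np.mean(np.sum(d * d, axis=-1), axis=0)
    return ObservableTrack(
        name="mobility", values=m, units="sigma^2",
        params={
            "lag_tau": actual,
            "requested_lag_tau": lag_tau,
            "lag_s": actual * traj.mapping.tau_s,
            "values_um2": m * (traj.mapping.sigma_nm / 1000.0) ** 2,
        },
        mapping=traj.mapping)


def local_density(traj: Trajectory, radius: float = 3.0) -> ObservableTrack:
    """Mean count of other particles (beads + proteins) within ``radius``.

    Minimum-image distances; self excluded; averaged over frames.  The
    default 3 sigma corresponds to ~53 nm at the default length mapping.
    """
    if radius >= traj.box / 2:
        raise ValueError("radius must be smaller than half the box")
    nb = traj.n_beads
    counts = np.zeros(nb)
    for f in range(traj.n_frames):
        pts = np.vstack([traj.bead_positions[f], traj.protein_positions[f]])
        pts = wrap_coords(pts, traj.box)
        tree = cKDTree(pts, boxsize=traj.box)
        c = tree.query_ball_point(pts[:nb], radius, return_length=True)
        counts += c - 1  # exclude self
    counts /= traj.n_frames
    return ObservableTrack(
        name="local_density", values=counts, units="particles",
        params={"radius_sigma": radius,
                "radius_nm": radius * traj.mapping.sigma_nm},
        mapping=traj.mapping)


def extruder_occupancy(traj: Trajectory) -> ObservableTrack:
    """phi_e: fraction of frames a bead lies within +-1 bead of an anchor."""
    nb = traj.n_beads
    hits = np.zeros(nb)
    for f in range(traj.n_frames):
        frame_hits = np.zeros(nb, dtype=bool)
        for left, right in traj.extruder_anchors[f]:
            if left < 0:
                continue
            for a in (int(left), int(right)):
                frame_hits[max(0, a - 1):min(nb, a + 2)] = True
        hits += frame_hits
    return ObservableTrack(
        name="extruder_occupancy", values=hits / traj.n_frames,
        units="fraction", params={"vicinity_beads": 1}, mapping=traj.mapping)


def localness(traj: Trajectory, contact_threshold: float = 3.5,
              genomic_cutoff: int = 100_000, pseudocount: int = 1
              ) -> ObservableTrack:
    """Localness L = near contacts / (far contacts + pseudocount).

    A contact is two beads of the same locus copy closer than
    ``contact_threshold`` sigma (default 3.5 sigma ~ 62 nm); near means a
    genomic separation below ``genomic_cutoff`` bp.  Pooled over frames.
    Spacer beads get NaN.  log2 L is available in ``params['log2_values']``.
    """
    if contact_threshold <= 0 or genomic_cutoff <= 0:
        raise ValueError("thresholds must be positive")
    nb = traj.n_beads
    ann = traj.annotation
    near = np.zeros(nb)
    far = np.zeros(nb)
    cut_beads = genomic_cutoff / ann.bead_bp
    for f in range(traj.n_frames):
        pts = wrap_coords(traj.bead_positions[f].astype(float), traj.box)
        tree = cKDTree(pts, boxsize=traj.box)
        pairs = tree.query_pairs(contact_threshold, output_type="ndarray")
        if len(pairs) == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        same = (ann.copy_id[i] == ann.copy_id[j]) & (ann.copy_id[i] != 0)
        i, j = i[same], j[same]
        sep = np.abs(i - j)
        is_near = sep < cut_beads
        np.add.at(near, i[is_near], 1)
        np.add.at(near, j[is_near], 1)
        np.add.at(far, i[~is_near], 1)
        np.add.at(far, j[~is_near], 1)
    L = near / (far + pseudocount)
    L[ann.copy_id == 0] = np.nan
    with np.errstate(divide="ignore"):
        log2 = np.log2(np.where(L > 0, L, np.nan))
    return ObservableTrack(
        name="localness", values=L, units="ratio",
        params={"contact_threshold_sigma": contact_threshold,
                "contact_threshold_nm":
                    contact_threshold * traj.mapping.sigma_nm,
                "genomic_cutoff_bp": genomic_cutoff,
                "pseudocount": pseudocount,
                "log2_values": log2},
        mapping=traj.mapping)


def _equivalent_copies(ann: BeadAnnotation, copy_id: int):
    """Copies sharing the source annotation of ``copy_id`` (incl. itself)."""
    src = next(c for c in ann.copies if c.copy_id == copy_id).source_index
    return [c for c in ann.copies if c.source_index == src]


def simulated_capturec(traj: Trajectory, viewpoints: Sequence[int],
                       contact_threshold: float = 3.5
                       ) -> dict[int, np.ndarray]:
    """Ensemble contact profile from viewpoint beads (CaptureC-like).

    ``viewpoints`` are global bead indices.  For each, the profile over the
    copy-local coordinate is the fraction of (frame, copy) observations in
    which a bead lies within ``contact_threshold`` sigma of the viewpoint,
    pooled across frames and across all copies sharing the viewpoint's
    source annotation.  The viewpoint bead +-1 is masked NaN.
    """
    ann = traj.annotation
    out: dict[int, np.ndarray] = {}
    for v in viewpoints:
        cid = int(ann.copy_id[v])
        if cid == 0:
            raise ValueError(f"viewpoint bead {v} lies in spacer chromatin")
        home = next(c for c in ann.copies if c.copy_id == cid)
        v_loc = v - home.start_bead
        n_loc = home.n_beads
        acc = np.zeros(n_loc)
        n_obs = 0
        for c in _equivalent_copies(ann, cid):
            beads = slice(c.start_bead, c.start_bead + c.n_beads)
            vp = c.start_bead + v_loc
            d = traj.bead_positions[:, beads, :].astype(float) \
                - traj.bead_positions[:, vp, None, :]
            d -= traj.box * np.round(d / traj.box)
            dist = np.sqrt(np.sum(d * d, axis=-1))  # (F, n_loc)
            acc += (dist < contact_threshold).sum(axis=0)
            n_obs += traj.n_frames
        profile = acc / n_obs
        profile[max(0, v_loc - 1):v_loc + 2] = np.nan
        out[int(v)] = profile
    return out


def capturec_to_bedgraph(profiles: Mapping[int, np.ndarray],
                         traj: Trajectory, path_pattern: str) -> list[str]:
    """Write each viewpoint profile as bedGraph in source coordinates.

    ``path_pattern`` must contain ``{viewpoint}``.
    """
    ann = traj.annotation
    written = []
    for v, profile in profiles.items():
        cid = int(ann.copy_id[v])
        home = next(c for c in ann.copies if c.copy_id == cid)
        sources = getattr(ann, "source_regions", None) or [ann.region]
        region = sources[min(home.source_index, len(sources) - 1)]
        path = path_pattern.format(viewpoint=v)
        write_bedgraph(profile, region, ann.bead_bp, path,
                       track_name=f"capturec_viewpoint_{v}")
        written.append(path)
    return written


def simulated_fish(traj: Trajectory, probes: Sequence[ProbeRegion],
                   all_copies: bool = False) -> pd.DataFrame:
    """Pairwise probe center-of-mass separations per frame, in nm.

    Returns a tidy frame with columns (pair, frame, copy, separation_nm).
    With ``all_copies=True`` the probes are replicated across every copy
    sharing their source annotation and observations pooled.
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probes")
    ann = traj.annotation
    layouts: list[tuple[int, list[ProbeRegion]]] = []
    if all_copies:
        home = next(c for c in ann.copies if c.copy_id == probes[0].copy_id)
        for c in _equivalent_copies(ann, probes[0].copy_id):
            off = c.start_bead - home.start_bead
            layouts.append((c.copy_id, [p.shifted(off, c.copy_id)
                                        for p in probes]))
    else:
        layouts.append((probes[0].copy_id, list(probes)))
    rows = []
    for copy_id, ps in layouts:
        coms = {p.name: _probe_com(traj, p) for p in ps}
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                d = coms[ps[a].name] - coms[ps[b].name]
                sep = np.sqrt(np.sum(d * d, axis=-1)) * traj.mapping.sigma_nm
                for f, s in enumerate(sep):
                    rows.append((f"{ps[a].name}-{ps[b].name}", f, copy_id,
                                 float(s)))
    return pd.DataFrame(rows,
                        columns=["pair", "frame", "copy", "separation_nm"])


def fish_summary(distances: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of separations per probe pair."""
    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    return distances.groupby("pair")["separation_nm"].agg(
        median="median", iqr=iqr, n="count").reset_index()


@dataclass
class ContactKinetics:
    """Run-length decomposition of a two-probe contact time series."""

    contact_durations_s: np.ndarray
    gap_durations_s: np.ndarray
    first_censored: bool
    last_censored: bool
    frame_interval_s: float

    @property
    def mean_contact_s(self) -> float:
        x = self.contact_durations_s
        return float(np.mean(x)) if len(x) else np.nan

    @property
    def mean_gap_s(self) -> float:
        x = self.gap_durations_s
        return float(np.mean(x)) if len(x) else np.nan


def contact_kinetics(traj: Trajectory, pair: tuple[ProbeRegion, ProbeRegion],
                     contact_threshold: float = 3.5) -> ContactKinetics:
    """Collision intervals and contact durations of a probe pair.

    Contact per frame: COM separation below ``contact_threshold`` sigma.
    Episode durations are run lengths times the frame interval, converted
    to seconds.  The first and last episodes are censored (their true
    length extends beyond the sampled window) and flagged.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    a, b = pair
    d = _probe_com(traj, a) - _probe_com(traj, b)
    sep = np.sqrt(np.sum(d * d, axis=-1))
    in_contact = sep < contact_threshold
    dt_s = traj.frame_interval_s
    runs: list[tuple[bool, int]] = []
    start = 0
    for f in range(1, len(in_contact) + 1):
        if f == len(in_contact) or in_contact[f] != in_contact[start]:
            runs.append((bool(in_contact[start]), f - start))
            start = f
    contacts = np.array([r[1] for r in runs if r[0]], dtype=float) * dt_s
    gaps = np.array([r[1] for r in runs if not r[0]], dtype=float) * dt_s
    return ContactKinetics(
        contact_durations_s=contacts,
        gap_durations_s=gaps,
        first_censored=True,
        last_censored=True,
        frame_interval_s=dt_s,
    )


def probe_size_sweep(traj: Trajectory, sizes_bp: Sequence[int],
                     lag_tau: float | None = None) -> pd.DataFrame:
    """Mean and s.d. of windowed COM mobility vs probe size.

    Each locus copy is tiled with non-overlapping windows of the given
    genomic size; the COM mobility (MSD at ``lag_tau``) of each window is
    computed and pooled across copies.  Default lag: 10 frame intervals.
    """
    ann = traj.annotation
    bp = ann.bead_bp
    if lag_tau is None:
        lag_tau = 10 * traj.frame_interval_tau
    k = max(1, int(round(lag_tau / traj.frame_interval_tau)))
    if k >= traj.n_frames:
        raise ValueError("lag exceeds trajectory span")
    rows = []
    for size in sizes_bp:
        if size < bp:
            raise ValueError(f"probe size {size} below bead size {bp}")
        w = size // bp
        vals = []
        for c in ann.copies:
            if w > c.n_beads:
                raise ValueError(
                    f"window of {size} bp exceeds copy length "
                    f"{c.n_beads * bp} bp")
            for s in range(c.start_bead, c.stop_bead - w + 1, w):
                com = traj.bead_positions[:, s:s + w, :].mean(axis=1)
                d = com[k:] - com[:-k]
                vals.append(float(np.mean(np.sum(d * d, axis=-1))))
        vals = np.asarray(vals)
        rows.append((size, float(vals.mean()), float(vals.std(ddof=1))
                     if len(vals) > 1 else 0.0, len(vals)))
    return pd.DataFrame(rows, columns=["size_bp", "mean_mobility_sigma2",
                                       "sd_mobility_sigma2", "n_windows"])
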