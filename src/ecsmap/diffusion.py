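"""Mean-squared-displacement (MSD) confinement analysis.

For a 2D track sampled at interval dt, MSD(n*dt) is the mean of
|r(i+n) - r(i)|^2 over all frame pairs present in the track (overlapping
pairs; blinking gaps simply remove pairs).  The instantaneous diffusion
coefficient D comes from an ordinary least-squares line through the first
four MSD points (MSD = 4*D*tau + b in 2D; the intercept b absorbs the
4*sigma_loc^2 localization-noise floor).  Under confinement the MSD plateaus
at the mean squared distance between two independent positions in the
accessible domain; the confinement area of a recording is the average MSD
over lags in the 0.8-1.0 s plateau window, averaged over trajectories.

The paired "percent change in ECS confinement" statistic for a treated vs
untreated recording pair is

    (ECSconf_treated - ECSconf_untreated) / ((ECSconf_treated + ECSconf_untreated)/2) * 100,

a symmetric percent difference bounded in (-200, 200), computed over all
cross pairs of recordings within one region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Trajectory, TrajectorySet
from .stats import TestReport, compare_groups, dunn_posthoc, summarize  # noqa: F401

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "ConfinementRecord",
    "PercentChangeDistribution",
    "compute_msd",
    "ensemble_msd",
    "fit_diffusion_coefficient",
    "confinement_area",
    "confinement_by_recording",
    "percent_change_confinement",
    "compare_groups",
]


@dataclass
class MSDCurve:
    """MSD vs time lag; lag 0 is omitted and zero-pair lags are dropped."""

    lags_s: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    owner: str = ""

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(self.msd < 0):
            raise ValueError("MSD values must be non-negative")
        if np.any(self.n_pairs < 1):
            raise ValueError("reported lags must have at least one pair")

    @property
    def n_lags(self) -> int:
        return int(self.lags_s.size)


@dataclass
class DiffusionEstimate:
    d: float  # um^2/s, slope/4
    intercept: float  # um^2
    n_fit: int
    negative_slope: bool = False

    @property
    def d_clamped(self) -> float:
        """Non-negative D for summary tables (raw value kept in ``d``)."""
        return max(self.d, 0.0)


@dataclass
class ConfinementRecord:
    recording: str
    condition: str
    region: str
    area_um2: float
    n_trajectories: int
    method: str = "per_trajectory"


@dataclass
class PercentChangeDistribution:
    values: np.ndarray
    pairs: list[tuple[str, str]]
    region: str = ""
    zero_pairs: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def iqr(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.values, 25)),
            float(np.percentile(self.values, 75)),
        )


def compute_msd(
    traj: Trajectory, dt: float, max_lag_frames: int | None = None
) -> MSDCurve:
    """Time-averaged MSD of one track using all overlapping frame pairs.

    Pairs whose endpoints both exist are used regardless of interior gaps;
    lags with zero pairs are omitted.
    """
    if traj.n_points < 2:
        raise ValueError(f"track {traj.track_id!r} has fewer than 2 localizations")
    frames = traj.frames
    pos = traj.positions
    span = int(frames[-1] - frames[0])
    max_lag = span if max_lag_frames is None else min(max_lag_frames, span)
    # presence/index lookup over the frame span
    offset = frames[0]
    idx = np.full(span + 1, -1, dtype=np.int64)
    idx[frames - offset] = np.arange(frames.size)
    lags, msd, counts = [], [], []
    rel = frames - offset
    for n in range(1, max_lag + 1):
        tgt = rel + n
        ok = tgt <= span
        j = idx[tgt[ok]]
        have = j >= 0
        if not have.any():
            continue
        i = np.flatnonzero(ok)[have]
        disp = pos[j[have]] - pos[i]
        lags.append(n * dt)
        msd.append(float((disp**2).sum(axis=1).mean()))
        counts.append(int(have.sum()))
    if not lags:
        raise ValueError(f"track {traj.track_id!r}: no valid lag pairs")
    return MSDCurve(np.array(lags), np.array(msd), np.array(counts),
                    owner=f"{traj.recording}/{traj.track_id}")


def ensemble_msd(
    ts: TrajectorySet, max_lag_frames: int | None = None, pooled: bool = True
) -> MSDCurve:
    """Recording-level MSD curve.

    pooled=True averages squared displacements over all pairs of all tracks
    (pair-weighted); pooled=False averages the per-track MSD curves with
    equal weight per track at each lag.
    """
    acc_num: dict[int, float] = {}
    acc_cnt: dict[int, float] = {}
    acc_pairs: dict[int, int] = {}
    for t in ts:
        if t.n_points < 2:
            continue
        c = compute_msd(t, ts.dt, max_lag_frames)
        for lag, m, n in zip(c.lags_s, c.msd, c.n_pairs):
            k = int(round(lag / ts.dt))
            if pooled:
                acc_num[k] = acc_num.get(k, 0.0) + m * n
                acc_cnt[k] = acc_cnt.get(k, 0.0) + n
            else:
                acc_num[k] = acc_num.get(k, 0.0) + m
                acc_cnt[k] = acc_cnt.get(k, 0.0) + 1
            acc_pairs[k] = acc_pairs.get(k, 0) + int(n)
    if not acc_num:
        raise ValueError("no track in the set has >= 2 localizations")
    ks = sorted(acc_num)
    return MSDCurve(
        np.array([k * ts.dt for k in ks]),
        np.array([acc_num[k] / acc_cnt[k] for k in ks]),
        np.array([acc_pairs[k] for k in ks]),
        owner="ensemble",
    )


def fit_diffusion_coefficient(msd: MSDCurve, n_fit: int = 4) -> DiffusionEstimate:
    """OLS line through the first ``n_fit`` MSD points; D = slope/4 (2D).

    Negative slopes are reported as-is with a flag; clamping to zero is left
    to summary tables.
    """
    if msd.n_lags < n_fit:
        raise ValueError(f"need >= {n_fit} lags, have {msd.n_lags}")
    tau = msd.lags_s[:n_fit]
    y = msd.msd[:n_fit]
    slope, intercept = np.polyfit(tau, y, 1)
    return DiffusionEstimate(
        d=float(slope) / 4.0,
        intercept=float(intercept),
        n_fit=n_fit,
        negative_slope=bool(slope < 0),
    )


def confinement_area(
    ts: TrajectorySet,
    plateau_window: tuple[float, float] = (0.8, 1.0),
    method: str = "per_trajectory",
) -> ConfinementRecord:
    """Confinement area of one recording from the MSD plateau.

    Per trajectory, the MSD is averaged over lags inside the closed plateau
    window; the recording-level area is the unweighted mean of these
    per-trajectory values ("per_trajectory", default).  "pooled" instead
    averages the pair-pooled recording MSD curve over window lags.
    Trajectories too short to reach the window contribute nothing.
    """
    lo, hi = plateau_window
    if not 0 < lo <= hi:
        raise ValueError("invalid plateau window")
    recs = {t.recording for t in ts}
    rec = next(iter(recs)) if len(recs) == 1 else ",".join(sorted(recs))
    max_lag = int(np.ceil(hi / ts.dt))
    if method == "pooled":
        curve = ensemble_msd(ts, max_lag_frames=max_lag, pooled=True)
        sel = (curve.lags_s >= lo - 1e-12) & (curve.lags_s <= hi + 1e-12)
        if not sel.any():
            raise ValueError(f"recording {rec!r}: no lag reaches the plateau window")
        n_contrib = sum(
            1 for t in ts if t.n_points >= 2 and (t.frames[-1] - t.frames[0]) * ts.dt >= lo
        )
        area = float(curve.msd[sel].mean())
    elif method == "per_trajectory":
        per_track = []
        for t in ts:
            if t.n_points < 2:
                continue
            c = compute_msd(t, ts.dt, max_lag)
            sel = (c.lags_s >= lo - 1e-12) & (c.lags_s <= hi + 1e-12)
            if sel.any():
                per_track.append(float(c.msd[sel].mean()))
        if not per_track:
            raise ValueError(f"recording {rec!r}: no trajectory reaches the plateau window")
        area = float(np.mean(per_track))
        n_contrib = len(per_track)
    else:
        raise ValueError(f"unknown method {method!r}")
    first = ts.trajectories[0]
    return ConfinementRecord(
        recording=rec,
        condition=first.condition,
        region=first.region,
        area_um2=area,
        n_trajectories=n_contrib,
        method=method,
    )


def confinement_by_recording(
    ts: TrajectorySet,
    plateau_window: tuple[float, float] = (0.8, 1.0),
    method: str = "per_trajectory",
) -> list[ConfinementRecord]:
    return [
        confinement_area(ts.subset(rec), plateau_window, method)
        for rec in ts.recordings()
    ]


def percent_change_confinement(
    treated: list[ConfinementRecord],
    untreated: list[ConfinementRecord],
) -> PercentChangeDistribution:
    """Percent change in ECS confinement over all treated x untreated pairs.

    Pairs where both confinement areas are zero get value 0 by convention
    (counted in ``zero_pairs``).  Both lists must share one region label.
    """
    if not treated or not untreated:
        raise ValueError("both record lists must be non-empty")
    regions = {r.region for r in treated} | {r.region for r in untreated}
    if len(regions) > 1:
        raise ValueError(f"region mismatch between groups: {sorted(regions)}")
    values, pairs = [], []
    zero_pairs = 0
    for t in treated:
        for u in untreated:
            if t.area_um2 == 0.0 and u.area_um2 == 0.0:
                values.append(0.0)
                zero_pairs += 1
            else:
                values.append(
                    (t.area_um2 - u.area_um2) / ((t.area_um2 + u.area_um2) / 2.0) * 100.0
                )
            pairs.append((t.recording, u.recording))
    return PercentChangeDistribution(
        np.array(values), pairs, region=next(iter(regions)), zero_pairs=zero_pairs
    )
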