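"""Gastrulation milestones, transcription transition point, and the
increasing-nucleus classifier.

Mesoderm invagination drives MSE nuclei ventrally; the mean DV speed of
transcribing MSE nuclei therefore shows a large ventral peak.  In embryos
mounted at a tilt, the whole embryo first rolls dorsally during apical
constriction, producing an earlier, opposite-signed peak; the trough between
the two movements marks the start of invagination.  The transition point of
a mean transcription trace is the changepoint of the best two-plateau
piecewise-constant fit (exhaustive residual-sum-of-squares search), accepted
only when it clearly improves on a single plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal


@dataclass(frozen=True)
class GastroParams:
    window_pre: float = 15.0        # min before the reference event
    window_post: float = 15.0       # min after
    increase_fold: float = 1.7      # fold threshold of the classifier
    movement_smooth: int = 5        # frames, median, on the speed profile
    peak_fraction: float = 0.2      # θ for phase onset/offset
    min_peak_speed: float = 0.3     # µm/min absolute floor for milestones
    peak_snr: float = 8.0           # robust z of the peak vs profile noise
    min_segment: int = 4            # frames, changepoint minimum segment
    variance_ratio: float = 2.0     # SSE0/SSE1 acceptance for a transition
    onset_quantile: float = 0.9     # cohort onsets covered before the
                                    # transition search window opens

    def __post_init__(self) -> None:
        if self.window_pre <= 0 or self.window_post <= 0:
            raise ValueError("windows must be positive")
        if self.increase_fold <= 1:
            raise ValueError("increase_fold must exceed 1")
        if not 0 < self.peak_fraction < 1:
            raise ValueError("peak_fraction must be in (0, 1)")


@dataclass
class GastrulationEvents:
    t_constriction: float | None
    t_invagination: float | None
    t_end: float | None
    n_peaks: int
    found: bool


@dataclass
class TransitionResult:
    t_transition: float
    level_pre: float
    level_post: float
    fold: float
    found: bool


# ---------------------------------------------------------------------------
# movement

def movement_profile(tracks: pd.DataFrame, track_ids=None,
                     params: GastroParams = GastroParams(),
                     signed: bool = True) -> pd.DataFrame:
    """Mean DV (y-axis) speed of the selected nuclei per frame (µm/min).

    ``tracks`` needs columns track_id (or nucleus_id), frame, t_min, y_um.
    Per nucleus the per-frame y displacement is divided by the elapsed time;
    the mean over nuclei is median-smoothed over ``movement_smooth`` frames.
    With ``signed`` the profile is oriented so the ventral (invagination)
    direction is positive: the sign of the profile's largest-magnitude
    excursion is flipped to + if needed, which makes an early rolling phase
    appear with the opposite sign.  ``signed=False`` averages |dy|/dt.
    """
    tr = tracks.rename(columns={"nucleus_id": "track_id"})
    if track_ids is not None:
        tr = tr[tr.track_id.isin(track_ids)]
    if tr.track_id.nunique() == 0:
        raise ValueError("no tracks selected for the movement profile")
    tr = tr.sort_values(["track_id", "frame"])

    pieces = []
    for tid, g in tr.groupby("track_id"):
        t = g.t_min.to_numpy()
        y = g.y_um.to_numpy()
        dt = np.diff(t)
        dy = np.diff(y)
        ok = dt > 0
        v = dy[ok] / dt[ok]
        if not signed:
            v = np.abs(v)
        pieces.append(pd.DataFrame({"t_min": t[1:][ok], "v": v}))
    prof = (pd.concat(pieces).groupby("t_min")["v"].mean().reset_index())
    prof["v"] = ndimage.median_filter(prof.v.to_numpy(),
                                      size=params.movement_smooth,
                                      mode="nearest")
    if signed and len(prof) and prof.v.abs().max() > 0:
        if prof.v.to_numpy()[int(np.argmax(prof.v.abs().to_numpy()))] < 0:
            prof["v"] = -prof["v"]
    return prof


def detect_milestones(profile: pd.DataFrame,
                      params: GastroParams = GastroParams()
                      ) -> GastrulationEvents:
    """Gastrulation milestones from a DV speed profile.

    Peaks of |v| with prominence at least peak_fraction x the global maximum
    are considered.  Two peaks (tilted mount): the invagination start is the
    inter-peak minimum of |v| and the constriction start is the onset of the
    first peak.  One peak: invagination starts when the ventral speed first
    exceeds peak_fraction x peak height.  Gastrulation ends when the speed
    falls back below that level after the ventral peak.  A flat profile
    (failed invagination) yields found=False.
    """
    t = profile.t_min.to_numpy()
    v = profile.v.to_numpy()
    av = np.abs(v)
    vmax = av.max() if len(av) else 0.0
    med = np.median(v) if len(v) else 0.0
    mad = 1.4826 * np.median(np.abs(v - med)) if len(v) else 0.0
    snr = (vmax - med) / mad if mad > 0 else np.inf
    if vmax < params.min_peak_speed or snr < params.peak_snr:
        return GastrulationEvents(None, None, None, 0, False)

    peaks, props = signal.find_peaks(av, prominence=params.peak_fraction * vmax)
    # keep peaks reaching a meaningful height
    peaks = peaks[av[peaks] >= params.peak_fraction * vmax]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(av))])
    n_peaks = len(peaks)

    vent_peak = peaks[np.argmax(v[peaks])]      # the ventral (positive) peak
    level = params.peak_fraction * v[vent_peak]

    def cross_up(series, level, i_peak):
        """Interpolated time the series last rises through `level` before
        the peak."""
        i0 = i_peak
        while i0 > 0 and series[i0 - 1] >= level:
            i0 -= 1
        if i0 == 0 or series[i0] <= series[i0 - 1]:
            return float(t[i0])
        frac = (level - series[i0 - 1]) / (series[i0] - series[i0 - 1])
        return float(t[i0 - 1] + frac * (t[i0] - t[i0 - 1]))

    if n_peaks >= 2 and peaks[0] < vent_peak:
        first = peaks[0]
        trough = first + int(np.argmin(av[first:vent_peak + 1]))
        t_inv = float(t[trough])
        t_constr = cross_up(av, params.peak_fraction * av[first], first)
    else:
        n_peaks = 1
        t_constr = None
        t_inv = cross_up(v, level, vent_peak)

    i1 = vent_peak
    while i1 < len(v) - 1 and v[i1 + 1] >= level:
        i1 += 1
    if i1 < len(v) - 1 and v[i1] > v[i1 + 1]:
        frac = (v[i1] - level) / (v[i1] - v[i1 + 1])
        t_end = float(t[i1] + frac * (t[i1 + 1] - t[i1]))
    else:
        t_end = float(t[min(i1 + 1, len(t) - 1)])
    return GastrulationEvents(t_constr, t_inv, t_end, int(n_peaks), True)


# ---------------------------------------------------------------------------
# transition point

def detect_transition(t: np.ndarray, y: np.ndarray,
                      params: GastroParams = GastroParams(),
                      window: tuple[float, float] | None = None
                      ) -> TransitionResult:
    """Best two-plateau piecewise-constant fit of a mean trace.

    Exhaustive search over all changepoints k (each segment at least
    ``min_segment`` points) minimizing the residual sum of squares; the
    transition is accepted only when SSE(one plateau) / SSE(two plateaus)
    reaches ``variance_ratio``.  ``window`` (min into nc14) restricts the
    search — cohort-level callers use it to exclude the activity-onset ramp.
    Returns the changepoint time (first point of the upper segment), both
    plateau levels and their fold change.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    n = len(y)
    if n < 2 * params.min_segment:
        raise ValueError("series shorter than two minimum segments")
    mean0 = y.mean()
    sse0 = float(((y - mean0) ** 2).sum())

    best_k, best_sse = None, np.inf
    c = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y ** 2)])
    for k in range(params.min_segment, n - params.min_segment + 1):
        sse = (c2[k] - c[k] ** 2 / k) + (c2[n] - c2[k] - (c[n] - c[k]) ** 2 / (n - k))
        if sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    k = best_k
    lvl_pre = float(c[k] / k)
    lvl_post = float((c[n] - c[k]) / (n - k))
    fold = lvl_post / lvl_pre if lvl_pre > 0 else np.nan
    if best_sse > 0:
        ratio = sse0 / best_sse
    else:
        ratio = np.inf if sse0 > 0 else 0.0   # perfectly flat: no transition
    found = bool(ratio >= params.variance_ratio)
    return TransitionResult(t_transition=float(t[k]), level_pre=lvl_pre,
                            level_post=lvl_post, fold=float(fold), found=found)


def cohort_mean_trace(table: pd.DataFrame, region: str | None = "MSE"
                      ) -> pd.DataFrame:
    """Mean normalized trace over active nuclei (optionally one region)."""
    sel = table[table.active]
    if region is not None and "region" in sel.columns:
        sel = sel[sel.region == region]
    m = sel.groupby("t_min")["normalized"].mean().reset_index()
    return m.rename(columns={"normalized": "mean_norm"})


def detect_cohort_transition(table: pd.DataFrame,
                             params: GastroParams = GastroParams(),
                             region: str | None = "MSE") -> TransitionResult:
    """Transition of a cohort's mean trace, searched after activity onset.

    The mean normalized trace rises as nuclei initiate transcription; a
    changepoint fit over the whole movie would lock onto that ramp.  The
    search window therefore opens once ``onset_quantile`` of the active
    nuclei have had their onset (default 90%), and runs to the end.
    """
    sel = table[table.active]
    if region is not None and "region" in sel.columns and \
            (sel.region == region).any():
        sel = sel[sel.region == region]
    onsets = sel.groupby("track_id")["onset"].first().dropna()
    start = float(np.quantile(onsets, params.onset_quantile)) if len(onsets) \
        else float(sel.t_min.min())
    m = sel.groupby("t_min")["normalized"].mean().reset_index()
    return detect_transition(m.t_min.to_numpy(), m.normalized.to_numpy(),
                             params, window=(start, float(m.t_min.max())))


# ---------------------------------------------------------------------------
# per-nucleus classification and summaries

def classify_increasing(trace: pd.DataFrame, cohort_post_mean: float,
                        t_invagination: float,
                        params: GastroParams = GastroParams()
                        ) -> tuple[bool | None, float, float]:
    """Increasing-nucleus rule.

    A nucleus increases when its mean normalized intensity over the
    ``window_post`` minutes from invagination start (i) exceeds the cohort
    mean over the same window and (ii) is at least ``increase_fold`` times
    its own mean over the ``window_pre`` minutes before invagination.
    Returns (flag, post_mean, pre_mean); flag is None when either window is
    not covered.
    """
    pre = trace[(trace.t_min >= t_invagination - params.window_pre)
                & (trace.t_min < t_invagination)].normalized.dropna()
    post = trace[(trace.t_min >= t_invagination)
                 & (trace.t_min <= t_invagination + params.window_post)
                 ].normalized.dropna()
    if len(pre) == 0 or len(post) == 0:
        return None, np.nan, np.nan
    pre_m, post_m = float(pre.mean()), float(post.mean())
    flag = (post_m > cohort_post_mean) and (post_m >= params.increase_fold * pre_m)
    return bool(flag), post_m, pre_m


def classify_cohort(table: pd.DataFrame, t_invagination: float,
                    params: GastroParams = GastroParams()) -> pd.DataFrame:
    """Apply the increasing rule to every active nucleus of a cohort."""
    act = table[table.active]
    post_all = act[(act.t_min >= t_invagination)
                   & (act.t_min <= t_invagination + params.window_post)]
    cohort_post = float(post_all.normalized.dropna().mean())
    rows = []
    for tid, g in act.groupby("track_id"):
        flag, post_m, pre_m = classify_increasing(g, cohort_post,
                                                  t_invagination, params)
        rows.append((tid, flag, post_m, pre_m,
                     post_m / pre_m if pre_m and pre_m > 0 else np.nan))
    return pd.DataFrame(rows, columns=["track_id", "increasing", "post_mean",
                                       "pre_mean", "fold"])


def fold_change(trace: pd.DataFrame, t_ref: float,
                params: GastroParams = GastroParams()) -> float:
    """Ratio of post-window to pre-window mean of a (mean) trace."""
    col = "mean_norm" if "mean_norm" in trace.columns else "normalized"
    pre = trace[(trace.t_min >= t_ref - params.window_pre)
                & (trace.t_min < t_ref)][col].dropna()
    post = trace[(trace.t_min >= t_ref)
                 & (trace.t_min <= t_ref + params.window_post)][col].dropna()
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("fold_change windows not covered by the trace")
    pre_m = pre.mean()
    if pre_m <= 0:
        warnings.warn("pre-window mean non-positive; fold undefined",
                      stacklevel=2)
        return float("nan")
    return float(post.mean() / pre_m)


def correlate_pooled(x, y) -> float:
    """Squared Pearson correlation of pooled per-embryo pairs.

    Pairs with a missing value (embryos without a detected transition) are
    excluded; fewer than 3 remaining pairs is undefined (ValueError).  A
    degenerate (constant) variable yields 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("pooled R^2 needs at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("degenerate variable in pooled correlation; R^2 = 0",
                      stacklevel=2)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
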