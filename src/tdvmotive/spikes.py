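"""Event-locked response detection, discounted-value regression, neuron
classification, and time-resolved effect-size curves for spike trains.

Spike timestamps are in ms relative to cue onset; per-trial event times
(``go_ms``, ``release_ms``, ``reward_ms``) live in the trial metadata frame.
Only correct trials are analyzed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: search range of the sliding test window, ms relative to the aligning event
EVENT_RANGES = {"cue": (0.0, 1500.0), "release": (-300.0, 300.0), "reward": (0.0, 500.0)}

#: background window, ms relative to cue onset
BACKGROUND_WINDOW = (-500.0, 0.0)

#: default sliding range of the effect-size timecourse, ms relative to event
TIMECOURSE_RANGES = {"cue": (-500.0, 1500.0), "release": (-1000.0, 500.0)}

CATEGORIES = ("DV", "Size_and_Delay", "Size", "Delay", "NA")


@dataclass
class SpikeData:
    """Spikes of one neuron across the correct trials of one session.

    ``trials`` carries per-trial metadata including event times; ``spikes``
    has one sorted timestamp array (ms, relative to cue onset) per row of
    ``trials``.
    """

    neuron_id: str
    trials: pd.DataFrame
    spikes: list

    def __post_init__(self) -> None:
        if len(self.spikes) != len(self.trials):
            raise ValueError("one spike array per trial row is required")
        for i, s in enumerate(self.spikes):
            arr = np.asarray(s, dtype=float)
            if arr.size and np.any(np.diff(arr) < 0):
                raise ValueError(f"trial {i}: spike timestamps are not sorted")
            self.spikes[i] = arr

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def aligned(self, event: str) -> list:
        """Spike times re-referenced to ``event`` ('cue', 'release', 'reward')."""
        if event == "cue":
            return self.spikes
        col = f"{event}_ms"
        ev = self.trials[col].to_numpy(dtype=float)
        if np.isnan(ev).any():
            raise ValueError(f"missing {event} time on a correct trial")
        return [s - e for s, e in zip(self.spikes, ev)]


@dataclass
class ResponseWindow:
    """Detected event-locked response interval (ms relative to the event)."""

    event: str
    start_ms: float | None
    end_ms: float | None
    is_responsive: bool
    p_values: np.ndarray = field(repr=False)
    window_starts: np.ndarray = field(repr=False)
    significant: np.ndarray = field(repr=False)
    max_run: int = 0

    @property
    def duration_ms(self) -> float | None:
        if self.start_ms is None:
            return None
        return self.end_ms - self.start_ms

    @property
    def detected(self) -> bool:
        return self.start_ms is not None


@dataclass
class RegressionFit:
    """OLS fit with standardized partial regression coefficients (SPRC)."""

    names: tuple[str, ...]
    coef: np.ndarray
    sprc: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    n_trials: int

    def coef_of(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def sprc_of(self, name: str) -> float:
        return float(self.sprc[self.names.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


@dataclass
class EffectSizeTimecourse:
    alignment: str
    times_ms: np.ndarray
    r2: np.ndarray
    window_ms: float = 200.0
    step_ms: float = 10.0


# ---------------------------------------------------------------------------
# sliding chi-square response detection
# ---------------------------------------------------------------------------

def _filled_bin_counts(aligned: list, t0: float, t1: float) -> np.ndarray:
    """Per-1 ms-bin count of trials containing at least one spike, over [t0, t1)."""
    n_bins = int(round(t1 - t0))
    counts = np.zeros(n_bins, dtype=np.int64)
    for s in aligned:
        sel = s[(s >= t0) & (s < t1)]
        if sel.size:
            counts[np.unique(np.floor(sel - t0).astype(np.int64))] += 1
    return counts


def _chi2_2x2(a, b, c, d):
    """Pearson chi-square (1 df, no continuity correction), vectorized."""
    a = np.asarray(a, dtype=float)
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return stats.chi2.sf(stat, 1)


def _exact_2x2(a, b, c, d):
    """Exact conditional (hypergeometric) two-sided p for elevation, vectorized.

    Twice the one-sided upper tail, capped at 1; the valid small-sample form
    of the 2x2 comparison when expected filled-bin counts are far below 5.
    """
    a = np.asarray(a, dtype=np.int64)
    M = a + b + c + d
    K = a + c
    n1 = a + b
    one_sided = stats.hypergeom.sf(a - 1, M, K, n1)
    return np.minimum(2.0 * one_sided, 1.0)


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of True runs (stop exclusive)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return
    padded = np.concatenate([[False], m, [False]]).astype(int)
    d = np.diff(padded)
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        yield s, e


def detect_response(
    sd: SpikeData,
    event: str = "cue",
    *,
    alpha: float = 0.05,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
    search_range: tuple[float, float] | None = None,
    min_onset_run: int = 4,
    min_responsive_run: int = 5,
    max_gap: int = 4,
    test: str = "exact",
) -> ResponseWindow:
    """Sliding chi-square detection of an event-locked response elevation.

    For each ``window_ms`` test window stepped by ``step_ms`` over the
    event-specific search range, the pooled proportion of filled (>= 1 spike)
    to empty 1 ms bins across trials is compared against the 500 ms pre-cue
    background with a 2x2 test; a window is significant when p < ``alpha``
    and its filled proportion exceeds the background's.  ``test="exact"``
    (default) uses the exact conditional form of the chi-square comparison,
    which keeps its level at the sparse filled-bin counts typical of
    low-rate neurons; ``test="pearson"`` is the plain asymptotic statistic
    (1 df, no continuity correction).

    The response start is the middle of the first of ``min_onset_run``
    consecutive significant windows; the end is the middle of the last
    significant window in the block reachable from that run without a gap of
    ``max_gap`` consecutive non-significant windows.  ``is_responsive``
    additionally requires a run of ``min_responsive_run`` significant windows.
    """
    if sd.n_trials < 1:
        raise ValueError("at least one trial is required")
    lo, hi = search_range if search_range is not None else EVENT_RANGES[event]
    aligned = sd.aligned(event)

    bg_counts = _filled_bin_counts(sd.spikes, *BACKGROUND_WINDOW)
    n_bg = bg_counts.size * sd.n_trials
    if n_bg == 0:
        raise ValueError("empty background window")
    filled_bg = int(bg_counts.sum())

    counts = _filled_bin_counts(aligned, lo, hi)
    w = int(round(window_ms))
    starts = np.arange(0, counts.size - w + 1, int(round(step_ms)))
    csum = np.concatenate([[0], np.cumsum(counts)])
    filled_w = csum[starts + w] - csum[starts]
    n_w = w * sd.n_trials
    if test == "pearson":
        p = _chi2_2x2(filled_w, n_w - filled_w, filled_bg, n_bg - filled_bg)
    elif test == "exact":
        p = _exact_2x2(filled_w, n_w - filled_w, filled_bg, n_bg - filled_bg)
    else:
        raise ValueError(f"unknown test {test!r}")
    elevated = filled_w / n_w > filled_bg / n_bg
    sig = (p < alpha) & elevated
    window_starts = starts + lo

    max_run = int(max((e - s for s, e in _runs(sig)), default=0))
    onset_idx = None
    for s, e in _runs(sig):
        if e - s >= min_onset_run:
            onset_idx = s
            break
    if onset_idx is None:
        return ResponseWindow(
            event=event, start_ms=None, end_ms=None, is_responsive=False,
            p_values=p, window_starts=window_starts, significant=sig, max_run=max_run,
        )
    # walk forward from the onset run allowing short non-significant gaps
    last_sig = onset_idx
    gap = 0
    for i in range(onset_idx, sig.size):
        if sig[i]:
            last_sig = i
            gap = 0
        else:
            gap += 1
            if gap >= max_gap:
                break
    half = window_ms / 2.0
    return ResponseWindow(
        event=event,
        start_ms=float(window_starts[onset_idx] + half),
        end_ms=float(window_starts[last_sig] + half),
        is_responsive=bool(max_run >= min_responsive_run),
        p_values=p,
        window_starts=window_starts,
        significant=sig,
        max_run=max_run,
    )


def response_rate(sd: SpikeData, window: ResponseWindow) -> np.ndarray:
    """Per-trial firing rate (spikes/s) in the detected half-open window."""
    if window.start_ms is None:
        raise ValueError("window is empty (no detected response)")
    dur = window.end_ms - window.start_ms
    if dur <= 0:
        raise ValueError("zero-duration window")
    aligned = sd.aligned(window.event)
    counts = np.array(
        [int(np.count_nonzero((s >= window.start_ms) & (s < window.end_ms))) for s in aligned]
    )
    return counts / (dur / 1000.0)


# ---------------------------------------------------------------------------
# regression analyses
# ---------------------------------------------------------------------------

def _sprc(coef: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    sy = np.std(y, ddof=1)
    if sy == 0:
        return np.zeros_like(coef)
    return coef * np.std(X, axis=0, ddof=1) / sy


def _ols_fit(y: np.ndarray, X: np.ndarray, names: tuple[str, ...]) -> RegressionFit:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    coef = model.params[1:]
    return RegressionFit(
        names=names,
        coef=np.asarray(coef),
        sprc=_sprc(np.asarray(coef), X, y),
        pvalues=np.asarray(model.pvalues[1:]),
        r_squared=float(model.rsquared),
        n_trials=len(y),
    )


def fit_dv_regression(rates: np.ndarray, dv: np.ndarray) -> RegressionFit:
    """Single-regressor OLS of firing rate on discounted value.

    The reported r_squared equals the squared Pearson correlation between
    rate and DV (single-regressor identity); the coefficient p-value is the
    two-sided t-test of the slope.
    """
    rates = np.asarray(rates, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if np.unique(dv).size < 2:
        raise ValueError("DV regressor is constant; slope undefined")
    res = stats.linregress(dv, rates)
    coef = np.array([res.slope])
    X = dv[:, None]
    return RegressionFit(
        names=("dv",),
        coef=coef,
        sprc=_sprc(coef, X, rates),
        pvalues=np.array([res.pvalue]),
        r_squared=float(res.rvalue**2),
        n_trials=len(rates),
    )


def classify_neuron(
    rates: np.ndarray,
    delay: np.ndarray,
    size: np.ndarray,
    dv: np.ndarray,
    *,
    alpha: float = 0.05,
    cond_limit: float = 1e6,
) -> tuple[str, RegressionFit]:
    """Classify coding by the multiple regression of rate on delay, size, DV.

    Category: ``DV`` whenever the DV coefficient is significant (regardless
    of the others); ``Size_and_Delay`` when both size and delay but not DV
    are significant; ``Size`` / ``Delay`` when exclusively one is; ``NA``
    otherwise.  No multiplicity correction is applied.
    """
    X = np.column_stack([np.asarray(delay, float), np.asarray(size, float), np.asarray(dv, float)])
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("all regressors must vary")
    Z = (X - X.mean(axis=0)) / sds
    cond = np.linalg.cond(np.column_stack([np.ones(len(Z)), Z]))
    if cond > cond_limit:
        raise ValueError(
            f"design is rank-deficient (condition number {cond:.3g}); "
            "DV is collinear with delay and size for this condition set"
        )
    fit = _ols_fit(np.asarray(rates, dtype=float), X, ("delay", "size", "dv"))
    sig = fit.pvalues < alpha
    s_delay, s_size, s_dv = sig
    if s_dv:
        category = "DV"
    elif s_size and s_delay:
        category = "Size_and_Delay"
    elif s_size:
        category = "Size"
    elif s_delay:
        category = "Delay"
    else:
        category = "NA"
    return category, fit


def satiation_regression(rates: np.ndarray, dv: np.ndarray, rcum: np.ndarray) -> RegressionFit:
    """OLS of firing rate on discounted value and normalized cumulative reward."""
    rcum = np.asarray(rcum, dtype=float)
    if np.ptp(rcum) == 0:
        raise ValueError("rcum spans no range")
    X = np.column_stack([np.asarray(dv, float), rcum])
    return _ols_fit(np.asarray(rates, dtype=float), X, ("dv", "rcum"))


# ---------------------------------------------------------------------------
# time-resolved effect size
# ---------------------------------------------------------------------------

def dv_effect_timecourse(
    sd: SpikeData,
    dv: np.ndarray,
    alignment: str = "cue",
    *,
    window_ms: float = 200.0,
    step_ms: float = 10.0,
    t_range: tuple[float, float] | None = None,
) -> EffectSizeTimecourse:
    """Sliding-window DV effect size: per-step R^2 of rate-on-DV regression.

    Windows of ``window_ms`` stepped by ``step_ms`` over ``t_range`` (default
    per alignment event); windows with zero spike-count variance yield
    R^2 = 0 rather than being dropped.
    """
    lo, hi = t_range if t_range is not None else TIMECOURSE_RANGES[alignment]
    aligned = sd.aligned(alignment)
    dv = np.asarray(dv, dtype=float)
    n_bins = int(round(hi - lo))
    w = int(round(window_ms))
    starts = np.arange(0, n_bins - w + 1, int(round(step_ms)))
    # per-trial cumulative spike counts over 1 ms bins
    counts = np.zeros((len(aligned), len(starts)))
    for i, s in enumerate(aligned):
        hist = np.bincount(
            np.floor(s[(s >= lo) & (s < hi)] - lo).astype(np.int64), minlength=n_bins
        )
        csum = np.concatenate([[0], np.cumsum(hist)])
        counts[i] = csum[starts + w] - csum[starts]
    dvc = dv - dv.mean()
    denom_dv = np.sqrt(np.sum(dvc**2))
    cc = counts - counts.mean(axis=0, keepdims=True)
    denom_c = np.sqrt(np.sum(cc**2, axis=0))
    ok = (denom_c > 0) & (denom_dv > 0)
    r = np.zeros(len(starts))
    r[ok] = (dvc @ cc[:, ok]) / (denom_c[ok] * denom_dv)
    return EffectSizeTimecourse(
        alignment=alignment,
        times_ms=starts + lo + window_ms / 2.0,
        r2=r**2,
        window_ms=window_ms,
        step_ms=step_ms,
    )


# ---------------------------------------------------------------------------
# first/second-half comparison
# ---------------------------------------------------------------------------

def half_split_comparison(sd: SpikeData, window: ResponseWindow) -> pd.DataFrame:
    """First- vs second-half mean response per condition, normalized by the
    first-half mean of the immediate large-reward condition.

    Returns a frame indexed by (reward_size, delay_class) with columns
    ``first`` and ``second``; conditions missing from a half are NaN and
    logged.
    """
    rates = response_rate(sd, window)
    df = sd.trials[["reward_size", "delay_class"]].copy()
    df["rate"] = rates
    df["half"] = np.where(np.arange(len(df)) < len(df) / 2, "first", "second")
    means = df.groupby(["reward_size", "delay_class", "half"])["rate"].mean().unstack("half")
    means = means.reindex(columns=["first", "second"])
    norm_key = (df["reward_size"].max(), df.loc[df["reward_size"] == df["reward_size"].max(), "delay_class"].min())
    normalizer = means.loc[norm_key, "first"]
    if not np.isfinite(normalizer) or normalizer == 0:
        raise ValueError("normalizer condition (first-half immediate large) is empty or zero")
    if means.isna().any().any():
        logger.warning("neuron %s: some condition/half cells are empty", sd.neuron_id)
    return means / normalizer
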