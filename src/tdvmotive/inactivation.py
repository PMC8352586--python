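"""Session-normalized error-rate patterns and the bootstrap SSR test for
deviation from the normal discounting model."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior

logger = logging.getLogger(__name__)

#: columns identifying a condition cell in a per-session rate frame
CONDITION_KEYS = ("reward_size", "delay_class", "delay_mean_s", "rcum_bin")


@dataclass
class BootstrapResult:
    """Null SSR distribution, observed SSR, and the add-one p-value."""

    model_name: str
    n_resamples: int
    resample_size: int
    ssr_null: np.ndarray = field(repr=False)
    ssr_observed: float = 0.0
    p_value: float = 1.0
    seed: int = 0
    n_redrawn: int = 0

    def quantiles(self, q=(0.5, 0.95, 0.99)) -> dict[float, float]:
        return {float(x): float(v) for x, v in zip(q, np.quantile(self.ssr_null, q))}


def _condition_keys(df: pd.DataFrame) -> list[str]:
    return [k for k in CONDITION_KEYS if k in df.columns and df[k].notna().any()]


def normalize_sessions(rates: pd.DataFrame) -> pd.DataFrame:
    """Divide each session's per-condition error rates by its maximum rate.

    ``rates`` is long-format with columns ``session_id``, condition columns
    (``reward_size``, ``delay_class``/``delay_mean_s``, optional
    ``rcum_bin``) and ``error_rate``.  Sessions with zero errors everywhere
    are excluded with a warning.
    """
    out = []
    for sid, grp in rates.groupby("session_id", sort=True):
        mx = grp["error_rate"].max()
        if mx <= 0:
            logger.warning("session %s has no errors; excluded from normalization", sid)
            continue
        g = grp.copy()
        g["error_rate"] = g["error_rate"] / mx
        out.append(g)
    if not out:
        raise ValueError("no session with at least one error")
    return pd.concat(out, ignore_index=True)


def session_rate_table(trials: pd.DataFrame, *, by_quartile: bool = False) -> pd.DataFrame:
    """Per-session per-condition error rates from a multi-session trial table.

    Equivalent to :func:`tdvmotive.behavior.compute_error_rates` applied per
    session (asserted by tests), but computed in one grouped pass.
    """
    bad = ~trials["outcome"].isin(("correct", "early", "late"))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"row {trials.index[i]}: invalid outcome {trials['outcome'].iloc[i]!r}"
        )
    df = trials.copy()
    df["_err"] = (df["outcome"] != "correct").astype(int)
    keys = ["session_id", "reward_size", "delay_class", "delay_mean_s"]
    if by_quartile:
        rc = df["rcum"].to_numpy(dtype=float)
        q = np.minimum((rc * 4).astype(int), 3)
        df["rcum_bin"] = np.asarray(behavior.QUARTILE_MIDPOINTS)[q]
        keys.append("rcum_bin")
    agg = {"n_trials": ("_err", "size"), "n_errors": ("_err", "sum")}
    if "treatment" in df.columns:
        agg["treatment"] = ("treatment", "first")
    out = df.groupby(keys, sort=True).agg(**agg).reset_index()
    out["error_rate"] = out["n_errors"] / out["n_trials"]
    return out


def mean_condition_rates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Average normalized rates across sessions, per condition."""
    keys = _condition_keys(normalized)
    return normalized.groupby(keys, as_index=False, sort=True)["error_rate"].mean()


def bootstrap_ssr_test(
    baseline: pd.DataFrame,
    test_mean: pd.DataFrame,
    model_name: str = "hyperbolic",
    *,
    n_resamples: int = 20000,
    resample_size: int = 5,
    seed: int = 0,
    method: str = "resample_sessions",
    n_trials_per_condition: int = 20,
    fit_starts: int = 3,
    **fit_kwargs,
) -> BootstrapResult:
    """Locate a test pattern's best-fit SSR in a resampled-baseline null.

    Each of ``n_resamples`` resamples draws ``resample_size`` baseline
    sessions with replacement (sessions ordered by id, so the test is
    invariant to input row order), averages their normalized per-condition
    rates, and refits ``model_name`` from scratch; the null is the
    distribution of those best-fit SSRs.  ``ssr_observed`` is the best-fit
    SSR to ``test_mean`` (per-condition mean normalized rates of the test
    treatment).  The one-sided p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_resamples)``.

    ``method="simulate"`` instead simulates each resample from the model
    fitted to the pooled baseline mean plus binomial noise on
    ``n_trials_per_condition`` trials per condition (the alternative reading
    of a parametric bootstrap).
    """
    if model_name not in behavior.FREE_PARAMS or len(behavior.FREE_PARAMS[model_name]) != 2:
        raise ValueError("bootstrap_ssr_test supports the two-parameter models")
    keys = _condition_keys(baseline)
    wide = baseline.pivot_table(index="session_id", columns=keys, values="error_rate", sort=True)
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d baseline session(s) that did not observe every condition",
            int(incomplete.sum()),
        )
        wide = wide.loc[~incomplete]
    if len(wide) < resample_size:
        raise ValueError(
            f"baseline pool has {len(wide)} sessions; resample_size={resample_size}"
        )
    cond = pd.DataFrame(list(wide.columns), columns=keys)
    R = cond["reward_size"].to_numpy(dtype=float)
    D = (
        cond["delay_mean_s"].to_numpy(dtype=float)
        if "delay_mean_s" in cond
        else np.zeros(len(cond))
    )
    rcum = cond["rcum_bin"].to_numpy(dtype=float) if "rcum_bin" in cond else None
    mat = wide.to_numpy()

    rng = np.random.default_rng(seed)
    if method == "resample_sessions":
        idx = rng.integers(0, len(mat), size=(n_resamples, resample_size))
        Y = mat[idx].mean(axis=1)
    elif method == "simulate":
        pool_mean = mat.mean(axis=0)
        base_fit = behavior.fit_discount_model(
            pd.DataFrame(dict(reward_size=R, delay_mean_s=D, rcum_bin=rcum, error_rate=pool_mean)),
            model_name,
            **fit_kwargs,
        )
        p = behavior.predict_error_rate(
            model_name, R, D, rcum,
            k=base_fit.params.k, a=base_fit.params.a, lam=base_fit.params.lam,
            exponential_form=base_fit.exponential_form,
        )
        draws = rng.binomial(
            n_trials_per_condition, p, size=(n_resamples, resample_size, len(p))
        ) / n_trials_per_condition
        mx = draws.max(axis=2, keepdims=True)
        ok = mx[:, :, 0] > 0
        n_redrawn = int((~ok).sum())
        mx = np.where(mx > 0, mx, 1.0)
        Y = (draws / mx).mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")

    _, ssr_null = behavior.fit_batch(
        model_name, R, D, rcum, Y, seed=seed + 1, n_starts=fit_starts, **fit_kwargs
    )

    tm = test_mean.set_index(keys).loc[[tuple(c) if len(keys) > 1 else c for c in wide.columns]]
    y_obs = tm["error_rate"].to_numpy(dtype=float)[None, :]
    _, ssr_obs = behavior.fit_batch(
        model_name, R, D, rcum, y_obs, seed=seed + 2, n_starts=fit_starts, **fit_kwargs
    )
    ssr_observed = float(ssr_obs[0])
    p_value = (1.0 + np.count_nonzero(ssr_null >= ssr_observed)) / (1.0 + n_resamples)
    return BootstrapResult(
        model_name=model_name,
        n_resamples=n_resamples,
        resample_size=resample_size,
        ssr_null=np.asarray(ssr_null),
        ssr_observed=ssr_observed,
        p_value=float(p_value),
        seed=seed,
        n_redrawn=n_redrawn if method == "simulate" else 0,
    )


def trial_initiation_split(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean trial-initiation time in the first vs second half of each session.

    Initiation time is the interval from the previous trial's reward to the
    current trial's start, so the first trial of each session (no preceding
    reward) is excluded.  Returns one row per session and half; no test is
    performed here.
    """
    rows = []
    for sid, grp in trials.groupby("session_id", sort=True):
        g = grp.sort_values("trial_index").iloc[1:]
        g = g[g["initiation_time_s"].notna()]
        if len(g) < 4:
            raise ValueError(f"session {sid}: need >= 2 usable trials per half")
        half = np.where(np.arange(len(g)) < len(g) / 2, "first", "second")
        for h in ("first", "second"):
            sel = g["initiation_time_s"].to_numpy()[half == h]
            rows.append(
                {
                    "session_id": sid,
                    "half": h,
                    "mean_initiation_s": float(sel.mean()),
                    "n_trials": int(sel.size),
                }
            )
    return pd.DataFrame(rows)
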