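"""Discounting / satiation error-rate models, least-squares fitting, and model comparison.

The behavioral models relate per-condition error rates ``E`` to reward size
``R`` (drops), delay ``D`` (seconds) and normalized cumulative reward
``rcum`` in [0, 1]:

``hyperbolic``              E = (1 + k*D) / (a*R)
``exponential``             E = exp(-k*D) / (a*R)        (printed orientation)
                            E = exp(+k*D) / (a*R)        (value orientation)
``hyperbolic_satiation``    E = (1 + k*D) / (a*R) * F    (printed placement)
                            E = (1 + k*D) / (a*R) / F    (value placement)
``inverse_size_satiation``  E = 1 / (a*R*F)

with the satiation factor ``F(rcum) = exp(-lam*rcum)``.  Predictions are
clipped to [0, 1] before residual computation because error rates are
proportions.  Both orientations of the exponential model and both placements
of the satiation factor are exposed behind flags; the value placement makes
error rates rise with satiation and is the generative default elsewhere in
the package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "hyperbolic",
    "exponential",
    "hyperbolic_satiation",
    "inverse_size_satiation",
)

#: Free parameters fitted for each model, in optimizer order.
FREE_PARAMS = {
    "hyperbolic": ("k", "a"),
    "exponential": ("k", "a"),
    "hyperbolic_satiation": ("k", "a", "lam"),
    "inverse_size_satiation": ("a", "lam"),
}

#: Models whose prediction depends on normalized cumulative reward.
SATIATION_MODELS = ("hyperbolic_satiation", "inverse_size_satiation")

#: Midpoints of the four session quartiles of normalized cumulative reward.
QUARTILE_MIDPOINTS = (0.125, 0.375, 0.625, 0.875)

# log-uniform restart ranges for the multi-start optimizer
_RESTART_RANGES = {"k": (1e-3, 3.0), "a": (0.05, 50.0), "lam": (1e-2, 5.0)}


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (too few points, no convergence)."""


@dataclass(frozen=True)
class TrialCondition:
    """One reward-size x delay condition of the instrumental task."""

    reward_size: int
    delay_mean: float
    delay_class: int

    def __post_init__(self) -> None:
        if self.reward_size < 1:
            raise ValueError(f"reward_size must be >= 1, got {self.reward_size}")
        if self.delay_mean < 0:
            raise ValueError(f"delay_mean must be >= 0, got {self.delay_mean}")


@dataclass
class DiscountParams:
    """Discounting parameters: rate ``k`` (1/s), incentive scale ``a``
    (1/drops) and satiation decay ``lam`` (per unit normalized reward)."""

    k: float = 0.0
    a: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")


@dataclass
class ConditionErrorRate:
    """Observed error rate for one condition (optionally one rcum quartile)."""

    condition: TrialCondition
    n_trials: int
    n_errors: int
    error_rate: float
    rcum_bin: float | None = None

    def __post_init__(self) -> None:
        if self.n_errors > self.n_trials:
            raise ValueError("n_errors cannot exceed n_trials")


@dataclass
class DiscountFit:
    """Result of a least-squares model fit."""

    model_name: str
    params: DiscountParams
    ssr: float
    r_squared: float
    n_points: int
    satiation_form: str = "value"
    exponential_form: str = "printed"

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "k": self.params.k,
            "a": self.params.a,
            "lambda": self.params.lam,
            "ssr": self.ssr,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "satiation_form": self.satiation_form,
            "exponential_form": self.exponential_form,
        }


@dataclass
class ModelComparison:
    """Leave-one-session-out cross-validation comparison of two models."""

    models: tuple[str, str]
    per_fold_errors: dict[str, np.ndarray]
    preferred_model: str
    p_value: float


# ---------------------------------------------------------------------------
# model predictions
# ---------------------------------------------------------------------------

def hyperbolic_value(reward_size, delay, k):
    """Temporally discounted value ``R / (1 + k*D)`` (vectorized)."""
    R = np.asarray(reward_size, dtype=float)
    D = np.asarray(delay, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reward size must be positive")
    if np.any(D < 0):
        raise ValueError("delay must be nonnegative")
    if np.any(np.asarray(k) < 0):
        raise ValueError("k must be nonnegative")
    return R / (1.0 + np.asarray(k) * D)


def discounted_value(condition: TrialCondition, params: DiscountParams) -> float:
    """Discounted value of one condition under ``params`` (drops-equivalent)."""
    return float(hyperbolic_value(condition.reward_size, condition.delay_mean, params.k))


def satiation_factor(rcum, lam):
    """Satiation multiplier ``F(rcum) = exp(-lam * rcum)`` in (0, 1]."""
    rc = np.asarray(rcum, dtype=float)
    if np.any((rc < 0) | (rc > 1)):
        raise ValueError("rcum must lie in [0, 1]")
    if np.any(np.asarray(lam) < 0):
        raise ValueError("lam must be nonnegative")
    return np.exp(-np.asarray(lam) * rc)


def predict_error_rate(
    model_name: str,
    reward_size,
    delay,
    rcum=None,
    *,
    k: float = 0.0,
    a: float = 1.0,
    lam: float = 0.0,
    satiation_form: str = "value",
    exponential_form: str = "printed",
    clip: bool = True,
):
    """Predicted error proportion under ``model_name`` (vectorized).

    ``satiation_form`` selects where F(rcum) enters the satiation-extended
    delay model: ``"printed"`` multiplies the error rate by F (errors fall
    with satiation), ``"value"`` divides by F (errors rise with satiation).
    ``exponential_form`` selects the sign of the exponent of the exponential
    discounting model (``"printed"``: exp(-k*D); ``"value"``: exp(+k*D)).
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    R = np.asarray(reward_size, dtype=float)
    D = np.asarray(delay, dtype=float)
    if np.any(R < 1):
        raise ValueError("reward size must be >= 1")
    if np.any(D < 0):
        raise ValueError("delay must be nonnegative")
    if a <= 0:
        raise ValueError("a must be > 0")

    if model_name == "hyperbolic":
        pred = (1.0 + k * D) / (a * R)
    elif model_name == "exponential":
        if exponential_form == "printed":
            pred = np.exp(-k * D) / (a * R)
        elif exponential_form == "value":
            pred = np.exp(k * D) / (a * R)
        else:
            raise ValueError(f"unknown exponential_form {exponential_form!r}")
    else:
        if rcum is None:
            raise ValueError(f"model {model_name!r} requires rcum")
        F = satiation_factor(rcum, lam)
        if model_name == "inverse_size_satiation":
            pred = 1.0 / (a * R) / F
        elif satiation_form == "printed":
            pred = (1.0 + k * D) / (a * R) * F
        elif satiation_form == "value":
            pred = (1.0 + k * D) / (a * R) / F
        else:
            raise ValueError(f"unknown satiation_form {satiation_form!r}")
    if clip:
        pred = np.clip(pred, 0.0, 1.0)
    return pred


def error_rate_hyperbolic(condition: TrialCondition, params: DiscountParams) -> float:
    """Hyperbolic-discounting error rate ``(1 + k*D)/(a*R)`` clipped to [0, 1]."""
    return float(
        predict_error_rate(
            "hyperbolic", condition.reward_size, condition.delay_mean, k=params.k, a=params.a
        )
    )


def error_rate_exponential(
    condition: TrialCondition, params: DiscountParams, *, form: str = "printed"
) -> float:
    """Exponential-discounting error rate, clipped to [0, 1].

    ``form="printed"`` gives ``exp(-k*D)/(a*R)``; ``form="value"`` gives the
    orientation in which errors increase as the discounted value falls,
    ``exp(+k*D)/(a*R)``.
    """
    return float(
        predict_error_rate(
            "exponential",
            condition.reward_size,
            condition.delay_mean,
            k=params.k,
            a=params.a,
            exponential_form=form,
        )
    )


def error_rate_with_satiation(
    condition: TrialCondition, rcum: float, params: DiscountParams, *, form: str = "value"
) -> float:
    """Satiation-extended delayed-reward error rate, clipped to [0, 1]."""
    return float(
        predict_error_rate(
            "hyperbolic_satiation",
            condition.reward_size,
            condition.delay_mean,
            rcum,
            k=params.k,
            a=params.a,
            lam=params.lam,
            satiation_form=form,
        )
    )


def error_rate_reward_size(condition: TrialCondition, rcum: float, params: DiscountParams) -> float:
    """Reward-size-task error rate ``1/(a*R*F(rcum))``, clipped to [0, 1]."""
    return float(
        predict_error_rate(
            "inverse_size_satiation",
            condition.reward_size,
            condition.delay_mean,
            rcum,
            a=params.a,
            lam=params.lam,
        )
    )


def arcsine_transform(p):
    """Variance-stabilizing arcsine transform ``asin(sqrt(p))`` for proportions.

    Provided for exporting proportions to external ANOVA; never used inside
    model fitting.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(arr))


# ---------------------------------------------------------------------------
# observed error rates
# ---------------------------------------------------------------------------

_OUTCOMES = ("correct", "early", "late")


def compute_error_rates(
    trials: pd.DataFrame, *, by_quartile: bool = False
) -> list[ConditionErrorRate]:
    """Per-condition observed error rates from a trial table.

    Errors are early plus late releases over all trials of the group
    (post-error repeats count as ordinary trials).  With ``by_quartile`` the
    trials are additionally split into four bins of normalized cumulative
    reward, reported at the bin midpoints 0.125/0.375/0.625/0.875.
    """
    bad = ~trials["outcome"].isin(_OUTCOMES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"row {trials.index[i]}: invalid outcome {trials['outcome'].iloc[i]!r}"
        )
    df = trials.copy()
    keys = ["reward_size", "delay_class", "delay_mean_s"]
    if by_quartile:
        rc = df["rcum"].to_numpy(dtype=float)
        if np.any((rc < 0) | (rc > 1)):
            raise ValueError("rcum must lie in [0, 1] for quartile binning")
        q = np.minimum((rc * 4).astype(int), 3)
        df["rcum_bin"] = np.asarray(QUARTILE_MIDPOINTS)[q]
        keys = keys + ["rcum_bin"]

    out: list[ConditionErrorRate] = []
    for key, grp in df.groupby(keys, sort=True):
        n = len(grp)
        n_err = int((grp["outcome"] != "correct").sum())
        cond = TrialCondition(
            reward_size=int(key[0]), delay_mean=float(key[2]), delay_class=int(key[1])
        )
        out.append(
            ConditionErrorRate(
                condition=cond,
                n_trials=n,
                n_errors=n_err,
                error_rate=n_err / n,
                rcum_bin=float(key[3]) if by_quartile else None,
            )
        )
    return out


def rates_to_frame(rates: Sequence[ConditionErrorRate]) -> pd.DataFrame:
    """Tabulate a list of :class:`ConditionErrorRate` for fitting or export."""
    return pd.DataFrame(
        {
            "reward_size": [r.condition.reward_size for r in rates],
            "delay_class": [r.condition.delay_class for r in rates],
            "delay_mean_s": [r.condition.delay_mean for r in rates],
            "n_trials": [r.n_trials for r in rates],
            "n_errors": [r.n_errors for r in rates],
            "error_rate": [r.error_rate for r in rates],
            "rcum_bin": [r.rcum_bin for r in rates],
        }
    )


def _fit_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Extract (R, D, rcum, y) arrays from rate records or a data frame."""
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = rates_to_frame(list(data))
    if "n_trials" in df.columns:
        keep = df["n_trials"].to_numpy() > 0
        if not keep.all():
            logger.warning("dropping %d empty condition group(s) from fit", (~keep).sum())
            df = df.loc[keep]
    R = df["reward_size"].to_numpy(dtype=float)
    D = df["delay_mean_s"].to_numpy(dtype=float)
    y = df["error_rate"].to_numpy(dtype=float)
    rcum = None
    if "rcum_bin" in df.columns and df["rcum_bin"].notna().all():
        rcum = df["rcum_bin"].to_numpy(dtype=float)
    return R, D, rcum, y


def _r_squared(y: np.ndarray, ssr: float) -> float:
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot <= 1e-300:
        return 1.0 if ssr <= 1e-12 else 0.0
    return 1.0 - ssr / sstot


def _hyperbolic_nnls(R, D, y):
    """Global least squares for the hyperbolic model via its linear form.

    ``E = u*(1/R) + v*(D/R)`` with ``u = 1/a >= 0`` and ``v = k/a >= 0`` is
    linear in (u, v), so nonnegative least squares gives the exact optimum of
    the unclipped objective.
    """
    X = np.column_stack([1.0 / R, D / R])
    coef, _ = optimize.nnls(X, y)
    u, v = coef
    pred = X @ coef
    return u, v, pred


def fit_discount_model(
    data,
    model_name: str,
    *,
    satiation_form: str = "value",
    exponential_form: str = "printed",
    n_restarts: int = 20,
    seed: int = 0,
    clip: bool = True,
) -> DiscountFit:
    """Least-squares fit of one error-rate model to observed rates.

    ``data`` is a sequence of :class:`ConditionErrorRate` or an equivalent
    data frame (columns ``reward_size, delay_mean_s, error_rate`` and
    ``rcum_bin`` for satiation models).  The optimizer is a bounded
    multi-start Nelder-Mead in log-parameter space (``n_restarts`` restarts
    drawn log-uniformly, seeded), with an exact nonnegative-least-squares
    shortcut for the hyperbolic model whenever clipping is inactive there.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    R, D, rcum, y = _fit_arrays(data)
    names = FREE_PARAMS[model_name]
    if len(y) < len(names):
        raise FitError(
            f"{model_name}: {len(y)} data points for {len(names)} free parameters"
        )
    if np.any((y < 0) | (y > 1)):
        raise ValueError("observed error rates must lie in [0, 1]")
    if model_name in SATIATION_MODELS and rcum is None:
        raise FitError(f"{model_name}: rcum_bin values are required")

    def predict(params: dict) -> np.ndarray:
        return predict_error_rate(
            model_name,
            R,
            D,
            rcum,
            satiation_form=satiation_form,
            exponential_form=exponential_form,
            clip=clip,
            **params,
        )

    def ssr_of(params: dict) -> float:
        return float(np.sum((y - predict(params)) ** 2))

    best_params: dict | None = None
    best_ssr = np.inf

    # exact shortcut: unclipped global optimum of the hyperbolic model; safe to
    # return only when the clip cannot bind at the optimum (all predictions and
    # all observations comfortably below 1 -- saturating a prediction at 1 can
    # otherwise lower the clipped objective even when the NNLS fit stays < 1)
    if model_name == "hyperbolic":
        u, v, pred = _hyperbolic_nnls(R, D, y)
        if u > 1e-12:
            cand = {"k": v / u, "a": 1.0 / u}
            if (not clip) or np.all(pred <= 1.0 + 1e-12):
                s = ssr_of(cand)
                best_params, best_ssr = cand, s
                if (not clip) or (np.all(pred < 0.9) and np.all(y < 0.9)):
                    return _make_fit(
                        model_name, cand, s, y, satiation_form, exponential_form
                    )

    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        params = {n: float(np.exp(t)) for n, t in zip(names, theta)}
        return ssr_of(params)

    starts = []
    if best_params is not None:
        starts.append(np.log([max(best_params[n], 1e-8) for n in names]))
    # heuristic start from crude moment matching
    a0 = float(np.clip(1.0 / (max(y.mean(), 1e-3) * R.mean()), 0.05, 50.0))
    heur = {"k": 0.1, "a": a0, "lam": 0.5}
    starts.append(np.log([heur[n] for n in names]))
    for _ in range(max(n_restarts - len(starts), 0)):
        starts.append(
            np.array(
                [
                    rng.uniform(np.log(_RESTART_RANGES[n][0]), np.log(_RESTART_RANGES[n][1]))
                    for n in names
                ]
            )
        )

    n_ok = 0
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 4000, "maxfev": 6000},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best_ssr:
                best_ssr = float(res.fun)
                best_params = {n: float(np.exp(t)) for n, t in zip(names, res.x)}
    if best_params is None or n_ok == 0:
        raise FitError(f"{model_name}: optimizer failed on all {len(starts)} restarts")

    return _make_fit(model_name, best_params, best_ssr, y, satiation_form, exponential_form)


def _make_fit(model_name, params, ssr, y, satiation_form, exponential_form) -> DiscountFit:
    full = {"k": 0.0, "a": 1.0, "lam": 0.0}
    full.update(params)
    return DiscountFit(
        model_name=model_name,
        params=DiscountParams(**full),
        ssr=ssr,
        r_squared=_r_squared(y, ssr),
        n_points=len(y),
        satiation_form=satiation_form,
        exponential_form=exponential_form,
    )


# ---------------------------------------------------------------------------
# leave-one-session-out cross-validation
# ---------------------------------------------------------------------------

def _pool_rates(rate_sets: Iterable[Sequence[ConditionErrorRate]]) -> list[ConditionErrorRate]:
    """Pool per-session rate records by condition, combining trial counts."""
    acc: dict[tuple, list[int]] = {}
    conds: dict[tuple, ConditionErrorRate] = {}
    for rates in rate_sets:
        for r in rates:
            key = (r.condition.reward_size, r.condition.delay_class, r.condition.delay_mean, r.rcum_bin)
            if key not in acc:
                acc[key] = [0, 0]
                conds[key] = r
            acc[key][0] += r.n_trials
            acc[key][1] += r.n_errors
    out = []
    for key, (n, e) in sorted(acc.items()):
        ref = conds[key]
        out.append(
            ConditionErrorRate(
                condition=ref.condition,
                n_trials=n,
                n_errors=e,
                error_rate=e / n if n else np.nan,
                rcum_bin=ref.rcum_bin,
            )
        )
    return out


def loo_cv_compare(
    per_session_rates: Mapping[object, Sequence[ConditionErrorRate]],
    models: tuple[str, str] = ("hyperbolic", "exponential"),
    **fit_kwargs,
) -> ModelComparison:
    """Compare two models by leave-one-session-out cross-validation.

    Each fold holds out one session, fits both models to the remaining
    sessions' pooled rates, and scores the summed squared prediction error on
    the held-out session's observed rates.  The preferred model has the lower
    mean fold error; the p-value is a two-sided paired Wilcoxon signed-rank
    test across folds.
    """
    sessions = list(per_session_rates)
    if len(sessions) < 3:
        raise ValueError(f"need >= 3 sessions for cross-validation, got {len(sessions)}")
    errors: dict[str, list[float]] = {m: [] for m in models}
    for held in sessions:
        train = _pool_rates(
            per_session_rates[s] for s in sessions if s is not held and s != held
        )
        test = per_session_rates[held]
        Rt = np.array([r.condition.reward_size for r in test], dtype=float)
        Dt = np.array([r.condition.delay_mean for r in test], dtype=float)
        rct = np.array(
            [np.nan if r.rcum_bin is None else r.rcum_bin for r in test], dtype=float
        )
        yt = np.array([r.error_rate for r in test], dtype=float)
        for m in models:
            fit = fit_discount_model(train, m, **fit_kwargs)
            pred = predict_error_rate(
                m,
                Rt,
                Dt,
                rct if m in SATIATION_MODELS else None,
                k=fit.params.k,
                a=fit.params.a,
                lam=fit.params.lam,
                satiation_form=fit.satiation_form,
                exponential_form=fit.exponential_form,
            )
            errors[m].append(float(np.sum((yt - pred) ** 2)))
    err_arr = {m: np.asarray(v) for m, v in errors.items()}
    means = {m: float(v.mean()) for m, v in err_arr.items()}
    preferred = min(models, key=lambda m: means[m])
    diff = err_arr[models[0]] - err_arr[models[1]]
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)
    return ModelComparison(
        models=tuple(models), per_fold_errors=err_arr, preferred_model=preferred, p_value=p
    )


# ---------------------------------------------------------------------------
# batched fitting (used by the bootstrap test, which refits thousands of
# resampled data sets)
# ---------------------------------------------------------------------------

def _nm_batch(func, x0: np.ndarray, n_iter: int = 220) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Nelder-Mead over a batch of small problems.

    ``func(theta, prob_idx)`` maps an (N, d) parameter array plus the (N,)
    array of problem indices to an (N,) objective array; one simplex per
    problem is iterated in lockstep with masked accept rules.  Returns the
    best vertex and value per problem.
    """
    B, d = x0.shape
    all_idx = np.arange(B)
    simplex = np.repeat(x0[:, None, :], d + 1, axis=1)
    for j in range(d):
        simplex[:, j + 1, j] += 0.5
    fv = func(simplex.reshape(-1, d), np.repeat(all_idx, d + 1)).reshape(B, d + 1)
    for _ in range(n_iter):
        order = np.argsort(fv, axis=1)
        fv = np.take_along_axis(fv, order, axis=1)
        simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)
        centroid = simplex[:, :d, :].mean(axis=1)
        worst = simplex[:, d, :]
        xr = centroid + (centroid - worst)
        fr = func(xr, all_idx)
        xe = centroid + 2.0 * (centroid - worst)
        fe = func(xe, all_idx)
        xc = centroid + 0.5 * (worst - centroid)
        fc = func(xc, all_idx)
        f_best, f_second, f_worst = fv[:, 0], fv[:, d - 1], fv[:, d]
        use_e = (fr < f_best) & (fe < fr)
        use_r = ((fr < f_second) & ~use_e) | ((fr < f_best) & ~use_e)
        use_c = ~use_e & ~use_r & (fc < np.minimum(fr, f_worst))
        new = np.where(
            use_e[:, None], xe, np.where(use_r[:, None], xr, np.where(use_c[:, None], xc, worst))
        )
        newf = np.where(use_e, fe, np.where(use_r, fr, np.where(use_c, fc, f_worst)))
        shrink = ~(use_e | use_r | use_c)
        simplex[:, d, :] = new
        fv[:, d] = newf
        if shrink.any():
            idx = np.flatnonzero(shrink)
            shr = simplex[idx]
            shr[:, 1:, :] = shr[:, :1, :] + 0.5 * (shr[:, 1:, :] - shr[:, :1, :])
            simplex[idx] = shr
            fv[idx, 1:] = func(
                shr[:, 1:, :].reshape(-1, d), np.repeat(idx, d)
            ).reshape(len(idx), d)
    i = np.argmin(fv, axis=1)
    return simplex[np.arange(B), i], fv[np.arange(B), i]


def fit_batch(
    model_name: str,
    R: np.ndarray,
    D: np.ndarray,
    rcum: np.ndarray | None,
    Y: np.ndarray,
    *,
    seed: int = 0,
    n_starts: int = 3,
    n_iter: int = 220,
    satiation_form: str = "value",
    exponential_form: str = "printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a two-parameter model to many rate vectors at once.

    ``Y`` is (B, n_conditions); returns parameter array (B, 2) in
    ``FREE_PARAMS[model_name]`` order and the SSR vector (B,).  Supports the
    two-parameter models only (hyperbolic, exponential,
    inverse_size_satiation); predictions are clipped to [0, 1] as in
    :func:`fit_discount_model`.
    """
    names = FREE_PARAMS[model_name]
    if len(names) != 2:
        raise ValueError(f"fit_batch supports two-parameter models, not {model_name!r}")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    R = np.asarray(R, dtype=float)
    D = np.asarray(D, dtype=float)

    def predict(theta: np.ndarray) -> np.ndarray:
        p0 = np.exp(theta[:, 0])[:, None]
        p1 = np.exp(theta[:, 1])[:, None]
        if model_name == "hyperbolic":
            pred = (1.0 + p0 * D[None, :]) / (p1 * R[None, :])
        elif model_name == "exponential":
            sign = -1.0 if exponential_form == "printed" else 1.0
            pred = np.exp(sign * p0 * D[None, :]) / (p1 * R[None, :])
        else:  # inverse_size_satiation: names = (a, lam)
            pred = np.exp(p1 * rcum[None, :]) / (p0 * R[None, :])
        return np.clip(pred, 0.0, 1.0)

    def objective(theta: np.ndarray, prob_idx: np.ndarray) -> np.ndarray:
        pred = predict(theta)
        return np.sum((Yrep[prob_idx] - pred) ** 2, axis=1)

    rng = np.random.default_rng(seed)
    ycl = np.clip(Y, 1e-4, None)
    if model_name == "inverse_size_satiation":
        # log(y*R) = lam*rcum - log(a)
        X = np.column_stack([np.ones(n), rcum])
        coef, *_ = np.linalg.lstsq(X, np.log(ycl * R[None, :]).T, rcond=None)
        a0 = np.exp(-coef[0])
        lam0 = np.maximum(coef[1], 1e-4)
        warm = np.log(np.column_stack([np.clip(a0, 0.05, 50.0), np.clip(lam0, 1e-3, 5.0)]))
    elif model_name == "exponential":
        X = np.column_stack([np.ones(n), D])
        coef, *_ = np.linalg.lstsq(X, np.log(ycl * R[None, :]).T, rcond=None)
        sign = -1.0 if exponential_form == "printed" else 1.0
        k0 = np.maximum(sign * coef[1], 1e-4)
        a0 = np.exp(-coef[0])
        warm = np.log(np.column_stack([np.clip(k0, 1e-3, 3.0), np.clip(a0, 0.05, 50.0)]))
    else:
        # hyperbolic: nonneg normal equations on features (1/R, D/R)
        F = np.column_stack([1.0 / R, D / R])
        G = F.T @ F
        bmat = Y @ F  # (B, 2)
        sol = np.linalg.solve(G, bmat.T).T
        u = np.clip(sol[:, 0], 1e-6, None)
        v = np.clip(sol[:, 1], 1e-8, None)
        warm = np.log(np.column_stack([v / u, 1.0 / u]))

    # stack starts as independent problems, then reduce per original problem
    starts = [warm]
    for _ in range(n_starts - 1):
        starts.append(warm + rng.normal(0.0, 0.7, size=warm.shape))
    x0 = np.vstack(starts)
    Yrep = np.tile(Y, (n_starts, 1))

    xbest, fbest = _nm_batch(objective, x0, n_iter=n_iter)
    xbest = xbest.reshape(n_starts, B, 2)
    fbest = fbest.reshape(n_starts, B)
    pick = np.argmin(fbest, axis=0)
    theta = xbest[pick, np.arange(B), :]
    ssr = fbest[pick, np.arange(B)]
    return np.exp(theta), ssr
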