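"""Synthetic task sessions and spike trains with the statistical structure the
analyses assume: Bernoulli errors from the discounting model with
repeat-on-error, exponential satiation over cumulative reward, and
inhomogeneous Poisson spikes whose cue-response rate is linear in discounted
value."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import DiscountParams, TrialCondition, hyperbolic_value, predict_error_rate
from .spikes import SpikeData

logger = logging.getLogger(__name__)

CODING_CLASSES = ("positive_dv", "negative_dv", "non_dv_visual", "unresponsive", "size", "delay")


@dataclass(frozen=True)
class TaskSpec:
    """Structure of a cued instrumental task."""

    conditions: tuple[TrialCondition, ...]
    delay_jitter: dict[int, float]          # delay_class -> uniform half-range (s)
    response_window: tuple[float, float] = (0.2, 1.0)   # s after go
    iti: float = 1.0                        # s
    repeat_on_error: bool = True

    @classmethod
    def delayed_reward(cls, large_drops: int = 4) -> "TaskSpec":
        """Six-condition task: {1, large} drops x {0.3, 3.3, 6.9} s delays."""
        delays = [(0, 0.3, 0.1), (1, 3.3, 0.6), (2, 6.9, 1.2)]
        conds = tuple(
            TrialCondition(reward_size=r, delay_mean=d, delay_class=c)
            for r in (1, large_drops)
            for c, d, _ in delays
        )
        return cls(conditions=conds, delay_jitter={c: j for c, _, j in delays})

    @classmethod
    def reward_size(cls) -> "TaskSpec":
        """Four-condition task: {1, 2, 4, 8} drops, always immediate."""
        conds = tuple(
            TrialCondition(reward_size=r, delay_mean=0.3, delay_class=0) for r in (1, 2, 4, 8)
        )
        return cls(conditions=conds, delay_jitter={0: 0.1})


@dataclass
class BehaviorGenParams:
    """Generator settings for one behavioral session."""

    discount: DiscountParams = field(default_factory=lambda: DiscountParams(k=0.2, a=2.0, lam=1.0))
    early_fraction: float = 0.7
    stop_rule: tuple[str, float] = ("n_correct", 120)   # ("n_correct"|"n_trials"|"drops", N)
    max_trials: int = 5000
    satiation_form: str = "value"
    #: drops at which generative rcum reaches 1; None -> estimated from stop_rule
    reward_capacity: float | None = None
    p_error_cap: float = 0.95    # keeps repeat-on-error from jamming on clipped p=1 cells
    early_mean_s: float = 1.2
    early_sd_s: float = 0.5
    go_range_s: tuple[float, float] = (1.0, 2.0)   # cue -> go interval
    treatment: str = "baseline"

    def __post_init__(self) -> None:
        if not 0.0 <= self.early_fraction <= 1.0:
            raise ValueError("early_fraction must lie in [0, 1]")
        if self.stop_rule[0] not in ("n_correct", "n_trials", "drops"):
            raise ValueError(f"unknown stop rule {self.stop_rule[0]!r}")


@dataclass
class ResponseKernel:
    """Rectangular cue-response rate kernel (ms relative to cue onset)."""

    onset_ms: float = 100.0
    duration_ms: float = 600.0


@dataclass
class NeuronGenParams:
    baseline_rate: float = 1.0      # spikes/s, phasic projection-neuron regime (< 2)
    beta0: float = 10.0             # response intercept, spikes/s
    betaV: float = 5.0              # response slope per unit DV (or R / D for size/delay classes)
    kernel: ResponseKernel = field(default_factory=ResponseKernel)
    coding_class: str = "positive_dv"

    def __post_init__(self) -> None:
        if self.coding_class not in CODING_CLASSES:
            raise ValueError(f"unknown coding class {self.coding_class!r}")


def _estimate_capacity(task: TaskSpec, gen: BehaviorGenParams) -> float:
    mean_r = float(np.mean([c.reward_size for c in task.conditions]))
    rule, n = gen.stop_rule
    if rule == "drops":
        return float(n)
    if rule == "n_correct":
        return n * mean_r
    # total-trial stop: guess roughly half of trials end correct
    return 0.5 * n * mean_r


def generate_session(
    task: TaskSpec,
    gen: BehaviorGenParams,
    *,
    session_id: str = "s000",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one session as a trial table.

    Conditions are drawn uniformly, except that an error trial is repeated
    with the same condition.  The error probability of each trial is the
    satiation-extended discounting model evaluated at the generative
    normalized cumulative reward (delivered drops over ``reward_capacity``);
    the stored ``rcum`` column is renormalized by the session's realized
    total so it ends at 1.  Event times (go, release, reward) are in ms
    relative to cue onset; release is NaN on late errors, reward is NaN on
    all errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    capacity = gen.reward_capacity or _estimate_capacity(task, gen)
    rule, n_stop = gen.stop_rule

    rows = []
    p_cache: dict[tuple, float] = {}
    cum_drops = 0.0
    n_correct = 0
    prev_error = False
    prev_cond: TrialCondition | None = None
    prev_reward_gap = np.nan  # s from previous trial's reward to this trial start
    t_index = 0
    while True:
        if rule == "n_correct" and n_correct >= n_stop:
            break
        if rule == "n_trials" and t_index >= n_stop:
            break
        if rule == "drops" and cum_drops >= n_stop:
            break
        if t_index >= gen.max_trials:
            logger.warning(
                "session %s: stop rule %s not reached after %d trials; capping",
                session_id, gen.stop_rule, gen.max_trials,
            )
            break
        if task.repeat_on_error and prev_error and prev_cond is not None:
            cond = prev_cond
            is_repeat = 1
        else:
            cond = task.conditions[rng.integers(len(task.conditions))]
            is_repeat = 0

        rcum_gen = min(cum_drops / capacity, 1.0)
        # memoized on (condition, rcum to 1e-4): the error model is smooth in
        # rcum, and sessions revisit identical states constantly
        cache_key = (cond.delay_class, cond.reward_size, round(rcum_gen, 4))
        p_err = p_cache.get(cache_key)
        if p_err is None:
            p_err = min(
                float(
                    predict_error_rate(
                        "hyperbolic_satiation",
                        cond.reward_size,
                        cond.delay_mean,
                        round(rcum_gen, 4),
                        k=gen.discount.k,
                        a=gen.discount.a,
                        lam=gen.discount.lam,
                        satiation_form=gen.satiation_form,
                    )
                ),
                gen.p_error_cap,
            )
            p_cache[cache_key] = p_err

        go_ms = rng.uniform(*gen.go_range_s) * 1000.0
        initiation_s = float(rng.exponential(0.5) + 0.2) if t_index > 0 else np.nan
        if rng.random() < p_err:
            outcome = "early" if rng.random() < gen.early_fraction else "late"
            if outcome == "early":
                # premature release, peaking between cue and go
                hi = go_ms + task.response_window[0] * 1000.0
                rel = np.clip(
                    rng.normal(gen.early_mean_s * 1000.0, gen.early_sd_s * 1000.0), 100.0, hi
                )
                release_ms = float(rel)
            else:
                release_ms = np.nan
            reward_ms = np.nan
            delay_actual = np.nan
            prev_error = True
        else:
            outcome = "correct"
            rt = np.clip(
                rng.normal(0.35, 0.1),
                task.response_window[0] + 0.01,
                task.response_window[1] - 0.01,
            )
            release_ms = go_ms + rt * 1000.0
            jit = task.delay_jitter.get(cond.delay_class, 0.0)
            delay_actual = float(cond.delay_mean + rng.uniform(-jit, jit))
            reward_ms = release_ms + delay_actual * 1000.0
            cum_drops += cond.reward_size
            n_correct += 1
            prev_error = False
        rows.append(
            {
                "session_id": session_id,
                "trial_index": t_index,
                "reward_size": cond.reward_size,
                "delay_class": cond.delay_class,
                "delay_mean_s": cond.delay_mean,
                "delay_actual_s": delay_actual,
                "outcome": outcome,
                "is_repeat": is_repeat,
                "cum_reward_drops": cum_drops,
                "treatment": gen.treatment,
                "initiation_time_s": initiation_s,
                "go_ms": go_ms,
                "release_ms": release_ms,
                "reward_ms": reward_ms,
            }
        )
        prev_cond = cond
        t_index += 1

    df = pd.DataFrame(rows)
    total = df["cum_reward_drops"].iloc[-1] if len(df) else 0.0
    df["rcum"] = df["cum_reward_drops"] / total if total > 0 else 0.0
    cols = [
        "session_id", "trial_index", "reward_size", "delay_class", "delay_mean_s",
        "outcome", "is_repeat", "cum_reward_drops", "rcum", "treatment",
        "delay_actual_s", "initiation_time_s", "go_ms", "release_ms", "reward_ms",
    ]
    return df[cols]


def generate_sessions(
    task: TaskSpec,
    gen: BehaviorGenParams,
    n_sessions: int,
    *,
    seed: int = 0,
    calibrate_capacity: bool = True,
    n_pilot: int = 8,
) -> pd.DataFrame:
    """Simulate ``n_sessions`` sessions with deterministic per-session substreams.

    With ``calibrate_capacity`` the generative reward capacity is set to the
    mean total reward of a pilot batch, so the generative normalized
    cumulative reward matches the per-session normalization applied by the
    analyses (required for satiation-parameter recovery).
    """
    ss = np.random.SeedSequence(seed)
    if calibrate_capacity and gen.reward_capacity is None:
        pilot_rngs = [np.random.default_rng(s) for s in ss.spawn(n_pilot)]
        totals = [
            generate_session(task, gen, session_id=f"pilot{i}", seed=r)["cum_reward_drops"].iloc[-1]
            for i, r in enumerate(pilot_rngs)
        ]
        gen = replace(gen, reward_capacity=float(np.mean(totals)))
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_pilot + n_sessions)[n_pilot:]]
    frames = [
        generate_session(task, gen, session_id=f"s{i:03d}", seed=r)
        for i, r in enumerate(rngs)
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0) / 1000.0)
    return rng.uniform(t0, t1, n)


def _response_rate_hz(neuron: NeuronGenParams, R: float, D: float, dv: float) -> float:
    cls = neuron.coding_class
    if cls == "unresponsive":
        return 0.0
    if cls == "non_dv_visual":
        mod = neuron.beta0
    elif cls == "positive_dv":
        mod = neuron.beta0 + abs(neuron.betaV) * dv
    elif cls == "negative_dv":
        mod = neuron.beta0 - abs(neuron.betaV) * dv
    elif cls == "size":
        mod = neuron.beta0 + abs(neuron.betaV) * R
    else:  # delay
        mod = neuron.beta0 + abs(neuron.betaV) * D
    return max(mod, 0.0)  # rectification


def generate_spike_train(
    trials: pd.DataFrame,
    neuron: NeuronGenParams,
    dv_params: DiscountParams,
    *,
    neuron_id: str = "n000",
    seed: int | np.random.Generator = 0,
    pre_ms: float = 1000.0,
    post_ms: float = 500.0,
) -> SpikeData:
    """Inhomogeneous Poisson spikes for the correct trials of one session.

    Baseline rate everywhere from ``-pre_ms`` before cue to ``post_ms`` after
    reward, plus a rectangular cue-locked response kernel whose rate is
    linear in the trial's discounted value (or size / delay, or flat, per
    ``coding_class``).  Timestamps are ms relative to cue onset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ct = trials[trials["outcome"] == "correct"].reset_index(drop=True)
    if ct["reward_ms"].isna().any():
        raise ValueError("correct trials must carry reward event times")
    k_on = neuron.kernel.onset_ms
    k_off = k_on + neuron.kernel.duration_ms
    spikes: list[np.ndarray] = []
    for _, tr in ct.iterrows():
        t_end = float(tr["reward_ms"]) + post_ms
        if k_off > t_end:
            logger.warning("neuron %s: response kernel truncated at trial end", neuron_id)
        dv = float(hyperbolic_value(tr["reward_size"], tr["delay_mean_s"], dv_params.k))
        extra = _response_rate_hz(neuron, float(tr["reward_size"]), float(tr["delay_mean_s"]), dv)
        t = np.concatenate(
            [
                _poisson_times(rng, neuron.baseline_rate, -pre_ms, t_end),
                _poisson_times(rng, extra, k_on, min(k_off, t_end)),
            ]
        )
        spikes.append(np.sort(t))
    return SpikeData(neuron_id=neuron_id, trials=ct, spikes=spikes)


def generate_population(
    n_neurons: int,
    class_mix: dict[str, float],
    trials: pd.DataFrame,
    dv_params: DiscountParams,
    *,
    seed: int = 0,
    neuron_params: dict[str, NeuronGenParams] | None = None,
) -> list[tuple[SpikeData, str]]:
    """Labeled synthetic population sharing one session's trials.

    ``class_mix`` maps coding classes to proportions summing to 1; counts are
    apportioned by largest remainder.  Each neuron gets a deterministic
    substream of ``seed``, so two runs are byte-identical.
    """
    if n_neurons == 0:
        return []
    props = np.array(list(class_mix.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    classes = list(class_mix)
    raw = props * n_neurons
    counts = np.floor(raw).astype(int)
    rem = n_neurons - counts.sum()
    for i in np.argsort(raw - counts)[::-1][:rem]:
        counts[i] += 1
    labels = [c for c, n in zip(classes, counts) for _ in range(n)]
    defaults = neuron_params or {}
    out = []
    for i, (lab, sub) in enumerate(zip(labels, np.random.SeedSequence(seed).spawn(n_neurons))):
        npar = defaults.get(lab, NeuronGenParams(coding_class=lab))
        if npar.coding_class != lab:
            npar = replace(npar, coding_class=lab)
        sd = generate_spike_train(
            trials, npar, dv_params, neuron_id=f"n{i:03d}", seed=np.random.default_rng(sub)
        )
        out.append((sd, lab))
    return out
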