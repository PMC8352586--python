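"""End-to-end orchestration: simulate -> fit behavior -> detect responses ->
classify neurons -> bootstrap test, with a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, inactivation, io, spikes, synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    task: str = "delayed"               # "delayed" | "rewardsize"
    k: float = 0.2
    a: float = 2.0
    lam: float = 1.0
    n_sessions: int = 10
    n_test_sessions: int = 3
    n_trials_per_session: int = 120
    stop_rule: str = "n_correct"
    n_neurons: int = 8
    class_mix: dict = field(
        default_factory=lambda: {
            "positive_dv": 0.2, "negative_dv": 0.1, "non_dv_visual": 0.5, "unresponsive": 0.2,
        }
    )
    alpha: float = 0.05
    window_ms: float = 100.0
    step_ms: float = 10.0
    n_resamples: int = 2000
    resample_size: int = 5
    seed: int = 0
    out_dir: str = "pipeline_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def canonical(self) -> str:
        """Canonical JSON of the run semantics (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return json.dumps(d, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write all outputs plus a manifest.

    Returns a result bundle with the fitted behavior models, per-neuron
    classifications and the bootstrap test summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task = synth.TaskSpec.delayed_reward() if config.task == "delayed" else synth.TaskSpec.reward_size()
    params = behavior.DiscountParams(k=config.k, a=config.a, lam=config.lam)
    gen = synth.BehaviorGenParams(
        discount=params, stop_rule=(config.stop_rule, config.n_trials_per_session)
    )

    logger.info("simulating %d sessions (seed=%d)", config.n_sessions, config.seed)
    trials = synth.generate_sessions(task, gen, config.n_sessions, seed=config.seed)
    io.write_trials(trials, out / "trials.csv")

    # behavior fits on the pooled baseline sessions
    model = "hyperbolic" if config.task == "delayed" else "inverse_size_satiation"
    rates = behavior.compute_error_rates(trials, by_quartile=config.task != "delayed")
    fit = behavior.fit_discount_model(rates, model, seed=config.seed)
    fits = {model: fit.to_dict()}
    if config.task == "delayed":
        qrates = behavior.compute_error_rates(trials, by_quartile=True)
        fits["hyperbolic_satiation"] = behavior.fit_discount_model(
            qrates, "hyperbolic_satiation", seed=config.seed
        ).to_dict()
    (out / "behavior_fits.json").write_text(json.dumps(fits, indent=2))

    # spikes for the first session
    first = trials[trials["session_id"] == trials["session_id"].iloc[0]]
    population = synth.generate_population(
        config.n_neurons, config.class_mix, first, params, seed=config.seed + 1
    )
    io.write_spikes(population, out / "spikes.csv", out / "events.csv")

    neuron_records = []
    for sd, label in population:
        win = spikes.detect_response(
            sd, "cue", alpha=config.alpha, window_ms=config.window_ms, step_ms=config.step_ms
        )
        rec = {"neuron_id": sd.neuron_id, "true_class": label, "responsive": win.is_responsive}
        if win.is_responsive:
            rr = spikes.response_rate(sd, win)
            dv = behavior.hyperbolic_value(
                sd.trials["reward_size"], sd.trials["delay_mean_s"], fit.params.k
            )
            category, reg = spikes.classify_neuron(
                rr, sd.trials["delay_mean_s"], sd.trials["reward_size"], dv, alpha=config.alpha
            )
            rec.update(
                {
                    "window": {"start_ms": win.start_ms, "end_ms": win.end_ms},
                    "category": category,
                    "sprc": dict(zip(reg.names, reg.sprc.tolist())),
                }
            )
        else:
            rec["category"] = "NA"
        neuron_records.append(rec)
    (out / "neurons.json").write_text(json.dumps(neuron_records, indent=2))

    # bootstrap: last n_test_sessions play the role of the test treatment
    sess_rates = inactivation.session_rate_table(trials, by_quartile=config.task != "delayed")
    norm = inactivation.normalize_sessions(sess_rates)
    sids = sorted(norm["session_id"].unique())
    test_ids = sids[-config.n_test_sessions:]
    base = norm[~norm["session_id"].isin(test_ids)]
    test_mean = inactivation.mean_condition_rates(norm[norm["session_id"].isin(test_ids)])
    boot = inactivation.bootstrap_ssr_test(
        base,
        test_mean,
        model,
        n_resamples=config.n_resamples,
        resample_size=config.resample_size,
        seed=config.seed + 2,
    )
    boot_record = {
        "model_name": boot.model_name,
        "ssr_observed": boot.ssr_observed,
        "p_value": boot.p_value,
        "n_resamples": boot.n_resamples,
        "resample_size": boot.resample_size,
        "ssr_null_quantiles": boot.quantiles(),
    }
    (out / "bootstrap.json").write_text(json.dumps(boot_record, indent=2))

    config.to_yaml(out / "config.yaml")
    outputs = sorted(
        p.name
        for p in out.iterdir()
        if p.name not in ("manifest.json", "config.yaml") and p.is_file()
    )
    manifest = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "tdvmotive": __import__("tdvmotive").__version__,
        },
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"behavior_fits": fits, "neurons": neuron_records, "bootstrap": boot_record,
            "manifest": manifest}
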