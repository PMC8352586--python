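# tdvmotive

Models and analyses for cued instrumental delayed-reward tasks in which the
error rate is an inverse index of motivation:

* **Behavioral models** (`tdvmotive.behavior`) — hyperbolic / exponential
  temporal-discounting error-rate models, an exponential satiation factor
  over normalized cumulative reward, least-squares fitting with a seeded
  multi-start optimizer, and leave-one-session-out cross-validated model
  comparison.
* **Synthetic data** (`tdvmotive.synth`) — generative task sessions
  (Bernoulli errors from the discounting model, repeat-on-error, satiation)
  and inhomogeneous-Poisson spike trains whose cue response is linear in
  temporally discounted value (DV), with labeled populations for validating
  the classifiers.
* **Spike analysis** (`tdvmotive.spikes`) — sliding-window χ² detection of
  event-locked responses (filled/empty 1 ms bins vs a 500 ms pre-cue
  background), DV regression and standardized partial regression coefficient
  (SPRC) classification of neurons (DV / Size / Delay / Size-and-Delay /
  NA), time-resolved DV effect-size (R²) curves, satiation regression, and
  first/second-half response comparison.
* **Inactivation analysis** (`tdvmotive.inactivation`) — per-session
  max-normalized error-rate patterns and a bootstrap SSR test locating a
  test condition's best-fit residual in a resampled-baseline null.
* **Pipeline & I/O** (`tdvmotive.io`, `tdvmotive.pipeline`) —
  schema-validated CSV ingestion, YAML run configs, and an end-to-end
  orchestration that writes a reproducibility manifest.

## Command line

```sh
tdvmotive simulate --task delayed --k 0.2 --a 2 --lambda 1 \
    --n-sessions 10 --n-neurons 8 --seed 1 --out out/
tdvmotive fit-behavior --trials out/trials.csv --model hyperbolic --out fit.json
tdvmotive detect-responses --trials out/trials.csv --spikes out/spikes.csv \
    --events out/events.csv --out responses.json
tdvmotive classify-neurons --trials out/trials.csv --spikes out/spikes.csv \
    --events out/events.csv --k 0.2 --out neurons.json
tdvmotive dv-timecourse --trials out/trials.csv --spikes out/spikes.csv \
    --events out/events.csv --k 0.2 --alignment cue --out timecourse.csv
tdvmotive bootstrap-test --baseline baseline.csv --test inactivation.csv \
    --model hyperbolic --n 20000 --resample-size 5 --seed 1 --out boot.json
tdvmotive run --config config.yaml
```

## File formats

Trial tables are CSV with one row per trial: `session_id`, `trial_index`,
`reward_size` (drops), `delay_class`, `delay_mean_s`, `outcome`
(`correct`/`early`/`late`), `is_repeat`, `cum_reward_drops`, `rcum`
(normalized cumulative reward in [0, 1]), `treatment`
(`baseline`/`control`/`inactivation`), plus optional event columns in ms
relative to cue onset (`go_ms`, `release_ms`, `reward_ms`) and
`initiation_time_s`. Spike data split into a spikes CSV (`neuron_id`,
`session_id`, `trial_index`, `spike_time_ms`) and an events CSV
(`session_id`, `trial_index`, `cue_ms`, `go_ms`, `release_ms`, `reward_ms`).
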