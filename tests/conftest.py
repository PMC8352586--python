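import numpy as np
import pandas as pd
import pytest

from tdvmotive import behavior, synth


@pytest.fixture(scope="session")
def delayed_task():
    return synth.TaskSpec.delayed_reward()


@pytest.fixture(scope="session")
def flat_satiation_params():
    """Generator parameters with no satiation and no clipped cells."""
    return behavior.DiscountParams(k=0.5, a=6.0, lam=0.0)


@pytest.fixture(scope="session")
def session_trials(delayed_task, flat_satiation_params):
    """One 150-correct-trial session shared by spike-analysis tests."""
    gen = synth.BehaviorGenParams(
        discount=flat_satiation_params, stop_rule=("n_correct", 150)
    )
    return synth.generate_session(delayed_task, gen, session_id="s000", seed=11)


def poisson_spike_data(
    rng,
    n_trials=30,
    rate_fn=None,
    t0=-1000.0,
    t1=2100.0,
    go_ms=1000.0,
):
    """Homogeneous/piecewise-rate Poisson SpikeData with flat trial metadata.

    ``rate_fn`` maps trial index -> list of (start, stop, rate_hz) segments;
    default is 0.5 sp/s everywhere.
    """
    from tdvmotive.spikes import SpikeData

    spikes = []
    for i in range(n_trials):
        segs = rate_fn(i) if rate_fn else [(t0, t1, 0.5)]
        t = []
        for a, b, r in segs:
            n = rng.poisson(r * (b - a) / 1000.0)
            t.append(rng.uniform(a, b, n))
        spikes.append(np.sort(np.concatenate(t)))
    trials = pd.DataFrame(
        {
            "session_id": "s",
            "trial_index": np.arange(n_trials),
            "reward_size": 1,
            "delay_class": 0,
            "delay_mean_s": 0.3,
            "outcome": "correct",
            "rcum": np.linspace(0.01, 1.0, n_trials),
            "go_ms": go_ms,
            "release_ms": go_ms + 350.0,
            "reward_ms": go_ms + 650.0,
        }
    )
    return SpikeData(neuron_id="n", trials=trials, spikes=spikes)
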