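import numpy as np
import pytest

from ejectkin import fit_dp_curve, population_metrics
from ejectkin.simulate import default_config, simulate_ejection_times, synthesize_dp_trace

#: the headline experimental conditions (temperature °C, MgCl2 mM)
CONDITIONS = [(22.0, 10.0), (32.0, 10.0), (37.0, 10.0), (42.0, 10.0), (37.0, 5.0), (37.0, 20.0)]


@pytest.fixture(scope="session")
def condition_results():
    """Simulated + deconvolved DP curves for every headline condition.

    Computed once per session; keyed (temperature, mg) → (trace, fit, metrics).
    """
    out = {}
    for T, mg in CONDITIONS:
        cfg = default_config(T, mg, seed=1)
        events = simulate_ejection_times(cfg)
        trace = synthesize_dp_trace(events, n_physical=cfg.n_physical)
        fit = fit_dp_curve(trace, mode="auto")
        metrics = population_metrics(fit, trace)
        out[(T, mg)] = (trace, fit, metrics)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
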