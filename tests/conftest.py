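import numpy as np
import pytest

from labelkin import FitSpec, Model1Params
from labelkin.observables import BOUND_DIRECT, ObservableMap
from labelkin.preprocess import average_all_replicates, extract_baseline
from labelkin import synthetic as syn


@pytest.fixture
def fp_map() -> ObservableMap:
    """Typical FP observable: 60 mP free, 300 mP bound."""
    return ObservableMap(60.0, 300.0, BOUND_DIRECT)


@pytest.fixture
def small_platereader():
    """Reduced microplate design for fast fits: 4 protein concs + baseline."""
    return syn.platereader_std(
        seed=11,
        protein_ladder=(0.0, 900e-9, 225e-9, 56e-9, 14e-9),
        grid=np.arange(0.0, 7201.0, 300.0),
    )


def make_fitted_set(template, truth, obs_map):
    """generate -> average -> baseline; returns (averaged set, FitSpec kwargs)."""
    ts = syn.generate(template, truth, obs_map)
    av = average_all_replicates(ts)
    return av, extract_baseline(av)


@pytest.fixture
def model1_noisy_fit(small_platereader, fp_map):
    """A converged noisy model-1 global fit used by uncertainty tests."""
    from labelkin import global_fit

    truth = Model1Params(1.51e5)
    tpl = small_platereader.with_(noise_sd=3.0)
    av, r_free = make_fitted_set(tpl, truth, fp_map)
    spec = FitSpec(scheme="model1", r_free=r_free, n_starts=3)
    fit = global_fit(av, spec, fp_map)
    return av, spec, fit, truth
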