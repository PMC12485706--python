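import numpy as np
import pytest

from spindlelab import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nrem_config():
    """Short session pinned to NREM after one unavoidable wake epoch."""
    return sg.SynthConfig(total_duration=300.0,
                          state_dwell_means=(1e-9, np.inf, 1e-9), seed=0)


@pytest.fixture
def nrem_hypnogram(nrem_config):
    return sg.generate_hypnogram(nrem_config, 0)


def interval_f1(truth, detected, min_overlap=0.5):
    """Event-level F1 with a >=50%-of-truth overlap matching rule."""
    used, tp = set(), 0
    for s, e in truth:
        for j, (ds, de) in enumerate(detected):
            if j in used:
                continue
            if max(0.0, min(e, de) - max(s, ds)) >= min_overlap * (e - s):
                used.add(j)
                tp += 1
                break
    fp = len(detected) - len(used)
    fn = len(truth) - tp
    prec = tp / max(tp + fp, 1)
    rec = tp / max(tp + fn, 1)
    return 2 * prec * rec / max(prec + rec, 1e-12)
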