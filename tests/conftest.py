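import numpy as np
import pytest

import emgtremor as et
from emgtremor.preprocess import segment_study


@pytest.fixture(scope="session")
def subject_windows():
    """One subject's full six-task study, filtered and windowed."""
    profile = et.make_subject("s01", seed=0)
    recordings = et.generate_study([profile])
    filtered = [et.lowpass_filter(r) for r in recordings]
    return segment_study(filtered)


@pytest.fixture(scope="session")
def toy_two_class():
    """Tiny linearly separable window dataset: constant-offset channels."""
    rng = np.random.default_rng(42)
    n_per, l, d = 40, 10, 2
    Xa = 0.5 + 0.05 * rng.standard_normal((n_per, l, d))
    Xb = -0.5 + 0.05 * rng.standard_normal((n_per, l, d))
    X = np.concatenate([Xa, Xb])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    order = rng.permutation(2 * n_per)
    return X[order], y[order]
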