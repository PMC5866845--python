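import pytest

import pahteq as pq
from pahteq.synthetic import study_config


@pytest.fixture
def gjic_curves():
    """Dose-response curves passing exactly through the equi-effective doses
    (reference 1 uM, fluoranthene 10 uM, 1-methylanthracene 20 uM at 40 %
    GJIC inhibition)."""
    return {
        "B[a]P": pq.DoseResponseCurve("B[a]P", ((0.3, 15), (1, 40), (3, 60), (10, 75))),
        "Flthn": pq.DoseResponseCurve("Flthn", ((1, 10), (5, 28), (10, 40))),
        "1-MeA": pq.DoseResponseCurve("1-MeA", ((5, 15), (10, 28), (20, 40))),
    }


@pytest.fixture
def study_mixtures():
    """The three tested combinations: 1 uM reference + 1, 5, 10 uM 1:1 mix."""
    return [
        pq.MixtureSpec("combo_1", {"B[a]P": 1, "Flthn": 0.5, "1-MeA": 0.5}),
        pq.MixtureSpec("combo_5", {"B[a]P": 1, "Flthn": 2.5, "1-MeA": 2.5}),
        pq.MixtureSpec("combo_10", {"B[a]P": 1, "Flthn": 5.0, "1-MeA": 5.0}),
    ]


@pytest.fixture
def noiseless_config():
    return study_config(area_cv=0.0, ct_sd=0.0, response_cv=0.0)


@pytest.fixture
def noisy_config():
    return study_config()
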