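import numpy as np
import pandas as pd
import pytest

from freeassoc.norms import CueNorms
from freeassoc.params import SMPParameters


@pytest.fixture
def five_assoc_cue() -> CueNorms:
    """A fixed 5-association cue with long-tailed typicalities."""
    typ = np.array([0.5, 0.25, 0.12, 0.08, 0.05])
    return CueNorms(
        cue_id="sunset",
        lemmas=["orange", "beach", "evening", "glow", "dusk"],
        counts=(typ * 100).astype(int),
        typicalities=typ,
        n_respondents=100,
    )


@pytest.fixture
def moderate_params() -> SMPParameters:
    return SMPParameters(
        beta=-0.3, alpha_I=0.6, alpha_sign=1, s_mu=0.1, lam=0.6, tau0=0.4, tau_r=0.6
    )


@pytest.fixture
def raw_trials() -> pd.DataFrame:
    rows = [
        ("p1", "c1", "Sky", 1200.0),
        ("p2", "c1", "sky", 1500.0),
        ("p3", "c1", "skies", 900.0),
        ("p4", "c1", "pillow", 2000.0),
        ("p1", "c2", "blue", 1000.0),
        ("p2", "c2", "x", 1100.0),
        ("p3", "c2", "qwzrt", 1300.0),
        ("p4", "c2", "chores", 1250.0),
        ("p1", "c3", "", 0.0),
        ("p2", "c3", "chore", 1600.0),
    ]
    return pd.DataFrame(rows, columns=["participant_id", "cue_id", "response_raw", "rt_ms"])


@pytest.fixture
def small_lexicon() -> set[str]:
    return {"sky", "skies", "pillow", "blue", "chore", "chores", "cloud", "sea"}
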