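import numpy as np
import pytest

import nadbold as nb


@pytest.fixture(scope="session")
def session_10s():
    """One synthetic stimulated session with a 10-s afterdischarge,
    conditioned once and shared across tests (generation is the slow part)."""
    design = nb.SessionDesign(seed=42)
    truth = nb.LfpTruth(nad_duration=10.0)
    raw, _ = nb.generate_lfp(design, truth)
    cond = nb.condition(raw)
    base = nb.baseline_amplitude(cond, design.stim_onset)
    return {"design": design, "truth": truth, "raw": raw,
            "conditioned": cond, "baseline": base}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
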