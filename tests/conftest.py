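import numpy as np
import pytest

from repairmap.simulate import (
    DEFAULT_BASELINE_PROBS,
    SpectrumSpec,
    gen_edited_reads,
    gen_target_locus,
)


@pytest.fixture(scope="session")
def syn_locus():
    """A synthetic locus with planted small (4 bp, MH 2) and large (8 bp, MH 3)
    deletion sites, shared across tests."""
    return gen_target_locus(seed=3)


@pytest.fixture(scope="session")
def labeled_reads(syn_locus):
    """2,000 truth-labeled reads from the default spectrum (20% unedited)."""
    probs = {p: 0.8 * w for p, w in DEFAULT_BASELINE_PROBS.items()}
    probs["Unedited"] = 0.2
    spec = SpectrumSpec(pattern_probs=probs)
    return gen_edited_reads(syn_locus, spec, 2_000, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
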