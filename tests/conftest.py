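import numpy as np
import pytest

import epitarget as et


@pytest.fixture(scope="session")
def panel():
    return et.load_panel()


@pytest.fixture(scope="session")
def episignature():
    return et.load_episignature()


@pytest.fixture(scope="session")
def refs(panel):
    return et.synthetic_references(panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_truth_factory(panel):
    """SampleTruth with one flat methylation level at every panel CpG."""

    def make(level: float, sample_id: str = "s", label: str = "control"):
        return et.SampleTruth(
            sample_id=sample_id,
            label=label,
            true_methylation={
                p: float(level) for a in panel for p in a.encompassed_cpgs
            },
        )

    return make
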