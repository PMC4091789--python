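import numpy as np
import pytest

from phorcmap import PipelineParams, ProbeLayout
from phorcmap.synthetic_data import default_pho_pwm


@pytest.fixture
def params():
    return PipelineParams()


@pytest.fixture
def default_pwm():
    return default_pho_pwm()


@pytest.fixture
def toy_pwm():
    """Width-2 PWM: pos1 prefers C (0.5), pos2 prefers A (0.5), others 1/6."""
    from phorcmap.motif_analysis import PWM

    probs = np.array(
        [
            [1 / 6, 0.5, 1 / 6, 1 / 6],
            [0.5, 1 / 6, 1 / 6, 1 / 6],
        ]
    )
    return PWM(probs)


def make_layout(n, spacing=36, length=25, chrom="chr1", start0=0):
    starts = start0 + spacing * np.arange(n)
    return ProbeLayout([chrom] * n, starts, [length] * n)


@pytest.fixture
def layout_factory():
    return make_layout
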