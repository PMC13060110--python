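import numpy as np
import pytest

from swcapacity import ChannelFit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fit(coefficients, noise_variance, order=None) -> ChannelFit:
    """Assemble a ChannelFit directly from taps and noise power, for
    exercising the capacity engine without a regression."""
    coefficients = np.asarray(coefficients, float)
    return ChannelFit(
        order=order or coefficients.size,
        coefficients=coefficients,
        noise_variance=noise_variance,
        residuals=np.zeros(2),
        prediction=np.zeros(2),
        n_used=2,
    )
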