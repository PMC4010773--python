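import numpy as np


def random_symmetric_weights(rng, n, low=0.05, high=0.95):
    """A dense random symmetric zero-diagonal weight matrix in [low, high]."""
    a = rng.uniform(low, high, size=(n, n))
    w = np.triu(a, 1)
    return w + w.T
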