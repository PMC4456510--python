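import numpy as np

from virduet import DistributionSummary


def two_bin_summary(probs, window=1.5):
    """Distribution summary with the given bin probabilities."""
    probs = np.asarray(probs, dtype=float)
    edges = np.linspace(0.0, window, probs.size + 1)
    width = np.diff(edges)
    dens = probs / probs.sum() / width
    z = np.zeros_like(dens)
    return DistributionSummary(edges, dens, z, z, 0.0, 100)
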