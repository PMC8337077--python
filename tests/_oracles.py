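"""Small independent oracles shared across test modules."""

import numpy as np


def sequential_inclusion_probs(weights, k):
    """Inclusion probabilities of sequential weighted draws without replacement.

    Exhaustive enumeration over all draw orders; the reference for both the
    exponential-key sampler and the fitness-weighted cull.
    """
    n = len(weights)
    probs = np.zeros(n)

    def recurse(remaining, chosen, p):
        if len(chosen) == k:
            for i in chosen:
                probs[i] += p
            return
        tot = sum(weights[i] for i in remaining)
        for i in list(remaining):
            if weights[i] > 0:
                recurse(remaining - {i}, chosen + [i], p * weights[i] / tot)

    recurse(frozenset(range(n)), [], 1.0)
    return probs
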