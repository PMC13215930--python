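import numpy as np


def mean_congruence(recovered, planted):
    """Mean |Tucker congruence| after best column matching (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    phi = np.zeros((planted.shape[1], recovered.shape[1]))
    for a in range(planted.shape[1]):
        for b in range(recovered.shape[1]):
            x, y = planted[:, a], recovered[:, b]
            phi[a, b] = abs(x @ y) / np.sqrt((x @ x) * (y @ y))
    rows, cols = linear_sum_assignment(-phi)
    return float(phi[rows, cols].mean())
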