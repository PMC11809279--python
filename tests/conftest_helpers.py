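"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the 2x2 singular values
come from the characteristic polynomial of M^T M, not from any SVD routine.
"""

import math

import numpy as np


def svd_2x2_closed_form(M):
    """Singular values of a 2x2 matrix in closed form (descending)."""
    (a, b), (c, d) = np.asarray(M, dtype=float)
    s1 = a * a + b * b + c * c + d * d
    det = a * d - b * c
    disc = math.sqrt(max(s1 * s1 - 4.0 * det * det, 0.0))
    sig1 = math.sqrt((s1 + disc) / 2.0)
    sig2 = math.sqrt(max((s1 - disc) / 2.0, 0.0))
    return np.array([sig1, sig2]), det
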