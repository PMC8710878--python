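"""Linear-scale scalar-variability psychophysics of quantity comparison.

A quantity ``n`` is mentally represented as a Gaussian with mean ``n`` and
standard deviation ``w * n``, where ``w`` is the species' Weber fraction.
Comparing two quantities amounts to ordering two independent Gaussian draws,
so the probability of a correct two-alternative judgement has the probit
closed form

    P(correct) = Phi(|n1 - n2| / (w * sqrt(n1**2 + n2**2)))

which depends on the pair only through its ratio (Weber's law) and is
always in [0.5, 1).  The threshold reading of ``w`` — the proportional
difference needed for reliable discrimination — is provided by
:func:`discrimination_bound`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr


def predict_accuracy(n1, n2, w):
    """Probability of correctly ordering quantities ``n1`` and ``n2``.

    Vectorized over ``n1``/``n2``; symmetric in the two quantities; returns
    exactly 0.5 for equal pairs.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("quantities must be >= 1")
    w = float(w)
    if w <= 0:
        raise ValueError("Weber fraction must be positive")
    p = ndtr(np.abs(n1 - n2) / (w * np.hypot(n1, n2)))
    # keep strictly below 1 so log(1 - p) stays finite downstream
    p = np.minimum(p, 1.0 - 1e-16)
    return p if p.ndim else float(p)


def discrimination_bound(reference: int, w: float) -> int:
    """Smallest integer m > reference with (m - reference)/reference >= w.

    The threshold interpretation of the Weber fraction: w = 0.2 means a
    reference of 10 is reliably discriminable from 12 but nothing finer;
    w = 0.5 pushes that to 15.  Integer granularity floors the answer at
    reference + 1.
    """
    if reference < 1:
        raise ValueError("reference must be a positive integer")
    if w <= 0:
        raise ValueError("Weber fraction must be positive")
    # small fuzz so 0.2 * 10 (float 2.0000000000000004) still yields 12
    step = math.ceil(w * reference - 1e-9)
    return reference + max(step, 1)
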