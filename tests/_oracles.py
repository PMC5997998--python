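"""Independent scalar oracle for the piecewise position-score equations.

A literal case-by-case transcription of the published score map,
deliberately kept free of the production code's profile objects and
branch bookkeeping so the two paths can disagree.
"""

from __future__ import annotations

import math

import numpy as np


def lambda_oracle(
    kappa: float,
    q2a: float,
    q2b: float,
    mina: float,
    maxa: float,
    minb: float,
    maxb: float,
) -> float:
    """Position score for one transcript, evaluated case by case."""
    eps = 1 if q2a < q2b else -1
    if eps == 1:
        lower_max, upper_min = maxa, minb
    else:
        lower_max, upper_min = maxb, mina
    theta = upper_min - lower_max
    if theta > 0 and lower_max < kappa < upper_min:
        theta_c = 0.5 * (lower_max + upper_min)
        lam = 2.0 * eps * (theta_c - kappa) / theta
    else:
        da = abs(kappa - q2a)
        db = abs(kappa - q2b)
        if da == db:
            lam = 0.0
        else:
            delta = 1 if da < db else -1
            if delta == 1:
                q2, lo, hi = q2a, mina, maxa
            else:
                q2, lo, hi = q2b, minb, maxb
            if kappa == q2:
                lam = 1.5 * delta
            elif kappa < q2:
                denom = 2.0 * abs(lo - q2)
                lam = 1.5 * delta + (
                    eps * abs(kappa - q2) / denom if denom > 0 else eps * math.inf
                )
            else:
                denom = 2.0 * abs(hi - q2)
                lam = 1.5 * delta - (
                    eps * abs(kappa - q2) / denom if denom > 0 else eps * math.inf
                )
    return min(2.0, max(-2.0, lam))


def random_profile_params(rng: np.random.Generator) -> tuple:
    """(q2a, q2b, mina, maxa, minb, maxb) of a random non-degenerate profile.

    Half the draws are separated enough to have a gap, half overlap.
    """
    while True:
        a = rng.normal(0.0, 1.0, size=8)
        shift = rng.choice([-1, 1]) * rng.uniform(0.5, 4.0)
        b = rng.normal(shift, 1.0, size=8)
        q2a, q2b = float(np.median(a)), float(np.median(b))
        if q2a != q2b:
            return (
                q2a,
                q2b,
                float(a.min()),
                float(a.max()),
                float(b.min()),
                float(b.max()),
            )
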