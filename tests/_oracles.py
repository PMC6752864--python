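"""Independent reference implementations used only by the tests.

These deliberately avoid the package's code paths: the monthly step is a
plain-Python scalar transcription of the documented pool equations, and
the steady state is obtained by composing the twelve monthly affine
updates into one annual linear map and solving it, rather than by
iterating the kernel.
"""

import math

import numpy as np

KS = (10.0, 0.3, 0.66, 0.02)  # DPM, RPM, BIO, HUM rate constants, 1/yr


def partition(clay):
    x = 1.67 * (1.85 + 1.60 * math.exp(-0.0786 * clay))
    return x / (x + 1.0), 0.46 / (x + 1.0), 0.54 / (x + 1.0)


def naive_step(pools, plant, fym, a, b, c, ratio, clay):
    """One month of decomposition, scalar arithmetic only.

    ``pools`` is (dpm, rpm, bio, hum, iom); returns (new_pools, co2).
    """
    dpm, rpm, bio, hum, iom = pools
    abc = a * b * c
    losses = [p * (1.0 - math.exp(-k * abc / 12.0))
              for p, k in zip((dpm, rpm, bio, hum), KS)]
    decomposed = sum(losses)
    f_co2, f_bio, f_hum = partition(clay)
    dpm = dpm - losses[0] + plant * ratio / (1.0 + ratio) + 0.49 * fym
    rpm = rpm - losses[1] + plant / (1.0 + ratio) + 0.49 * fym
    bio = bio - losses[2] + decomposed * f_bio
    hum = hum - losses[3] + decomposed * f_hum + 0.02 * fym
    return (dpm, rpm, bio, hum, iom), decomposed * f_co2


def naive_run(pools, plant12, fym12, a12, b12, c12, ratio, clay, years):
    """Iterate naive_step for whole years; returns annual totals."""
    totals = [sum(pools)]
    for _ in range(years):
        for m in range(12):
            pools, _ = naive_step(pools, plant12[m], fym12[m], a12[m],
                                  b12[m], c12[m], ratio, clay)
        totals.append(sum(pools))
    return np.array(totals)


def steady_state_active_pools(plant12, fym12, a12, b12, c12, ratio, clay):
    """Fixed point of the annual map, by linear solve over the 4 active pools.

    Composes the twelve monthly affine updates x -> A_m x + u_m into one
    annual map and solves (I - M) x = u.  Order: DPM, RPM, BIO, HUM.
    """
    f_co2, f_bio, f_hum = partition(clay)
    P = np.zeros((4, 4))
    P[2, :] = f_bio
    P[3, :] = f_hum
    M = np.eye(4)
    u = np.zeros(4)
    for m in range(12):
        abc = a12[m] * b12[m] * c12[m]
        d = np.exp(-np.asarray(KS) * abc / 12.0)
        A = np.diag(d) + P @ (np.eye(4) - np.diag(d))
        inp = np.array([
            plant12[m] * ratio / (1.0 + ratio) + 0.49 * fym12[m],
            plant12[m] / (1.0 + ratio) + 0.49 * fym12[m],
            0.0,
            0.02 * fym12[m],
        ])
        M = A @ M
        u = A @ u + inp
    return np.linalg.solve(np.eye(4) - M, u)
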