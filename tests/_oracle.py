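"""Independent high-precision oracle for the perception recursion.

A literal arbitrary-precision transcription of the reference recursion
(first-period formula + per-period association loop), evaluated with mpmath
at >= 50 significant digits.  Deliberately kept independent of the package
implementation: no imports from riskperc, same operation order as the
published listing.
"""

from __future__ import annotations

import mpmath as mp


def oracle_kernel(p, k, n, dps: int = 60):
    """Stimulus kernel F(p, k, n) at ``dps`` digits."""
    with mp.workdps(dps):
        p, k, n = mp.mpf(p), mp.mpf(k), mp.mpf(n)
        u = p ** (1 / n)
        v = k ** (1 / n)
        return u * p / (u - v) / (u - 1) - v * k / (u - v) / (v - 1) + 1 / (u - 1) / (v - 1)


def oracle_association_weight(k, n, dps: int = 60):
    with mp.workdps(dps):
        k, n = mp.mpf(k), mp.mpf(n)
        v = k ** (1 / n)
        return v / (1 - v)


def oracle_trajectory(p, k, N, S, dps: int = 60) -> list[mp.mpf]:
    """Full trajectory y_1..y_T by the reference recursion at high precision."""
    with mp.workdps(dps):
        p = mp.mpf(p)
        k = mp.mpf(k)
        N = [mp.mpf(n) for n in N]
        S = [mp.mpf(s) for s in S]
        T = len(N)
        u1 = p ** (1 / N[0])
        v1 = k ** (1 / N[0])
        y = [S[0] * (u1 * p / (u1 - v1) / (u1 - 1) - v1 * k / (u1 - v1) / (v1 - 1) + 1 / (u1 - 1) / (v1 - 1))]
        for t in range(2, T + 1):
            cycle = mp.mpf(0)
            for i in range(1, t + 1):
                vi = k ** (1 / N[i - 1])
                cycle += vi / (1 - vi) * k ** (t - i)
            u = p ** (1 / N[t - 1])
            v = k ** (1 / N[t - 1])
            F = u * p / (u - v) / (u - 1) - v * k / (u - v) / (v - 1) + 1 / (u - 1) / (v - 1)
            y.append(p * y[-1] + S[t - 1] * ((p - k) / (u - v) * (1 - k) * cycle + F))
        return y


def random_valid_draw(rng):
    """One random valid (rho, k, N, S, T<=30) problem from a seeded Generator."""
    T = int(rng.integers(2, 31))
    while True:
        rho = float(rng.uniform(0.05, 0.95))
        k = float(rng.uniform(0.05, 0.95))
        if abs(rho - k) >= 0.01:
            break
    N = rng.uniform(0.5, 60.0, size=T).tolist()
    S = rng.uniform(-3.0, 6.0, size=T).tolist()
    return rho, k, N, S
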