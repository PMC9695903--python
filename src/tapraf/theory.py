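"""Closed-form probabilities for the all-network RAF event.

For a TAP-generated network with ``m`` species, ``M0`` of them food, the
``R = m - M0`` reactions form an RAF precisely when every reaction has at
least one catalyst (the network is automatically food-generated).  Under
independent per-pair catalysis with probability ``p`` this gives

    P_all(m) = (1 - (1 - p)**R)**R .

Asymptotically, P_all -> 1 for any fixed p > 0 as m grows; along the
critical scaling p = ln(x*m)/m the probability converges to exp(-1/x);
and the level of catalysis f = p*R (mean number of reactions catalyzed
per non-food molecule type) required for P_all = theta grows like
ln(m) + ln(1/ln(1/theta)) — logarithmically in m.

All probability arithmetic is routed through log1p/expm1 so values close
to 0 and 1 retain full double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "TheoryPoint",
    "p_all",
    "p_all_limit",
    "required_level_of_catalysis",
    "exact_required_p",
    "theory_table",
]

#: Relative tolerance of the numeric inversion of P_all in p.
BISECT_RTOL = 1e-12


@dataclass(frozen=True)
class TheoryPoint:
    """One evaluated point of the all-network RAF probability curve."""

    m: int
    M0: int
    p: float
    p_all: float
    f: float

    @classmethod
    def evaluate(cls, m: int, M0: int, p: float) -> "TheoryPoint":
        return cls(m=m, M0=M0, p=p, p_all=p_all(m, M0, p), f=p * (m - M0))


def p_all(m: int, M0: int, p: float) -> float:
    """Probability that the entire m-species network is an RAF.

    Evaluates ``(1 - (1-p)**(m-M0))**(m-M0)`` in the log domain.  The
    reaction-free case ``m == M0`` is 1 by convention (an empty reaction
    set is vacuously an RAF; equivalently the 0**0 = 1 reading of the
    formula).
    """
    if M0 < 1:
        raise ValueError(f"M0 must be >= 1, got {M0}")
    if m < M0:
        raise ValueError(f"m must be >= M0, got m={m}, M0={M0}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    r = m - M0
    if r == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    log_q = r * math.log1p(-p)  # ln of per-reaction miss prob (1-p)^R
    # ln(1 - q) with the branch split that keeps precision in both
    # tails: expm1 when q is near 1, log1p when q is near 0.
    if log_q > -math.log(2):
        one_minus_q = -math.expm1(log_q)
        if one_minus_q <= 0.0:
            return 0.0
        log_hit = math.log(one_minus_q)
    else:
        log_hit = math.log1p(-math.exp(log_q))
    return math.exp(r * log_hit)


def p_all_limit(x: float) -> float:
    """Limit of ``p_all`` under the critical scaling ``p = ln(x*m)/m``.

    As m -> infinity with that scaling (x > 0), the all-network RAF
    probability converges to ``exp(-1/x)``.
    """
    if x <= 0.0:
        raise ValueError(f"x must be positive, got {x}")
    return math.exp(-1.0 / x)


def required_level_of_catalysis(m: int, theta: float) -> float:
    """Asymptotic level of catalysis f at which P_all equals ``theta``.

    Returns ``ln(m) + ln(1/ln(1/theta))``, the large-m expression for
    f = p*(m - M0) solving P_all = theta (the p*M0 correction is o(1)
    and dropped).  For theta = 1/2 the additive constant is
    ln(1/ln 2) ~= 0.367.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    return math.log(m) + math.log(1.0 / math.log(1.0 / theta))


def exact_required_p(m: int, M0: int, theta: float) -> float:
    """The unique p in (0, 1) with ``p_all(m, M0, p) == theta``.

    P_all is strictly increasing in p for m > M0, so the root is unique;
    it is bracketed on (0, 1) and found by Brent's method to relative
    tolerance ``BISECT_RTOL``.  This finite-m inversion exists so that
    tests of the asymptotic ``required_level_of_catalysis`` never
    conflate asymptotic and finite-m values.
    """
    if m <= M0:
        raise ValueError(f"m must exceed M0, got m={m}, M0={M0}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    # Closed-form seed bracket from the double inversion:
    #   q = 1 - theta**(1/R); p = 1 - q**(1/R)
    # is exact up to floating error; Brent polish keeps the contract
    # independent of that derivation.
    return brentq(
        lambda p: p_all(m, M0, p) - theta,
        1e-300,
        1.0 - 1e-16,
        rtol=BISECT_RTOL,
        xtol=1e-300,
    )


def theory_table(ms, M0: int, p: float):
    """Closed-form curve over species counts, as a (m, p, f, p_all) table.

    Convenience export for plotting against simulation sweeps; returns a
    pandas DataFrame with one row per entry of ``ms``.
    """
    import pandas as pd

    points = [TheoryPoint.evaluate(int(m), M0, p) for m in ms]
    return pd.DataFrame(
        {
            "m": [pt.m for pt in points],
            "p": [pt.p for pt in points],
            "f": [pt.f for pt in points],
            "p_all": [pt.p_all for pt in points],
        }
    )
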