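"""Fano-inequality predictability bounds and perplexity.

An entropy estimate ``S`` (bits per visit) over ``n`` distinct locations
bounds how often any predictor can guess the next location correctly. The
bound ``Π`` is the root of::

    S = H(Π) + (1 - Π) log2(n - 1),       H(x) = -x log2 x - (1-x) log2(1-x)

on ``[1/n, 1]``, where the right-hand side decreases strictly from
``log2 n`` to 0, so the root is unique. Degenerate corners: a single
location or zero entropy gives ``Π = 1``; ``S >= log2 n`` (possible for
the estimators on short sequences) is clipped to the random-guessing bound
``Π = 1/n`` and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import bisect

from .datatypes import Trajectory
from .entropy import EntropyEstimate

__all__ = [
    "PredictabilityEstimate",
    "fano_predictability",
    "perplexity",
    "cross_predictability",
]

_BISECT_XTOL = 1e-12
_REPORTED_TOL = 1e-9


@dataclass
class PredictabilityEstimate:
    """A Fano upper bound ``pi`` with the inputs that produced it."""

    pi: float
    n: int
    entropy_bits: float
    tolerance: float = _REPORTED_TOL
    clipped: bool = False

    def to_dict(self) -> dict:
        return {
            "pi": self.pi,
            "n": self.n,
            "entropy_bits": self.entropy_bits,
            "tolerance": self.tolerance,
            "clipped": self.clipped,
        }


def _binary_entropy(x: float) -> float:
    if x <= 0.0 or x >= 1.0:
        return 0.0
    return -x * math.log2(x) - (1.0 - x) * math.log2(1.0 - x)


def fano_predictability(S: float, n: int) -> PredictabilityEstimate:
    """Invert Fano's inequality: the unique ``Π`` in ``[1/n, 1]`` for ``S`` bits.

    Solved by bisection to an absolute tolerance of 1e-9 or better.
    """
    if S < 0:
        raise ValueError("entropy must be nonnegative")
    if n < 1:
        raise ValueError("distinct-location count must be >= 1")
    if n == 1 or S == 0.0:
        return PredictabilityEstimate(pi=1.0, n=n, entropy_bits=S)
    log2n = math.log2(n)
    if S >= log2n:
        return PredictabilityEstimate(pi=1.0 / n, n=n, entropy_bits=S, clipped=True)

    log_nm1 = math.log2(n - 1)

    def f(pi: float) -> float:
        return _binary_entropy(pi) + (1.0 - pi) * log_nm1 - S

    # f(1/n) = log2 n - S > 0 and f(1) = -S < 0: a sign change is guaranteed.
    pi = bisect(f, 1.0 / n, 1.0, xtol=_BISECT_XTOL)
    return PredictabilityEstimate(pi=float(pi), n=n, entropy_bits=S)


def perplexity(S: float) -> float:
    """Effective number of equally likely locations, ``2**S``."""
    if S < 0:
        raise ValueError("entropy must be nonnegative")
    return float(2.0**S)


def cross_predictability(est: EntropyEstimate, ego: Trajectory) -> PredictabilityEstimate:
    """Fano bound for a cross / cumulative estimate, using the ego's own ``n``.

    The bound concerns guessing the ego's next location among the ego's
    alternatives, so the inversion uses the ego's distinct-location count,
    not the alter's.
    """
    if est.mode not in ("cross", "cumulative"):
        raise ValueError("estimate must be cross or cumulative mode")
    if est.user != ego.user_id:
        raise ValueError(
            f"estimate is for user {est.user!r}, not ego {ego.user_id!r}"
        )
    return fano_predictability(est.value, ego.n)
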