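"""Distinct-location overlap between an ego and its alters.

The overlapped distinct location ratio (ODLR) of an ego ``A`` and alter
``B`` is ``|Y_A ∩ Y_B| / |Y_A|``, the fraction of the ego's distinct
locations that the alter also visits. Its cumulative version (CODLR) takes
the union of intersections over a set of alters, so it is nondecreasing as
alters are added. Both are pure set statistics over each user's whole
observation window; time enters only through the entropy estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datatypes import Trajectory

__all__ = ["OverlapResult", "odlr", "codlr"]


@dataclass
class OverlapResult:
    """An overlap fraction with the cardinalities behind it."""

    eta: float
    ego: str
    alter_ids: tuple
    n_ego_locations: int
    n_overlap: int


def odlr(A: Trajectory, B: Trajectory) -> OverlapResult:
    """Fraction of A's distinct locations also visited by B."""
    if A.n < 1:
        raise ValueError("ego trajectory has no locations")
    overlap = A.distinct & B.distinct
    return OverlapResult(
        eta=len(overlap) / A.n,
        ego=A.user_id,
        alter_ids=(B.user_id,),
        n_ego_locations=A.n,
        n_overlap=len(overlap),
    )


def codlr(A: Trajectory, alters: Sequence[Trajectory]) -> OverlapResult:
    """Fraction of A's distinct locations covered by the union over a set of alters.

    A singleton set reduces exactly to :func:`odlr`.
    """
    alters = list(alters)
    if not alters:
        raise ValueError("alter set must be nonempty")
    if A.n < 1:
        raise ValueError("ego trajectory has no locations")
    union = frozenset().union(*(A.distinct & B.distinct for B in alters))
    return OverlapResult(
        eta=len(union) / A.n,
        ego=A.user_id,
        alter_ids=tuple(B.user_id for B in alters),
        n_ego_locations=A.n,
        n_overlap=len(union),
    )
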