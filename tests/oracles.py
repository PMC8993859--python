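"""Brute-force match-length oracles, independent of the package internals.

Implements the match-length definitions literally: for each target
position, grow the candidate substring one symbol at a time and test
occurrence inside the admissible reference by direct substring search.
Quadratic-to-cubic time, used only to pin down exact expected values.

Sequences are given as small nonnegative ints (< 256) so substring search
can run on bytes.
"""

from __future__ import annotations

from typing import Optional, Sequence


def _occurs(sub: bytes, ref: bytes) -> bool:
    return sub in ref


def self_lambdas_bruteforce(seq: Sequence[int]) -> list:
    """Λ_i against the sequence's own prefix, by direct search."""
    b = bytes(seq)
    n = len(b)
    out = []
    for i in range(n):
        prefix = b[:i]
        L = 0
        while i + L < n and _occurs(b[i : i + L + 1], prefix):
            L += 1
        out.append(L + 1)
    return out


def cross_lambdas_bruteforce(
    seq_a: Sequence[int],
    seq_b: Sequence[int],
    times_a: Optional[Sequence[float]] = None,
    times_b: Optional[Sequence[float]] = None,
) -> list:
    """Λ_i of A against B's admissible history, by direct search.

    With timestamps, the reference for position i is the prefix of B whose
    events are strictly earlier than A's i-th timestamp; without, all of B.
    """
    a = bytes(seq_a)
    b = bytes(seq_b)
    na = len(a)
    out = []
    for i in range(na):
        if times_a is None:
            ref = b
        else:
            m = sum(1 for t in times_b if t < times_a[i])
            ref = b[:m]
        L = 0
        while i + L < na and _occurs(a[i : i + L + 1], ref):
            L += 1
        out.append(L + 1)
    return out


def canonical_sequences(max_len: int, max_alphabet: int):
    """Yield every sequence of length 1..max_len in first-occurrence order.

    A sequence is canonical when its symbols are 0..k-1 numbered by first
    appearance (a restricted-growth string). Match-length code compares
    symbols only for equality, so agreement on canonical sequences is
    agreement on all sequences over alphabets of the same size.
    """
    stack = [((0,), 1)]
    while stack:
        seq, k = stack.pop()
        yield seq
        if len(seq) < max_len:
            for s in range(min(k + 1, max_alphabet)):
                stack.append((seq + (s,), max(k, s + 1)))
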