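"""Maximal pairings: occurrences of maximal common substrings.

A *pairing* ``(p, t, l)`` records that the transcript ``P`` and the genome
``T`` share the substring ``P[p:p+l] == T[t:t+l]``. A pairing is *maximal*
when the shared factor cannot be extended by one character to the left on
both sequences nor to the right on both sequences. Maximal pairings are the
anchors from which every spliced alignment is assembled.

Coordinates are 0-based, half-open, on the forward strand throughout the
package; output writers convert to 1-based formats.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np

VALID_ALPHABET = frozenset("ACGTN")


class Pairing(NamedTuple):
    """Occurrence of a common substring: positions on transcript and genome.

    ``p``: start on the transcript, ``t``: start on the genome, ``l``:
    length. The base ``N`` never takes part in a pairing, so low-quality
    stretches split matches rather than bridging them.
    """

    p: int
    t: int
    l: int

    @property
    def p_end(self) -> int:
        return self.p + self.l

    @property
    def t_end(self) -> int:
        return self.t + self.l

    def contains(self, other: "Pairing") -> bool:
        """Containment: ``other`` is a sub-pairing at consistent offsets."""
        off = other.p - self.p
        return (off >= 0 and other.t - self.t == off
                and other.p + other.l <= self.p + self.l)


def _validate_sequence(name: str, s: str) -> None:
    if not s:
        raise ValueError(f"{name} is empty")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")


def check_pairing(v: Pairing, P: str, T: str) -> None:
    """Raise if ``v`` violates the pairing invariants against P and T."""
    if v.l < 1 or v.p < 0 or v.t < 0 or v.p_end > len(P) or v.t_end > len(T):
        raise ValueError(f"pairing {v} out of bounds for |P|={len(P)}, |T|={len(T)}")
    fp = P[v.p:v.p_end]
    if fp != T[v.t:v.t_end] or "N" in fp:
        raise ValueError(f"pairing {v} does not induce a common factor")


def is_maximal(v: Pairing, P: str, T: str) -> bool:
    """True iff ``v`` cannot be extended on both sequences in either direction."""
    check_pairing(v, P, T)
    left_blocked = (v.p == 0 or v.t == 0
                    or P[v.p - 1] != T[v.t - 1]
                    or P[v.p - 1] == "N")
    right_blocked = (v.p_end == len(P) or v.t_end == len(T)
                     or P[v.p_end] != T[v.t_end]
                     or P[v.p_end] == "N")
    return left_blocked and right_blocked


def find_maximal_pairings(P: str, T: str, ell_E: int = 1) -> list[Pairing]:
    """All maximal pairings of P in T with length >= ``ell_E``, sorted by (p, t).

    The scan computes, row by row, the longest common extension
    ``M[i, j] = lce(P[i:], T[j:])`` with the recurrence
    ``M[i, j] = M[i+1, j+1] + 1`` when ``P[i] == T[j]`` (and neither is N).
    A triple ``(i, j, M[i, j])`` is a maximal pairing exactly when the match
    is left-blocked, since ``M`` already extends maximally to the right.
    Vectorizing each row keeps memory linear in ``|T|``.
    """
    _validate_sequence("P", P)
    _validate_sequence("T", T)
    if ell_E < 1:
        raise ValueError("ell_E must be >= 1")

    t_arr = np.frombuffer(T.encode("ascii"), dtype=np.uint8)
    p_arr = np.frombuffer(P.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    t_is_n = t_arr == n_code

    out: list[Pairing] = []
    nxt = np.zeros(len(T), dtype=np.int32)  # row i+1 of M
    cur = np.zeros(len(T), dtype=np.int32)
    for i in range(len(P) - 1, -1, -1):
        eq = (t_arr == p_arr[i]) & ~t_is_n if p_arr[i] != n_code else np.zeros(len(T), bool)
        cur[:] = 0
        if eq.any():
            cur[eq[:-1].nonzero()[0]] = nxt[1:][eq[:-1]] + 1
            if eq[-1]:
                cur[-1] = 1
        if i == 0:
            left_open = np.ones(len(T), dtype=bool)
        else:
            prev = p_arr[i - 1]
            left_open = np.empty(len(T), dtype=bool)
            left_open[0] = True
            if prev == n_code:
                left_open[1:] = True
            else:
                left_open[1:] = (t_arr[:-1] != prev) | t_is_n[:-1]
        hits = ((cur >= ell_E) & left_open).nonzero()[0]
        for j in hits:
            out.append(Pairing(i, int(j), int(cur[j])))
        nxt, cur = cur, nxt
    out.sort()
    return out


def resolve_overlap(
    e_k: Pairing, v_next: Pairing, ell_E: int
) -> tuple[Pairing, Pairing] | None:
    """Trim two overlapping pairings into a non-overlapping consecutive pair.

    Used when two anchors belong to the same exon but overlap on the
    transcript and/or the genome: ``e_k`` is replaced by its shortest
    prefix-pairing and ``v_next`` by its longest suffix-pairing such that
    the results do not overlap on either sequence and both are at least
    ``ell_E`` long. Non-overlapping inputs are returned unchanged; ``None``
    signals that no valid trim exists.
    """
    if e_k.p_end <= v_next.p and e_k.t_end <= v_next.t:
        return e_k, v_next
    a = ell_E  # shortest admissible prefix of e_k
    if a > e_k.l:
        return None
    # v_next suffix of length bmax starts at p_end - bmax; require starts
    # at or after the trimmed e_k ends, on both sequences.
    bmax = min(
        v_next.l,
        v_next.p_end - (e_k.p + a),
        v_next.t_end - (e_k.t + a),
    )
    if bmax < ell_E:
        return None
    trimmed_k = Pairing(e_k.p, e_k.t, a)
    trimmed_next = Pairing(v_next.p_end - bmax, v_next.t_end - bmax, bmax)
    return trimmed_k, trimmed_next
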