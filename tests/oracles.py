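"""Independent brute-force oracles used by the test suite.

Everything here re-states the definitions directly (definitional scans,
exhaustive enumerations); nothing imports the production algorithms they
are checking, except where a shared low-level helper is unavoidable and
noted.
"""
from __future__ import annotations

import itertools
import random

from spliceagree.pairings import Pairing
from spliceagree.params import Parameters

BASES = "ACGT"


def random_dna(rng: random.Random, n: int, alphabet: str = BASES) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def brute_maximal_pairings(P: str, T: str, ell_E: int) -> list[Pairing]:
    """Definitional scan: every (p, t) start, extend right, check left."""
    out = []
    for p in range(len(P)):
        for t in range(len(T)):
            if (p > 0 and t > 0 and P[p - 1] == T[t - 1] and P[p - 1] != "N"):
                continue  # left-extendable: not maximal
            l = 0
            while (p + l < len(P) and t + l < len(T)
                   and P[p + l] == T[t + l] and P[p + l] != "N"):
                l += 1
            if l >= ell_E:
                out.append(Pairing(p, t, l))
    return out


def brute_edges(vertices: list[Pairing], params: Parameters) -> set[tuple]:
    """All-pairs evaluation of the printed edge conditions."""
    out = set()
    for v1 in vertices:
        for v2 in vertices:
            if v1 == v2:
                continue
            if not (v1.p < v2.p or (v1.p == v2.p and v1.t < v2.t)):
                continue
            cond_i = v2.p - (v1.p + v1.l) <= params.ell_D
            drift = v2.t - v1.t - (v2.p - v1.p)
            cond_ii = abs(drift) <= params.ell_D or drift >= params.ell_I
            if cond_i and cond_ii:
                out.add((v1, v2))
    return out


def all_pairings(P: str, T: str, min_len: int) -> list[Pairing]:
    """Every pairing (diagonal sub-interval of a maximal pairing)."""
    out = []
    for m in brute_maximal_pairings(P, T, 1):
        for off in range(m.l):
            for l in range(min_len, m.l - off + 1):
                out.append(Pairing(m.p + off, m.t + off, l))
    return sorted(set(out))


def _chain_ok(a: Pairing, b: Pairing, params: Parameters) -> bool:
    if b.p < a.p_end or b.t < a.t_end:
        return False  # overlap / not increasing
    if b.p - a.p_end > params.ell_D:
        return False
    drift = (b.t - a.t) - (b.p - a.p)
    return abs(drift) <= params.ell_D or drift >= params.ell_I


def representative_chains(
    P: str, T: str, params: Parameters, cap: int = 200_000
) -> list[tuple[Pairing, ...]]:
    """Exhaustive representative embeddings over all pairings (small inputs).

    Enumerates every chain of non-overlapping, strictly advancing
    pairings of length >= ell_E whose consecutive gaps satisfy the
    representative-embedding constraints, then discards chains that are
    visibly non-maximal: an element can be grown along its diagonal, an
    extra pairing can be inserted, or two consecutive elements lie inside
    the same maximal pairing (their merge contains the chain).
    """
    pool = all_pairings(P, T, params.ell_E)
    short = all_pairings(P, T, 1)
    maximal = brute_maximal_pairings(P, T, 1)

    def container(v: Pairing) -> Pairing:
        cands = [m for m in maximal if m.contains(v)]
        assert len(cands) == 1, f"non-unique maximal container for {v}"
        return cands[0]

    chains: list[tuple[Pairing, ...]] = []
    budget = [cap]

    def grow(chain: tuple[Pairing, ...]) -> None:
        if budget[0] <= 0:
            raise RuntimeError("oracle enumeration cap exceeded")
        budget[0] -= 1
        chains.append(chain)
        last = chain[-1]
        for v in pool:
            if v.p < last.p_end:
                continue
            if _chain_ok(last, v, params):
                grow(chain + (v,))

    for v in pool:
        grow((v,))

    def diag_growable(chain: tuple[Pairing, ...], i: int) -> bool:
        v = chain[i]
        c = container(v)
        left_room = v.p > c.p and (i == 0 or chain[i - 1].p_end < v.p
                                   and chain[i - 1].t_end < v.t)
        right_room = v.p_end < c.p_end and (
            i == len(chain) - 1
            or (v.p_end < chain[i + 1].p and v.t_end < chain[i + 1].t))
        return left_room or right_room

    def insertable(chain: tuple[Pairing, ...]) -> bool:
        for v in short:
            fits = all(v.p_end <= w.p and v.t_end <= w.t
                       or w.p_end <= v.p and w.t_end <= v.t
                       for w in chain)
            if fits and v not in chain:
                return True
        return False

    def merged_pair(chain: tuple[Pairing, ...]) -> bool:
        return any(container(a) == container(b)
                   for a, b in zip(chain, chain[1:]))

    out = []
    for chain in chains:
        if merged_pair(chain):
            continue
        if any(diag_growable(chain, i) for i in range(len(chain))):
            continue
        if insertable(chain):
            continue
        out.append(chain)
    return out


def unique_maximal_container(v: Pairing, maximal: list[Pairing]) -> Pairing:
    cands = [m for m in maximal if m.contains(v)]
    assert len(cands) == 1
    return cands[0]


def chain_enumeration_compositions(
    P: str, T: str, params: Parameters, transcript_id: str = "P"
):
    """Compositions via plain recursion over maximal pairings.

    Independent of the embedding-graph object, the extended-source
    selection and the visit caps: every chain of maximal pairings whose
    consecutive pairs satisfy the directly restated gap conditions is
    expanded through the shared case-resolution helpers and merged.
    """
    from spliceagree.spliced_alignment import (Composition, _Chain,
                                               _chain_to_factors, _retained,
                                               extend_embedding)

    maximal = brute_maximal_pairings(P, T, params.ell_E)
    best: dict[tuple, Composition] = {}

    def emit(chain: _Chain) -> None:
        if chain.pairings[0].p > params.end_clip:
            return
        if chain.pairings[-1].p_end < len(P) - params.end_clip:
            return
        factors = _chain_to_factors(chain, P, T)
        if factors is None or not _retained(factors, params):
            return
        comp = Composition(transcript_id, tuple(factors),
                           sum(f.edit for f in factors))
        key = comp.genomic_intervals()
        old = best.get(key)
        if old is None or comp.total_edit < old.total_edit:
            best[key] = comp

    def grow(chain: _Chain, vertex: Pairing, used: frozenset) -> None:
        emit(chain)
        for w in maximal:
            if w in used or w == vertex:
                continue
            cond_i = w.p - (vertex.p + vertex.l) <= params.ell_D
            drift = w.t - vertex.t - (w.p - vertex.p)
            cond_ii = abs(drift) <= params.ell_D or drift >= params.ell_I
            forward = vertex.p < w.p or (vertex.p == w.p and vertex.t < w.t)
            if not (cond_i and cond_ii and forward):
                continue
            for ext in extend_embedding(chain, w, P, T, params):
                grow(ext, w, used | {w})

    for v in maximal:
        grow(_Chain([v], []), v, frozenset([v]))
    return sorted(best.values(),
                  key=lambda c: (c.total_edit, len(c.factors),
                                 c.factors[0].t_start, c.genomic_intervals()))


def exhaustive_mfa(factor_sets: dict[str, list[frozenset[int]]], nf: int) -> set[int]:
    """Smallest agreement set by scanning all 2^nf subsets in size order."""
    universe = list(range(nf))
    for k in range(nf + 1):
        for combo in itertools.combinations(universe, k):
            chosen = set(combo)
            if all(any(fs <= chosen for fs in sets)
                   for sets in factor_sets.values()):
                return chosen
    raise AssertionError("unreachable")
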