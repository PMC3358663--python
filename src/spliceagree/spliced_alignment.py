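"""Spliced alignments (compositions) from embedding-graph visits.

The visit starts at the extended sources of the embedding graph and grows
anchor chains edge by edge. How a chain is extended depends on the relative
position of its last anchor ``e_k`` and the new vertex ``v``:

* overlap on both sequences (a): either the two anchors belong to the same
  exon (small drift; trim the overlap) or the drift is intron-sized, which
  is ambiguous between an intron and a tandem repeat on the genome — both
  interpretations are kept and the consensus stage disambiguates;
* overlap on the genome only (b): same-exon continuation, trim;
* overlap on the transcript only (c): same-exon trim for small drift; for
  intron-sized drift the junction is ambiguous (a suffix of the donor exon
  equals a prefix of the acceptor exon) and is placed by splice-pattern
  priority GT-AG > GC-AG > AT-AC > other, then leftmost;
* no overlap (d): the gap strings G_P (transcript) and G_T (genome) are
  compared directly — same exon when their edit distance is small, or an
  intron whose boundaries minimize the edit distance between G_P and the
  retained prefix+suffix of G_T.

Chains are then merged into factors: maximal runs of anchors joined by
same-exon links become one (transcript factor, genomic factor) pair whose
edit distance is computed on the full merged intervals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import edlib

from .embedding_graph import EmbeddingGraph, extended_sources
from .pairings import Pairing, resolve_overlap
from .params import Parameters

SPLICE_PATTERNS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}
_PATTERN_RANK = {"GT-AG": 0, "GC-AG": 1, "AT-AC": 2, "other": 3}


def splice_pattern(donor: str, acceptor: str) -> str:
    return SPLICE_PATTERNS.get((donor, acceptor), "other")


def _pattern_rank(donor: str, acceptor: str) -> int:
    return _PATTERN_RANK[splice_pattern(donor, acceptor)]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


class AlignedFactor(NamedTuple):
    """One exon of a spliced alignment: paired transcript/genomic intervals."""

    p_start: int
    p_end: int
    t_start: int
    t_end: int
    edit: int

    @property
    def p_len(self) -> int:
        return self.p_end - self.p_start

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Composition:
    """A spliced alignment of one transcript: ordered factors + total cost."""

    transcript_id: str
    factors: tuple[AlignedFactor, ...]
    total_edit: int

    def genomic_intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple((f.t_start, f.t_end) for f in self.factors)

    def introns(self) -> list[tuple[int, int]]:
        return [(a.t_end, b.t_start) for a, b in zip(self.factors, self.factors[1:])]

    def validate(self, params: Parameters, p_len: int | None = None) -> None:
        """Assert the composition invariants; raise AssertionError on violation."""
        fs = self.factors
        assert fs, "empty composition"
        for f in fs:
            assert f.p_end > f.p_start and f.t_end > f.t_start
            assert f.edit <= params.resolve_edit_threshold(f.p_len)
        for a, b in zip(fs, fs[1:]):
            assert b.p_start == a.p_end, "transcript factors not contiguous"
            assert b.t_start - a.t_end >= params.ell_I, "intron shorter than ell_I"
        assert self.total_edit == sum(f.edit for f in fs)


def refine_intron_split(
    G_P: str, G_T: str, ell_I: int
) -> tuple[int, int, int, str, str]:
    """Place an intron inside the genomic gap G_T.

    Chooses a prefix of length ``prefix_len`` and a suffix of length
    ``suffix_len`` of G_T to keep in the flanking exons so that the edit
    distance between G_P and their concatenation is minimal; the excised
    middle (length >= ell_I) is the intron. Ties are broken by the splice
    pattern of the excised interval (GT-AG > GC-AG > AT-AC > other), then
    by leftmost donor. Returns (prefix_len, suffix_len, edit, donor,
    acceptor).
    """
    slack = len(G_T) - len(G_P)
    if slack < ell_I:
        raise ValueError("intron branch requires |G_T| - |G_P| >= ell_I")
    # A split keeping more than 2|G_P| characters can never reach the
    # minimum (edit >= kept - |G_P| > |G_P| >= edit of the empty split).
    cap = min(len(G_T) - ell_I, 2 * len(G_P))
    best: tuple[int, int, int, int] | None = None  # (edit, rank, pre, suf)
    for pre in range(cap + 1):
        for suf in range(cap - pre + 1):
            kept = G_T[:pre] + (G_T[len(G_T) - suf:] if suf else "")
            ed = edit_distance(G_P, kept)
            excised = G_T[pre:len(G_T) - suf]
            rank = _pattern_rank(excised[:2], excised[-2:])
            cand = (ed, rank, pre, suf)
            if best is None or cand < best:
                best = cand
    ed, _rank, pre, suf = best
    excised = G_T[pre:len(G_T) - suf]
    return pre, suf, ed, excised[:2], excised[-2:]


def _split_transcript_gap(G_P: str, kept_prefix: str, kept_suffix: str) -> tuple[int, int]:
    """Divide G_P between the two flanking exons, minimizing total edit."""
    best = (len(G_P) + len(kept_prefix) + len(kept_suffix) + 1, 0)
    for k in range(len(G_P) + 1):
        ed = edit_distance(G_P[:k], kept_prefix) + edit_distance(G_P[k:], kept_suffix)
        if ed < best[0]:
            best = (ed, k)
    return best[1], best[0]


class _Link(NamedTuple):
    """Junction between consecutive chain anchors.

    ``intron`` is None for a same-exon link; otherwise the genomic
    interval excised between the factors, with ``p_cut`` the transcript
    coordinate at which the factors abut.
    """

    intron: tuple[int, int] | None
    p_cut: int | None


@dataclass
class _Chain:
    pairings: list[Pairing]
    links: list[_Link]

    def extended(self, trimmed_last: Pairing, new: Pairing, link: _Link) -> "_Chain":
        return _Chain(self.pairings[:-1] + [trimmed_last, new], self.links + [link])


def _ambiguous_junction(
    e_k: Pairing, v: Pairing, T: str
) -> tuple[Pairing, Pairing, _Link] | None:
    """Place an intron when the anchors overlap on the transcript.

    Every cut point in the overlap yields an intron of the same length
    (the genomic drift); the cut is chosen by splice-pattern priority,
    then leftmost.
    """
    lo = max(v.p, e_k.p + 1)
    hi = min(e_k.p_end, v.p_end - 1)
    if lo > hi:
        return None
    best: tuple[int, int] | None = None  # (rank, cut)
    for c in range(lo, hi + 1):
        i_start = e_k.t + (c - e_k.p)
        i_end = v.t + (c - v.p)
        rank = _pattern_rank(T[i_start:i_start + 2], T[i_end - 2:i_end])
        if best is None or (rank, c) < best:
            best = (rank, c)
    _rank, c = best
    i_start = e_k.t + (c - e_k.p)
    i_end = v.t + (c - v.p)
    trimmed = Pairing(e_k.p, e_k.t, c - e_k.p)
    new = Pairing(c, i_end, v.p_end - c)
    return trimmed, new, _Link((i_start, i_end), c)


def extend_embedding(
    chain: _Chain, v: Pairing, P: str, T: str, params: Parameters
) -> list[_Chain]:
    """All ways of appending graph vertex ``v`` to a chain (may be empty)."""
    e_k = chain.pairings[-1]
    if v.p < e_k.p or (v.p_end <= e_k.p_end and v.t_end <= e_k.t_end):
        return []
    overlap_p = v.p < e_k.p_end
    overlap_t = v.t < e_k.t_end
    drift = (v.t - e_k.t) - (v.p - e_k.p)
    out: list[_Chain] = []

    if (overlap_p or overlap_t) and abs(drift) <= params.ell_D:
        # cases (a)/(b)/(c), same-exon subcase: trim the overlap
        rr = resolve_overlap(e_k, v, params.ell_E)
        if rr is not None:
            out.append(chain.extended(rr[0], rr[1], _Link(None, None)))
    elif overlap_p and overlap_t and drift >= params.ell_I:
        # case (a), intron-sized drift: ambiguous between an intron and a
        # tandem repeat on T — keep both interpretations
        cut = _ambiguous_junction(e_k, v, T)
        if cut is not None:
            out.append(chain.extended(cut[0], cut[1], cut[2]))
        out.append(chain.extended(e_k, v, _Link(None, None)))  # repeat absorbed
    elif overlap_p and drift >= params.ell_I:
        # case (c), intron-sized drift: ambiguous junction placement
        cut = _ambiguous_junction(e_k, v, T)
        if cut is not None:
            out.append(chain.extended(cut[0], cut[1], cut[2]))
    elif not overlap_p and not overlap_t:
        # case (d)
        G_P = P[e_k.p_end:v.p]
        G_T = T[e_k.t_end:v.t]
        if abs(drift) <= params.ell_D:
            threshold = params.gap_edit_threshold(max(len(G_P), len(G_T)))
            if edit_distance(G_P, G_T) <= threshold:
                out.append(chain.extended(e_k, v, _Link(None, None)))
        elif drift >= params.ell_I:
            pre, suf, ed, _d, _a = refine_intron_split(G_P, G_T, params.ell_I)
            if ed <= params.gap_edit_threshold(len(G_P)):
                kept_pre = G_T[:pre]
                kept_suf = G_T[len(G_T) - suf:] if suf else ""
                k, _ = _split_transcript_gap(G_P, kept_pre, kept_suf)
                link = _Link(
                    (e_k.t_end + pre, v.t - suf), e_k.p_end + k)
                out.append(chain.extended(e_k, v, link))
    return out


def _chain_to_factors(chain: _Chain, P: str, T: str) -> list[AlignedFactor] | None:
    """Merge same-exon runs into factors and score each with edlib."""
    factors: list[AlignedFactor] = []
    boundaries: list[tuple[int, int, int, int]] = []  # p_start, p_end, t_start, t_end
    prev_p, prev_t = chain.pairings[0].p, chain.pairings[0].t
    for link in chain.links:
        if link.intron is not None:
            boundaries.append((prev_p, link.p_cut, prev_t, link.intron[0]))
            prev_p, prev_t = link.p_cut, link.intron[1]
    last = chain.pairings[-1]
    boundaries.append((prev_p, last.p_end, prev_t, last.t_end))
    for p0, p1, t0, t1 in boundaries:
        if p1 <= p0 or t1 <= t0:
            return None
        ed = edit_distance(P[p0:p1], T[t0:t1])
        factors.append(AlignedFactor(p0, p1, t0, t1, ed))
    for a, b in zip(factors, factors[1:]):
        if b.t_start <= a.t_end:  # genomic monotonicity (defensive)
            return None
    return factors


def _retained(factors: list[AlignedFactor], params: Parameters) -> bool:
    for f in factors:
        if min(f.p_len, f.t_len) < params.min_factor_len:
            return False
        if f.edit > params.resolve_edit_threshold(f.p_len):
            return False
    return True


def enumerate_compositions(
    g: EmbeddingGraph,
    P: str,
    T: str,
    params: Parameters,
    transcript_id: str = "P",
) -> list[Composition]:
    """All distinct retained spliced alignments of P against T.

    Visits simple paths of the embedding graph from its extended sources,
    extends chains per the overlap cases, emits every chain that covers
    the transcript up to ``end_clip`` at either end, merges anchors into
    factors and applies the per-factor edit retention rule. Compositions
    with identical genomic factor lists are deduplicated (best total edit
    kept); output is capped at ``max_compositions``, kept by lowest total
    edit, then fewest factors, then leftmost genomic start.
    """
    best: dict[tuple, Composition] = {}
    p_len = len(P)

    def emit(chain: _Chain) -> None:
        if chain.pairings[0].p > params.end_clip:
            return
        if chain.pairings[-1].p_end < p_len - params.end_clip:
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

    for src in extended_sources(g, params):
        budget = params.max_embeddings_per_source
        stack: list[tuple[_Chain, Pairing, frozenset]] = [
            (_Chain([src], []), src, frozenset([src]))
        ]
        while stack and budget > 0:
            chain, vertex, visited = stack.pop()
            budget -= 1
            emit(chain)
            for w in g.successors(vertex):
                if w in visited:
                    continue
                for ext in extend_embedding(chain, w, P, T, params):
                    stack.append((ext, w, visited | {w}))

    comps = sorted(
        best.values(),
        key=lambda c: (c.total_edit, len(c.factors), c.factors[0].t_start,
                       c.genomic_intervals()),
    )
    return comps[: params.max_compositions]
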