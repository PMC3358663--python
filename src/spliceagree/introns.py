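"""Intron extraction, splice-pattern classification and reduction.

The chosen compositions induce a set of genomic introns. Each intron is
classified by its terminal dinucleotides (GT-AG and GC-AG are processed
by the major, U2, spliceosome; AT-AC by the minor, U12, spliceosome;
anything else is unclassified — a pattern-based simplification of
sequence-based U-type classifiers). Introns that follow none of these
rules and lack RefSeq support are suspected false positives: the
reduction step tries to shift their supporting junctions onto a nearby
trusted intron at a cost of at most ``b`` extra alignment errors,
scanning RefSeq-supported introns first, then GT-AG, GC-AG, AT-AC.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .params import Parameters
from .spliced_alignment import AlignedFactor, Composition, edit_distance, splice_pattern

U_TYPE = {"GT-AG": "U2", "GC-AG": "U2", "AT-AC": "U12", "other": "unclassified"}


def classify_intron(donor: str, acceptor: str) -> tuple[str, str]:
    """Splice pattern and spliceosome type from the terminal dinucleotides."""
    pattern = splice_pattern(donor, acceptor)
    return pattern, U_TYPE[pattern]


@dataclass
class IntronRecord:
    """A genomic intron with its classification and supporting junctions."""

    t_start: int
    t_end: int
    donor: str
    acceptor: str
    pattern: str
    u_type: str
    supports: list[tuple[str, int]] = field(default_factory=list)
    refseq_supported: bool = False

    @property
    def length(self) -> int:
        return self.t_end - self.t_start

    def key(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)


def _record_for(interval: tuple[int, int], T: str) -> IntronRecord:
    s, e = interval
    donor, acceptor = T[s:s + 2], T[e - 2:e]
    pattern, u_type = classify_intron(donor, acceptor)
    return IntronRecord(s, e, donor, acceptor, pattern, u_type)


def extract_introns(
    chosen: dict[str, Composition], T: str, refseq_ids: set[str] | None = None
) -> list[IntronRecord]:
    """One record per distinct genomic interval between consecutive factors."""
    refseq_ids = refseq_ids or set()
    records: dict[tuple[int, int], IntronRecord] = {}
    for tid in sorted(chosen):
        for j, iv in enumerate(chosen[tid].introns()):
            rec = records.get(iv)
            if rec is None:
                rec = records[iv] = _record_for(iv, T)
            rec.supports.append((tid, j))
            if tid in refseq_ids:
                rec.refseq_supported = True
    return sorted(records.values(), key=lambda r: r.key())


def b_reducible(
    composition: Composition,
    junction_index: int,
    target: tuple[int, int],
    b: int,
    P: str,
    T: str,
    params: Parameters,
) -> tuple[bool, tuple[AlignedFactor, AlignedFactor] | None]:
    """Can this junction be shifted onto ``target`` with <= b extra errors?

    Re-aligns the two factors flanking junction ``junction_index`` with
    their genomic boundaries moved to the target intron, searching the
    transcript split point near the original one; returns the re-aligned
    factor pair when the added edit cost is within budget.
    """
    f1 = composition.factors[junction_index]
    f2 = composition.factors[junction_index + 1]
    i_start, i_end = target
    if (i_start, i_end) == (f1.t_end, f2.t_start):
        return True, (f1, f2)
    if i_end - i_start < params.ell_I:
        return False, None
    if abs(i_start - f1.t_end) > params.shift_window:
        return False, None
    if abs(i_end - f2.t_start) > params.shift_window:
        return False, None
    if i_start <= f1.t_start or i_end >= f2.t_end:
        return False, None
    orig = f1.edit + f2.edit
    window = params.shift_window + b
    best: tuple[int, int] | None = None  # (total_edit, p_cut)
    for p_cut in range(max(f1.p_start + 1, f1.p_end - window),
                       min(f2.p_end, f1.p_end + window) + 1):
        e1 = edit_distance(P[f1.p_start:p_cut], T[f1.t_start:i_start])
        e2 = edit_distance(P[p_cut:f2.p_end], T[i_end:f2.t_end])
        if best is None or (e1 + e2, p_cut) < best:
            best = (e1 + e2, p_cut)
    if best is None or best[0] > orig + b:
        return False, None
    total, p_cut = best
    g1 = AlignedFactor(f1.p_start, p_cut, f1.t_start, i_start,
                       edit_distance(P[f1.p_start:p_cut], T[f1.t_start:i_start]))
    g2 = AlignedFactor(p_cut, f2.p_end, i_end, f2.t_end,
                       edit_distance(P[p_cut:f2.p_end], T[i_end:f2.t_end]))
    return True, (g1, g2)


def _apply_shift(comp: Composition, j: int,
                 pair: tuple[AlignedFactor, AlignedFactor]) -> Composition:
    factors = list(comp.factors)
    factors[j], factors[j + 1] = pair
    return replace(comp, factors=tuple(factors),
                   total_edit=sum(f.edit for f in factors))


def reduce_introns(
    introns: list[IntronRecord],
    chosen: dict[str, Composition],
    P_map: dict[str, str],
    T: str,
    params: Parameters,
    refseq_ids: set[str] | None = None,
) -> tuple[list[IntronRecord], dict[str, Composition]]:
    """Merge probable false-positive introns into supported ones.

    Only junction supports of non-RefSeq transcripts on introns that
    follow no U2/U12 rule are candidates. Each is re-assigned to the
    first reducible target scanning the RefSeq-supported introns, then
    GT-AG, then GC-AG, then AT-AC introns (within a set: nearest
    interval, ties leftmost). Unreducible supports stay put; records
    left without supports are dropped; support lists, flags and the
    affected compositions are recomputed. Total support count is
    conserved and the procedure is idempotent.
    """
    refseq_ids = refseq_ids or set()
    chosen = dict(chosen)
    n_supports = sum(len(r.supports) for r in introns)
    records = introns

    def find_moves(recs: list[IntronRecord]):
        refseq = [r.key() for r in recs if r.refseq_supported]
        by_pat: dict[str, list[tuple[int, int]]] = {"GT-AG": [], "GC-AG": [], "AT-AC": []}
        for r in recs:
            if not r.refseq_supported and r.pattern in by_pat:
                by_pat[r.pattern].append(r.key())
        tiers = [refseq, by_pat["GT-AG"], by_pat["GC-AG"], by_pat["AT-AC"]]
        moves = []
        for rec in recs:
            if rec.pattern != "other" or rec.refseq_supported:
                continue
            for tid, j in list(rec.supports):
                if tid in refseq_ids:
                    continue
                for tier in tiers:
                    cands = sorted(
                        (iv for iv in tier if iv != rec.key()),
                        key=lambda iv: (abs(iv[0] - rec.t_start)
                                        + abs(iv[1] - rec.t_end), iv),
                    )
                    found = None
                    for iv in cands:
                        ok, pair = b_reducible(chosen[tid], j, iv, params.b,
                                               P_map[tid], T, params)
                        if ok:
                            found = (tid, j, pair)
                            break
                    if found:
                        moves.append(found)
                        break
                else:
                    continue
        return moves

    # Iterate to a fixpoint: shifted supports land on trusted introns and
    # are never candidates again, so this terminates; a support whose
    # neighbouring junction moved in the same round is retried next round.
    for _ in range(1 + sum(len(r.supports) for r in records)):
        moves = find_moves(records)
        touched: set[tuple[str, int]] = set()
        applied = 0
        for tid, j, pair in moves:
            if (tid, j) in touched or (tid, j + 1) in touched:
                continue
            chosen[tid] = _apply_shift(chosen[tid], j, pair)
            touched.update({(tid, j), (tid, j + 1)})
            applied += 1
        if not applied:
            break
        # rebuild so supports, dinucleotides and flags stay consistent
        records = extract_introns(chosen, T, refseq_ids)

    rebuilt = extract_introns(chosen, T, refseq_ids)
    assert sum(len(r.supports) for r in rebuilt) == n_supports, \
        "support count not conserved by intron reduction"
    return rebuilt, chosen
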