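"""Consensus gene structure via Minimum Factorization Agreement (MFA).

Each transcript may have several surviving spliced alignments. The
consensus step picks the maximum-parsimony explanation: the smallest set
F' of genomic factors (exons) such that every transcript keeps at least
one alignment whose factors all lie in F'. Finding a minimum F' is the
NP-hard MFA problem; an exact branch-and-bound style solver handles the
universes this package typically produces, with a greedy fallback above
``exact_limit``.

Building the factor universe must cope with EST truncation: the outer
boundary of a transcript's first/last factor is a sequencing artifact,
not a splice site. Such *soft* boundaries are unified into the factor
group sharing their anchored junction; the representative interval of a
group is its widest observed extent, so a full-length (e.g. RefSeq)
transcript pins the true exon boundaries.
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

from .params import Parameters
from .spliced_alignment import Composition


@dataclass
class FactorUniverse:
    """Ordered exon candidates plus, per transcript, its factor-index sets."""

    factors: list[tuple[int, int]]
    factor_sets: dict[str, list[frozenset[int]]]
    compositions: dict[str, list[Composition]] = field(default_factory=dict)
    uncovered: list[str] = field(default_factory=list)


def _cluster_boundaries(coords: set[int], tol: int) -> dict[int, int]:
    """Map each coordinate to a cluster representative (within tol)."""
    mapping: dict[int, int] = {}
    rep = None
    for c in sorted(coords):
        if rep is None or c - rep > tol:
            rep = c
        mapping[c] = rep
    return mapping


def build_factor_universe(
    all_compositions: dict[str, list[Composition]],
    boundary_tol: int = 0,
) -> FactorUniverse:
    """Unify genomic factors across transcripts into an ordered universe.

    Junction coordinates differing by at most ``boundary_tol`` are merged
    (representative = smallest in the cluster). A factor boundary at a
    transcript end is soft: the factor joins the group sharing its
    anchored junction(s); fully soft factors (single-factor alignments)
    join the group whose representative interval contains them. Group
    representatives take the widest observed extent on each soft side.
    Transcripts with no composition are recorded as uncovered and left
    out of the MFA instance.
    """
    covered = {tid: comps for tid, comps in all_compositions.items() if comps}
    uncovered = sorted(set(all_compositions) - set(covered))
    if uncovered:
        warnings.warn(f"transcripts without compositions excluded from MFA: {uncovered}")
    if not covered:
        raise ValueError("no transcript has a surviving composition")

    # occurrence: (start, end, left_anchored, right_anchored)
    occs: list[tuple[int, int, bool, bool]] = []
    for comps in covered.values():
        for comp in comps:
            n = len(comp.factors)
            for i, f in enumerate(comp.factors):
                occs.append((f.t_start, f.t_end, i > 0, i < n - 1))

    junctions = {s for s, e, la, ra in occs if la} | {e for s, e, la, ra in occs if ra}
    jmap = _cluster_boundaries(junctions, boundary_tol)

    def canon(s: int, e: int, la: bool, ra: bool) -> tuple[int, int, bool, bool]:
        return (jmap.get(s, s) if la else s, jmap.get(e, e) if ra else e, la, ra)

    occs = [canon(*o) for o in occs]

    # Group key: anchored junction signature.
    groups: dict[tuple, list[tuple[int, int, bool, bool]]] = {}
    free: list[tuple[int, int, bool, bool]] = []  # fully soft occurrences
    for o in occs:
        s, e, la, ra = o
        if la and ra:
            groups.setdefault(("B", s, e), []).append(o)
        elif la:
            groups.setdefault(("L", s), []).append(o)
        elif ra:
            groups.setdefault(("R", e), []).append(o)
        else:
            free.append(o)

    # Merge one-sided groups into fully anchored groups sharing the junction.
    anchored = {k for k in groups if k[0] == "B"}
    merged: dict[tuple, list] = {k: list(v) for k, v in groups.items() if k[0] == "B"}
    for k, v in groups.items():
        if k[0] == "B":
            continue
        if k[0] == "L":
            cands = sorted(a for a in anchored if a[1] == k[1])
        else:
            cands = sorted(a for a in anchored if a[2] == k[1])
        if cands:
            # most frequent anchored interval wins, ties leftmost
            tgt = max(cands, key=lambda a: (len(groups.get(a, [])), (-a[1], -a[2])))
            merged[tgt].extend(v)
        else:
            merged[k] = list(v)

    # Representative interval per group: anchored sides fixed, soft sides widest.
    reps: dict[tuple, tuple[int, int]] = {}
    for k, v in merged.items():
        if k[0] == "B":
            reps[k] = (k[1], k[2])
        elif k[0] == "L":
            reps[k] = (k[1], max(e for s, e, la, ra in v))
        else:
            reps[k] = (min(s for s, e, la, ra in v), k[1])

    # Fully soft occurrences attach to a containing representative, else
    # become their own factor (widest identical-occurrence extent).
    def key_for(o: tuple[int, int, bool, bool]) -> tuple:
        s, e, la, ra = o
        if la and ra:
            return ("B", s, e)
        if la:
            k = ("L", s)
        elif ra:
            k = ("R", e)
        else:
            conts = [k2 for k2, (rs, re) in reps.items() if rs <= s and e <= re]
            if conts:
                return min(conts, key=lambda k2: (reps[k2][1] - reps[k2][0], reps[k2]))
            return ("F", s, e)
        if k in merged:
            return k
        # one-sided group that was merged into an anchored one
        if k[0] == "L":
            cands = sorted(a for a in anchored if a[1] == k[1])
        else:
            cands = sorted(a for a in anchored if a[2] == k[1])
        return max(cands, key=lambda a: (len(groups.get(a, [])), (-a[1], -a[2])))

    for o in free:
        s, e, la, ra = o
        k = key_for(o)
        if k[0] == "F" and k not in reps:
            reps[k] = (s, e)
        elif k[0] == "F":
            rs, re = reps[k]
            reps[k] = (min(rs, s), max(re, e))

    ordered = sorted(set(reps.items()), key=lambda kv: (kv[1][0], kv[1][1]))
    index_of = {k: i for i, (k, _interval) in enumerate(ordered)}
    factors = [interval for _k, interval in ordered]

    factor_sets: dict[str, list[frozenset[int]]] = {}
    comps_out: dict[str, list[Composition]] = {}
    for tid, comps in sorted(covered.items()):
        sets: list[frozenset[int]] = []
        kept: list[Composition] = []
        for comp in comps:
            n = len(comp.factors)
            idxs = []
            for i, f in enumerate(comp.factors):
                o = canon(f.t_start, f.t_end, i > 0, i < n - 1)
                idxs.append(index_of[key_for(o)])
            fs = frozenset(idxs)
            if fs not in sets:
                sets.append(fs)
                kept.append(comp)
            else:
                j = sets.index(fs)
                if comp.total_edit < kept[j].total_edit:
                    kept[j] = comp
        factor_sets[tid] = sets
        comps_out[tid] = kept
    return FactorUniverse(factors, factor_sets, comps_out, uncovered)


def is_agreement_set(u: FactorUniverse, chosen: set[int]) -> bool:
    """True iff every transcript has a factor set fully inside ``chosen``."""
    return all(any(fs <= chosen for fs in sets) for sets in u.factor_sets.values())


def solve_mfa_exact(u: FactorUniverse, exact_limit: int = 24) -> set[int]:
    """Minimum-cardinality factorization agreement set.

    Iterative deepening over subset size with forced-factor preprocessing
    and bitmask feasibility checks; among minimum solutions the
    lexicographically smallest index set is returned. Refuses universes
    larger than ``exact_limit`` (use the greedy solver there).
    """
    nf = len(u.factors)
    if nf > exact_limit:
        raise ValueError(
            f"universe of {nf} factors exceeds exact_limit={exact_limit}; "
            "use solve_mfa_greedy")
    if not u.factor_sets:
        raise ValueError("no transcripts")
    masks = [
        [sum(1 << i for i in fs) for fs in sets]
        for sets in u.factor_sets.values()
    ]
    if any(not ms for ms in masks):
        raise ValueError("transcript with no factor set")
    # factors present in every factor set of some transcript are forced
    forced = 0
    for ms in masks:
        inter = ms[0]
        for m in ms[1:]:
            inter &= m
        forced |= inter
    union = 0
    for ms in masks:
        for m in ms:
            union |= m
    candidates = [i for i in range(nf) if union >> i & 1 and not forced >> i & 1]

    def valid(mask: int) -> bool:
        return all(any(m & ~mask == 0 for m in ms) for ms in masks)

    if valid(forced):
        return {i for i in range(nf) if forced >> i & 1}
    base = bin(forced).count("1")
    for extra in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, extra):
            mask = forced
            for i in combo:
                mask |= 1 << i
            if valid(mask):
                return {i for i in range(nf) if mask >> i & 1}
        if base + extra > nf:
            break
    raise AssertionError("unreachable: full universe is always an agreement set")


def solve_mfa_greedy(u: FactorUniverse) -> set[int]:
    """Valid (not necessarily minimum) agreement set, built greedily.

    Iteratively adds the factor that makes the largest number of not-yet
    satisfied transcripts' cheapest remaining factor sets complete, ties
    by lowest factor index; guaranteed valid, flagged non-optimal unless
    it matches the trivial forced-factor lower bound.
    """
    chosen: set[int] = set()
    # seed with each unsatisfied transcript's needs, factor by factor
    def unsatisfied() -> list[str]:
        return [tid for tid, sets in u.factor_sets.items()
                if not any(fs <= chosen for fs in sets)]

    while True:
        todo = unsatisfied()
        if not todo:
            return chosen
        gains: dict[int, int] = {}
        for tid in todo:
            best_missing = min(
                (fs - chosen for fs in u.factor_sets[tid]),
                key=lambda miss: (len(miss), sorted(miss)),
            )
            for f in best_missing:
                gains[f] = gains.get(f, 0) + (1 if len(best_missing) == 1 else 0)
        completing = {f: g for f, g in gains.items() if g > 0}
        if completing:
            pick = min(completing, key=lambda f: (-completing[f], f))
        else:
            pick = min(gains, key=lambda f: f)
        chosen.add(pick)


def select_compositions(u: FactorUniverse, chosen: set[int]) -> dict[str, Composition]:
    """One composition per transcript, restricted to the chosen factors.

    Among qualifying compositions picks the lowest total edit, ties by
    fewer factors, then leftmost genomic start.
    """
    out: dict[str, Composition] = {}
    for tid, sets in u.factor_sets.items():
        pool = [c for fs, c in zip(sets, u.compositions[tid]) if fs <= chosen]
        if not pool:
            raise ValueError(f"chosen set is not an agreement set: {tid} uncovered")
        out[tid] = min(pool, key=lambda c: (c.total_edit, len(c.factors),
                                            c.factors[0].t_start))
    return out


@dataclass
class GeneStructure:
    """MFA solution: selected exons plus one composition per transcript."""

    selected_factors: list[tuple[int, int]]
    chosen: dict[str, Composition]
    exact: bool
    uncovered: list[str] = field(default_factory=list)


def consensus_gene_structure(
    all_compositions: dict[str, list[Composition]],
    params: Parameters,
) -> GeneStructure:
    """Build the factor universe, solve MFA, select compositions."""
    u = build_factor_universe(all_compositions, params.boundary_tol)
    if len(u.factors) <= params.exact_limit:
        chosen = solve_mfa_exact(u, params.exact_limit)
        exact = True
    else:
        chosen = solve_mfa_greedy(u)
        exact = False
    assert is_agreement_set(u, chosen)
    selected = sorted(u.factors[i] for i in chosen)
    return GeneStructure(selected, select_compositions(u, chosen), exact, u.uncovered)


def universe_to_json(u: FactorUniverse) -> str:
    return json.dumps(
        {
            "factors": [list(f) for f in u.factors],
            "factor_sets": {
                tid: [sorted(fs) for fs in sets]
                for tid, sets in sorted(u.factor_sets.items())
            },
        },
        indent=2, sort_keys=True,
    )


def universe_from_json(text: str) -> FactorUniverse:
    data = json.loads(text)
    return FactorUniverse(
        [tuple(f) for f in data["factors"]],
        {tid: [frozenset(fs) for fs in sets]
         for tid, sets in data["factor_sets"].items()},
    )
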