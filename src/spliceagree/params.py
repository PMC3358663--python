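"""Tunable thresholds shared by every pipeline stage."""
from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Parameters:
    """Alignment and consensus thresholds.

    Attributes
    ----------
    ell_E:
        Minimum length (nt) of a pairing used as an alignment anchor.
    ell_D:
        Maximum span (nt) of a mismatch gap tolerated inside one exon.
    ell_I:
        Minimum intron length (nt); genomic gaps at least this long are
        interpreted as introns, shorter ones as alignment noise.
    max_factor_edit:
        Maximum edit distance allowed between a transcript factor and its
        genomic factor. Values < 1 are a fraction of the factor length
        (floored at ``min_abs_edit``); values >= 1 are an absolute count.
    b:
        Intron-reduction error budget: a junction may be shifted onto a
        better-supported intron if the re-alignment costs at most ``b``
        extra edit operations.
    min_factor_len:
        Minimum retained factor length (nt); compositions containing a
        shorter factor are rejected.
    source_window:
        Transcript-start window (nt) for extended sources of the embedding
        graph visit.
    end_clip:
        Maximum number of unaligned nucleotides tolerated at either
        transcript end (EST ends are noisy).
    boundary_tol:
        Junction clustering tolerance (nt) when building the factor
        universe for the consensus step.
    exact_limit:
        Largest factor universe handed to the exact consensus solver.
    max_embeddings_per_source / max_compositions:
        Visit-explosion guards.
    """

    ell_E: int = 15
    ell_D: int = 20
    ell_I: int = 60
    max_factor_edit: float = 0.05
    min_abs_edit: int = 2
    b: int = 4
    min_factor_len: int = 10
    source_window: int = 50
    end_clip: int = 30
    gap_edit_fraction: float = 0.3
    boundary_tol: int = 0
    exact_limit: int = 24
    max_embeddings_per_source: int = 10_000
    max_compositions: int = 500
    shift_window: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.ell_E < 1:
            raise ValueError("ell_E must be >= 1")
        if self.ell_D < 0:
            raise ValueError("ell_D must be >= 0")
        if self.ell_I <= self.ell_D:
            raise ValueError("ell_I must exceed ell_D")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.shift_window < 0:
            object.__setattr__(self, "shift_window", 2 * self.b + 6)

    def resolve_edit_threshold(self, length: int) -> int:
        """Edit-distance ceiling for a factor of the given length."""
        if self.max_factor_edit < 1:
            return max(self.min_abs_edit,
                       math.ceil(self.max_factor_edit * length))
        return int(self.max_factor_edit)

    def gap_edit_threshold(self, length: int) -> int:
        """Edit ceiling for the short gap joining two anchors of one exon.

        Gaps are bounded by ell_D and may be mismatch-dense (clustered
        sequencing errors), so the local filter is lenient; unrelated DNA
        still fails it (random 4-letter strings differ by roughly half
        their length), and the per-factor retention rule remains the
        final arbiter.
        """
        return max(self.min_abs_edit, math.ceil(self.gap_edit_fraction * length))


DEFAULT_PARAMS = Parameters()
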