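"""Design of G4-disrupting and loop-control mutants of a detected PQS.

Disruption follows the strategy that works best experimentally:
substitute guanines with adenines in the two *inner* G-runs (runs 2 and 3
of the four, in sequence order), which abolishes quadruplex formation
more reliably than touching the outer runs.  The loop control substitutes
a CG dinucleotide in a loop with TC — same loop length, untouched runs —
so the motif still folds and the scanner score is unchanged; it separates
structure effects from sequence effects.

Designs work for hits on either strand: substitutions are computed on the
scanned strand and reported (and applied) in plus-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .scanner import (
    DEFAULT_PARAMS,
    PQSHit,
    ScannerParams,
    reverse_complement,
    scan,
)

__all__ = [
    "MutantDesign",
    "design_g4_mutant",
    "design_loop_control",
    "make_mutagenic_primer",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class MutantDesign:
    """A same-length mutant with its substitution list.

    ``substitutions`` are (plus-strand position, from_base, to_base) on
    the input sequence; ``kind`` is ``g4_disrupting`` or ``loop_control``.
    """

    original_seq: str
    mutant_seq: str
    substitutions: tuple[tuple[int, str, str], ...]
    kind: str
    target_hit: PQSHit

    def __post_init__(self) -> None:
        if len(self.mutant_seq) != len(self.original_seq):
            raise ValueError("mutant must preserve sequence length")
        for pos, frm, to in self.substitutions:
            if self.original_seq[pos] != frm or self.mutant_seq[pos] != to:
                raise ValueError(f"substitution at {pos} inconsistent")


def _scanned_to_plus(pos: int, length: int, strand: str) -> int:
    return pos if strand == "+" else length - 1 - pos


def _apply_on_scanned(
    sequence: str, hit: PQSHit, scanned_subs: Sequence[tuple[int, str, str]], kind: str
) -> MutantDesign:
    """Map substitutions from the scanned strand back to plus coordinates."""
    seq = sequence.upper()
    n = len(seq)
    plus_subs = []
    for pos, frm, to in scanned_subs:
        if hit.strand == "-":
            pos = _scanned_to_plus(pos, n, "-")
            frm, to = _COMP[frm], _COMP[to]
        if seq[pos] != frm:
            raise ValueError(
                f"hit does not match sequence: expected {frm} at {pos}, "
                f"found {seq[pos]}"
            )
        plus_subs.append((pos, frm, to))
    plus_subs.sort()
    mutant = list(seq)
    for pos, _frm, to in plus_subs:
        mutant[pos] = to
    return MutantDesign(
        original_seq=seq,
        mutant_seq="".join(mutant),
        substitutions=tuple(plus_subs),
        kind=kind,
        target_hit=hit,
    )


def _working_strand(sequence: str, hit: PQSHit) -> str:
    seq = sequence.upper()
    return seq if hit.strand == "+" else reverse_complement(seq)


def design_g4_mutant(
    sequence: str,
    hit: PQSHit,
    params: ScannerParams = DEFAULT_PARAMS,
    n_subs_per_run: int | None = None,
    verify_threshold: float | None = None,
) -> MutantDesign:
    """G->A substitutions in the two inner runs of ``hit``.

    By default every guanine of runs 2 and 3 is replaced (guaranteeing no
    surviving run of ``min_run_len``); ``n_subs_per_run`` limits the count
    (taken from the run's 5' end on the scanned strand).  The design is
    verified by re-scanning: no hit on the hit's strand may overlap the
    original interval at ``verify_threshold`` (the report threshold when
    None).  In long sequences whose background holds many two-tetrad
    runs, weak overlapping candidates can be unavoidable; verifying at
    the strict threshold then asserts loss of the quadruplex proper.
    """
    work = _working_strand(sequence, hit)
    scanned_subs: list[tuple[int, str, str]] = []
    for run in hit.runs[1:3]:
        g_positions = [i for i in range(run.start, run.end) if work[i] == "G"]
        if not g_positions:
            raise ValueError("hit does not match sequence: inner run has no G")
        if n_subs_per_run is not None:
            g_positions = g_positions[:n_subs_per_run]
        scanned_subs.extend((i, "G", "A") for i in g_positions)
    design = _apply_on_scanned(sequence, hit, scanned_subs, "g4_disrupting")

    floor = params.report_threshold if verify_threshold is None else verify_threshold
    surviving = [
        h
        for h in scan(design.mutant_seq, params, strands=hit.strand)
        if h.overlaps(hit.start, hit.end) and h.score >= floor
    ]
    if surviving:
        raise ValueError(
            "disruption failed verification: a PQS overlapping the target "
            f"interval survives with score {surviving[0].score:g}; "
            "increase n_subs_per_run or substitute all inner-run guanines"
        )
    return design


def design_loop_control(
    sequence: str,
    hit: PQSHit,
    motif_from: str = "CG",
    motif_to: str = "TC",
    params: ScannerParams = DEFAULT_PARAMS,
) -> MutantDesign:
    """Replace the first loop occurrence of ``motif_from`` with ``motif_to``.

    Both motifs must have equal length so loop lengths — and hence the
    score — are untouched.  Verified by re-scanning: the mutant must carry
    a hit with the same run structure and identical score over the
    original interval.
    """
    if len(motif_from) != len(motif_to):
        raise ValueError("control substitution must preserve loop length")
    work = _working_strand(sequence, hit)
    loop_spans = [
        (a.end, b.start) for a, b in zip(hit.runs[:3], hit.runs[1:])
    ]
    found = None
    for s, e in loop_spans:
        idx = work.find(motif_from, s, e - len(motif_from) + 1)
        if idx >= 0:
            found = idx
            break
    if found is None:
        raise ValueError(
            f"motif {motif_from!r} not found in any loop of the target hit"
        )
    scanned_subs = [
        (found + k, motif_from[k], motif_to[k])
        for k in range(len(motif_from))
        if motif_from[k] != motif_to[k]
    ]
    design = _apply_on_scanned(sequence, hit, scanned_subs, "loop_control")

    retained = [
        h
        for h in scan(design.mutant_seq, params, strands=hit.strand)
        if h.overlaps(hit.start, hit.end)
    ]
    ok = any(
        h.score == hit.score
        and tuple((r.start, r.end) for r in h.runs)
        == tuple((r.start, r.end) for r in hit.runs)
        for h in retained
    )
    if not ok:
        raise ValueError(
            "loop control altered the run structure or score; choose a "
            "substitution confined to loop positions"
        )
    return design


def make_mutagenic_primer(
    sequence: str, design: MutantDesign, flank: int = 20
) -> str:
    """Mutant subsequence spanning all substitutions plus ``flank`` nt on
    each side (clipped at the sequence ends)."""
    if flank < 10:
        raise ValueError("flank must be >= 10 nt for a usable primer")
    positions = [p for p, _f, _t in design.substitutions]
    lo = max(0, min(positions) - flank)
    hi = min(len(design.mutant_seq), max(positions) + 1 + flank)
    return design.mutant_seq[lo:hi]
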