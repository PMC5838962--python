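"""Detection and scoring of potential quadruplex-forming sequences (PQS).

A G-quadruplex (G4) is a four-stranded nucleic-acid structure built from
stacked tetrads of guanines.  On the sequence level a *potential*
quadruplex-forming sequence is four suitably spaced guanine runs::

    G{n} loop G{n} loop G{n} loop G{n}

The scanner enumerates ordered four-run combinations of guanine tracts
(perfect tracts and singly-bulged tracts), scores each candidate with a
simple additive model — a reward per guanine tetrad, a penalty per
nucleotide of mean loop length, a penalty per bulged run — and reports
greedily selected non-overlapping candidates per strand.  The scoring
constants are calibrated so that one bulge or ~25 nt of extra mean loop
cancels the stabilising effect of one extra tetrad.

Minus-strand motifs are found by scanning the reverse complement; their
reported coordinates are always on the plus strand of the input.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "ScannerParams",
    "GRun",
    "PQSHit",
    "ScoreTier",
    "find_g_runs",
    "score_candidate",
    "scan",
    "classify_score",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RE = re.compile(r"[^ACGTN]")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the DNA alphabet A/C/G/T/N (case-insensitive)."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScannerParams:
    """Constraint system and scoring constants for PQS detection.

    Parameters
    ----------
    min_run_len
        Minimum guanines in a perfect G-run (biological floor is 2; two
        tetrads are the least that can stack).
    max_run_len_counted
        Cap on guanines per run counted toward the tetrad number; extra
        guanines beyond the cap neither score nor hurt.
    loop_min, loop_max
        Admissible loop lengths in nt.  Long loops up to 50 nt are kept
        admissible because biologically relevant motifs with 27–49 nt
        central loops exist.
    max_pqs_len
        Cap on the total candidate span in nt.
    tetrad_reward, loop_penalty_per_nt, bulge_penalty
        Additive scoring constants; defaults make one bulge cancel exactly
        one tetrad and ~25 nt of mean loop cancel one tetrad.
    max_bulged_runs
        How many of the four runs may be bulged.
    report_threshold, high_score_threshold, strict_threshold
        Score tiers: hits are reported at ``report_threshold``;
        ``classify_score`` grades them with strict ``>`` comparisons
        against all three thresholds (24 / 64 / 65 by default — the two
        top tiers are deliberately distinct knobs).
    """

    min_run_len: int = 2
    max_run_len_counted: int = 5
    loop_min: int = 1
    loop_max: int = 50
    max_pqs_len: int = 110
    tetrad_reward: float = 25.0
    loop_penalty_per_nt: float = 1.0
    bulge_penalty: float = 25.0
    max_bulged_runs: int = 1
    report_threshold: float = 24.0
    high_score_threshold: float = 64.0
    strict_threshold: float = 65.0

    def __post_init__(self) -> None:
        if self.min_run_len < 2:
            raise ValueError("min_run_len must be >= 2")
        if self.loop_min > self.loop_max:
            raise ValueError("loop_min must be <= loop_max")
        if self.loop_min < 0:
            raise ValueError("loop_min must be >= 0")
        if not (
            self.report_threshold
            <= self.high_score_threshold
            <= self.strict_threshold
        ):
            raise ValueError(
                "thresholds must satisfy report <= high_score <= strict"
            )
        for name in ("tetrad_reward", "loop_penalty_per_nt", "bulge_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_PARAMS = ScannerParams()


@dataclass(frozen=True)
class GRun:
    """One guanine tract on the scanned strand (0-based half-open coords).

    A *perfect* run is a maximal tract of consecutive G.  A *bulged* run is
    two G segments of at least two guanines each separated by a single
    1–3 nt non-G insert, with at least ``min_run_len + 1`` guanines in
    total.  A lone guanine flanked by non-G bases is loop material and
    never seeds a bulged run.
    """

    start: int
    end: int
    g_count: int
    bulged: bool = False
    insert_len: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("GRun end must exceed start")
        if self.bulged and not (1 <= self.insert_len <= 3):
            raise ValueError("bulged run insert must be 1-3 nt")
        if not self.bulged and self.insert_len != 0:
            raise ValueError("perfect run cannot carry an insert")


class ScoreTier(str, Enum):
    """Score tier of a reported hit; comparisons are strict ``>``."""

    BELOW = "below"
    REPORTED = "reported"
    HIGH_SCORING = "high_scoring"
    STRICT = "strict"


@dataclass(frozen=True)
class PQSHit:
    """A scored PQS candidate.

    ``start``/``end`` are plus-strand coordinates of the input sequence
    regardless of ``strand``; ``runs`` keep the coordinates of the strand
    that was scanned (for a minus hit, coordinates on the reverse
    complement).  ``tetrads`` is the minimum effective run length across
    the four runs.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    runs: tuple[GRun, GRun, GRun, GRun]
    loops: tuple[int, int, int]
    tetrads: int
    n_bulged: int
    score: float

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    m = _VALID_RE.search(seq)
    if m:
        raise ValueError(
            f"non-IUPAC character {seq[m.start()]!r} at position {m.start()}"
        )
    return seq


def find_g_runs(sequence: str, params: ScannerParams = DEFAULT_PARAMS) -> list[GRun]:
    """All candidate guanine runs of ``sequence``, sorted by start.

    Returns every maximal perfect G tract of length >= ``min_run_len``
    plus every bulged run (two G segments split by one 1–3 nt non-G
    insert, total guanines >= ``min_run_len + 1``).  N never extends a
    run; it is treated as loop (or bulge-insert) material.
    """
    seq = _validate_sequence(sequence)
    tracts = [(m.start(), m.end()) for m in re.finditer(r"G+", seq)]
    runs: list[GRun] = [
        GRun(s, e, e - s) for s, e in tracts if e - s >= params.min_run_len
    ]
    if params.max_bulged_runs > 0:
        for (s1, e1), (s2, e2) in zip(tracts, tracts[1:]):
            gap = s2 - e1
            g_total = (e1 - s1) + (e2 - s2)
            if e1 - s1 < 2 or e2 - s2 < 2:
                continue
            if 1 <= gap <= 3 and g_total >= params.min_run_len + 1:
                runs.append(GRun(s1, e2, g_total, bulged=True, insert_len=gap))
    runs.sort(key=lambda r: (r.start, r.end))
    return runs


def score_candidate(
    runs: Sequence[GRun],
    loops: Sequence[int],
    params: ScannerParams = DEFAULT_PARAMS,
) -> float:
    """Additive score of a four-run candidate.

    score = tetrads * tetrad_reward
            - mean(loops) * loop_penalty_per_nt
            - n_bulged * bulge_penalty

    where tetrads = min over the four runs of min(g_count,
    max_run_len_counted).  Monotone non-decreasing in tetrads,
    non-increasing in loop lengths and in the number of bulges.
    """
    if len(runs) != 4:
        raise ValueError("a PQS candidate has exactly 4 G-runs")
    if len(loops) != 3:
        raise ValueError("a PQS candidate has exactly 3 loops")
    tetrads = min(min(r.g_count, params.max_run_len_counted) for r in runs)
    n_bulged = sum(1 for r in runs if r.bulged)
    return (
        tetrads * params.tetrad_reward
        - (sum(loops) / 3.0) * params.loop_penalty_per_nt
        - n_bulged * params.bulge_penalty
    )


def _enumerate_candidates(
    runs: list[GRun], params: ScannerParams
) -> list[tuple[tuple[GRun, GRun, GRun, GRun], tuple[int, int, int], float]]:
    """All constraint-satisfying ordered four-run tuples with their scores."""
    out = []
    starts = [r.start for r in runs]
    n = len(runs)

    def successors(prev: GRun) -> Iterable[GRun]:
        lo = bisect_left(starts, prev.end + params.loop_min)
        for idx in range(lo, n):
            r = runs[idx]
            gap = r.start - prev.end
            if gap > params.loop_max:
                # starts are sorted but runs of different lengths share
                # starts; a longer gap for one start can still admit later
                # runs only if their starts are within reach
                if r.start - prev.end > params.loop_max:
                    break
            if params.loop_min <= gap <= params.loop_max:
                yield r

    for r1 in runs:
        for r2 in successors(r1):
            if r2.end - r1.start > params.max_pqs_len:
                continue
            for r3 in successors(r2):
                if r3.end - r1.start > params.max_pqs_len:
                    continue
                for r4 in successors(r3):
                    if r4.end - r1.start > params.max_pqs_len:
                        continue
                    quad = (r1, r2, r3, r4)
                    if sum(r.bulged for r in quad) > params.max_bulged_runs:
                        continue
                    loops = (
                        r2.start - r1.end,
                        r3.start - r2.end,
                        r4.start - r3.end,
                    )
                    out.append((quad, loops, score_candidate(quad, loops, params)))
    return out


def _select_non_overlapping(candidates, params):
    """Greedy overlap resolution: highest score wins; ties broken by more
    tetrads, shorter span, leftmost start."""
    def tetrads_of(quad):
        return min(min(r.g_count, params.max_run_len_counted) for r in quad)

    ranked = sorted(
        candidates,
        key=lambda c: (
            -c[2],
            -tetrads_of(c[0]),
            c[0][3].end - c[0][0].start,
            c[0][0].start,
        ),
    )
    accepted: list[tuple] = []
    for quad, loops, score in ranked:
        s, e = quad[0].start, quad[3].end
        if all(not (s < ae and as_ < e) for as_, ae in accepted):
            accepted.append((s, e))
            yield quad, loops, score


def scan(
    sequence: str,
    params: ScannerParams = DEFAULT_PARAMS,
    strands: str = "both",
    seq_id: str = "seq",
) -> list[PQSHit]:
    """Scan a sequence for PQS on the requested strands.

    ``strands`` is one of ``"+"``, ``"-"`` or ``"both"``.  Minus-strand
    hits are found on the reverse complement and reported in plus-strand
    coordinates.  Only hits scoring at least ``params.report_threshold``
    are returned, sorted by plus-strand start.
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError('strands must be "+", "-" or "both"')
    seq = _validate_sequence(sequence)
    length = len(seq)
    hits: list[PQSHit] = []

    todo = []
    if strands in {"+", "both"}:
        todo.append(("+", seq))
    if strands in {"-", "both"}:
        todo.append(("-", reverse_complement(seq)))

    for strand, work in todo:
        runs = find_g_runs(work, params)
        candidates = [
            c
            for c in _enumerate_candidates(runs, params)
            if c[2] >= params.report_threshold
        ]
        for quad, loops, score in _select_non_overlapping(candidates, params):
            s, e = quad[0].start, quad[3].end
            if strand == "-":
                s, e = length - e, length - s
            hits.append(
                PQSHit(
                    seq_id=seq_id,
                    start=s,
                    end=e,
                    strand=strand,
                    runs=quad,
                    loops=loops,
                    tetrads=min(
                        min(r.g_count, params.max_run_len_counted) for r in quad
                    ),
                    n_bulged=sum(r.bulged for r in quad),
                    score=score,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def classify_score(
    hit: PQSHit | float, params: ScannerParams = DEFAULT_PARAMS
) -> ScoreTier:
    """Tier of a hit (or bare score) under strict ``>`` threshold tests."""
    score = hit.score if isinstance(hit, PQSHit) else float(hit)
    if score > params.strict_threshold:
        return ScoreTier.STRICT
    if score > params.high_score_threshold:
        return ScoreTier.HIGH_SCORING
    if score > params.report_threshold:
        return ScoreTier.REPORTED
    return ScoreTier.BELOW
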