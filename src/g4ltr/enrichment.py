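"""Per-family and per-superfamily PQS statistics and positional profiles.

Answers the questions a motif-in-TE survey asks: what fraction of
families carry at least one PQS, how many motifs does a carrier hold, how
motif density (per family and kb) differs between LTR and internal
regions, how hits split by strand, and where hits fall along the
length-normalised element (meta-profiles in 2%-of-length windows with an
overlay of LTR length fractions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scanner import PQSHit
from .te import Region, Superfamily, TERecord, classify_position, normalized_position

__all__ = [
    "FamilySummary",
    "SuperfamilyStats",
    "PositionalProfile",
    "summarize_family",
    "aggregate",
    "positional_profile",
]


@dataclass(frozen=True)
class FamilySummary:
    """PQS counts of one family, split by strand and region.

    A hit is assigned to the region of its start position; with a positive
    margin the NEAR_LTR neighborhood is grouped with the LTR counts (the
    way count statements group "LTRs and their immediate neighborhood"),
    while the length denominators always use the annotated LTR intervals
    only.
    """

    te_id: str
    superfamily: Superfamily
    n_pqs_plus: int
    n_pqs_minus: int
    counts: Mapping[tuple[str, str], int]  # (region "LTR"/"INT", strand)
    ltr_len_total: int
    int_len_total: int
    total_len: int

    @property
    def n_pqs(self) -> int:
        return self.n_pqs_plus + self.n_pqs_minus


@dataclass(frozen=True)
class SuperfamilyStats:
    superfamily: str
    n_families: int
    frac_families_with_pqs: float
    mean_pqs_per_pqs_family: float
    density_ltr: float  # PQS per kb, per family then averaged
    density_int: float
    density_whole: float
    frac_minus_strand: float
    frac_plus_in_ltr: float


@dataclass(frozen=True)
class PositionalProfile:
    superfamily: str
    strand: str
    window_frac: float
    counts: np.ndarray  # one bin per window tiling [0, 1)
    ltr_overlay: tuple[float, float, float]  # (q3, mean, max) LTR length fraction
    n_hits: int


def summarize_family(
    te: TERecord, hits: Sequence[PQSHit], margin: int = 0
) -> FamilySummary:
    """Tabulate a family's hits by strand and region (LTR vs INT)."""
    counts: Counter = Counter()
    n_plus = n_minus = 0
    for h in hits:
        if h.seq_id != te.te_id or not (0 <= h.start < te.length):
            raise ValueError(f"hit {h.seq_id}:{h.start} outside {te.te_id}")
        call = classify_position(te, h.start, margin=margin)
        region = "LTR" if call.region in (Region.LTR, Region.NEAR_LTR) else "INT"
        counts[(region, h.strand)] += 1
        if h.strand == "+":
            n_plus += 1
        else:
            n_minus += 1
    for key in (("LTR", "+"), ("LTR", "-"), ("INT", "+"), ("INT", "-")):
        counts.setdefault(key, 0)
    return FamilySummary(
        te_id=te.te_id,
        superfamily=te.superfamily,
        n_pqs_plus=n_plus,
        n_pqs_minus=n_minus,
        counts=dict(counts),
        ltr_len_total=te.ltr_len_total,
        int_len_total=te.int_len_total,
        total_len=te.length,
    )


def _stats_for(group: Sequence[FamilySummary], label: str) -> SuperfamilyStats:
    n_fam = len(group)
    with_pqs = [s for s in group if s.n_pqs > 0]
    total_hits = sum(s.n_pqs for s in group)
    total_minus = sum(s.n_pqs_minus for s in group)
    total_plus = sum(s.n_pqs_plus for s in group)
    plus_in_ltr = sum(s.counts[("LTR", "+")] for s in group)

    def mean_density(count_of, len_of) -> float:
        vals = [
            count_of(s) / (len_of(s) / 1000.0) for s in group if len_of(s) > 0
        ]
        return float(np.mean(vals)) if vals else float("nan")

    return SuperfamilyStats(
        superfamily=label,
        n_families=n_fam,
        frac_families_with_pqs=len(with_pqs) / n_fam,
        mean_pqs_per_pqs_family=(
            float(np.mean([s.n_pqs for s in with_pqs])) if with_pqs else 0.0
        ),
        density_ltr=mean_density(
            lambda s: s.counts[("LTR", "+")] + s.counts[("LTR", "-")],
            lambda s: s.ltr_len_total,
        ),
        density_int=mean_density(
            lambda s: s.counts[("INT", "+")] + s.counts[("INT", "-")],
            lambda s: s.int_len_total,
        ),
        density_whole=mean_density(lambda s: s.n_pqs, lambda s: s.total_len),
        frac_minus_strand=total_minus / total_hits if total_hits else float("nan"),
        frac_plus_in_ltr=plus_in_ltr / total_plus if total_plus else float("nan"),
    )


def aggregate(summaries: Sequence[FamilySummary]) -> dict[str, SuperfamilyStats]:
    """Per-superfamily statistics plus an "All" row.

    ``frac_families_with_pqs`` is over all families;
    ``mean_pqs_per_pqs_family`` conditions on carrying at least one hit.
    Densities are per-family PQS/kb averaged across families (families
    with a zero-length denominator, e.g. no annotated LTRs, are excluded
    from that density's mean).  Permutation-invariant in input order.
    """
    if not summaries:
        raise ValueError("aggregate needs at least one family summary")
    out: dict[str, SuperfamilyStats] = {}
    for sf in sorted({s.superfamily for s in summaries}, key=lambda s: s.value):
        group = [s for s in summaries if s.superfamily == sf]
        out[sf.value] = _stats_for(group, sf.value)
    out["All"] = _stats_for(list(summaries), "All")
    return out


def aggregate_table(summaries: Sequence[FamilySummary]) -> pd.DataFrame:
    """``aggregate`` as a DataFrame, one row per superfamily plus "All"."""
    rows = [vars(st) for st in aggregate(summaries).values()]
    return pd.DataFrame(rows).set_index("superfamily")


def positional_profile(
    tes: Sequence[TERecord],
    hits: Sequence[PQSHit],
    window_frac: float = 0.02,
    strand: str = "both",
    score_floor: float | None = None,
    superfamily: Superfamily | None = None,
) -> PositionalProfile:
    """Meta-profile of hit start positions along length-normalised elements.

    Hits are binned by ``normalized_position`` of their plus-strand start
    into ``1/window_frac`` windows tiling [0, 1), optionally filtered by
    strand, score floor (strict ``>``) and superfamily.  The LTR overlay
    reports (3rd quartile, mean, max) of per-LTR length fractions of the
    profiled element set.
    """
    if not tes:
        raise ValueError("positional_profile needs at least one element")
    n_windows = round(1.0 / window_frac)
    if abs(n_windows * window_frac - 1.0) > 1e-9:
        raise ValueError("window_frac must divide 1 evenly")
    by_id = {te.te_id: te for te in tes}
    if superfamily is not None:
        by_id = {k: v for k, v in by_id.items() if v.superfamily == superfamily}
    counts = np.zeros(n_windows, dtype=int)
    n_hits = 0
    for h in hits:
        te = by_id.get(h.seq_id)
        if te is None:
            continue
        if strand != "both" and h.strand != strand:
            continue
        if score_floor is not None and not (h.score > score_floor):
            continue
        frac = normalized_position(te, h.start)
        counts[min(int(frac / window_frac), n_windows - 1)] += 1
        n_hits += 1
    ltr_fracs = [
        (iv[1] - iv[0]) / te.length
        for te in by_id.values()
        for iv in (te.ltr5, te.ltr3)
        if iv is not None
    ]
    if ltr_fracs:
        arr = np.asarray(ltr_fracs)
        overlay = (
            float(np.percentile(arr, 75)),
            float(arr.mean()),
            float(arr.max()),
        )
    else:
        overlay = (float("nan"),) * 3
    return PositionalProfile(
        superfamily=superfamily.value if superfamily else "All",
        strand=strand,
        window_frac=window_frac,
        counts=counts,
        ltr_overlay=overlay,
        n_hits=n_hits,
    )
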