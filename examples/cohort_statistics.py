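"""Enrichment statistics on a synthetic LTR-retrotransposon cohort.

Generates 200 TE families with planted PQS (37% of families carry
motifs, minus-strand bias 0.79, LTR:INT density ratio 2, LTR length
fraction ~0.10), scans both strands, and recovers the planted structure:
strand fraction, per-kb density contrast between LTRs and internal
regions, and the positional meta-profile overlay.
"""

from g4ltr import (
    ScoreTier,
    aggregate_table,
    classify_score,
    gen_te_cohort,
    positional_profile,
    scan,
    summarize_family,
)

records, truth = gen_te_cohort(n_families=200, seed=7)
summaries, strict_hits = [], []
for te in records:
    hits = [
        h
        for h in scan(te.sequence, strands="both", seq_id=te.te_id)
        if classify_score(h) is ScoreTier.STRICT
    ]
    strict_hits.extend(hits)
    summaries.append(summarize_family(te, hits))

table = aggregate_table(summaries)
cols = [
    "frac_families_with_pqs",
    "mean_pqs_per_pqs_family",
    "density_ltr",
    "density_int",
    "frac_minus_strand",
]
print(table[cols].round(3))

prof = positional_profile(records, strict_hits)
q3, mean, mx = prof.ltr_overlay
print(f"\nstrict-tier hits: {len(strict_hits)} (planted: {len(truth.planted_pqs)})")
print(f"LTR length fraction overlay: q3={q3:.3f} mean={mean:.3f} max={mx:.3f}")
print(
    "\nDensities are PQS per kb per family; the LTR column should sit near "
    "twice the INT column, the minus-strand fraction near 0.79 and the "
    "mean LTR fraction near 0.10 — the parameters the cohort was built with."
)
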