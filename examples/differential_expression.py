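"""TE-level differential expression on a synthetic 4-vs-4 count matrix.

Negative-binomial counts for 2000 elements with 5% planted 8-fold
(|LFC| = 3) changes.  The pipeline: CPM, the literal low-expression
filter (drop elements with CPM < 45 in at least 3 samples), the pooled
conditioned-binomial exact test, Benjamini-Hochberg adjustment, and DE
calls at |LFC| > 1.5 and FDR < 0.05.
"""

from g4ltr import de_test, filter_low_expression, gen_count_matrix, normalization_factors

matrix, groups, truth = gen_count_matrix(
    n_te=2000, n_per_group=4, de_frac=0.05, true_lfc=3.0, seed=1
)
retained, filtered = filter_low_expression(matrix)
print(f"{len(filtered)} of {len(matrix)} elements removed by the CPM filter")

factors = normalization_factors(matrix, method="tmm")
print("TMM factors:", ", ".join(f"{f:.3f}" for f in factors))

res = de_test(matrix, groups)
called = res[res["status"].isin(["DE_up", "DE_down"])]
planted = set(truth.de_true_lfc)
tp = len(set(called.index) & planted)
print(f"\nDE calls: {len(called)} ({(res['status'] == 'DE_up').sum()} up, "
      f"{(res['status'] == 'DE_down').sum()} down)")
print(f"planted changes recovered: {tp}/{len(planted)}; "
      f"false discoveries: {len(called) - tp}")
print(res.loc[sorted(planted)[:5]].round(3).to_string())
print(
    "\nEach row shows group mean CPM, log2 fold change, the exact-test "
    "p-value and its BH adjustment; recovery should be near-complete at "
    "8-fold with almost no false calls."
)
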