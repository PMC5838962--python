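"""Count-matrix filtering, differential-expression calls and coverage.

The workflow mirrors a TE-level RNA-Seq comparison of treated vs control
libraries: counts per element (fractional values allowed, as produced by
fractional assignment of multi-mapped reads) are converted to CPM, poorly
expressed elements are removed with a literal low-expression rule (an
element is dropped when at least ``min_samples`` samples fall below the
CPM threshold; the conventional keep-rule is available behind a flag),
and the retained elements are tested between groups.

The between-group test is a stand-in for a negative-binomial exact test:
a conditioned binomial exact test on pooled, normalisation-adjusted
counts per group (exact for equal effective library sizes, ignoring
overdispersion).  Externally computed p-values can be plugged in for
parity studies.  Log2 fold changes use a 0.5 prior count; adjustment is
Benjamini-Hochberg; elements are called DE at |LFC| > 1.5 and FDR < 0.05.

Per-base coverage vectors are scaled by per-library normalisation
factors (TMM or total-count) and averaged within a group, with detected
G4 positions overlaid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scanner import PQSHit

__all__ = [
    "cpm",
    "filter_low_expression",
    "normalization_factors",
    "de_test",
    "CoverageProfile",
    "aggregate_coverage",
]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample: counts / library total * 1e6."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"library with zero total counts: {bad}")
    return counts / totals * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    cpm_threshold: float = 45.0,
    min_samples: int = 3,
    rule: str = "remove_low",
) -> tuple[list, list]:
    """Split elements into (retained, filtered) by the CPM rule.

    ``rule="remove_low"`` (default, the literal reading): an element is
    removed iff at least ``min_samples`` samples have CPM below
    ``cpm_threshold``.  ``rule="keep_high"`` (conventional): an element is
    retained iff at least ``min_samples`` samples have CPM at or above the
    threshold.  Both lists are returned, in input order.
    """
    if counts.shape[1] < min_samples:
        raise ValueError("fewer samples than min_samples")
    below = (cpm(counts) < cpm_threshold).sum(axis=1)
    if rule == "remove_low":
        removed = below >= min_samples
    elif rule == "keep_high":
        removed = (counts.shape[1] - below) < min_samples
    else:
        raise ValueError('rule must be "remove_low" or "keep_high"')
    retained = counts.index[~removed].tolist()
    filtered = counts.index[removed].tolist()
    return retained, filtered


def _tmm_factor(counts: pd.DataFrame, lib: str, ref: str) -> float:
    """Trimmed mean of M-values of one library against the reference
    (30% M-trim, 5% A-trim, precision weights)."""
    y = counts[lib].to_numpy(dtype=float)
    r = counts[ref].to_numpy(dtype=float)
    n_y, n_r = y.sum(), r.sum()
    keep = (y > 0) & (r > 0)
    y, r = y[keep], r[keep]
    if y.size == 0:
        return 1.0
    m = np.log2((y / n_y) / (r / n_r))
    a = 0.5 * np.log2((y / n_y) * (r / n_r))
    w = (n_y - y) / (n_y * y) + (n_r - r) / (n_r * r)
    lo_m, hi_m = np.quantile(m, [0.30, 0.70])
    lo_a, hi_a = np.quantile(a, [0.05, 0.95])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 1.0
    return float(2 ** (np.sum(m[keep] * (1 / w[keep])) / np.sum(1 / w[keep])))


def normalization_factors(
    counts: pd.DataFrame, method: str = "tmm"
) -> pd.Series:
    """Per-library normalisation factors, scaled to geometric mean 1.

    ``method="total"``: factors proportional to 1/library total.
    ``method="tmm"``: trimmed mean of M-values against the library whose
    upper-quartile CPM is closest to the mean upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two libraries")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero library")
    if method == "total":
        factors = 1.0 / totals
    elif method == "tmm":
        uq = cpm(counts).quantile(0.75, axis=0)
        ref = (uq - uq.mean()).abs().idxmin()
        tmm = pd.Series(
            {lib: _tmm_factor(counts, lib, ref) for lib in counts.columns}
        )
        # effective library size = total * TMM; scale counts by its inverse
        factors = 1.0 / (totals * tmm)
    else:
        raise ValueError('method must be "tmm" or "total"')
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return factors.reindex(counts.columns)


def _binom_two_sided(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Vectorised central two-sided binomial p-value: 2*min(cdf, sf) capped."""
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def de_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    retained: Sequence | None = None,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    prior_count: float = 0.5,
    norm_method: str = "tmm",
    external_pvalues: pd.Series | None = None,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Two-group exact-test stand-in with BH adjustment and DE status.

    ``groups`` maps sample id to "treated" or "control".  Elements not in
    ``retained`` (when given) are carried through with status
    ``filtered``.  Returns a DataFrame indexed by element with per-group
    mean CPM, ``lfc`` (log2, prior ``prior_count`` added to mean CPMs),
    ``p``, ``fdr`` and ``status`` in {DE_up, DE_down, not_DE, filtered}.
    """
    treated = [s for s in counts.columns if groups.get(s) == "treated"]
    control = [s for s in counts.columns if groups.get(s) == "control"]
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    if min(len(treated), len(control)) < min_per_group:
        raise ValueError(
            f"each group needs at least {min_per_group} libraries "
            f"(got {len(treated)} treated, {len(control)} control)"
        )

    cpm_mat = cpm(counts)
    mean_t = cpm_mat[treated].mean(axis=1)
    mean_c = cpm_mat[control].mean(axis=1)
    lfc = np.log2((mean_t + prior_count) / (mean_c + prior_count))

    if retained is None:
        retained = counts.index
    retained = pd.Index(retained)

    if external_pvalues is not None:
        pvals = external_pvalues.reindex(retained).to_numpy(dtype=float)
    else:
        # pool factor-adjusted counts per group; binomial test conditioned
        # on the pooled total with success probability n_treated / n_total
        factors = normalization_factors(counts, method=norm_method)
        eff = counts.sum(axis=0) * factors
        adj = counts * (eff.mean() / eff)
        sum_t = adj.loc[retained, treated].sum(axis=1).round().to_numpy()
        sum_c = adj.loc[retained, control].sum(axis=1).round().to_numpy()
        n = sum_t + sum_c
        p_null = len(treated) / (len(treated) + len(control))
        with np.errstate(invalid="ignore"):
            pvals = _binom_two_sided(sum_t, n, p_null)
        pvals = np.where(n > 0, pvals, 1.0)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "mean_cpm_treated": mean_t,
            "mean_cpm_control": mean_c,
            "lfc": lfc,
            "p": np.nan,
            "fdr": np.nan,
            "status": "filtered",
        },
        index=counts.index,
    )
    result.loc[retained, "p"] = pvals
    result.loc[retained, "fdr"] = fdr
    is_de = (result["lfc"].abs() > lfc_threshold) & (result["fdr"] < fdr_threshold)
    status = np.where(
        is_de & (result["lfc"] > 0),
        "DE_up",
        np.where(is_de, "DE_down", "not_DE"),
    )
    result.loc[retained, "status"] = pd.Series(status, index=counts.index).loc[
        retained
    ]
    return result


@dataclass(frozen=True)
class CoverageProfile:
    """Group-averaged, normalised per-base coverage of one element."""

    te_id: str
    coverage: np.ndarray
    norm_factors: tuple[float, ...]
    group: str
    g4_positions: tuple[tuple[int, str], ...] = ()


def aggregate_coverage(
    per_library_coverage: Sequence[np.ndarray],
    norm_factors: Sequence[float],
    group: str = "all",
    te_id: str = "te",
    hits: Sequence[PQSHit] = (),
) -> CoverageProfile:
    """Mean over libraries of (coverage x its normalisation factor).

    All vectors must share one length; ``hits`` (from the scanner) are
    carried along as (start, strand) overlay positions.
    """
    vectors = [np.asarray(v, dtype=float) for v in per_library_coverage]
    if len(vectors) != len(norm_factors):
        raise ValueError("one normalisation factor per library is required")
    lengths = {v.shape[0] for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"coverage vectors differ in length: {sorted(lengths)}")
    profile = np.mean(
        [v * f for v, f in zip(vectors, norm_factors)], axis=0
    )
    return CoverageProfile(
        te_id=te_id,
        coverage=profile,
        norm_factors=tuple(float(f) for f in norm_factors),
        group=group,
        g4_positions=tuple((h.start, h.strand) for h in hits),
    )
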