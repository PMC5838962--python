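"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the real inputs —
a database of LTR-retrotransposon family consensuses with planted PQS,
a six-colony / three-replicate reporter-assay plate, negative-binomial
treated-vs-control count matrices with planted differential expression,
and per-base coverage vectors with an LTR peak — while recording ground
truth so every downstream stage can be tested for recovery.

Background sequences are G4-free *by construction* at the strict score
tier: G and C homopolymer runs are capped at two nucleotides, and a
strict-tier hit (score > 65 under default scoring) requires four runs of
at least three guanines with at most one bulge, which capped background
cannot supply.  Planted motifs are therefore the only strict-tier signal
and planted-truth recovery is well defined.

All generators take an explicit integer seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import PlateReading
from .te import Superfamily, TERecord

__all__ = [
    "PlantedPQS",
    "SimTruth",
    "gen_te_cohort",
    "gen_plate_data",
    "gen_count_matrix",
    "gen_coverage",
]

_BASES = np.array(list("ACGT"))
_BG_PROBS = np.array([0.30, 0.20, 0.20, 0.30])  # A, C, G, T


@dataclass(frozen=True)
class PlantedPQS:
    te_id: str
    start: int  # plus-strand start of the motif
    end: int
    strand: str
    run_lens: tuple[int, int, int, int]
    loop_lens: tuple[int, int, int]
    region: str  # "LTR" or "INT"


@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset."""

    seed: int
    planted_pqs: list[PlantedPQS] = field(default_factory=list)
    strand_bias_minus: float | None = None
    ltr_int_density_ratio: float | None = None
    de_true_lfc: dict[str, float] = field(default_factory=dict)
    assay_effects: dict[str, float] = field(default_factory=dict)


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random sequence with G/C homopolymer runs capped at 2 nt."""
    idx = rng.choice(4, size=length, p=_BG_PROBS)
    seq = _BASES[idx]
    if length >= 3:
        gc = (seq == "G") | (seq == "C")
        same = (seq[2:] == seq[1:-1]) & (seq[1:-1] == seq[:-2])
        bad = np.where(same & gc[2:])[0] + 2
        if bad.size:
            seq[bad] = rng.choice(["A", "T"], size=bad.size)
    return seq


def _motif(
    rng: np.random.Generator,
    run_len_dist: Callable[[np.random.Generator], int],
    loop_len_dist: Callable[[np.random.Generator], int],
) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
    """A planted PQS on its own strand: 4 G-runs with non-G loops.

    Loops draw from A/T/C and reject CC dinucleotides so the reverse
    complement gains no spurious G-runs.
    """
    run_lens = tuple(int(run_len_dist(rng)) for _ in range(4))
    loop_lens = tuple(int(loop_len_dist(rng)) for _ in range(3))
    parts = []
    for i, rl in enumerate(run_lens):
        parts.append("G" * rl)
        if i < 3:
            while True:
                loop = "".join(
                    rng.choice(["A", "T", "C"], size=loop_lens[i], p=[0.4, 0.4, 0.2])
                )
                if "CC" not in loop:
                    break
            parts.append(loop)
    return "".join(parts), run_lens, loop_lens


def _default_run_len(rng: np.random.Generator) -> int:
    return int(rng.choice([3, 4, 5], p=[0.4, 0.4, 0.2]))


def _default_loop_len(rng: np.random.Generator) -> int:
    return int(rng.integers(2, 8))


def _default_length(rng: np.random.Generator) -> int:
    return int(rng.integers(4000, 10001))


def _default_ltr_frac(rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(0.10, 0.02), 0.03, 0.25))


_REVCOMP = str.maketrans("ACGT", "TGCA")


def gen_te_cohort(
    n_families: int = 200,
    superfamily_mix: Mapping[str, float] | None = None,
    length_dist: Callable[[np.random.Generator], int] = _default_length,
    ltr_frac_dist: Callable[[np.random.Generator], float] = _default_ltr_frac,
    pqs_rate: float = 0.37,
    region_bias: float = 2.0,
    strand_bias: float = 0.79,
    run_len_dist: Callable[[np.random.Generator], int] = _default_run_len,
    loop_len_dist: Callable[[np.random.Generator], int] = _default_loop_len,
    seed: int = 0,
) -> tuple[list[TERecord], SimTruth]:
    """Synthetic TE family cohort with planted PQS.

    ``pqs_rate`` is the fraction of families carrying at least one PQS
    (default 0.37); carriers receive ``1 + Poisson(2.2)`` motifs (mean
    ~3.2 per carrier).  ``region_bias`` is the target LTR:INT *density*
    ratio (motifs per kb); ``strand_bias`` the minus-strand fraction.
    LTR length fractions default to ~N(0.10, 0.02) per LTR.
    """
    if superfamily_mix is None:
        superfamily_mix = {"Gypsy": 0.5, "Copia": 0.3, "Other": 0.2}
    rng = np.random.default_rng(seed)
    sf_names = list(superfamily_mix)
    sf_probs = np.array([superfamily_mix[k] for k in sf_names], dtype=float)
    sf_probs = sf_probs / sf_probs.sum()

    truth = SimTruth(
        seed=seed,
        strand_bias_minus=strand_bias,
        ltr_int_density_ratio=region_bias,
    )
    records: list[TERecord] = []
    for i in range(n_families):
        te_id = f"TE{i:04d}"
        sf = Superfamily(rng.choice(sf_names, p=sf_probs))
        length = int(length_dist(rng))
        ltr_len = max(50, int(round(ltr_frac_dist(rng) * length)))
        if 2 * ltr_len >= length:
            raise ValueError(f"{te_id}: element too short for its LTRs")
        seq = _random_background(rng, length)
        ltr5, ltr3 = (0, ltr_len), (length - ltr_len, length)

        n_pqs = 0
        if pqs_rate > 0 and rng.random() < pqs_rate:
            n_pqs = 1 + int(rng.poisson(2.2))
        occupied: list[tuple[int, int]] = []
        pad = 60  # > loop_max keeps planted motifs from merging
        for _ in range(n_pqs):
            motif, run_lens, loop_lens = _motif(rng, run_len_dist, loop_len_dist)
            mlen = len(motif)
            # choose region so motif density (per nt) ratio LTR:INT = bias
            len_ltr, len_int = 2 * ltr_len, length - 2 * ltr_len
            p_ltr = region_bias * len_ltr / (region_bias * len_ltr + len_int)
            region = "LTR" if rng.random() < p_ltr else "INT"
            strand = "-" if rng.random() < strand_bias else "+"
            placed = False
            for _attempt in range(200):
                if region == "LTR":
                    iv = ltr5 if rng.random() < 0.5 else ltr3
                else:
                    iv = (ltr5[1], ltr3[0])
                lo, hi = iv[0] + 5, iv[1] - mlen - 5
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + mlen
                if any(start < e + pad and s - pad < end for s, e in occupied):
                    continue
                insert = motif if strand == "+" else motif.translate(_REVCOMP)[::-1]
                seq[start:end] = list(insert)
                occupied.append((start, end))
                truth.planted_pqs.append(
                    PlantedPQS(te_id, start, end, strand, run_lens, loop_lens, region)
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"{te_id}: could not place a {mlen} nt motif; element too "
                    "short or too crowded"
                )
        records.append(
            TERecord(
                te_id=te_id,
                superfamily=sf,
                sequence="".join(seq),
                family_name=f"fam{i:04d}",
                ltr5=ltr5,
                ltr3=ltr3,
            )
        )
    return records, truth


def gen_plate_data(
    constructs: Sequence[str],
    effect_map: Mapping[str, float] | None = None,
    cv: float = 0.15,
    n_colonies: int = 6,
    n_replicates: int = 3,
    base_units: float = 5.0,
    replicate_cv: float = 0.05,
    od600: float = 1.0,
    volume_ml: float = 0.2,
    time_min: float = 20.0,
    blank: float = 0.05,
    seed: int = 0,
) -> tuple[list[PlateReading], SimTruth]:
    """Reporter-assay plate: lognormal colony effects x replicate noise.

    Each construct's expected activity is ``base_units * effect_map[c]``
    (effect 1.0 when absent).  ``cv`` is the colony-to-colony coefficient
    of variation; Abs420 values are back-computed from the unit formula so
    the blank well is included in every reading.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    effect_map = dict(effect_map or {})
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed, assay_effects={
        c: effect_map.get(c, 1.0) for c in constructs
    })
    sigma_col = np.sqrt(np.log(1 + cv**2))
    sigma_rep = np.sqrt(np.log(1 + replicate_cv**2))
    readings: list[PlateReading] = []
    for construct in constructs:
        mean_units = base_units * effect_map.get(construct, 1.0)
        for colony in range(n_colonies):
            colony_units = mean_units * rng.lognormal(
                -0.5 * sigma_col**2, sigma_col
            )
            for rep in range(n_replicates):
                u = colony_units * rng.lognormal(-0.5 * sigma_rep**2, sigma_rep)
                abs420 = blank + u * od600 * volume_ml * time_min / 1000.0
                readings.append(
                    PlateReading(
                        construct_id=construct,
                        colony_id=f"c{colony + 1}",
                        replicate_id=f"r{rep + 1}",
                        abs420=abs420,
                        abs420_blank=blank,
                        od600=od600,
                        volume_ml=volume_ml,
                        time_min=time_min,
                    )
                )
    return readings, truth


def gen_count_matrix(
    n_te: int = 2000,
    n_per_group: int = 4,
    baseline_dist: Callable[[np.random.Generator], float] | None = None,
    dispersion: float = 0.1,
    de_frac: float = 0.05,
    true_lfc: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """Negative-binomial TE-by-sample counts with planted DE.

    Baseline per-TE means default to lognormal(log 150, 1.0).  A fraction
    ``de_frac`` of elements is shifted by ``true_lfc`` log2 units in the
    treated group, with random sign.  ``dispersion`` 0 gives Poisson
    counts.  Returns (counts, sample->group map, truth).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if baseline_dist is None:
        baseline = rng.lognormal(np.log(150.0), 1.0, size=n_te)
    else:
        baseline = np.array([baseline_dist(rng) for _ in range(n_te)])
    te_ids = [f"TE{i:04d}" for i in range(n_te)]
    n_de = int(round(de_frac * n_te))
    de_idx = rng.choice(n_te, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n_te)
    lfc[de_idx] = signs * abs(true_lfc)

    samples = [f"T{j + 1}" for j in range(n_per_group)] + [
        f"C{j + 1}" for j in range(n_per_group)
    ]
    groups = {s: ("treated" if s.startswith("T") else "control") for s in samples}
    mu = np.column_stack(
        [baseline * 2.0**lfc] * n_per_group + [baseline] * n_per_group
    )

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))
    matrix = pd.DataFrame(counts, index=te_ids, columns=samples)
    truth = SimTruth(
        seed=seed,
        de_true_lfc={te_ids[i]: float(lfc[i]) for i in de_idx},
    )
    return matrix, groups, truth


def gen_coverage(
    te: TERecord,
    expression_level: float = 10.0,
    ltr_peak_fold: float = 3.0,
    noise: float = 1.0,
    n_libraries: int = 1,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-base coverage vectors: flat expected coverage with a fold-change
    peak over the 5' LTR, Poisson noise per base (``noise=0`` returns the
    expectation exactly).  Deterministic in (arguments, seed).
    """
    rng = np.random.default_rng(seed)
    expected = np.full(te.length, float(expression_level))
    if te.ltr5 is not None:
        expected[te.ltr5[0] : te.ltr5[1]] *= ltr_peak_fold
    out = []
    for _ in range(n_libraries):
        if noise == 0:
            out.append(expected.copy())
        else:
            out.append(rng.poisson(expected * noise) / noise)
    return out
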