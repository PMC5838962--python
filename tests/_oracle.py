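"""Independent brute-force PQS oracle for cross-checking the scanner.

Everything here is written from the constraint definitions directly —
regex run discovery, exhaustive itertools enumeration of four-run tuples,
inline scoring arithmetic and an independently coded greedy selection —
and deliberately shares no enumeration or selection code with the
package.
"""

from __future__ import annotations

import re
from itertools import combinations

COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_hits(seq: str, params, strand: str = "+"):
    """All reported (start, end, strand, loops, tetrads, n_bulged, score)
    tuples on one strand of ``seq``, after greedy overlap resolution.
    Coordinates are plus-strand. Quadratic/quartic; small inputs only."""
    length = len(seq)
    work = seq.upper() if strand == "+" else seq.upper().translate(COMP)[::-1]

    tracts = [(m.start(), m.end()) for m in re.finditer("G+", work)]
    runs = []  # (start, end, g_count, bulged)
    for s, e in tracts:
        if e - s >= params.min_run_len:
            runs.append((s, e, e - s, False))
    for (s1, e1), (s2, e2) in combinations(tracts, 2):
        if s2 - e1 < 1 or s2 - e1 > 3:
            continue
        if e1 - s1 < 2 or e2 - s2 < 2:
            continue
        if (e1 - s1) + (e2 - s2) >= params.min_run_len + 1:
            runs.append((s1, e2, (e1 - s1) + (e2 - s2), True))

    candidates = []
    for quad in combinations(sorted(runs), 4):
        ok = True
        loops = []
        for a, b in zip(quad, quad[1:]):
            gap = b[0] - a[1]
            if not (params.loop_min <= gap <= params.loop_max):
                ok = False
                break
            loops.append(gap)
        if not ok:
            continue
        if quad[3][1] - quad[0][0] > params.max_pqs_len:
            continue
        n_bulged = sum(1 for r in quad if r[3])
        if n_bulged > params.max_bulged_runs:
            continue
        tetrads = min(min(r[2], params.max_run_len_counted) for r in quad)
        score = (
            tetrads * params.tetrad_reward
            - sum(loops) / 3 * params.loop_penalty_per_nt
            - n_bulged * params.bulge_penalty
        )
        if score >= params.report_threshold:
            candidates.append(
                (quad[0][0], quad[3][1], tuple(loops), tetrads, n_bulged, score)
            )

    # greedy: best score, then more tetrads, shorter span, leftmost
    candidates.sort(key=lambda c: (-c[5], -c[3], c[1] - c[0], c[0]))
    chosen = []
    for cand in candidates:
        if all(not (cand[0] < c[1] and c[0] < cand[1]) for c in chosen):
            chosen.append(cand)

    out = []
    for s, e, loops, tetrads, n_bulged, score in chosen:
        if strand == "-":
            s, e = length - e, length - s
        out.append((s, e, strand, loops, tetrads, n_bulged, score))
    return sorted(out)


def bh_adjust(pvalues):
    """Benjamini-Hochberg by the textbook recipe: p*m/rank, then a
    cumulative minimum from the largest rank down, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvalues[idx] * m / rank)
        adj[idx] = running
    return adj
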