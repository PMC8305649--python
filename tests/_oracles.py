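"""Independent brute-force references used to check the package.

Everything here is deliberately naive (enumeration, quadratic scans) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating every one of the C(N, n) draws."""
    total = 0
    hits = 0
    success = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in success) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_suffix_counts(N: int, n: int, K: int) -> list[float]:
    """Tail probabilities [P(X >= k) for k in 0..min(K, n)] by enumeration."""
    m = min(K, n)
    counts = [0] * (m + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        overlap = sum(1 for x in draw if x < K)
        counts[overlap] += 1
    tails = []
    running = 0
    suffix = [0] * (m + 2)
    for k in range(m, -1, -1):
        running += counts[k]
        suffix[k] = running
    for k in range(m + 1):
        tails.append(suffix[k] / total)
    return tails


def bh_quadratic(p_values) -> list[float]:
    """Step-up BH by the definitional quadratic scan: on the ascending order
    statistics, q_(i) = min over j >= i of m * p_(j) / j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(indexed):
        best = math.inf
        for j in range(rank_pos, m):
            pj = p_values[indexed[j]]
            best = min(best, m * pj / (j + 1))
        q[idx] = min(best, 1.0)
    return q


def brute_force_signature(calls, min_consistency: float, min_reports: int):
    """Re-derive the up/down commonly-reported lists from raw (gene, study,
    direction) triples with plain loops.

    ``calls`` is an iterable of objects with study_id, canonical_symbol and
    direction.  Returns (up, down) lists ordered by descending report count
    then ascending symbol — the published-list ordering.
    """
    per_gene = defaultdict(list)
    for c in calls:
        per_gene[c.canonical_symbol].append((c.study_id, c.direction))
    rows = []
    for gene, pairs in per_gene.items():
        studies = {s for s, _ in pairs}
        assert len(studies) == len(pairs), "duplicate study calls"
        ups = sum(1 for _, d in pairs if d > 0)
        downs = len(pairs) - ups
        n = len(pairs)
        consistency = max(ups, downs) / n
        if consistency < min_consistency or ups == downs:
            continue
        if n < min_reports:
            continue
        rows.append((gene, n, 1 if ups > downs else -1))
    rows.sort(key=lambda r: (-r[1], r[0]))
    up = [g for g, _, d in rows if d == 1]
    down = [g for g, _, d in rows if d == -1]
    return up, down


def brute_force_venn(organ_sets: dict):
    """Per-gene membership check: signature -> sorted gene list."""
    organs = list(organ_sets)
    union = set()
    for s in organ_sets.values():
        union |= set(s)
    out = defaultdict(list)
    for gene in sorted(union):
        sig = tuple(o for o in organs if gene in organ_sets[o])
        out[sig].append(gene)
    return dict(out)


def exact_recovery_expectation(
    n_studies: int,
    report_prob: float,
    flip_prob: float,
    min_reports: int,
    min_consistency: float,
) -> float:
    """Probability a planted signature gene is recovered with the correct
    direction, straight from the generative model.

    A gene is reported by r ~ Binomial(S, report_prob) studies; each report
    carries the true direction with probability 1 - flip_prob.  Recovery
    needs r >= min_reports and at least ceil(min_consistency * r) correct
    reports (which also forces the consensus to the true direction).
    """
    total = 0.0
    for r in range(min_reports, n_studies + 1):
        p_r = math.comb(n_studies, r) * report_prob**r * (1 - report_prob) ** (n_studies - r)
        need = math.ceil(min_consistency * r)
        p_ok = sum(
            math.comb(r, c) * (1 - flip_prob) ** c * flip_prob ** (r - c)
            for c in range(need, r + 1)
            # an exact 50/50 split can never satisfy need > r/2, so no tie case
        )
        total += p_r * p_ok
    return total
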