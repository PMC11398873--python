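"""Independent brute-force reference implementations.

Every function here recomputes a statistic by direct enumeration — running
sums walked position by position, pairings enumerated exhaustively,
binomial tails summed term by term — sharing no code with the package
implementations they check.
"""

from __future__ import annotations

import itertools
import math


def ks_brute(positions, n):
    """Direct evaluation of both KS maxima over j = 1..t."""
    pos = sorted(positions)
    t = len(pos)
    a = max(j / t - pos[j - 1] / n for j in range(1, t + 1))
    b = max(pos[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def cmap_brute(up_positions, down_positions, n):
    ks_up = ks_brute(up_positions, n)
    ks_down = ks_brute(down_positions, n)
    if ks_up * ks_down < 0:
        return ks_up - ks_down
    return 0.0


def es_walk_brute(hit_weight_by_position, n):
    """Enrichment running sum walked over every position 1..n.

    ``hit_weight_by_position`` maps hit position -> weight. Returns the
    signed value of largest magnitude (positive branch wins ties).
    """
    t = len(hit_weight_by_position)
    total = sum(hit_weight_by_position.values())
    if total <= 0:
        hit_weight_by_position = {p: 1.0 for p in hit_weight_by_position}
        total = float(t)
    miss = 1.0 / (n - t)
    running = 0.0
    peak, trough = 0.0, 0.0
    for p in range(1, n + 1):
        if p in hit_weight_by_position:
            running += hit_weight_by_position[p] / total
        else:
            running -= miss
        peak = max(peak, running)
        trough = min(trough, running)
    # exact ties (peak == -trough) go to the positive branch; the walk's
    # accumulated float error must not flip that
    return peak if peak >= -trough - 1e-12 else trough


def gsea_brute(up_positions, down_positions, stats_desc, n, weight_p):
    """Two-sided connectivity from two walked running sums.

    ``stats_desc`` lists the profile stat at each position 1..n."""
    def side(positions):
        w = {p: abs(stats_desc[p - 1]) ** weight_p for p in positions}
        return es_walk_brute(w, n)

    es_up = side(up_positions)
    es_down = side(down_positions)
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def zhang_brute(sig_stats, ref_stats):
    """Signed-rank connection with the denominator found by exhaustive
    pairing enumeration.

    Both arguments map gene -> signed stat over the same tag genes."""
    genes = sorted(sig_stats)

    def signed_ranks(values):
        order = sorted(genes, key=lambda g: (abs(values[g]), g))
        return {g: math.copysign(i + 1, values[g]) for i, g in enumerate(order)}

    s = signed_ranks(sig_stats)
    r = signed_ranks(ref_stats)
    raw = sum(s[g] * r[g] for g in genes)
    smags = [abs(s[g]) for g in genes]
    rmags = [abs(r[g]) for g in genes]
    best = max(
        sum(a * b for a, b in zip(smags, perm))
        for perm in itertools.permutations(rmags)
    )
    return raw / best


def xsum_brute(up_tags, down_tags, stats, top_genes, bottom_genes):
    ext = set(top_genes) | set(bottom_genes)
    up = sum(stats[g] for g in up_tags if g in ext and g in stats)
    down = sum(stats[g] for g in down_tags if g in ext and g in stats)
    return up - down


def xcos_brute(sig_stats, ref_stats, tags, top_genes, bottom_genes):
    ext = set(top_genes) | set(bottom_genes)
    shared = [g for g in tags if g in ext and g in ref_stats]
    if not shared:
        return 0.0
    dot = sum(sig_stats[g] * ref_stats[g] for g in shared)
    nx = math.sqrt(sum(sig_stats[g] ** 2 for g in shared))
    ny = math.sqrt(sum(ref_stats[g] ** 2 for g in shared))
    if nx == 0 or ny == 0:
        return 0.0
    return dot / (nx * ny)


def auc_brute(effective_scores, ineffective_scores):
    """Concordant-pair count with negated scores predicting Effective."""
    wins = 0.0
    for e in effective_scores:
        for i in ineffective_scores:
            if -e > -i:
                wins += 1.0
            elif -e == -i:
                wins += 0.5
    return wins / (len(effective_scores) * len(ineffective_scores))


def rra_brute(ranks):
    """Direct binomial-tail evaluation of the rank-aggregation p-value."""
    r = sorted(ranks)
    k_total = len(r)
    betas = []
    for k in range(1, k_total + 1):
        x = r[k - 1]
        tail = sum(
            math.comb(k_total, j) * x**j * (1 - x) ** (k_total - j)
            for j in range(k, k_total + 1)
        )
        betas.append(tail)
    return min(1.0, min(betas) * k_total)


def ps_brute(ranks, m):
    return sum((m - r) / (m - 1) for r in ranks) / len(ranks)
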