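"""Independent brute-force oracles used to verify the statistical paths.

Everything here is a direct enumeration or closed form, sharing no code
with the implementations it checks.
"""

from itertools import combinations
from math import comb, sqrt


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all 2x2 tables with fixed margins.

    Sums the hypergeometric probabilities of every table at most as
    probable as the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # P(upper-left cell = x) under fixed margins
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def rank_sum_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group splits.

    Assumes no ties. The statistic is the Mann-Whitney U of the first
    group; two-sidedness is |U - mean| at least as extreme.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    nx, ny = len(x), len(y)
    values = sorted(pooled)

    def u_of(subset_vals):
        sv = set(subset_vals)
        u = 0
        for v in subset_vals:
            u += sum(1 for w in values if w not in sv and w < v)
        return u

    u_obs = u_of(list(x))
    mean = nx * ny / 2
    dev = abs(u_obs - mean)
    count = total = 0
    for subset in combinations(range(nx + ny), nx):
        vals = [values[i] for i in subset]
        total += 1
        if abs(u_of(vals) - mean) >= dev - 1e-12:
            count += 1
    return count / total


def spearman_rho(x, y) -> float:
    """Pearson correlation of (tie-free) ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_perm_p(x, y) -> float:
    """Two-sided permutation p on |rho| over all n! pairings."""
    from itertools import permutations

    obs = abs(spearman_rho(x, y))
    count = total = 0
    for perm in permutations(y):
        total += 1
        if abs(spearman_rho(x, list(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def recovery_auc(ranks_of_set_genes, n_genes: int, set_size: int, k: int) -> float:
    """Brute-force step-curve integration of the rank-AUC score.

    ranks_of_set_genes are 1-based positions of the set's genes in the
    cell's ranking.
    """
    y_sum = 0
    for i in range(1, k + 1):
        y_sum += sum(1 for r in ranks_of_set_genes if r <= i)
    m = min(set_size, k)
    max_area = sum(min(i, m) for i in range(1, k + 1))
    return y_sum / max_area


def translate_first_stop(mrna: str, nt_from: int):
    """Codon index of the first frame-0 stop starting at or after nt_from."""
    stops = {"TAA", "TAG", "TGA"}
    c = 0
    while 3 * c < nt_from:
        c += 1
    while 3 * c + 3 <= len(mrna):
        if mrna[3 * c : 3 * c + 3] in stops:
            return c
        c += 1
    return None


def bh_adjust(pvals):
    """Step-up Benjamini-Hochberg by direct arithmetic."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = pvals[i] * m / rank_from_top
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj
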