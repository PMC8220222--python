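"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) they check: exact-integer enumeration for the 2×2 exact test and
the hypergeometric tail, a sort-based step-by-step TMM evaluation, and a
literal step-up implementation of BH.
"""

import math

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-sided Fisher p by exhaustive table enumeration.

    All tables with the observed margins are enumerated; a table is counted
    iff its (integer, exact) hypergeometric weight does not exceed the
    observed table's weight.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(r1 + r2, c1)
    acc = 0
    for ap in range(lo, hi + 1):
        w = math.comb(r1, ap) * math.comb(r2, c1 - ap)
        if w <= obs:
            acc += w
    return acc / total


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X ≥ k) for X ~ Hypergeom(N, K, n) by exact summation."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(K, n) + 1)
              if n - i <= N - K)
    return num / math.comb(N, n)


def bh_stepup_oracle(pvalues) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j ≥ i} p_(j)·n/j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(n)
    running_min = np.inf
    for rank in range(n, 0, -1):
        val = p[order[rank - 1]] * n / rank
        running_min = min(running_min, val)
        q_sorted[rank - 1] = min(running_min, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def tmm_pair_oracle(x, n, r, nr, trim_m=0.30, trim_a=0.05) -> float:
    """Spreadsheet-style evaluation of one sample's TMM factor vs a reference.

    Sorting-based double trim and an explicit loop — no shared code with the
    implementation.
    """
    x = np.asarray(x, float)
    r = np.asarray(r, float)
    genes = [i for i in range(len(x)) if x[i] > 0 and r[i] > 0]
    M, A, W = {}, {}, {}
    for i in genes:
        px, pr = x[i] / n, r[i] / nr
        M[i] = math.log2(px / pr)
        A[i] = 0.5 * math.log2(px * pr)
        W[i] = (n - x[i]) / (n * x[i]) + (nr - r[i]) / (nr * r[i])
    if max(abs(v) for v in M.values()) < 1e-6:
        return 1.0
    ng = len(genes)

    def kept_by(values, trim):
        lo = math.floor(ng * trim) + 1
        hi = ng + 1 - lo
        ranked = sorted(genes, key=lambda i: values[i])
        # average ranks for ties, as R's rank() does
        ranks = {}
        i = 0
        while i < ng:
            j = i
            while j + 1 < ng and values[ranked[j + 1]] == values[ranked[i]]:
                j += 1
            avg = (i + 1 + j + 1) / 2
            for t in range(i, j + 1):
                ranks[ranked[t]] = avg
            i = j + 1
        return {g for g in genes if lo <= ranks[g] <= hi}

    keep = kept_by(M, trim_m) & kept_by(A, trim_a)
    num = sum(M[g] / W[g] for g in keep)
    den = sum(1.0 / W[g] for g in keep)
    return 2.0 ** (num / den)


def contrast_t_oracle(values_by_species: dict, mh: list, at: list):
    """Ordinary (unmoderated) contrast t for one orthogroup, from scratch.

    ``values_by_species[sp]`` is the list of per-individual ratios. Returns
    (delta, t, df).
    """
    means = {sp: float(np.mean(v)) for sp, v in values_by_species.items()}
    n = {sp: len(v) for sp, v in values_by_species.items()}
    rss = sum(float(np.sum((np.asarray(v) - means[sp]) ** 2))
              for sp, v in values_by_species.items())
    d = sum(n.values()) - len(n)
    s2 = rss / d
    delta = (sum(means[sp] for sp in mh) / len(mh)
             - sum(means[sp] for sp in at) / len(at))
    var_c = (sum(1.0 / (len(mh) ** 2 * n[sp]) for sp in mh)
             + sum(1.0 / (len(at) ** 2 * n[sp]) for sp in at))
    se = math.sqrt(s2 * var_c)
    return delta, delta / se, d
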