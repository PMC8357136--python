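"""Independent brute-force reference implementations used as test oracles.

Deliberately written with explicit Python loops and sorts, straight from
the published definitions, sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def tmm_factors_bruteforce(counts, gene_ids, logratio_trim=0.3, abs_trim=0.05):
    """Doubly trimmed, precision-weighted mean of M-values, step by step."""
    counts = np.asarray(counts, dtype=float)
    G, S = counts.shape
    gene_ids = [str(g) for g in gene_ids]
    N = [float(counts[:, k].sum()) for k in range(S)]
    # reference: upper-quartile CPM closest to the mean upper quartile
    uq = [float(np.quantile([counts[g, k] / N[k] * 1e6 for g in range(G)], 0.75))
          for k in range(S)]
    mean_uq = sum(uq) / S
    ref = min(range(S), key=lambda k: (abs(uq[k] - mean_uq), k))

    factors = [1.0] * S
    for k in range(S):
        if k == ref:
            continue
        rows = []
        for g in range(G):
            yk, yr = counts[g, k], counts[g, ref]
            if yk > 0 and yr > 0:
                M = math.log2((yk / N[k]) / (yr / N[ref]))
                A = 0.5 * math.log2((yk / N[k]) * (yr / N[ref]))
                w = (N[k] - yk) / (N[k] * yk) + (N[ref] - yr) / (N[ref] * yr)
                rows.append((gene_ids[g], M, A, w))
        n = len(rows)
        tm = int(math.floor(logratio_trim * n))
        ta = int(math.floor(abs_trim * n))
        by_m = sorted(rows, key=lambda t: (t[1], t[0]))
        keep_m = {t[0] for t in by_m[tm: n - tm]} if n - 2 * tm > 0 else set()
        by_a = sorted(rows, key=lambda t: (t[2], t[0]))
        keep_a = {t[0] for t in by_a[ta: n - ta]} if n - 2 * ta > 0 else set()
        kept = [t for t in rows if t[0] in keep_m and t[0] in keep_a and t[3] > 0]
        if not kept:
            factors[k] = 1.0
            continue
        num = sum(t[1] / t[3] for t in kept)
        den = sum(1.0 / t[3] for t in kept)
        factors[k] = 2.0 ** (num / den)
    gm = math.exp(sum(math.log(f) for f in factors) / S)
    return np.array([f / gm for f in factors]), ref


def rle_size_factors_bruteforce(counts):
    """Median of per-gene ratios to the geometric-mean pseudo-reference."""
    counts = np.asarray(counts, dtype=float)
    G, S = counts.shape
    usable = [g for g in range(G) if all(counts[g, k] > 0 for k in range(S))]
    assert usable, "no gene positive in all samples"
    ref = {g: math.exp(sum(math.log(counts[g, k]) for k in range(S)) / S) for g in usable}
    return np.array(
        [float(np.median([counts[g, k] / ref[g] for g in usable])) for k in range(S)]
    )


def pearson_bruteforce(x, y):
    """Textbook two-pass Pearson correlation."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def best_match_bruteforce(rows):
    """Repeatedly extract the global best row, deleting its row and column.

    ``rows`` is a list of (gene_a, gene_b, score); ties broken by
    (gene_a, gene_b) ascending.
    """
    remaining = list(rows)
    out = []
    while remaining:
        best = min(remaining, key=lambda t: (-t[2], t[0], t[1]))
        out.append(best)
        remaining = [t for t in remaining if t[0] != best[0] and t[1] != best[1]]
    return out


def regression_loop_bruteforce(X, y, seed, n_iterations, train_fraction, make_model):
    """Independent resampled-regression loop with hand-computed R²."""
    rng = np.random.default_rng(seed)
    n = len(y)
    r2s = []
    for _ in range(n_iterations):
        n_train = int(math.floor(train_fraction * n + 0.5))
        perm = rng.permutation(n)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        m_seed = int(rng.integers(2**31))
        if test.size < 2 or np.all(y[test] == y[test][0]):
            continue
        model = make_model(m_seed)
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[test]), dtype=float)
        resid = float(np.sum((y[test] - pred) ** 2))
        total = float(np.sum((y[test] - np.mean(y[test])) ** 2))
        r2s.append(1.0 - resid / total)
    return np.array(r2s)
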