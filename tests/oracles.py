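"""Independent reference implementations used only by the tests.

Each oracle is deliberately naive (loops, enumeration, brute force) and
shares no code with the package's implementation paths it cross-checks.
"""

import numpy as np
from scipy import stats


def naive_cnn_forward(weights, x, conv_filters, kernel_len, pool_len):
    """Pure-loop forward pass of the conv/pool/dense/softmax stack."""
    a = [[float(v)] for v in x]  # L x C lists
    for li, _ in enumerate(conv_filters, start=1):
        W = weights[f"conv{li}_W"]  # (k, c_in, c_out)
        b = weights[f"conv{li}_b"]
        k, c_in, c_out = W.shape
        L = len(a)
        conv = []
        for pos in range(L - k + 1):
            row = []
            for f in range(c_out):
                s = b[f]
                for t in range(k):
                    for c in range(c_in):
                        s += a[pos + t][c] * W[t, c, f]
                row.append(max(s, 0.0))  # ReLU
            conv.append(row)
        pooled = []
        for start in range(0, (len(conv) // pool_len) * pool_len, pool_len):
            row = []
            for f in range(c_out):
                row.append(max(conv[start + t][f] for t in range(pool_len)))
            pooled.append(row)
        a = pooled
    flat = [v for row in a for v in row]
    W1, b1 = weights["dense1_W"], weights["dense1_b"]
    h = []
    for j in range(W1.shape[1]):
        s = b1[j]
        for i, v in enumerate(flat):
            s += v * W1[i, j]
        h.append(max(s, 0.0))
    W2, b2 = weights["dense2_W"], weights["dense2_b"]
    z = []
    for j in range(W2.shape[1]):
        s = b2[j]
        for i, v in enumerate(h):
            s += v * W2[i, j]
        z.append(s)
    zmax = max(z)
    e = [np.exp(v - zmax) for v in z]
    tot = sum(e)
    return np.array([v / tot for v in e])


def mann_whitney_auc(y_true, scores):
    """AUC as the concordant-pair fraction (half credit for ties)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def anova_sums_of_squares(groups):
    """Textbook sums-of-squares expansion of one-way ANOVA."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - np.mean(g)) ** 2 for v in g) for g in groups)
    k, n = len(groups), len(allv)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return ssb, ssw, f, p


def permutation_anova_pvalue(groups, n_shuffles=10_000, seed=0):
    """Permutation p-value for the one-way ANOVA F statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    _, _, f_obs, _ = anova_sums_of_squares(groups)
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        _, _, f, _ = anova_sums_of_squares(parts)
        if f >= f_obs:
            count += 1
    return (count + 1) / (n_shuffles + 1)


def two_group_duncan_range(mse, df_within, n_h, alpha=0.05):
    """Least significant range for two means via the t relation.

    For a range of two means the studentized-range variable is sqrt(2)|T|
    with T ~ t(df), so q_{alpha}(2, df) = sqrt(2) t_{alpha/2}(df) — an
    independent route that never touches scipy's studentized_range.
    """
    q = np.sqrt(2.0) * stats.t.ppf(1.0 - alpha / 2.0, df_within)
    return q * np.sqrt(mse / n_h)
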