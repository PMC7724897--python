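"""Independent brute-force oracles for the test suite.

Deliberately naive (double loops, direct formula transcription) and written
against the defining sums only — never importing the implementation paths
they check.
"""

import math

import numpy as np


def mk_statistic(x):
    """Standardized Mann–Kendall statistic by direct double loop."""
    x = np.asarray(x, float)
    n = len(x)
    mk = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            mk += np.sign(x[j] - x[i])
    # tie groups
    var = n * (n - 1) * (2 * n + 5)
    for v in set(x.tolist()):
        t = int(np.sum(x == v))
        if t > 1:
            var -= t * (t - 1) * (2 * t + 5)
    var /= 18.0
    if var <= 0:
        return 0.0
    if mk > 0:
        return (mk - 1) / math.sqrt(var)
    if mk < 0:
        return (mk + 1) / math.sqrt(var)
    return 0.0


def mw_statistic(x, n1):
    """Standardized rank-sum of the leading n1 points (average ranks)."""
    x = np.asarray(x, float)
    n = len(x)
    n2 = n - n1
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    s = x[order]
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rs = float(np.sum(ranks[:n1]))
    return (rs - n1 * (n1 + n2 + 1) / 2.0) / math.sqrt(
        n1 * n2 * (n1 + n2 + 1) / 12.0
    )


def mw_exact_pvalue(x, n1):
    """Exact two-sided permutation p-value of the rank-sum statistic."""
    from itertools import combinations

    x = np.asarray(x, float)
    n = len(x)
    obs = abs(mw_statistic(x, n1))
    idx = list(range(n))
    count = total = 0
    for comb in combinations(idx, n1):
        perm = np.concatenate([x[list(comb)],
                               x[[i for i in idx if i not in comb]]])
        total += 1
        if abs(mw_statistic(perm, n1)) >= obs - 1e-12:
            count += 1
    return count / total


def fisher_f_statistic(x):
    """F ratio at the maximal periodogram ordinate by direct summation."""
    x = np.asarray(x, float)
    n = len(x)
    k = (n - 1) // 2
    best, best_z = -1.0, None
    coefs = {}
    for z in range(1, k + 1):
        a = b = 0.0
        for t in range(1, n + 1):
            a += x[t - 1] * math.cos(2 * math.pi * z * t / n)
            b += x[t - 1] * math.sin(2 * math.pi * z * t / n)
        a *= 2.0 / n
        b *= 2.0 / n
        coefs[z] = (a, b)
        if a * a + b * b > best:
            best, best_z = a * a + b * b, z
    a, b = coefs[best_z]
    xbar = float(np.mean(x))
    rss = 0.0
    for t in range(1, n + 1):
        w = 2 * math.pi * best_z * t / n
        rss += (x[t - 1] - xbar - a * math.cos(w) - b * math.sin(w)) ** 2
    return n * (n - 2) * best / (4 * rss)


def smk_statistic(x, omega):
    """Standardized seasonal Mann–Kendall by per-season double loops,
    with the continuity correction applied once to the aggregate score."""
    x = np.asarray(x, float)
    smk = 0.0
    var = 0.0
    for kk in range(omega):
        xs = x[kk::omega]
        nk = len(xs)
        s = 0.0
        for i in range(nk - 1):
            for j in range(i + 1, nk):
                s += np.sign(xs[j] - xs[i])
        smk += s
        v = nk * (nk - 1) * (2 * nk + 5)
        for val in set(xs.tolist()):
            t = int(np.sum(xs == val))
            if t > 1:
                v -= t * (t - 1) * (2 * t + 5)
        var += v / 18.0
    if var <= 0 or smk == 0:
        return 0.0
    return (smk - np.sign(smk)) / math.sqrt(var)


def metrics_oracle(obs, pred):
    """Single-pass transcription of the verification-index formulas."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    n = len(obs)
    ob, pb = obs.mean(), pred.mean()
    num = float(np.sum((obs - ob) * (pred - pb)))
    den = math.sqrt(float(np.sum((obs - ob) ** 2) * np.sum((pred - pb) ** 2)))
    r = num / den
    rmse = math.sqrt(float(np.mean((obs - pred) ** 2)))
    si = rmse / ob
    mape = 100.0 / n * float(np.sum(np.abs(obs - pred) / np.abs(obs)))
    rho = si / (1 + r)
    e_ns = 1 - float(np.sum((obs - pred) ** 2)) / float(np.sum((obs - ob) ** 2))
    return {"r": r, "si": si, "mape": mape, "rmse": rmse,
            "rmsre": 100 * si, "rho": rho, "e_ns": e_ns}


def aicc_residual_oracle(obs, pred, k):
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    n = len(obs)
    sig2 = float(np.var(obs - pred))
    return (2 * k * n + (n * math.log(sig2) * (n - k - 1))) / (n - k - 1)


def acf_oracle(x, max_lag):
    """Biased-estimator autocorrelation by direct summation."""
    x = np.asarray(x, float)
    n = len(x)
    m = x.mean()
    denom = float(np.sum((x - m) ** 2))
    out = []
    for k in range(max_lag + 1):
        s = 0.0
        for t in range(n - k):
            s += (x[t] - m) * (x[t + k] - m)
        out.append(s / denom)
    return np.array(out)


def pacf_oracle(x, max_lag):
    """PACF via successive OLS autoregressions (last coefficient)."""
    x = np.asarray(x, float)
    rho = acf_oracle(x, max_lag)
    out = [1.0]
    for k in range(1, max_lag + 1):
        # Yule-Walker solve from the defining Toeplitz system
        R = np.array([[rho[abs(i - j)] for j in range(k)] for i in range(k)])
        b = np.array([rho[i + 1] for i in range(k)])
        phi = np.linalg.solve(R, b)
        out.append(phi[-1])
    return np.array(out)
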