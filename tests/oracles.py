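"""Independent reference implementations used only as test oracles.

Each oracle deliberately takes a different computational route from the
package code it checks: explicit loops where the package vectorizes,
matrix algebra where the package loops over event times, enumeration or
permutation where the package uses asymptotics.
"""

from __future__ import annotations

import numpy as np


def median_bruteforce(values):
    """Median by explicit sort-and-index (no numpy.median)."""
    s = sorted(float(v) for v in values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 == 1 else (s[mid - 1] + s[mid]) / 2.0


def math_bruteforce(vafs):
    """MATH via explicit median/MAD loops: 100 * 1.4826 * MAD / median."""
    med = median_bruteforce(vafs)
    deviations = [abs(float(v) - med) for v in vafs]
    mad = median_bruteforce(deviations)
    return 100.0 * 1.4826 * mad / med


def _risk_matrices(time, event):
    """Per-death-time at-risk and death indicator matrices (n x T)."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    death_times = np.unique(time[event])
    at_risk = time[:, None] >= death_times[None, :]
    dying = event[:, None] & (time[:, None] == death_times[None, :])
    return at_risk, dying


def logrank_chi2_matrix(time, event, labels):
    """Log-rank chi-square for many group labelings at once.

    ``labels`` is an (m, n) 0/1 matrix; returns m chi-square values.
    Computed with counting-process matrix algebra, independent of the
    per-time-loop implementation in the package.
    """
    at_risk, dying = _risk_matrices(time, event)
    n_t = at_risk.sum(axis=0).astype(float)
    d_t = dying.sum(axis=0).astype(float)
    labels = np.atleast_2d(np.asarray(labels, float))
    n1 = labels @ at_risk
    d1 = labels @ dying
    oe = (d1 - d_t * n1 / n_t).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    terms[:, n_t <= 1] = 0.0
    var = terms.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, oe**2 / var, np.nan)
    return chi2


def cutpoint_bruteforce(values, time, event, minprop):
    """Exhaustive scan over midpoint thresholds: returns
    (threshold, chi2) of the maximal admissible split, smallest
    threshold on ties."""
    values = np.asarray(values, float)
    n = values.size
    distinct = np.unique(values)
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    min_group = int(np.ceil(minprop * n))
    best = None
    for thr in thresholds:
        labels = (values > thr).astype(float)
        k = int(labels.sum())
        if min(k, n - k) < min_group:
            continue
        chi2 = float(logrank_chi2_matrix(time, event, labels[None, :])[0])
        if np.isnan(chi2):
            continue
        if best is None or chi2 > best[1] + 1e-9:
            best = (float(thr), chi2)
    return best


def permutation_logrank_p(time, event, in_a, n_perm, rng):
    """Permutation p-value for the two-group log-rank chi-square."""
    in_a = np.asarray(in_a, bool)
    observed = float(logrank_chi2_matrix(time, event, in_a.astype(float)[None, :])[0])
    n = in_a.size
    perms = np.zeros((n_perm, n))
    for i in range(n_perm):
        perms[i, rng.permutation(n)[: in_a.sum()]] = 1.0
    chi2 = logrank_chi2_matrix(time, event, perms)
    return float(np.mean(chi2[~np.isnan(chi2)] >= observed - 1e-12))


def permutation_ranksum_p(x, y, n_perm, rng):
    """Permutation p-value for the two-sided rank-sum contrast,
    using the rank-sum of the first sample as the statistic."""
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n_x = len(x)
    observed = ranks[:n_x].sum()
    expected = n_x * (len(pooled) + 1) / 2.0
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[:n_x].sum() - expected) >= abs(observed - expected) - 1e-12:
            count += 1
    return count / n_perm


def km_survival_bruteforce(time, event, t_query):
    """Product-limit estimate at one time point by direct multiplication."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    s = 1.0
    for t in sorted(np.unique(time[event])):
        if t > t_query:
            break
        n = (time >= t).sum()
        d = (event & (time == t)).sum()
        s *= 1 - d / n
    return s
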