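"""Independent brute-force / direct-formula oracles.

Everything here is written from the textbook definition of each
quantity, without using the package's implementation paths, so tests
can compare the two routes on random instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# annotation oracles
# ---------------------------------------------------------------------------


def brute_classify(snp, genes):
    """(location_class, host_gene) by scanning every (snp, gene) pair."""
    pos0 = snp.pos - 1
    hosts = [
        g for g in genes if g.chrom == snp.chrom and g.start <= pos0 < g.end
    ]
    if not hosts:
        return "intergenic", ""
    best = sorted(hosts, key=lambda g: (abs(pos0 - g.tss), g.gene_id))[0]
    return "intragenic", best.gene_id


def brute_nearest(snp, genes):
    pos0 = snp.pos - 1
    same = [g for g in genes if g.chrom == snp.chrom]
    if not same:
        return None
    best = sorted(same, key=lambda g: (abs(pos0 - g.tss), g.gene_id))[0]
    return best.gene_id, abs(pos0 - best.tss)


# ---------------------------------------------------------------------------
# classical test statistics, direct formulas
# ---------------------------------------------------------------------------


def chisq_2x2(x1, n1, x2, n2, correction=False):
    """Pearson chi-square on the 2x2 table from the expected-count formula."""
    from scipy.stats import chi2

    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    exp = np.outer(row, col) / total
    diff = np.abs(obs - exp)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / exp).sum())
    return stat, float(chi2.sf(stat, df=1))


def student_t(sample1, sample2):
    """Pooled-variance two-sample t from the hand formula."""
    from scipy.stats import t as tdist

    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    n1, n2 = len(a), len(b)
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, 2 * float(tdist.sf(abs(t), df))


def mw_exact(sample1, sample2):
    """Two-sided exact Mann-Whitney by counting pairwise wins over every
    relabeling of the pooled sample (no rank formula)."""
    pooled = list(sample1) + list(sample2)
    n1 = len(sample1)

    def u_of(group1):
        u = 0.0
        group2 = pooled.copy()
        for v in group1:
            group2.remove(v)
        for x in group1:
            for y in group2:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_of(list(sample1))
    null = [
        u_of([pooled[i] for i in idx])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    null = np.array(null)
    eps = 1e-9
    p = 2 * min((null <= u_obs + eps).mean(), (null >= u_obs - eps).mean())
    return u_obs, min(1.0, float(p))


def kruskal_h(samples):
    """Kruskal-Wallis H with tie correction from the rank formula."""
    from scipy.stats import chi2, rankdata

    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    n = len(pooled)
    ranks = rankdata(pooled)
    start = 0
    h = 0.0
    for s in samples:
        k = len(s)
        r = ranks[start : start + k]
        h += r.sum() ** 2 / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(((counts**3 - counts)).sum())
    denom = 1.0 - ties / (n**3 - n)
    if denom == 0:
        return 0.0, 1.0
    h /= denom
    return h, float(chi2.sf(h, df=len(samples) - 1))


# ---------------------------------------------------------------------------
# survival oracles
# ---------------------------------------------------------------------------


def product_limit(times, events):
    """Kaplan-Meier by the product-limit formula: at each distinct
    observation time t, S *= (1 - d_t / n_t).  Returns (times, survival,
    at_risk) over all distinct observed times."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    distinct = sorted(set(times.tolist()))
    s = 1.0
    surv, at_risk = [], []
    for t in distinct:
        n_t = int((times >= t - 1e-12).sum())
        d_t = int(((np.abs(times - t) < 1e-12) & (events == 1)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
    return distinct, surv, at_risk


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from the observed/expected and
    hypergeometric-variance sums at each distinct event time."""
    from scipy.stats import chi2

    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ea = np.asarray(events_a, int)
    eb = np.asarray(events_b, int)
    event_times = sorted(set(ta[ea == 1].tolist()) | set(tb[eb == 1].tolist()))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = int((ta >= t - 1e-12).sum())
        nb = int((tb >= t - 1e-12).sum())
        da = int(((np.abs(ta - t) < 1e-12) & (ea == 1)).sum())
        db = int(((np.abs(tb - t) < 1e-12) & (eb == 1)).sum())
        n = na + nb
        d = da + db
        if n < 2:
            continue
        e_a = d * na / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += da - e_a
        var += v
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))
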