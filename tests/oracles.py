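"""Independent reference computations used to validate the statistics
layer: direct hand-tabulated formulas, grid-search likelihood
maximization, eigendecomposition, and established library
implementations.  Each battery runs an operation against its oracle on
many random small instances and returns the worst absolute deviation.
"""

import numpy as np
from scipy import optimize
from scipy import stats as sps

import sarcoscreen as ss
from sarcoscreen.data_model import SurvivalData


def hand_logrank_2sample(groups, times, events):
    """O-E / V tabulation over risk sets, written as the textbook loop."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        r = at_risk.sum()
        r1 = (at_risk & (groups == 1)).sum()
        dead = events & (times == t)
        d = dead.sum()
        d1 = (dead & (groups == 1)).sum()
        o_minus_e += d1 - d * r1 / r
        if r > 1:
            v += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    chi2 = o_minus_e**2 / v if v > 0 else 0.0
    return chi2, float(sps.chi2.sf(chi2, 1))


def cox_grid_oracle(groups, times, events):
    """Directly maximize the hand-written Breslow partial log-likelihood
    for a binary covariate by bounded scalar optimization."""
    groups = np.asarray(groups, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)

    def negloglik(beta):
        ll = 0.0
        for t in sorted(set(times[events])):
            at_risk = times >= t
            dead = events & (times == t)
            d1 = groups[dead].sum()
            d = dead.sum()
            denom = np.sum(np.exp(beta * groups[at_risk]))
            ll += beta * d1 - d * np.log(denom)
        return -ll

    res = optimize.minimize_scalar(negloglik, bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-9})
    return float(res.x)


def _surv(rng, n, tie_prob=0.3):
    if rng.random() < tie_prob:
        times = rng.integers(1, 8, n).astype(float)
    else:
        times = rng.exponential(10, n).round(3) + 0.001
    events = rng.random(n) < 0.7
    if not events.any():
        events[rng.integers(0, n)] = True
    return times, events


def battery_anova(n_instances=120, seed=0):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        k = rng.integers(2, 5)
        counts = rng.integers(2, 8, k)
        x = rng.normal(rng.normal(0, 1, k).repeat(counts), 1.0)
        g = np.arange(k).repeat(counts)
        mine = ss.anova_oneway(x, g)
        f_ref, p_ref = sps.f_oneway(*[x[g == i] for i in range(k)])
        # second, fully hand-computed F from group sums
        means = np.array([x[g == i].mean() for i in range(k)])
        ssb = (counts * (means - x.mean()) ** 2).sum()
        ssw = sum(((x[g == i] - means[i]) ** 2).sum() for i in range(k))
        f_hand = (ssb / (k - 1)) / (ssw / (x.size - k))
        worst = max(worst, abs(mine.statistic - f_ref), abs(mine.p_value - p_ref),
                    abs(mine.statistic - f_hand))
    return worst


def battery_logrank(n_instances=120, seed=1):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(6, 25))
        times, events = _surv(rng, n)
        g = (rng.random(n) < 0.5).astype(int)
        if g.min() == g.max():
            g[0] = 1 - g[0]
        mine = ss.logrank(g, SurvivalData(times, events))
        chi2, p = hand_logrank_2sample(g, times, events)
        worst = max(worst, abs(mine.statistic - chi2), abs(mine.p_value - p))
    return worst


def battery_welch(n_instances=150, seed=2):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(2, 12))
        y = rng.normal(rng.normal(), rng.uniform(0.5, 3), rng.integers(2, 12))
        mine = ss.welch_t(x, y)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
        worst = max(worst, abs(mine.statistic - t_ref), abs(mine.p_value - p_ref))
    return worst


def battery_spearman(n_instances=150, seed=3):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 5, n).astype(float)  # heavy ties, grade-like
        y = rng.normal(size=n)
        if np.all(x == x[0]):
            x[0] += 1
        rho, p = ss.spearman(x, y)
        ref = sps.spearmanr(x, y)
        # independent mid-rank Pearson
        rho_hand = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        worst = max(worst, abs(rho - ref.statistic), abs(p - ref.pvalue),
                    abs(rho - rho_hand))
    return worst


def battery_bh(n_instances=150, seed=4):
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        p = rng.random(int(rng.integers(1, 40)))
        q = ss.bh_adjust(p)
        q_ref = multipletests(p, method="fdr_bh")[1]
        worst = max(worst, float(np.abs(q - q_ref).max()))
    return worst


def battery_km(n_instances=120, seed=5):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 25))
        times, events = _surv(rng, n)
        curve = ss.km_curve(SurvivalData(times, events))
        # no-censoring identity on a second draw
        t2 = rng.exponential(5, n).round(3) + 0.001
        c2 = ss.km_curve(SurvivalData(t2, np.ones(n, dtype=bool)))
        for tt, sv in zip(c2.event_times, c2.survival):
            worst = max(worst, abs(sv - (t2 > tt).mean()))
        # hand product-limit on the censored draw
        s = 1.0
        for t in sorted(set(times[events])):
            r = (times >= t).sum()
            d = (events & (times == t)).sum()
            s *= 1 - d / r
            worst = max(worst, abs(curve.survival_at(t) - s))
    return worst


def battery_cox(n_instances=100, seed=6):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(6, 20))
        times = rng.exponential(10, n).round(3) + 0.001
        g = (rng.random(n) < 0.5).astype(int)
        if g.min() == g.max():
            g[0] = 1 - g[0]
        events = rng.random(n) < 0.8
        if not (events & (g == 1)).any() or not (events & (g == 0)).any():
            continue  # monotone likelihood: handled separately
        mine = ss.cox_binary(g, SurvivalData(times, events))
        if not mine.converged or abs(mine.log_hr) > 8:
            continue
        ref = cox_grid_oracle(g, times, events)
        worst = max(worst, abs(mine.log_hr - ref))
    return worst


def battery_pca(n_instances=100, seed=7):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n, p = int(rng.integers(4, 15)), int(rng.integers(2, 6))
        x = rng.normal(size=(n, p)) * rng.uniform(0.5, 20, p)
        res = ss.pca(x, scale=True)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        eigval, eigvec = np.linalg.eigh(np.corrcoef(x, rowvar=False))
        eigval = np.sort(np.clip(eigval, 0, None))[::-1] * (n - 1) / n
        # proportions from the independent eigendecomposition
        prop = eigval / eigval.sum()
        worst = max(worst, float(np.abs(res.variance_proportion - prop).max()))
        worst = max(worst, float(np.abs(res.scores @ res.loadings.T - z).max()))
    return worst


def battery_hclust(n_instances=100, seed=8):
    from scipy.cluster.hierarchy import linkage

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 12))
        x = rng.normal(size=(n, 3))
        mine = ss.hclust_complete(x)
        ref = linkage(x, method="complete")
        worst = max(worst, float(np.abs(np.sort(mine.merges[:, 2]) - np.sort(ref[:, 2])).max()))
    return worst


def battery_row_scale(n_instances=100, seed=9):
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        x = rng.normal(size=(int(rng.integers(1, 6)), int(rng.integers(3, 12))))
        mine = ss.row_scale(x)
        ref = sps.zscore(x, axis=1, ddof=1)
        worst = max(worst, float(np.abs(mine - ref).max()))
    return worst


ALL_BATTERIES = {
    "anova": (battery_anova, 1e-10),
    "logrank": (battery_logrank, 1e-10),
    "welch": (battery_welch, 1e-10),
    "spearman": (battery_spearman, 1e-10),
    "bh": (battery_bh, 1e-12),
    "km": (battery_km, 1e-12),
    "cox": (battery_cox, 1e-6),
    "pca": (battery_pca, 1e-8),
    "hclust": (battery_hclust, 1e-10),
    "row_scale": (battery_row_scale, 1e-12),
}
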