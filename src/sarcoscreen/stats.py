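"""Statistical primitives used throughout the screening pipeline.

Each routine is written directly from its defining formula (group sums for
the one-way F, risk-set tabulation for the logrank test, Newton iteration
on the Breslow partial likelihood for the Cox model, eigendecomposition of
the correlation matrix for PCA, naive agglomeration for complete-linkage
clustering).  Only distribution functions (F, t, chi-square) come from
:mod:`scipy.stats`.  The test suite cross-checks every routine against an
independent reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value.

    ``df`` is a float for chi-square/t tests and a ``(df1, df2)`` pair for
    the F test.  ``flag`` marks degenerate inputs (e.g. a logrank test with
    no events) for which a conventional value is returned instead of an
    error, so genome-wide scans never abort.
    """

    statistic: float
    p_value: float
    df: object
    n_used: int
    flag: str | None = None


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate stepped at event times only."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): survival just after time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class CoxResult:
    """Binary-covariate Cox fit: ``log_hr`` is the partial-likelihood MLE B,
    ``hazard_ratio`` is exp(B)."""

    log_hr: float
    hazard_ratio: float
    converged: bool


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_proportion: np.ndarray
    cumulative_proportion: np.ndarray
    dropped_variables: tuple = ()


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence in scipy linkage convention:
    row t merges cluster ids ``a`` and ``b`` (original items are 0..n-1,
    the cluster formed at step t gets id n+t) at ``height``."""

    merges: np.ndarray  # (n-1, 4): a, b, height, size
    leaf_order: tuple

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_oneway(values, groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    Parameters
    ----------
    values : array-like of float
    groups : array-like of labels, at least two levels with >=2 members each

    Returns the F statistic on (k-1, n-k) degrees of freedom and its upper
    tail p-value.  A grid with zero variance everywhere returns F=0, p=1;
    zero within-group variance with distinct means returns p=0.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape or x.ndim != 1:
        raise ValueError("values and groups must be 1-d and aligned")
    levels, codes = np.unique(g, return_inverse=True)
    k = levels.size
    n = x.size
    if k < 2:
        raise ValueError("ANOVA needs at least two group levels")
    counts = np.bincount(codes, minlength=k)
    if (counts < 2).any():
        small = [str(levels[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"group level(s) with fewer than 2 members: {small}")
    sums = np.bincount(codes, weights=x, minlength=k)
    ssq = np.bincount(codes, weights=x * x, minlength=k)
    grand = sums.sum()
    ss_between = float((sums**2 / counts).sum() - grand**2 / n)
    ss_within = float(ssq.sum() - (sums**2 / counts).sum())
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        if ss_between <= 1e-12 * max(1.0, float(np.abs(x).max()) ** 2):
            return TestResult(0.0, 1.0, (df1, df2), n, flag="zero_variance")
        return TestResult(np.inf, 0.0, (df1, df2), n, flag="zero_within_variance")
    f = (ss_between / df1) / (ss_within / df2)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), p, (df1, df2), n)


# ---------------------------------------------------------------------------
# logrank test (k-sample, with ties)
# ---------------------------------------------------------------------------

def logrank(groups, sd) -> TestResult:
    """k-sample logrank test of equality of survival distributions.

    Observed-minus-expected event counts are accumulated over the risk set
    at every distinct event time; the chi-square statistic uses the
    hypergeometric covariance with k-1 degrees of freedom (for two groups
    this reduces to (O-E)^2/V).  With no events at all the test is
    undefined and ``p=1`` is returned with a flag.
    """
    g = np.asarray(groups)
    times = np.asarray(sd.times, dtype=float)
    events = np.asarray(sd.events, dtype=bool)
    if g.shape != times.shape:
        raise ValueError("groups and survival data must be aligned")
    levels, codes = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("logrank needs at least two nonempty groups")
    n = times.size
    if not events.any():
        return TestResult(0.0, 1.0, k - 1, n, flag="no_events")

    order = np.argsort(times, kind="stable")
    t_s, e_s, c_s = times[order], events[order], codes[order]
    # at-risk count per group just before each position
    at_risk = np.zeros(k)
    np.add.at(at_risk, c_s, 1)

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    i = 0
    risk_by_group = at_risk.copy()
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        if d > 0:
            r = risk_by_group.sum()
            d_by_group = np.bincount(c_s[i:j][e_s[i:j]], minlength=k).astype(float)
            expected = d * risk_by_group / r
            o_minus_e += d_by_group - expected
            if r > 1:
                frac = risk_by_group / r
                scale = d * (r - d) / (r - 1)
                cov += scale * (np.diag(frac) - np.outer(frac, frac))
        removed = np.bincount(c_s[i:j], minlength=k).astype(float)
        risk_by_group -= removed
        i = j

    # drop one group to obtain a full-rank covariance
    u = o_minus_e[:-1]
    v = cov[:-1, :-1]
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult(chi2, p, k - 1, n)


# ---------------------------------------------------------------------------
# Welch's t test
# ---------------------------------------------------------------------------

def welch_t(x, y) -> TestResult:
    """Two-sided Welch t test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, float(x.size + y.size - 2), x.size + y.size,
                              flag="zero_variance")
        raise ValueError("both samples degenerate with unequal means")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        (sx**2 / (x.size - 1)) + (sy**2 / (y.size - 1))
    )
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), p, float(df), x.size + y.size)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho (Pearson correlation of mid-ranks) with a
    two-sided p-value from the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for an all-tied vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at 1, returned in the input
    order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Kaplan-Meier product-limit estimate
# ---------------------------------------------------------------------------

def km_curve(sd) -> KMCurve:
    """Product-limit estimate with steps at distinct event times."""
    times = np.asarray(sd.times, dtype=float)
    events = np.asarray(sd.events, dtype=bool)
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    n = t_s.size
    event_times, survival, at_risk = [], [], []
    s = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        r = n - i
        if d > 0:
            s *= 1.0 - d / r
            event_times.append(t_s[i])
            survival.append(s)
            at_risk.append(r)
        i = j
    return KMCurve(
        np.asarray(event_times), np.asarray(survival), np.asarray(at_risk, dtype=int)
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate
# ---------------------------------------------------------------------------

_COX_BOUND = 15.0


def cox_binary(group, sd, tol: float = 1e-10, max_iter: int = 60) -> CoxResult:
    """Maximum partial-likelihood estimate of the log hazard ratio for a
    0/1 covariate, Breslow tie handling, Newton iteration.

    With a monotone likelihood (all events in one group) the estimate is
    clipped at ``+/-15`` on the log scale and flagged non-converged.
    """
    g = np.asarray(group, dtype=float)
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("group must be coded 0/1")
    if g.min() == g.max():
        raise ValueError("both groups must be nonempty")
    times = np.asarray(sd.times, dtype=float)
    events = np.asarray(sd.events, dtype=bool)
    if not events.any():
        raise ValueError("cox_binary requires at least one event")

    order = np.argsort(times, kind="stable")
    t_s, e_s, g_s = times[order], events[order], g[order]
    n = t_s.size

    # Breslow: per distinct event time, d events, d1 of them in group 1,
    # (n0, n1) at risk.
    recs = []
    i = 0
    n1_risk = g_s.sum()
    n_risk = float(n)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        if d > 0:
            d1 = float(g_s[i:j][e_s[i:j]].sum())
            recs.append((d, d1, n_risk - n1_risk, n1_risk))
        n_risk -= j - i
        n1_risk -= g_s[i:j].sum()
        i = j
    d_arr = np.array([r[0] for r in recs], dtype=float)
    d1_arr = np.array([r[1] for r in recs], dtype=float)
    n0_arr = np.array([r[2] for r in recs], dtype=float)
    n1_arr = np.array([r[3] for r in recs], dtype=float)

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        w = n1_arr * np.exp(beta)
        denom = n0_arr + w
        mu = w / denom
        score = float(d1_arr.sum() - (d_arr * mu).sum())
        info = float((d_arr * mu * (1 - mu)).sum())
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) > _COX_BOUND:
            beta = float(np.sign(beta) * _COX_BOUND)
            break
        if abs(step) < tol:
            converged = True
            break
    return CoxResult(float(beta), float(np.exp(beta)), converged)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(data, scale: bool = True) -> PCAResult:
    """Principal components of a samples x variables matrix.

    By default variables are standardized (correlation-matrix PCA), which
    is appropriate for expression signals spanning orders of magnitude; set
    ``scale=False`` for covariance PCA.  Zero-variance variables are
    dropped with a record in ``dropped_variables``.  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("pca needs a 2-d matrix with >=2 samples and >=2 variables")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(np.flatnonzero(~keep))
    x = x[:, keep]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 variables with positive variance")
    centered = x - x.mean(axis=0)
    if scale:
        centered = centered / x.std(axis=0, ddof=1)
    n = x.shape[0]
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    idx = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[idx], 0.0, None)
    eigvec = eigvec[:, idx]
    # deterministic sign: largest-magnitude loading positive
    for c in range(eigvec.shape[1]):
        col = eigvec[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, c] = -col
    scores = centered @ eigvec
    total = eigval.sum()
    prop = eigval / total if total > 0 else np.zeros_like(eigval)
    return PCAResult(
        scores=scores,
        loadings=eigvec,
        variance_proportion=prop,
        cumulative_proportion=np.cumsum(prop),
        dropped_variables=dropped,
    )


# ---------------------------------------------------------------------------
# complete-linkage hierarchical clustering
# ---------------------------------------------------------------------------

def hclust_complete(data) -> Dendrogram:
    """Agglomerative clustering with Euclidean distance and complete
    linkage.  Ties are broken by the lexicographically smallest cluster-id
    pair so the merge sequence is deterministic across platforms.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("hclust_complete needs >=2 items")
    n = x.shape[0]
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    active: dict[int, list] = {i: [i] for i in range(n)}
    cdist: dict[tuple, float] = {}
    ids = list(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            cdist[(a, b)] = float(dist[a, b])

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), h = min(cdist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[a] + active[b]
        for key in [k for k in cdist if a in k or b in k]:
            del cdist[key]
        del active[a], active[b]
        for other, omembers in active.items():
            d = max(
                float(dist[i, j]) for i in members for j in omembers
            )
            key = (other, next_id) if other < next_id else (next_id, other)
            cdist[key] = d
        active[next_id] = members
        merges[step] = (a, b, h, len(members))
        next_id += 1

    leaf_order = _leaf_order(merges, n)
    return Dendrogram(merges=merges, leaf_order=tuple(leaf_order))


def _leaf_order(merges: np.ndarray, n: int) -> list:
    def expand(cid: int) -> list:
        if cid < n:
            return [cid]
        a, b = int(merges[cid - n, 0]), int(merges[cid - n, 1])
        return expand(a) + expand(b)

    return expand(2 * n - 2)


# ---------------------------------------------------------------------------
# row scaling
# ---------------------------------------------------------------------------

def row_scale(data) -> np.ndarray:
    """Center each row to mean 0 and scale to unit standard deviation
    (ddof=1, matching the convention of R's ``scale``)."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("row_scale expects a 2-d matrix")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        bad = np.flatnonzero(sd.ravel() == 0)
        raise ValueError(f"zero-variance row(s): {bad.tolist()[:5]}")
    return (x - mean) / sd
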