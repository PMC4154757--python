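"""The integrated ANOVA x logrank screen and its permutation-minP null.

Each probe receives two p-values: ``p1`` from a one-way ANOVA of its
log-transformed signal across the four discrimination subtypes (UPS, MFS,
MLS, SS) and ``p2`` from a logrank test of the survival split at the
probe's median expression.  The integrated statistic is ``p' = p1 * p2``.
Because both tests share patients, ``p'`` is not uniform under the null;
it is converted to a family-wise-error-controlled adjusted p-value against
an empirical null built by permuting whole clinical rows (subtype,
survival, grade, metastasis move together) against the fixed expression
matrix and recording, for each of R permutations, the minimum ``p'`` over
all probes (a minP / Westfall-Young style single-step correction).

The expression-side quantities (median splits, log signals) are fixed
across permutations; only the clinical labels move.  This makes each
permutation a cheap relabeling and R in the tens of thousands tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special as spsp

from .data_model import (
    DEFAULT_CENSOR_HORIZON,
    DISCRIMINATION_SUBTYPES,
    ClinicalTable,
    ExpressionMatrix,
    SurvivalData,
)


def integrated_statistic(p1, p2):
    """The integrated screening statistic ``p' = p1 * p2``.

    Accepts scalars or arrays; inputs must lie in [0, 1].
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    for name, v in (("p1", a), ("p2", b)):
        if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
            raise ValueError(f"{name} outside [0, 1]")
    out = a * b
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScreeningResult:
    """Per-probe screen statistics.

    ``table`` is indexed by probe id with columns ``p_anova``,
    ``p_logrank``, ``p_integrated``, ``flag`` and - after :func:`adjust` -
    ``p_adjusted`` and ``reported_lt`` (True when no null minimum reached
    the observed ``p'``, conventionally displayed as ``<1/R``).
    """

    table: pd.DataFrame
    meta: dict

    @property
    def valid_probes(self) -> tuple:
        return tuple(self.table.index[self.table["flag"].isna()])


@dataclass(frozen=True)
class PermutationNull:
    """R per-permutation minima of ``p'`` defining the empirical null."""

    R: int
    null_min: np.ndarray
    seed: int | None

    def __post_init__(self):
        nm = np.asarray(self.null_min, dtype=float)
        if nm.size != self.R:
            raise ValueError("null_min length must equal R")
        object.__setattr__(self, "null_min", nm)


@dataclass(frozen=True)
class ThresholdScanResult:
    """Per-probe best-threshold logrank scan with permutation correction."""

    table: pd.DataFrame
    null_min: np.ndarray
    thresholds_pct: tuple
    R: int
    mode: str


def format_adjusted_p(p_adjusted: float, reported_lt: bool, R: int) -> str:
    """Render an adjusted p-value the way screening tables print it:
    the exceedance fraction, or ``<1/R`` when no null minimum was as small
    as the observed statistic."""
    if reported_lt:
        return f"<{1.0 / R:.2E}"
    return f"{p_adjusted:.2E}"


# ---------------------------------------------------------------------------
# fixed survival-sort structure (shared by observed data and permutations)
# ---------------------------------------------------------------------------

class _SurvSort:
    """Pre-sorted risk-set structure for a fixed set of clinical rows.

    Permuting whole clinical rows leaves the multiset of (time, event)
    pairs - and hence the sorted time axis, the tie segments, the event
    counts per segment and the at-risk totals - unchanged; only the group
    labels move.  Everything label-independent is computed once here.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray, rows: np.ndarray):
        self.rows = rows  # clinical row indices included in this cohort
        t = times[rows]
        e = events[rows].astype(float)
        order = np.argsort(t, kind="stable")
        self.order = order
        t_sorted = t[order]
        self.e_sorted = e[order]
        n = t_sorted.size
        _, seg_starts = np.unique(t_sorted, return_index=True)
        d_seg = np.add.reduceat(self.e_sorted, seg_starts)
        r_seg = (n - seg_starts).astype(float)
        valid = d_seg > 0
        self.seg_starts = seg_starts
        self.valid = valid
        d = d_seg[valid]
        r = r_seg[valid]
        self.d_over_r = d / r
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d * (r - d) / ((r - 1.0) * r * r)
        w[r <= 1.0] = 0.0
        self.w = w
        self.r = r
        self.n = n
        self.n_events = float(d.sum())

    def logrank_p(self, groups_sorted: np.ndarray) -> np.ndarray:
        """Vectorized 2-sample logrank p-values.

        ``groups_sorted`` is (n_probes, n) of 0/1 group indicators already
        aligned to the sorted time axis.  Returns the chi-square(1) upper
        tail; splits with zero variance give p = 1.
        """
        g = groups_sorted.astype(float, copy=False)
        r1 = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
        d1 = np.add.reduceat(g * self.e_sorted, self.seg_starts, axis=1)[:, self.valid]
        r1s = r1[:, self.seg_starts[self.valid]]
        u = d1.sum(axis=1) - r1s @ self.d_over_r
        v = (r1s * (self.r - r1s)) @ self.w
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = u * u / v
        p = np.ones_like(u)
        ok = v > 0
        p[ok] = spsp.chdtrc(1, chi2[ok])
        return p


class _ScreenEngine:
    """Computes (p1, p2) for all probes under any clinical-row permutation.

    A permutation ``perm`` assigns clinical row ``perm[s]`` to expression
    column ``s``; internally this is handled as the inverse map applied to
    the expression columns against fixed clinical rows, so all survival
    risk-set structure is precomputed.
    """

    def __init__(
        self,
        m_log: ExpressionMatrix,
        m_bin: ExpressionMatrix,
        clinical: ClinicalTable,
        discrimination_subtypes=DISCRIMINATION_SUBTYPES,
        survival_cohort: str = "all",
        horizon: float | None = DEFAULT_CENSOR_HORIZON,
    ):
        if m_log.probe_ids != m_bin.probe_ids:
            raise ValueError("log and binarized matrices must share probes")
        if m_log.sample_ids != m_bin.sample_ids:
            raise ValueError("log and binarized matrices must share samples")
        if set(clinical.patient_ids) != set(m_log.sample_ids):
            raise ValueError("clinical table must cover exactly the matrix samples")
        if survival_cohort not in ("all", "discrimination"):
            raise ValueError("survival_cohort must be 'all' or 'discrimination'")
        clinical = clinical.reorder(m_log.sample_ids)

        self.probe_ids = m_log.probe_ids
        self.n = len(clinical)
        subtype = clinical.subtype
        self.k = len(discrimination_subtypes)
        code = np.full(self.n, -1, dtype=int)
        for ci, s in enumerate(discrimination_subtypes):
            code[subtype == s] = ci
        present = np.unique(code[code >= 0])
        if present.size < 2:
            raise ValueError("fewer than 2 discrimination subtypes present")
        self.members = [np.flatnonzero(code == ci) for ci in range(self.k)]
        self.members = [m for m in self.members if m.size > 0]
        self.k = len(self.members)
        self.counts = np.array([m.size for m in self.members], dtype=float)
        self.n_disc = int(self.counts.sum())

        sd = clinical.survival_data(horizon=horizon)
        self.times = sd.times
        self.events = sd.events
        rows_all = np.arange(self.n)
        rows_surv = (
            rows_all if survival_cohort == "all" else np.concatenate(self.members)
        )
        self.surv = _SurvSort(self.times, self.events, np.sort(rows_surv))

        # degenerate probes: no median split, or constant log signal
        B = m_bin.signals
        bin_degenerate = (B.min(axis=1) == B.max(axis=1))
        const = m_log.signals.min(axis=1) == m_log.signals.max(axis=1)
        self.flags = np.where(
            bin_degenerate, "degenerate_split", np.where(const, "constant", None)
        )
        self.valid_mask = ~(bin_degenerate | const)
        self.X = m_log.signals[self.valid_mask]
        self.X2 = self.X * self.X
        self.B = B[self.valid_mask].astype(float)
        self.meta = {
            "discrimination_subtypes": tuple(discrimination_subtypes),
            "survival_cohort": survival_cohort,
            "horizon": horizon,
            "n_anova": self.n_disc,
            "n_logrank": int(self.surv.rows.size),
        }

    def pvalues(self, perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(p1, p2) for the valid probes under permutation ``perm``."""
        inv = np.argsort(perm)
        nv = self.X.shape[0]
        s1 = np.empty((nv, self.k))
        s2 = np.empty((nv, self.k))
        for gi, rows in enumerate(self.members):
            cols = inv[rows]
            s1[:, gi] = self.X[:, cols].sum(axis=1)
            s2[:, gi] = self.X2[:, cols].sum(axis=1)
        grand = s1.sum(axis=1)
        per_group = (s1 * s1 / self.counts).sum(axis=1)
        ssb = per_group - grand * grand / self.n_disc
        ssw = s2.sum(axis=1) - per_group
        df1, df2 = self.k - 1, self.n_disc - self.k
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / df1) / (ssw / df2)
        p1 = np.empty(nv)
        ok = ssw > 0
        p1[ok] = spsp.fdtrc(df1, df2, np.maximum(f[ok], 0.0))
        # zero within-group variance: p -> 0 if means differ, else 1
        p1[~ok] = np.where(ssb[~ok] > 1e-12, 0.0, 1.0)

        cols = inv[self.surv.rows][self.surv.order]
        p2 = self.surv.logrank_p(self.B[:, cols])
        return p1, p2

    def min_pprime(self, perm: np.ndarray) -> float:
        p1, p2 = self.pvalues(perm)
        return float(np.min(p1 * p2)) if p1.size else 1.0


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def screen(
    m_log: ExpressionMatrix,
    m_bin: ExpressionMatrix,
    clinical: ClinicalTable,
    discrimination_subtypes=DISCRIMINATION_SUBTYPES,
    survival_cohort: str = "all",
    horizon: float | None = DEFAULT_CENSOR_HORIZON,
) -> ScreeningResult:
    """Compute ``p1`` (subtype ANOVA), ``p2`` (median-split logrank) and
    ``p' = p1 * p2`` for every probe.

    ``survival_cohort`` selects whether the logrank test uses all patients
    (default) or only the discrimination subtypes.  Probes with a
    degenerate median split or constant signal are flagged and excluded
    from the statistics (their rows carry NaN).
    """
    eng = _ScreenEngine(
        m_log, m_bin, clinical, discrimination_subtypes, survival_cohort, horizon
    )
    p1v, p2v = eng.pvalues(np.arange(eng.n))
    p1 = np.full(len(eng.probe_ids), np.nan)
    p2 = np.full(len(eng.probe_ids), np.nan)
    p1[eng.valid_mask] = p1v
    p2[eng.valid_mask] = p2v
    table = pd.DataFrame(
        {
            "p_anova": p1,
            "p_logrank": p2,
            "p_integrated": p1 * p2,
            "flag": pd.array(eng.flags, dtype="object"),
        },
        index=pd.Index(eng.probe_ids, name="probe_id"),
    )
    return ScreeningResult(table=table, meta=dict(eng.meta))


def build_null(
    m_log: ExpressionMatrix,
    m_bin: ExpressionMatrix,
    clinical: ClinicalTable,
    R: int = 1000,
    seed: int | None = 0,
    permutations=None,
    discrimination_subtypes=DISCRIMINATION_SUBTYPES,
    survival_cohort: str = "all",
    horizon: float | None = DEFAULT_CENSOR_HORIZON,
) -> PermutationNull:
    """Build the empirical null of per-permutation minimum ``p'``.

    Whole clinical rows are permuted against the fixed expression columns;
    the discrimination subset is re-derived from the permuted labels each
    time.  Pass an explicit iterable of permutations (arrays of clinical
    row indices) to force particular relabelings - e.g. the identity, or
    an exhaustively enumerated subgroup; ``R`` is then ignored.
    """
    eng = _ScreenEngine(
        m_log, m_bin, clinical, discrimination_subtypes, survival_cohort, horizon
    )
    if permutations is not None:
        perms = [np.asarray(p, dtype=int) for p in permutations]
        R = len(perms)
        if R < 1:
            raise ValueError("need at least one permutation")
        mins = np.array([eng.min_pprime(p) for p in perms])
        return PermutationNull(R=R, null_min=mins, seed=seed)
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    mins = np.empty(R)
    for r in range(R):
        mins[r] = eng.min_pprime(rng.permutation(eng.n))
    return PermutationNull(R=R, null_min=mins, seed=seed)


def adjust(sr: ScreeningResult, null: PermutationNull) -> ScreeningResult:
    """Convert each observed ``p'`` to its adjusted p-value: the fraction
    of null minima at or below it.  When that count is zero the adjusted
    value is reported as ``<1/R`` (``reported_lt`` set, value 1/R)."""
    if null.R < 1:
        raise ValueError("empty permutation null")
    sorted_null = np.sort(null.null_min)
    pprime = sr.table["p_integrated"].to_numpy()
    counts = np.searchsorted(sorted_null, pprime, side="right").astype(float)
    counts[np.isnan(pprime)] = np.nan
    with np.errstate(invalid="ignore"):
        p_adj = counts / null.R
    reported_lt = counts == 0
    p_adj[reported_lt] = 1.0 / null.R
    table = sr.table.copy()
    table["p_adjusted"] = p_adj
    table["reported_lt"] = reported_lt
    meta = dict(sr.meta)
    meta.update({"R": null.R, "null_seed": null.seed})
    return ScreeningResult(table=table, meta=meta)


def screen_adjusted(
    m_log, m_bin, clinical, R: int = 1000, seed: int | None = 0, **kwargs
) -> tuple[ScreeningResult, PermutationNull]:
    """Convenience: observed screen plus permutation null plus adjustment."""
    sr = screen(m_log, m_bin, clinical, **kwargs)
    null = build_null(m_log, m_bin, clinical, R=R, seed=seed, **kwargs)
    return adjust(sr, null), null


# ---------------------------------------------------------------------------
# best-threshold logrank scan within one subtype cohort
# ---------------------------------------------------------------------------

DEFAULT_SCAN_THRESHOLDS = (30, 40, 50, 60, 70, 80)


def threshold_scan(
    m: ExpressionMatrix,
    sd: SurvivalData,
    thresholds_pct=DEFAULT_SCAN_THRESHOLDS,
    R: int = 1000,
    seed: int | None = 0,
    mode: str = "joint",
    permutations=None,
) -> ThresholdScanResult:
    """Scan percentile splits of each probe for survival association.

    For each probe, the expression signal within the cohort is split at
    each percentile threshold (linear-interpolation convention) and the
    two-group logrank p computed; ``p_best`` is the minimum over
    thresholds.  The permutation null permutes the cohort's survival rows
    and records, per repetition, the minimum p over all probe x threshold
    tests (``mode='joint'``, correcting for the whole grid) or the
    per-probe minimum over its thresholds (``mode='per_probe'``).
    Thresholds that give an empty group are skipped; probes with every
    threshold degenerate are flagged and excluded.
    """
    if mode not in ("joint", "per_probe"):
        raise ValueError("mode must be 'joint' or 'per_probe'")
    n = m.n_samples
    if n < 4:
        raise ValueError("cohort too small for a threshold scan")
    if len(sd) != n:
        raise ValueError("survival data must match the cohort")
    thresholds_pct = tuple(thresholds_pct)

    # fixed splits: (probe, threshold) -> 0/1 group vector
    split_rows: list[np.ndarray] = []
    split_probe: list[int] = []
    split_pct: list[float] = []
    for pi in range(m.n_probes):
        x = m.signals[pi]
        for pct in thresholds_pct:
            cut = np.percentile(x, pct, method="linear")
            g = (x > cut).astype(float)
            if 0 < g.sum() < n:
                split_rows.append(g)
                split_probe.append(pi)
                split_pct.append(pct)
    probe_flags = np.array(
        ["all_thresholds_degenerate"] * m.n_probes, dtype=object
    )
    for pi in set(split_probe):
        probe_flags[pi] = None
    if not split_rows:
        raise ValueError("every probe/threshold split is degenerate")

    G = np.asarray(split_rows)  # (n_tests, n)
    split_probe_arr = np.asarray(split_probe)
    split_pct_arr = np.asarray(split_pct, dtype=float)
    surv = _SurvSort(sd.times, np.asarray(sd.events, dtype=float), np.arange(n))

    p_obs = surv.logrank_p(G[:, surv.order])

    p_best = np.full(m.n_probes, np.nan)
    best_pct = np.full(m.n_probes, np.nan)
    for pi in range(m.n_probes):
        sel = split_probe_arr == pi
        if sel.any():
            ps = p_obs[sel]
            best = np.argmin(ps)
            p_best[pi] = ps[best]
            best_pct[pi] = split_pct_arr[sel][best]

    rng = np.random.default_rng(seed)
    if permutations is not None:
        perms = [np.asarray(p, dtype=int) for p in permutations]
        R = len(perms)
    else:
        perms = None

    def _perm(r):
        return perms[r] if perms is not None else rng.permutation(n)

    if mode == "joint":
        null_min = np.empty(R)
        for r in range(R):
            inv = np.argsort(_perm(r))
            cols = inv[surv.rows][surv.order]
            null_min[r] = surv.logrank_p(G[:, cols]).min()
        sorted_null = np.sort(null_min)
        counts = np.searchsorted(sorted_null, p_best, side="right").astype(float)
    else:
        null_min = np.empty((R, m.n_probes))
        for r in range(R):
            inv = np.argsort(_perm(r))
            cols = inv[surv.rows][surv.order]
            p_r = surv.logrank_p(G[:, cols])
            for pi in range(m.n_probes):
                sel = split_probe_arr == pi
                null_min[r, pi] = p_r[sel].min() if sel.any() else np.nan
        counts = (null_min <= p_best[None, :]).sum(axis=0).astype(float)

    counts[np.isnan(p_best)] = np.nan
    with np.errstate(invalid="ignore"):
        p_adj = counts / R
    reported_lt = counts == 0
    p_adj[reported_lt] = 1.0 / R

    table = pd.DataFrame(
        {
            "best_threshold_pct": best_pct,
            "p_best": p_best,
            "p_adjusted": p_adj,
            "reported_lt": reported_lt,
            "flag": pd.array(probe_flags, dtype="object"),
        },
        index=pd.Index(m.probe_ids, name="probe_id"),
    )
    return ThresholdScanResult(
        table=table,
        null_min=null_min if mode == "joint" else np.nanmin(null_min, axis=1),
        thresholds_pct=thresholds_pct,
        R=R,
        mode=mode,
    )
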