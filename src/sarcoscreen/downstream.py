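"""Characterization of screened genes: clinical correlations, pairwise
subtype comparisons with FDR control, Venn-style grouping against a
reference signature, heatmap/cluster export, PCA projections, and
Kaplan-Meier displays."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import stats
from .data_model import (
    DEFAULT_CENSOR_HORIZON,
    DISCRIMINATION_SUBTYPES,
    ClinicalTable,
    ExpressionMatrix,
    SurvivalData,
)

DEFAULT_PAIRS = (("UPS", "MFS"), ("UPS", "SS"), ("UPS", "MLS"))


def load_reference_signature() -> tuple:
    """Gene symbols of the bundled reference prognostic signature.

    This is a synthetic stand-in list of mitosis/chromosome-integrity
    genes shipped for overlap classification only; it is not the published
    67-gene signature.
    """
    text = (
        resources.files("sarcoscreen.data")
        .joinpath("synthetic_reference_signature.txt")
        .read_text()
    )
    return tuple(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


# ---------------------------------------------------------------------------
# Spearman correlations with grade / metastasis
# ---------------------------------------------------------------------------

def correlate_clinical(m: ExpressionMatrix, clinical: ClinicalTable) -> pd.DataFrame:
    """Per probe, Spearman rank correlation of the expression signal with
    histological grade (1-3) and with metastasis status (0/1).

    Returns a frame indexed by probe id with columns ``rho_grade``,
    ``p_grade``, ``rho_metastasis``, ``p_metastasis`` and ``flag``; probes
    with constant signal - or a clinical covariate with no variation - are
    flagged with NaN correlations rather than raising.
    """
    clinical = clinical.reorder(m.sample_ids)
    grade = clinical.grade.astype(float)
    meta = clinical.metastasis.astype(float)
    rows = []
    for pi, probe in enumerate(m.probe_ids):
        x = m.signals[pi]
        rec = {"rho_grade": np.nan, "p_grade": np.nan,
               "rho_metastasis": np.nan, "p_metastasis": np.nan, "flag": None}
        if np.all(x == x[0]):
            rec["flag"] = "constant_probe"
        else:
            try:
                rec["rho_grade"], rec["p_grade"] = stats.spearman(x, grade)
            except ValueError:
                rec["flag"] = "constant_grade"
            try:
                rec["rho_metastasis"], rec["p_metastasis"] = stats.spearman(x, meta)
            except ValueError:
                rec["flag"] = rec["flag"] or "constant_metastasis"
        rows.append(rec)
    return pd.DataFrame(rows, index=pd.Index(m.probe_ids, name="probe_id"))


# ---------------------------------------------------------------------------
# pairwise Welch comparisons with per-pair BH adjustment
# ---------------------------------------------------------------------------

def pairwise_compare(
    m_log: ExpressionMatrix,
    clinical: ClinicalTable,
    pairs=DEFAULT_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch's t test per probe for each subtype pair, with
    Benjamini-Hochberg adjustment within each comparison column (the
    family is the probe set tested for that pair).

    Returns a long-format frame with columns ``probe_id``, ``comparison``,
    ``p_welch``, ``q_bh``, ``significant``.
    """
    clinical = clinical.reorder(m_log.sample_ids)
    subtype = clinical.subtype
    frames = []
    for a, b in pairs:
        mask_a = subtype == a
        mask_b = subtype == b
        if not mask_a.any() or not mask_b.any():
            raise ValueError(f"subtype missing from cohort for pair {a} vs {b}")
        label = f"{a}-{b}"
        pvals = np.empty(m_log.n_probes)
        for pi in range(m_log.n_probes):
            pvals[pi] = stats.welch_t(
                m_log.signals[pi, mask_a], m_log.signals[pi, mask_b]
            ).p_value
        q = stats.bh_adjust(pvals)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": list(m_log.probe_ids),
                    "comparison": label,
                    "p_welch": pvals,
                    "q_bh": q,
                    "significant": q < alpha,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Venn classification over the three comparisons
# ---------------------------------------------------------------------------

def venn_classify(
    pairwise: pd.DataFrame,
    gene_symbols: dict | None = None,
    reference_list=None,
) -> pd.DataFrame:
    """Assign each probe to one of the 2^3 - 1 significance regions of the
    three pairwise comparisons (or ``none``), and flag overlap of its gene
    symbol with a reference signature list.

    ``gene_symbols`` maps probe id -> symbol (defaults to the probe id);
    ``reference_list`` defaults to the bundled synthetic signature.
    """
    comparisons = sorted(pairwise["comparison"].unique())
    if len(comparisons) != 3:
        raise ValueError("venn_classify expects exactly 3 comparisons")
    if reference_list is None:
        reference_list = load_reference_signature()
    ref = set(reference_list)
    wide = pairwise.pivot(index="probe_id", columns="comparison", values="significant")
    labels = []
    for probe, row in wide.iterrows():
        sig = [c for c in comparisons if bool(row[c])]
        labels.append("&".join(sig) if sig else "none")
    symbols = [
        (gene_symbols or {}).get(p, p) for p in wide.index
    ]
    return pd.DataFrame(
        {
            "region": labels,
            "gene_symbol": symbols,
            "in_reference": [s in ref for s in symbols],
        },
        index=wide.index,
    )


# ---------------------------------------------------------------------------
# heatmap export (row scaling + double dendrogram)
# ---------------------------------------------------------------------------

def heatmap_export(
    m_log: ExpressionMatrix, probes=None, clinical: ClinicalTable | None = None
) -> dict:
    """Row-scaled matrix with complete-linkage dendrograms on probes and
    samples (Euclidean distance), plus both leaf orders.

    Zero-variance probes are dropped with a warning.  Returns a dict with
    ``matrix`` (DataFrame), ``probe_dendrogram``, ``sample_dendrogram``,
    ``probe_order``, ``sample_order``.
    """
    mm = m_log if probes is None else m_log.subset_probes(list(probes))
    sd = mm.signals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance probe(s) from heatmap",
            stacklevel=2,
        )
        mm = mm.subset_probes(keep.tolist())
    if mm.n_probes < 2 or mm.n_samples < 2:
        raise ValueError("heatmap needs at least 2 probes and 2 samples")
    scaled = stats.row_scale(mm.signals)
    probe_dend = stats.hclust_complete(scaled)
    sample_dend = stats.hclust_complete(scaled.T)
    frame = pd.DataFrame(scaled, index=list(mm.probe_ids), columns=list(mm.sample_ids))
    return {
        "matrix": frame,
        "probe_dendrogram": probe_dend,
        "sample_dendrogram": sample_dend,
        "probe_order": tuple(mm.probe_ids[i] for i in probe_dend.leaf_order),
        "sample_order": tuple(mm.sample_ids[i] for i in sample_dend.leaf_order),
    }


def cut_dendrogram(dend: stats.Dendrogram, n_clusters: int) -> np.ndarray:
    """Labels from cutting the merge sequence into ``n_clusters`` groups
    (the last ``n_clusters - 1`` merges are undone)."""
    n = dend.merges.shape[0] + 1
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    parent = {}
    for t, (a, b, _, _) in enumerate(dend.merges[: n - n_clusters]):
        parent[int(a)] = n + t
        parent[int(b)] = n + t
    def root(i):
        while i in parent:
            i = parent[i]
        return i
    roots = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = root(leaf)
        labels[leaf] = roots.setdefault(r, len(roots))
    return labels


# ---------------------------------------------------------------------------
# PCA projection of samples over selected probes
# ---------------------------------------------------------------------------

def pca_project(
    m_log: ExpressionMatrix,
    probes=None,
    clinical: ClinicalTable | None = None,
    scale: bool = True,
) -> dict:
    """PCA of samples (observations) over the selected probes (variables).

    Returns ``result`` (:class:`~sarcoscreen.stats.PCAResult`), ``scores``
    (DataFrame with subtype labels when clinical is given) and
    ``eigenvectors`` / ``variance`` tables in the standard
    eigenvector / standard deviation / proportion / cumulative layout.
    """
    mm = m_log if probes is None else m_log.subset_probes(list(probes))
    if mm.n_probes < 2:
        raise ValueError("pca needs at least 2 probes")
    if mm.n_samples < 3:
        raise ValueError("pca needs at least 3 samples")
    res = stats.pca(mm.signals.T, scale=scale)
    ncomp = res.scores.shape[1]
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(res.scores, index=list(mm.sample_ids), columns=comp_names)
    if clinical is not None:
        scores.insert(0, "subtype", clinical.reorder(mm.sample_ids).subtype)
    kept = [p for i, p in enumerate(mm.probe_ids) if i not in res.dropped_variables]
    eig = pd.DataFrame(res.loadings, index=kept, columns=comp_names)
    var = pd.DataFrame(
        {
            "standard_deviation": res.scores.std(axis=0, ddof=1),
            "proportion_of_variance": res.variance_proportion,
            "cumulative_proportion": res.cumulative_proportion,
        },
        index=comp_names,
    )
    return {"result": res, "scores": scores, "eigenvectors": eig, "variance": var}


# ---------------------------------------------------------------------------
# Kaplan-Meier displays
# ---------------------------------------------------------------------------

def subtype_km(
    clinical: ClinicalTable,
    subtypes=DISCRIMINATION_SUBTYPES,
    horizon: float | None = DEFAULT_CENSOR_HORIZON,
) -> dict:
    """One Kaplan-Meier curve per subtype plus the k-group logrank p.

    With a single subtype present the logrank test is skipped (p NaN,
    flagged) but the curve is still produced.
    """
    mask = np.isin(clinical.subtype, list(subtypes))
    sub = clinical.subset(mask)
    sd = sub.survival_data(horizon=horizon)
    curves = {}
    for s in subtypes:
        smask = sub.subtype == s
        if smask.any():
            curves[s] = stats.km_curve(sd.subset(smask))
    if len(curves) >= 2:
        present = np.isin(sub.subtype, list(curves))
        lr = stats.logrank(sub.subtype[present], sd.subset(present))
    else:
        lr = stats.TestResult(np.nan, np.nan, 0, len(sub), flag="single_group")
    return {"curves": curves, "logrank": lr}


def km_by_gene(
    m: ExpressionMatrix,
    probe: str,
    split,
    sd: SurvivalData,
) -> dict:
    """High/low expression survival curves for one probe with the logrank
    p and the binary-covariate Cox hazard ratio.

    ``split`` is either a signal threshold (high group = signal strictly
    above it) or an explicit boolean mask of high-group samples.
    """
    x = m.signals[m.probe_index(probe)]
    if np.isscalar(split):
        high = x > float(split)
    else:
        high = np.asarray(split, dtype=bool)
        if high.shape != x.shape:
            raise ValueError("split mask length mismatch")
    if high.all() or not high.any():
        raise ValueError("split does not yield two nonempty groups")
    lr = stats.logrank(high.astype(int), sd)
    cox = stats.cox_binary(high.astype(int), sd)
    return {
        "km_high": stats.km_curve(sd.subset(high)),
        "km_low": stats.km_curve(sd.subset(~high)),
        "logrank": lr,
        "cox": cox,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }
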