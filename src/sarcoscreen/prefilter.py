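"""The probe-reduction cascade and the two transforms feeding the screen.

The cascade runs in a fixed order, each stage a pure subset operation on
the probe axis:

1. drop control and cross-hybridizing probes (annotation flags),
2. drop probes absent in too many samples (MAS5 detection calls),
3. drop low-dynamic-range probes (95th minus 5th signal percentile),
4. keep only probes in the disease-knowledge map (OMIM-derived).

Surviving probes are then log2-transformed (for the subtype ANOVA) and
binarized at the per-probe median (for the survival logrank test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix, KnowledgeMap, ProbeAnnotation

FILTER_STAGES = ("control", "cross_hyb", "absent_call", "low_range", "not_in_knowledge")


@dataclass(frozen=True)
class FilterReport:
    """Per-stage removal counts plus the ordered list of surviving probes."""

    removed: dict
    probes_remaining: tuple

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def exclude_flagged(m: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Remove probes flagged as controls or cross-hybridizing.  Every probe
    must be annotated; survivor order is preserved."""
    is_control, is_cross = ann.flags(m.probe_ids)
    keep = ~(is_control | is_cross)
    if not keep.any():
        warnings.warn("all probes flagged; result is empty", stacklevel=2)
    return m.subset_probes(keep.tolist())


def absent_call_filter(
    m: ExpressionMatrix,
    max_absent_fraction: float = 0.5,
    strict: bool = False,
    marginal_absent: bool = False,
) -> ExpressionMatrix:
    """Remove probes undetectable in too many samples.

    A probe is removed when its fraction of Absent calls reaches
    ``max_absent_fraction`` (``>=`` by default, so 44 of 88 removes; pass
    ``strict=True`` for the ``>`` reading).  Marginal calls count as
    present unless ``marginal_absent``.  Without a calls matrix this is a
    no-op (all cells treated as Present).
    """
    if m.calls is None:
        return m
    absent = m.calls == "A"
    if marginal_absent:
        absent |= m.calls == "M"
    frac = absent.mean(axis=1)
    keep = frac < max_absent_fraction if not strict else frac <= max_absent_fraction
    return m.subset_probes(keep.tolist())


def percentile_interpolated(values: np.ndarray, pct: float) -> np.ndarray:
    """Percentile by linear interpolation between order statistics at
    fractional index ``(n-1) * pct / 100`` (the common statistical-software
    default)."""
    return np.percentile(values, pct, axis=-1, method="linear")


def range_filter(
    m: ExpressionMatrix,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    min_range: float = 2000.0,
    method: str = "linear",
) -> ExpressionMatrix:
    """Remove probes whose signal range (``hi_pct`` percentile minus
    ``lo_pct`` percentile across samples) is below ``min_range``; a range
    exactly at the threshold is kept.  ``method`` selects the percentile
    convention (``linear`` interpolation or ``nearest`` rank)."""
    if m.n_samples < 2:
        raise ValueError("range filter requires at least 2 samples")
    lo = np.percentile(m.signals, lo_pct, axis=1, method=method)
    hi = np.percentile(m.signals, hi_pct, axis=1, method=method)
    keep = (hi - lo) >= min_range
    return m.subset_probes(keep.tolist())


def knowledge_filter(m: ExpressionMatrix, km: KnowledgeMap) -> ExpressionMatrix:
    """Keep only probes present in the knowledge map."""
    if len(km.probe_ids) == 0:
        raise ValueError("knowledge map is empty")
    keep = [p in km.probe_ids for p in m.probe_ids]
    if not any(keep):
        warnings.warn("no probes overlap the knowledge map; result is empty",
                      stacklevel=2)
    return m.subset_probes(keep)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every signal by log2(signal + 1); the +1 offset keeps zero
    signals finite and preserves ordering."""
    return ExpressionMatrix(
        m.probe_ids, m.sample_ids, np.log2(m.signals + 1.0), m.calls
    )


def binarize_by_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per probe, 1 where the signal exceeds the probe's median across all
    supplied samples, else 0.  The even-n median is the mean of the two
    middle order statistics; values equal to the median go to the low
    group.  A probe with all values equal binarizes to all zeros and must
    be flagged as degenerate downstream."""
    if m.n_samples < 2:
        raise ValueError("binarization requires at least 2 samples")
    med = np.median(m.signals, axis=1, keepdims=True)
    return ExpressionMatrix(
        m.probe_ids, m.sample_ids, (m.signals > med).astype(float), m.calls
    )


def run_prefilter(
    m: ExpressionMatrix,
    ann: ProbeAnnotation,
    km: KnowledgeMap | None,
    max_absent_fraction: float = 0.5,
    absent_strict: bool = False,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    min_range: float = 2000.0,
    percentile_method: str = "linear",
) -> tuple[ExpressionMatrix, FilterReport]:
    """Run the fixed-order cascade and report per-stage removal counts.

    Passing ``km=None`` skips the knowledge stage (counted as removing 0).
    """
    removed = {}

    is_control, is_cross = ann.flags(m.probe_ids)
    after_control = m.subset_probes((~is_control).tolist())
    removed["control"] = m.n_probes - after_control.n_probes

    _, is_cross2 = ann.flags(after_control.probe_ids)
    after_cross = after_control.subset_probes((~is_cross2).tolist())
    removed["cross_hyb"] = after_control.n_probes - after_cross.n_probes

    after_absent = absent_call_filter(
        after_cross, max_absent_fraction, strict=absent_strict
    )
    removed["absent_call"] = after_cross.n_probes - after_absent.n_probes

    after_range = range_filter(
        after_absent, lo_pct, hi_pct, min_range, method=percentile_method
    )
    removed["low_range"] = after_absent.n_probes - after_range.n_probes

    if km is not None:
        final = knowledge_filter(after_range, km)
        removed["not_in_knowledge"] = after_range.n_probes - final.n_probes
    else:
        final = after_range
        removed["not_in_knowledge"] = 0

    return final, FilterReport(removed=removed, probes_remaining=final.probe_ids)
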