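"""Core containers and tabular I/O for the screening pipeline.

The pipeline operates on four kinds of tables:

* an expression signal matrix (probes x samples, MAS5-scaled signals, TSV)
  with an optional Present/Marginal/Absent detection-call matrix of the
  same shape,
* a clinical table (one row per patient: subtype, grade, metastasis,
  survival time, death event),
* a probe annotation table (control / cross-hybridization flags, gene
  symbol, accession, MIM numbers),
* a knowledge map linking disease-associated MIM identifiers to probe ids.

Matrices are tab-separated with probe rows and a header of sample ids; the
clinical table is comma-separated.  All files are UTF-8 and ids are never
quoted.  Booleans are accepted as ``{0, 1, true, false, yes, no}`` on read
and always written as ``{0, 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The seven histological subtypes of the sarcoma cohort.
SUBTYPES = ("UPS", "MLS", "SS", "MFS", "LMS", "FS", "MPNST")

#: Subtypes used for the discrimination (ANOVA) arm of the screen.
DISCRIMINATION_SUBTYPES = ("UPS", "MFS", "MLS", "SS")

#: Valid MAS5 detection-call symbols.
CALL_SYMBOLS = ("P", "M", "A")

#: Default censoring horizon in months for all survival analyses.
DEFAULT_CENSOR_HORIZON = 50.0

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


def parse_bool(value) -> bool:
    """Parse a permissive boolean token (``0/1/true/false/yes/no``)."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), []
        for i in ids:
            if i in seen:
                dup.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dup))[:5]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes x samples signal grid with optional MAS5 detection calls.

    Parameters
    ----------
    probe_ids, sample_ids
        Ordered, unique identifiers.
    signals
        Non-negative float array of shape ``(n_probes, n_samples)``;
        MAS5-scaled arbitrary units.
    calls
        Optional array of the same shape with entries in ``{P, M, A}``.
    """

    probe_ids: tuple
    sample_ids: tuple
    signals: np.ndarray
    calls: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "signals", sig)
        _check_unique(self.probe_ids, "probe ids")
        _check_unique(self.sample_ids, "sample ids")
        if sig.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"signal grid shape {sig.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if sig.size and np.nanmin(sig) < 0:
            i, j = np.argwhere(sig < 0)[0]
            raise ValueError(
                f"negative signal at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.calls is not None:
            calls = np.asarray(self.calls, dtype="U1")
            if calls.shape != sig.shape:
                raise ValueError(
                    f"calls shape {calls.shape} does not match signals {sig.shape}"
                )
            bad = ~np.isin(calls, CALL_SYMBOLS)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"unknown call symbol {calls[i, j]!r} at probe "
                    f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            object.__setattr__(self, "calls", calls)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"unknown probe id {probe_id!r}") from None

    def subset_probes(self, keep) -> "ExpressionMatrix":
        """Return a matrix restricted to ``keep`` (bool mask or probe ids),
        preserving the original probe order for masks and the requested
        order for explicit id lists."""
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            mask = np.asarray(keep, dtype=bool)
            if mask.size != self.n_probes:
                raise ValueError("boolean mask length mismatch")
            idx = np.flatnonzero(mask)
        else:
            idx = np.array([self.probe_index(p) for p in keep], dtype=int)
        return ExpressionMatrix(
            tuple(self.probe_ids[i] for i in idx),
            self.sample_ids,
            self.signals[idx],
            None if self.calls is None else self.calls[idx],
        )

    def subset_samples(self, keep) -> "ExpressionMatrix":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            mask = np.asarray(keep, dtype=bool)
            if mask.size != self.n_samples:
                raise ValueError("boolean mask length mismatch")
            idx = np.flatnonzero(mask)
        else:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([lookup[s] for s in keep], dtype=int)
        return ExpressionMatrix(
            self.probe_ids,
            tuple(self.sample_ids[i] for i in idx),
            self.signals[:, idx],
            None if self.calls is None else self.calls[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signals, index=list(self.probe_ids), columns=list(self.sample_ids)
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        if not np.array_equal(self.signals, other.signals):
            return False
        if (self.calls is None) != (other.calls is None):
            return False
        return self.calls is None or np.array_equal(self.calls, other.calls)


CLINICAL_COLUMNS = (
    "patient_id",
    "subtype",
    "gender",
    "age",
    "grade",
    "metastasis",
    "survival_time",
    "death_event",
)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient clinical records (subtype, grade, metastasis, survival).

    Wraps a validated :class:`pandas.DataFrame` with the eight canonical
    columns.  Subtype tokens are normalized to upper case and must come
    from the seven-value vocabulary; survival times are strictly positive.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required clinical column(s): {missing}")
        df = df[list(CLINICAL_COLUMNS)].reset_index(drop=True)
        df["patient_id"] = df["patient_id"].astype(str)
        _check_unique(list(df["patient_id"]), "patient ids")
        df["subtype"] = df["subtype"].astype(str).str.strip().str.upper()
        bad = sorted(set(df["subtype"]) - set(SUBTYPES))
        if bad:
            raise ValueError(f"unknown subtype token(s): {bad}")
        df["gender"] = df["gender"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["gender"]) - {"male", "female"})
        if bad:
            raise ValueError(f"unknown gender token(s): {bad}")
        df["age"] = df["age"].astype(float)
        df["grade"] = df["grade"].astype(int)
        if not df["grade"].isin([1, 2, 3]).all():
            raise ValueError("grade must be in {1, 2, 3}")
        df["metastasis"] = df["metastasis"].map(parse_bool)
        df["death_event"] = df["death_event"].map(parse_bool)
        df["survival_time"] = df["survival_time"].astype(float)
        if (df["survival_time"] <= 0).any():
            bad_ids = list(df.loc[df["survival_time"] <= 0, "patient_id"])
            raise ValueError(f"non-positive survival_time for patient(s) {bad_ids}")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> tuple:
        return tuple(self.df["patient_id"])

    @property
    def subtype(self) -> np.ndarray:
        return self.df["subtype"].to_numpy()

    @property
    def grade(self) -> np.ndarray:
        return self.df["grade"].to_numpy()

    @property
    def metastasis(self) -> np.ndarray:
        return self.df["metastasis"].to_numpy(dtype=bool)

    def survival_data(self, horizon: float | None = None) -> "SurvivalData":
        """Extract survival times/events, optionally applying a censoring
        horizon (see :func:`apply_censor_horizon`)."""
        sd = SurvivalData(
            times=self.df["survival_time"].to_numpy(dtype=float),
            events=self.df["death_event"].to_numpy(dtype=bool),
            censor_horizon=None,
        )
        if horizon is not None:
            sd = apply_censor_horizon(sd, horizon)
        return sd

    def subset(self, mask) -> "ClinicalTable":
        mask = np.asarray(mask, dtype=bool)
        return ClinicalTable(self.df.loc[mask].reset_index(drop=True))

    def reorder(self, patient_ids: Iterable[str]) -> "ClinicalTable":
        lookup = {p: i for i, p in enumerate(self.df["patient_id"])}
        idx = [lookup[str(p)] for p in patient_ids]
        return ClinicalTable(self.df.iloc[idx].reset_index(drop=True))


@dataclass(frozen=True)
class SurvivalData:
    """Paired survival times (months) and death indicators.

    ``censor_horizon`` records the horizon already applied (None if raw).
    """

    times: np.ndarray
    events: np.ndarray
    censor_horizon: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=bool)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if self.censor_horizon is not None and t.size and t.max() > self.censor_horizon:
            raise ValueError("time exceeds declared censor horizon")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, mask) -> "SurvivalData":
        mask = np.asarray(mask, dtype=bool)
        return SurvivalData(self.times[mask], self.events[mask], self.censor_horizon)


def apply_censor_horizon(sd: SurvivalData, horizon: float) -> SurvivalData:
    """Administratively censor all follow-up beyond ``horizon`` months.

    Times greater than the horizon become ``(horizon, event=False)``;
    times at or below the horizon are unchanged.  Idempotent; never
    increases any time or the number of events.
    """
    if horizon <= 0:
        raise ValueError("censor horizon must be positive")
    over = sd.times > horizon
    times = np.where(over, horizon, sd.times)
    events = np.where(over, False, sd.events)
    return SurvivalData(times, events, censor_horizon=float(horizon))


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe annotation: control / cross-hybridization flags, gene
    symbol, accession, and the list of MIM numbers mapped to the probe."""

    df: pd.DataFrame

    REQUIRED = ("probe_id", "is_control", "is_cross_hyb", "gene_symbol", "accession")

    def __post_init__(self):
        df = self.df.copy().reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing annotation column(s): {missing}")
        df["probe_id"] = df["probe_id"].astype(str)
        _check_unique(list(df["probe_id"]), "annotation probe ids")
        df["is_control"] = df["is_control"].map(parse_bool)
        df["is_cross_hyb"] = df["is_cross_hyb"].map(parse_bool)
        if "mim_numbers" not in df.columns:
            df["mim_numbers"] = [[] for _ in range(len(df))]
        else:
            df["mim_numbers"] = df["mim_numbers"].map(_parse_mim_cell)
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    def flags(self, probe_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (is_control, is_cross_hyb) masks aligned to ``probe_ids``;
        raises KeyError for unannotated probes."""
        indexed = self.df.set_index("probe_id")
        missing = [p for p in probe_ids if p not in indexed.index]
        if missing:
            raise KeyError(f"probe(s) missing from annotation: {missing[:5]}")
        sub = indexed.loc[list(probe_ids)]
        return (
            sub["is_control"].to_numpy(dtype=bool),
            sub["is_cross_hyb"].to_numpy(dtype=bool),
        )

    def gene_symbols(self, probe_ids: Sequence[str]) -> list:
        indexed = self.df.set_index("probe_id")["gene_symbol"]
        return [str(indexed.get(p, "")) for p in probe_ids]

    def accessions(self, probe_ids: Sequence[str]) -> list:
        indexed = self.df.set_index("probe_id")["accession"]
        return [str(indexed.get(p, "")) for p in probe_ids]


def _parse_mim_cell(cell) -> list:
    if isinstance(cell, (list, tuple)):
        return [str(x) for x in cell]
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    return [tok for tok in text.split(";") if tok] if text else []


@dataclass(frozen=True)
class KnowledgeMap:
    """Disease-keyword MIM accession set and the probe ids mapped from it."""

    mim_ids: frozenset
    probe_ids: frozenset

    def __post_init__(self):
        object.__setattr__(self, "mim_ids", frozenset(str(m) for m in self.mim_ids))
        object.__setattr__(self, "probe_ids", frozenset(str(p) for p in self.probe_ids))

    def __len__(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path_signals, path_calls=None) -> ExpressionMatrix:
    """Read a signal TSV (probe rows, sample-id header) and an optional
    detection-call TSV of identical shape."""
    sig = pd.read_csv(
        path_signals, sep="\t", index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    sig.index = sig.index.astype(str)
    calls = None
    if path_calls is not None:
        cdf = pd.read_csv(path_calls, sep="\t", index_col=0, dtype=str)
        cdf.index = cdf.index.astype(str)
        if list(cdf.index) != list(sig.index) or list(cdf.columns) != list(sig.columns):
            raise ValueError("calls file does not match signal file dimensions/ids")
        calls = cdf.to_numpy(dtype="U1")
    return ExpressionMatrix(
        tuple(sig.index), tuple(sig.columns), sig.to_numpy(dtype=float), calls
    )


def write_expression(m: ExpressionMatrix, path_signals, path_calls=None) -> None:
    m.to_frame().to_csv(path_signals, sep="\t", index_label="probe_id")
    if path_calls is not None:
        if m.calls is None:
            raise ValueError("matrix has no calls to write")
        pd.DataFrame(
            m.calls, index=list(m.probe_ids), columns=list(m.sample_ids)
        ).to_csv(path_calls, sep="\t", index_label="probe_id")


def read_clinical(path) -> ClinicalTable:
    """Read the clinical CSV with the eight named columns."""
    return ClinicalTable(pd.read_csv(path, dtype={"patient_id": str}))


def write_clinical(ct: ClinicalTable, path) -> None:
    out = ct.df.copy()
    out["metastasis"] = out["metastasis"].astype(int)
    out["death_event"] = out["death_event"].astype(int)
    out.to_csv(path, index=False)


def read_annotation(path) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(ann: ProbeAnnotation, path) -> None:
    out = ann.df.copy()
    out["is_control"] = out["is_control"].astype(int)
    out["is_cross_hyb"] = out["is_cross_hyb"].astype(int)
    out["mim_numbers"] = out["mim_numbers"].map(";".join)
    out.to_csv(path, sep="\t", index=False)


def read_knowledge_map(path) -> KnowledgeMap:
    """Read a TSV with columns ``mim_id`` and ``probe_id`` (one pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mim_id", "probe_id"):
        if col not in df.columns:
            raise ValueError(f"knowledge map missing column {col!r}")
    return KnowledgeMap(frozenset(df["mim_id"]), frozenset(df["probe_id"]))


def write_knowledge_map(km: KnowledgeMap, path, pairs=None) -> None:
    """Write the map.  If explicit (mim, probe) ``pairs`` are not given the
    cartesian structure is not recoverable, so each probe is written against
    a placeholder row per mim id only when pairs are supplied; otherwise
    probes are listed with an empty mim column."""
    if pairs is None:
        pairs = [("", p) for p in sorted(km.probe_ids)]
    df = pd.DataFrame(sorted(pairs), columns=["mim_id", "probe_id"])
    df.to_csv(path, sep="\t", index=False)
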