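"""Domain containers and tabular I/O.

Count matrices, signature tables, sample labels and per-sample haemolysis
reports are all small tab-separated files; pandas does the parsing and this
module enforces the domain invariants (integer non-negative counts, unique
canonical miRNA names, closed label vocabulary).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HAEMOLYSIS_LABELS = frozenset({"haemolysed", "non_haemolysed", "borderline", "unknown"})

#: RT-qPCR convention: dCq(miR-23a-3p minus miR-451a) below this is clear of
#: contamination, above is haemolysed, exactly at it is borderline.
DELTA_CQ_CUTOFF = 7.0


class InvalidNameError(ValueError):
    """Raised for miRNA names that cannot be canonicalized."""


class MatrixFormatError(ValueError):
    """Raised when a count-matrix file violates the format contract."""


_MIR_PREFIX = re.compile(r"^mir-", re.IGNORECASE)


def canonicalize_name(name: str) -> str:
    """Return the canonical spelling of a mature miRNA name.

    Strips a leading species prefix (``hsa-``), lowercases, and restores the
    conventional ``miR-`` capitalisation, so that ``hsa-miR-451a``,
    ``MIR-451A`` and ``miR-451a`` all map to ``miR-451a``.  Idempotent.
    """
    if name is None:
        raise InvalidNameError("miRNA name is None")
    cleaned = name.strip()
    if not cleaned:
        raise InvalidNameError("empty miRNA name")
    cleaned = cleaned.lower()
    while cleaned.startswith("hsa-"):
        cleaned = cleaned[4:]
    if not cleaned:
        raise InvalidNameError(f"nothing left of {name!r} after prefix removal")
    cleaned = _MIR_PREFIX.sub("miR-", cleaned)
    return cleaned


@dataclass
class CountMatrix:
    """Raw integer miRNA-by-sample count matrix.

    Rows are canonical mature miRNA names, columns are samples; counts are
    non-negative integers and ``library_sizes`` are the column sums.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise MatrixFormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise MatrixFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise MatrixFormatError(
                    "counts must be integers; fractional counts are rejected "
                    "rather than rounded"
                )
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise MatrixFormatError("counts must be non-negative")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise MatrixFormatError("duplicate miRNA identifiers after canonicalization")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MatrixFormatError("duplicate sample identifiers")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.mirna_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_mirnas(self, keep: np.ndarray | list) -> "CountMatrix":
        """Row-subset by boolean mask or list of miRNA names (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array([i for i, m in enumerate(self.mirna_ids) if m in wanted], dtype=int)
        return CountMatrix(
            [self.mirna_ids[i] for i in idx], list(self.sample_ids), self.counts[idx, :]
        )

    def subset_samples(self, keep: list[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in keep]
        return CountMatrix(list(self.mirna_ids), list(keep), self.counts[:, idx])


def read_count_matrix(source, sep: str | None = None) -> CountMatrix:
    """Read a miRNA-by-sample count table (TSV by default, CSV accepted).

    First column holds miRNA names (canonicalized on read), the header row
    holds sample identifiers.  Rows that collapse to the same canonical name
    are summed with a warning.  Fractional or negative counts are rejected.
    """
    if sep is None:
        sep = "," if str(source).endswith(".csv") else "\t"
    try:
        frame = pd.read_csv(source, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixFormatError(f"could not parse count table: {exc}") from exc
    if frame.shape[1] == 0:
        raise MatrixFormatError("count table has no sample columns")
    if frame.shape[0] == 0:
        raise MatrixFormatError("count table has no miRNA rows")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise MatrixFormatError("count table contains non-numeric cells")
    if np.any(~np.isfinite(values.astype(float))):
        raise MatrixFormatError("count table contains missing or non-finite cells")
    canonical = [canonicalize_name(str(m)) for m in frame.index]
    frame.index = canonical
    if len(set(canonical)) != len(canonical):
        dupes = sorted({m for m in canonical if canonical.count(m) > 1})
        logger.warning(
            "summing %d duplicate miRNA row(s) after canonicalization: %s",
            len(dupes), ", ".join(dupes),
        )
        frame = frame.groupby(level=0, sort=False).sum()
    matrix = CountMatrix.from_frame(frame)
    if matrix.counts.sum() == 0:
        raise MatrixFormatError("count table is all zero")
    return matrix


def write_count_matrix(matrix: CountMatrix, dest, sep: str = "\t") -> None:
    frame = matrix.to_frame()
    frame.index.name = "mirna"
    frame.to_csv(dest, sep=sep)


@dataclass
class SignatureTable:
    """Haemolysis signature miRNAs with the statistics that selected them.

    ``condition_associated`` flags entries that are also differentially
    abundant with respect to the study condition (e.g. pregnancy) and are
    therefore candidates for exclusion from the metric.
    """

    mirna_ids: list[str]
    log2fc: np.ndarray
    avg_expr: np.ndarray
    adj_p: np.ndarray
    condition_associated: np.ndarray

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.avg_expr = np.asarray(self.avg_expr, dtype=float)
        self.adj_p = np.asarray(self.adj_p, dtype=float)
        self.condition_associated = np.asarray(self.condition_associated, dtype=bool)
        n = len(self.mirna_ids)
        for name, arr in (
            ("log2fc", self.log2fc),
            ("avg_expr", self.avg_expr),
            ("adj_p", self.adj_p),
            ("condition_associated", self.condition_associated),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} length does not match {n} entries")
        if len(set(self.mirna_ids)) != n:
            raise ValueError("duplicate miRNA identifiers in signature table")
        if n and (np.any(self.adj_p < 0) or np.any(self.adj_p > 1)):
            raise ValueError("adjusted p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna": self.mirna_ids,
                "log2fc": self.log2fc,
                "avg_expr": self.avg_expr,
                "adj_p": self.adj_p,
                "condition_associated": self.condition_associated,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SignatureTable":
        cond = frame["condition_associated"]
        if cond.dtype == object:
            cond = cond.astype(str).str.strip().str.lower().map({"true": True, "false": False})
            if cond.isna().any():
                raise ValueError("condition_associated must be true/false")
        return cls(
            [canonicalize_name(str(m)) for m in frame["mirna"]],
            frame["log2fc"].to_numpy(dtype=float),
            frame["avg_expr"].to_numpy(dtype=float),
            frame["adj_p"].to_numpy(dtype=float),
            cond.to_numpy(dtype=bool),
        )

    @property
    def condition_associated_ids(self) -> list[str]:
        return [m for m, f in zip(self.mirna_ids, self.condition_associated) if f]


def read_signature_table(source) -> SignatureTable:
    frame = pd.read_csv(source, sep="\t")
    required = {"mirna", "log2fc", "avg_expr", "adj_p", "condition_associated"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"signature table missing columns: {sorted(missing)}")
    return SignatureTable.from_frame(frame)


def write_signature_table(sig: SignatureTable, dest) -> None:
    frame = sig.to_frame()
    frame["condition_associated"] = np.where(frame["condition_associated"], "true", "false")
    frame.to_csv(dest, sep="\t", index=False)


def load_bundled_signature() -> SignatureTable:
    """Load the packaged 20-miRNA plasma haemolysis signature.

    Ten of the twenty entries are flagged as pregnancy-associated; for
    pregnancy-cohort data those ten are the default exclusion set, leaving
    ten miRNAs for the metric.
    """
    ref = resources.files("hemosig").joinpath("data/haemolysis_signature.tsv")
    with ref.open("r", encoding="utf-8") as handle:
        return read_signature_table(handle)


def label_from_delta_cq(delta_cq: float, cutoff: float = DELTA_CQ_CUTOFF) -> str:
    """Map an RT-qPCR dCq value to a haemolysis label (< cutoff clear,
    > cutoff haemolysed, == cutoff borderline)."""
    if not np.isfinite(delta_cq):
        return "unknown"
    if delta_cq < cutoff:
        return "non_haemolysed"
    if delta_cq > cutoff:
        return "haemolysed"
    return "borderline"


@dataclass
class LabelTable:
    """Per-sample annotations: haemolysis status, optional condition/batch."""

    sample_ids: list[str]
    haemolysis_labels: list[str]
    condition_labels: list[str] | None = None
    batches: list[str] | None = None
    delta_cq: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        bad = set(self.haemolysis_labels) - HAEMOLYSIS_LABELS
        if bad:
            raise ValueError(
                f"haemolysis labels {sorted(bad)} not in {sorted(HAEMOLYSIS_LABELS)}"
            )
        for name, seq in (("haemolysis_labels", self.haemolysis_labels),
                          ("condition_labels", self.condition_labels),
                          ("batches", self.batches)):
            if seq is not None and len(seq) != n:
                raise ValueError(f"{name} length does not match {n} samples")
        if self.delta_cq is not None:
            self.delta_cq = np.asarray(self.delta_cq, dtype=float)
            if self.delta_cq.shape != (n,):
                raise ValueError("delta_cq length does not match samples")

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.haemolysis_labels) if l == label]

    def validate_against(self, matrix: CountMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"label table samples absent from count matrix: {sorted(missing)}")


def read_label_table(
    source,
    delta_cq_orientation: str = "23a_minus_451a",
    cutoff: float = DELTA_CQ_CUTOFF,
) -> LabelTable:
    """Read a sample label TSV.

    Accepts either an explicit ``haemolysis_label`` column or a ``delta_cq``
    column.  ``delta_cq_orientation`` documents which subtraction the assay
    used: ``"23a_minus_451a"`` (larger = more haemolysis, the cutoff
    convention) or ``"451a_minus_23a"`` (sign is flipped before applying the
    cutoff).
    """
    frame = pd.read_csv(source, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError("label table needs a sample_id column")
    if delta_cq_orientation not in {"23a_minus_451a", "451a_minus_23a"}:
        raise ValueError(f"unknown delta_cq orientation {delta_cq_orientation!r}")
    delta = None
    if "delta_cq" in frame.columns:
        delta = frame["delta_cq"].to_numpy(dtype=float)
        if delta_cq_orientation == "451a_minus_23a":
            delta = -delta
    if "haemolysis_label" in frame.columns:
        labels = [str(x).strip().lower() for x in frame["haemolysis_label"]]
    elif delta is not None:
        labels = [label_from_delta_cq(d, cutoff) for d in delta]
    else:
        raise ValueError("label table needs haemolysis_label or delta_cq")
    return LabelTable(
        [str(s) for s in frame["sample_id"]],
        labels,
        [str(c) for c in frame["condition"]] if "condition" in frame.columns else None,
        [str(b) for b in frame["batch"]] if "batch" in frame.columns else None,
        delta,
    )


_REPORT_COLUMNS = [
    "sample_id",
    "haemolysis_metric",
    "classification",
    "proxy_delta_cq",
    "n_signature_used",
    "n_background_used",
    "library_size",
    "n_detected_mirnas",
]


@dataclass
class HaemolysisReport:
    """Per-sample haemolysis assessment.

    ``classification`` is ``Caution`` (evidence of red-blood-cell
    contamination, metric at or above the threshold), ``Clear`` (none
    detected) or ``NA`` when the metric is undefined for that sample.
    ``proxy_delta_cq`` is NaN when either marker miRNA is undetected.
    """

    sample_ids: list[str]
    haemolysis_metric: np.ndarray
    classification: list[str]
    proxy_delta_cq: np.ndarray
    n_signature_used: np.ndarray
    n_background_used: np.ndarray
    library_size: np.ndarray
    n_detected_mirnas: np.ndarray
    threshold: float = 1.9
    messages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.haemolysis_metric = np.asarray(self.haemolysis_metric, dtype=float)
        self.proxy_delta_cq = np.asarray(self.proxy_delta_cq, dtype=float)
        self.n_signature_used = np.asarray(self.n_signature_used, dtype=int)
        self.n_background_used = np.asarray(self.n_background_used, dtype=int)
        self.library_size = np.asarray(self.library_size, dtype=np.int64)
        self.n_detected_mirnas = np.asarray(self.n_detected_mirnas, dtype=int)
        for name in ("haemolysis_metric", "proxy_delta_cq", "n_signature_used",
                     "n_background_used", "library_size", "n_detected_mirnas"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length does not match {n} samples")
        if len(self.classification) != n:
            raise ValueError("classification length does not match samples")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "haemolysis_metric": self.haemolysis_metric,
                "classification": self.classification,
                "proxy_delta_cq": self.proxy_delta_cq,
                "n_signature_used": self.n_signature_used,
                "n_background_used": self.n_background_used,
                "library_size": self.library_size,
                "n_detected_mirnas": self.n_detected_mirnas,
            }
        )


def write_report(report: HaemolysisReport, dest) -> None:
    """Write a haemolysis report as TSV, one row per sample."""
    frame = report.to_frame()
    frame.to_csv(dest, sep="\t", index=False, float_format="%.10g")


def read_report(source, threshold: float = 1.9) -> HaemolysisReport:
    frame = pd.read_csv(source, sep="\t", dtype={"sample_id": str})
    missing = set(_REPORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"report missing columns: {sorted(missing)}")
    if len(frame) == 0:
        return HaemolysisReport([], np.empty(0), [], np.empty(0), np.empty(0, int),
                                np.empty(0, int), np.empty(0, np.int64),
                                np.empty(0, int), threshold)
    return HaemolysisReport(
        [str(s) for s in frame["sample_id"]],
        frame["haemolysis_metric"].to_numpy(dtype=float),
        [str(c) for c in frame["classification"]],
        frame["proxy_delta_cq"].to_numpy(dtype=float),
        frame["n_signature_used"].to_numpy(dtype=int),
        frame["n_background_used"].to_numpy(dtype=int),
        frame["library_size"].to_numpy(dtype=np.int64),
        frame["n_detected_mirnas"].to_numpy(dtype=int),
        threshold,
    )
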