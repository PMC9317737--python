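"""Per-sample haemolysis scoring.

A sample's haemolysis metric is the geometric mean of its log2 CPM values
over the (possibly reduced) signature set of red-blood-cell-associated
miRNAs minus the geometric mean over the background set (every other
retained miRNA).  Contamination inflates the signature miRNAs relative to
the background, so larger metrics mean more evidence of haemolysis; samples
at or above the threshold (default 1.9) are flagged ``Caution``.

Any miRNA known to be differentially abundant with respect to the study
condition should be passed as an exclusion: it is removed from both the
signature and the background so the metric cannot be confounded with the
biology of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix, HaemolysisReport, SignatureTable, canonicalize_name
from .normalize import NormalizedMatrix, normalize_pipeline

logger = logging.getLogger(__name__)

#: Metric value at or above which a sample is classified Caution.
DEFAULT_THRESHOLD = 1.9

#: Sequencing proxy for the RT-qPCR haemolysis assay: RBC-abundant marker
#: minus plasma-stable control, so larger values mean more haemolysis.
PROXY_MARKER = "miR-451a"
PROXY_CONTROL = "miR-23a-3p"

CLEAR = "Clear"
CAUTION = "Caution"
NOT_AVAILABLE = "NA"


class SignatureCoverageError(ValueError):
    """Raised when too few signature miRNAs are usable in the matrix."""


class UndefinedMetricError(ValueError):
    """Raised when a sample has no usable signature or background values."""


@dataclass
class AssessConfig:
    """Tunable parameters of the assessment pipeline (defaults as published)."""

    min_count: int = 5
    min_cpm: float = 40.0
    prior: float = 0.5
    threshold: float = DEFAULT_THRESHOLD
    min_signature: int = 5
    exclude_mode: str = "both"  # "both" or "signature_only"
    metric_mode: str = "gm_log2cpm"  # or "mean_log2cpm"


@dataclass
class SignaturePartition:
    """Split of the matrix rows into signature, background and excluded."""

    signature_ids: list[str]
    background_ids: list[str]
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sig, bg, exc = map(set, (self.signature_ids, self.background_ids, self.excluded_ids))
        if sig & bg or sig & exc or bg & exc:
            raise ValueError("signature, background and excluded sets must be disjoint")

    @property
    def p1(self) -> int:
        return len(self.signature_ids)

    @property
    def p2(self) -> int:
        return len(self.background_ids)


def partition_signature(
    norm: NormalizedMatrix,
    sig: SignatureTable,
    exclude: set[str] | None = None,
    min_signature: int = 5,
    exclude_mode: str = "both",
) -> SignaturePartition:
    """Partition the matrix rows into signature and background sets.

    Excluded miRNAs are removed from both sets by default (``both``); the
    ``signature_only`` mode drops them from the signature but lets them stay
    in the background.  Errors when fewer than ``min_signature`` signature
    miRNAs remain usable.
    """
    if exclude_mode not in {"both", "signature_only"}:
        raise ValueError(f"unknown exclude_mode {exclude_mode!r}")
    exclude = {canonicalize_name(x) for x in (exclude or set())}
    sig_names = [canonicalize_name(m) for m in sig.mirna_ids]
    present = set(norm.mirna_ids)
    absent = [m for m in sig_names if m not in present]
    if absent:
        logger.warning(
            "%d signature miRNA(s) absent from the matrix: %s",
            len(absent), ", ".join(absent),
        )
    sig_set = set(sig_names)
    signature = [m for m in norm.mirna_ids if m in sig_set and m not in exclude]
    if exclude_mode == "both":
        background = [m for m in norm.mirna_ids if m not in sig_set and m not in exclude]
        excluded = [m for m in norm.mirna_ids if m in exclude]
    else:
        background = [m for m in norm.mirna_ids if m not in sig_set]
        excluded = [m for m in norm.mirna_ids if m in exclude and m in sig_set]
    if len(signature) < min_signature:
        raise SignatureCoverageError(
            f"signature coverage too low: {len(signature)} usable signature "
            f"miRNA(s), need at least {min_signature}"
        )
    if len(background) < 1:
        raise ValueError("background set is empty")
    return SignaturePartition(signature, background, excluded)


def geometric_mean(values: np.ndarray) -> float:
    """Geometric mean of strictly positive values, computed in log space."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("geometric mean of an empty set is undefined")
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        raise ValueError(
            "geometric mean needs strictly positive finite values; "
            "undetected cells must be excluded first"
        )
    return float(np.exp(np.mean(np.log(values))))


def haemolysis_metric(
    norm: NormalizedMatrix,
    part: SignaturePartition,
    sample: str,
    metric_mode: str = "gm_log2cpm",
) -> tuple[float, int, int]:
    """Haemolysis metric for one sample.

    Returns ``(metric, n_signature_used, n_background_used)``; only cells
    detected in the sample (positive floored count) enter either set.  In
    the default mode the summary is the geometric mean of the log2 CPM
    values themselves; ``mean_log2cpm`` uses the arithmetic mean of log2 CPM
    (equivalently the log2 geometric mean of CPM).
    """
    if metric_mode not in {"gm_log2cpm", "mean_log2cpm"}:
        raise ValueError(f"unknown metric_mode {metric_mode!r}")
    j = norm.sample_index(sample)
    row_index = {m: i for i, m in enumerate(norm.mirna_ids)}

    def usable(ids: list[str]) -> np.ndarray:
        rows = np.array([row_index[m] for m in ids], dtype=int)
        detected = norm.detected_mask[rows, j]
        return norm.log2cpm[rows[detected], j]

    sig_vals = usable(part.signature_ids)
    bg_vals = usable(part.background_ids)
    if sig_vals.size == 0:
        raise UndefinedMetricError(f"no detected signature miRNA in sample {sample!r}")
    if bg_vals.size == 0:
        raise UndefinedMetricError(f"no detected background miRNA in sample {sample!r}")
    if metric_mode == "gm_log2cpm":
        value = geometric_mean(sig_vals) - geometric_mean(bg_vals)
    else:
        value = float(np.mean(sig_vals) - np.mean(bg_vals))
    return value, int(sig_vals.size), int(bg_vals.size)


def classify(metric: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """``Caution`` iff the metric is at or above the threshold, else ``Clear``."""
    if not np.isfinite(metric):
        raise ValueError("metric must be finite")
    return CAUTION if metric >= threshold else CLEAR


def proxy_delta_cq(norm: NormalizedMatrix, sample: str) -> float:
    """Sequencing analogue of the RT-qPCR haemolysis assay.

    log2 CPM of miR-451a (red-blood-cell abundant) minus log2 CPM of
    miR-23a-3p (plasma stable); NaN when either marker is absent or
    undetected in the sample.
    """
    j = norm.sample_index(sample)
    try:
        a = norm.mirna_index(PROXY_MARKER)
        b = norm.mirna_index(PROXY_CONTROL)
    except KeyError:
        return float("nan")
    if not (norm.detected_mask[a, j] and norm.detected_mask[b, j]):
        return float("nan")
    return float(norm.log2cpm[a, j] - norm.log2cpm[b, j])


def assess(
    m: CountMatrix,
    sig: SignatureTable,
    exclude: set[str] | None = None,
    config: AssessConfig | None = None,
) -> HaemolysisReport:
    """End-to-end haemolysis assessment of a raw count matrix.

    Pipeline: floor low counts, abundance-filter over all samples, TMM,
    log2 CPM, signature/background partition, then per-sample metric,
    classification and proxy assay value.  Per-sample failures (no usable
    signature values) are recorded in the report rather than aborting the
    batch.
    """
    config = config or AssessConfig()
    floored_counts = np.where(m.counts < config.min_count, 0, m.counts)
    n_detected = (floored_counts > 0).sum(axis=0)
    norm = normalize_pipeline(
        m, min_count=config.min_count, min_cpm=config.min_cpm, prior=config.prior
    )
    part = partition_signature(
        norm, sig, exclude, config.min_signature, config.exclude_mode
    )
    metrics, labels, proxies, n_sig, n_bg = [], [], [], [], []
    messages = []
    for sample in m.sample_ids:
        try:
            value, p1_used, p2_used = haemolysis_metric(norm, part, sample, config.metric_mode)
            metrics.append(value)
            labels.append(classify(value, config.threshold))
            n_sig.append(p1_used)
            n_bg.append(p2_used)
        except UndefinedMetricError as exc:
            logger.warning("sample %s: %s", sample, exc)
            messages.append(f"{sample}: {exc}")
            metrics.append(float("nan"))
            labels.append(NOT_AVAILABLE)
            n_sig.append(0)
            n_bg.append(0)
        proxies.append(proxy_delta_cq(norm, sample))
    return HaemolysisReport(
        list(m.sample_ids),
        np.array(metrics),
        labels,
        np.array(proxies),
        np.array(n_sig),
        np.array(n_bg),
        m.library_sizes,
        n_detected,
        config.threshold,
        messages,
    )
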