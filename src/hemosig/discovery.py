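"""Signature discovery from a labelled count matrix.

Differential abundance between haemolysed and non-haemolysed samples is
tested per miRNA by ordinary least squares of log2 CPM on a group indicator
(plus optional sequencing-batch dummies), followed by empirical-Bayes
variance moderation (a hierarchical scaled-inverse-chi-square prior on the
residual variances, estimated by moment matching on the log variances) and
Benjamini-Hochberg FDR adjustment.  The signature is the intersection of
the top-k miRNAs by average abundance, the top-k by smallest adjusted
p-value, and those with log2 fold change strictly above the cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, LabelTable, SignatureTable
from .normalize import normalize_pipeline

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-miRNA differential-abundance statistics (group coefficient)."""

    mirna_ids: list[str]
    log2fc: np.ndarray
    avg_expr: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    residual_df: float
    sigma2: np.ndarray
    stdev_unscaled: float
    moderated_t: np.ndarray | None = None
    adj_p: np.ndarray | None = None
    prior_df: float | None = None
    prior_var: float | None = None

    def __len__(self) -> int:
        return len(self.mirna_ids)


@dataclass
class DiscoveryConfig:
    """Selection parameters; defaults reproduce the published pipeline."""

    min_count: int = 5
    min_cpm: float = 40.0
    prior: float = 0.5
    top_k: int = 60
    top_percent: float | None = None  # alternative to top_k: percent of miRNAs
    lfc_cut: float = 0.9
    fdr_cut: float = 0.05
    include_batch: bool = True
    include_borderline: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")
        if not 0 < self.fdr_cut < 1:
            raise ValueError("fdr_cut must be in (0, 1)")
        if self.top_percent is not None and not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")


def _design_matrix(
    group: np.ndarray, batches: list[str] | None
) -> tuple[np.ndarray, list[str]]:
    columns = [np.ones(group.size), group.astype(float)]
    names = ["intercept", "group"]
    if batches is not None:
        levels = sorted(set(batches))
        for level in levels[1:]:  # first level is the baseline
            columns.append(np.array([1.0 if b == level else 0.0 for b in batches]))
            names.append(f"batch[{level}]")
    return np.column_stack(columns), names


def fit_group_model(
    log2cpm: np.ndarray,
    mirna_ids: list[str],
    group: np.ndarray,
    batches: list[str] | None = None,
) -> DEResult:
    """Per-miRNA OLS of log2 CPM on a 0/1 group indicator (+ batch dummies).

    ``group`` is 1 for haemolysed samples, so the group coefficient is the
    log2 fold change haemolysed minus non-haemolysed.  The ordinary
    t-statistic and two-sided p-value use the residual degrees of freedom.
    """
    y = np.asarray(log2cpm, dtype=float)
    group = np.asarray(group)
    if y.shape[1] != group.size:
        raise ValueError("group labels must align with samples")
    x, names = _design_matrix(group, batches)
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns "
            f"{names}); group and batch are confounded"
        )
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom; need more samples")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x p
    resid = y - beta @ x.T
    sigma2 = (resid ** 2).sum(axis=1) / df
    unscaled = float(np.sqrt(xtx_inv[1, 1]))  # leverage term of the group column
    se = np.sqrt(sigma2) * unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, 1] / se, 0.0)
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    return DEResult(
        mirna_ids=list(mirna_ids),
        log2fc=beta[:, 1],
        avg_expr=y.mean(axis=1),
        t_stat=t,
        p_value=p_val,
        residual_df=float(df),
        sigma2=sigma2,
        stdev_unscaled=unscaled,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-inverse-chi-square prior to the variances.

    Works on log variances: with s^2 ~ s0^2 * F(df, d0), log s^2 has known
    digamma mean and trigamma variance, so the excess spread of the observed
    log variances over the trigamma(df/2) sampling term identifies d0 (the
    prior degrees of freedom) and the centre identifies s0^2.  When the
    observed spread does not exceed the sampling term, d0 is infinite and
    the prior variance is the mean variance.
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.sum((e - e_mean) ** 2) / (e.size - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var > 0:
        prior_df = 2.0 * _trigamma_inverse(e_var)
        prior_var = float(
            np.exp(e_mean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
        )
    else:
        prior_df = np.inf
        prior_var = float(np.mean(s2[ok]))
    return prior_df, prior_var


def ebayes_moderate(de: DEResult) -> DEResult:
    """Empirical-Bayes moderation of the per-miRNA t statistics.

    Posterior variance is the df-weighted blend of the observed residual
    variance and the estimated prior variance; the moderated t uses it with
    residual + prior degrees of freedom, and p-values are recomputed.
    """
    prior_df, prior_var = estimate_variance_prior(de.sigma2, de.residual_df)
    df = de.residual_df
    if np.isinf(prior_df):
        post_var = np.full_like(de.sigma2, prior_var)
        total_df = np.inf
    else:
        post_var = (prior_df * prior_var + df * de.sigma2) / (prior_df + df)
        total_df = df + prior_df
    coef = de.log2fc
    se = np.sqrt(post_var) * de.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, coef / se, 0.0)
    if np.isinf(total_df):
        p_val = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_val = 2.0 * stats.t.sf(np.abs(t_mod), total_df)
    return replace(
        de,
        moderated_t=t_mod,
        p_value=p_val,
        prior_df=prior_df,
        prior_var=prior_var,
    )


def moderate_with_prior(de: DEResult, prior_df: float, prior_var: float) -> DEResult:
    """Moderation with a fixed prior (prior_df = 0 recovers the ordinary t)."""
    df = de.residual_df
    post_var = (prior_df * prior_var + df * de.sigma2) / (prior_df + df)
    se = np.sqrt(post_var) * de.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, de.log2fc / se, 0.0)
    p_val = 2.0 * stats.t.sf(np.abs(t_mod), df + prior_df)
    return replace(de, moderated_t=t_mod, p_value=p_val, prior_df=prior_df, prior_var=prior_var)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at one."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _top_set(values: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Boolean mask of the k best entries, with closed ranks: ties at the
    k-th position are all included."""
    if k >= values.size:
        return np.ones(values.size, dtype=bool)
    ordered = np.sort(values)
    if largest:
        cut = ordered[values.size - k]
        return values >= cut
    cut = ordered[k - 1]
    return values <= cut


def select_signature(de: DEResult, cfg: DiscoveryConfig | None = None) -> SignatureTable:
    """Rank-intersection selection of the haemolysis signature.

    Candidates are the significantly elevated miRNAs (adjusted p below
    ``fdr_cut`` with positive log2 fold change); of these, a miRNA is
    selected when it is simultaneously in the top-k by average abundance,
    in the top-k by smallest adjusted p-value (both ranks computed over the
    full tested table, ties at the k-th position included), and above the
    strict log2 fold-change cut.  ``top_percent`` replaces the absolute k
    by a percentage of the tested miRNAs.
    """
    cfg = cfg or DiscoveryConfig()
    if de.adj_p is None:
        raise ValueError("run bh_adjust (and moderation) before selection")
    n = len(de)
    if n == 0:
        return SignatureTable([], np.empty(0), np.empty(0), np.empty(0), np.empty(0, bool))
    if cfg.top_percent is not None:
        k = max(1, int(np.ceil(cfg.top_percent / 100.0 * n)))
    else:
        k = cfg.top_k
    keep = (
        (de.adj_p < cfg.fdr_cut)
        & (de.log2fc > 0)
        & _top_set(de.avg_expr, k, largest=True)
        & _top_set(de.adj_p, k, largest=False)
        & (de.log2fc > cfg.lfc_cut)
    )
    if not np.any(keep):
        logger.warning("no miRNA satisfies all selection criteria; empty signature")
    idx = np.flatnonzero(keep)
    return SignatureTable(
        [de.mirna_ids[i] for i in idx],
        de.log2fc[idx],
        de.avg_expr[idx],
        de.adj_p[idx],
        np.zeros(idx.size, dtype=bool),
    )


def flag_condition_association(
    de_condition: DEResult,
    sig: SignatureTable,
    fdr_cut: float = 0.05,
) -> SignatureTable:
    """Flag signature entries differentially abundant w.r.t. the condition.

    ``de_condition`` must come from non-haemolysed samples only, so the
    condition contrast is not itself confounded by haemolysis.  Entries are
    flagged, never deleted: removal happens at partition time through the
    exclusion set.
    """
    if de_condition.adj_p is None:
        raise ValueError("condition DE result lacks adjusted p-values")
    cond_p = dict(zip(de_condition.mirna_ids, de_condition.adj_p))
    flags = []
    missing = []
    for name in sig.mirna_ids:
        if name in cond_p:
            flags.append(bool(cond_p[name] < fdr_cut))
        else:
            flags.append(False)
            missing.append(name)
    if missing:
        logger.warning(
            "condition DE is missing %d signature miRNA(s) (flags left false): %s",
            len(missing), ", ".join(missing),
        )
    return SignatureTable(
        list(sig.mirna_ids),
        sig.log2fc.copy(),
        sig.avg_expr.copy(),
        sig.adj_p.copy(),
        np.array(flags, dtype=bool),
    )


def _split_groups(labels: LabelTable, include_borderline: bool) -> tuple[list[str], list[str]]:
    haemolysed = labels.samples_with_label("haemolysed")
    clear = labels.samples_with_label("non_haemolysed")
    if include_borderline:
        haemolysed = haemolysed + labels.samples_with_label("borderline")
    return haemolysed, clear


def discover(
    m: CountMatrix,
    labels: LabelTable,
    cfg: DiscoveryConfig | None = None,
) -> SignatureTable:
    """Re-derive a haemolysis signature from a labelled count matrix.

    Pipeline: floor, abundance filter over the haemolysed group, TMM,
    log2 CPM, per-miRNA group model (+ batch), empirical-Bayes moderation,
    BH adjustment, rank-intersection selection; when condition labels are
    present, the condition contrast is fitted on non-haemolysed samples and
    used to flag condition-associated signature entries.
    """
    cfg = cfg or DiscoveryConfig()
    labels.validate_against(m)
    haemolysed, clear = _split_groups(labels, cfg.include_borderline)
    if len(haemolysed) < 2 or len(clear) < 2:
        raise ValueError(
            f"need at least 2 samples per group, got {len(haemolysed)} haemolysed "
            f"and {len(clear)} non-haemolysed"
        )
    used = haemolysed + clear
    sub = m.subset_samples(used)
    norm = normalize_pipeline(
        sub,
        min_count=cfg.min_count,
        min_cpm=cfg.min_cpm,
        group_samples=haemolysed,
        prior=cfg.prior,
    )
    group = np.array([1 if s in set(haemolysed) else 0 for s in used])
    label_pos = {s: i for i, s in enumerate(labels.sample_ids)}
    batches = None
    if cfg.include_batch and labels.batches is not None:
        batches = [labels.batches[label_pos[s]] for s in used]
        if len(set(batches)) < 2:
            batches = None
    de = fit_group_model(norm.log2cpm, norm.mirna_ids, group, batches)
    de = ebayes_moderate(de)
    de.adj_p = bh_adjust(de.p_value)
    sig = select_signature(de, cfg)
    if labels.condition_labels is not None and len(sig) > 0:
        conditions = [labels.condition_labels[label_pos[s]] for s in clear]
        if len(set(conditions)) == 2 and min(
            sum(c == lvl for c in conditions) for lvl in set(conditions)
        ) >= 2:
            clear_norm = normalize_pipeline(
                m.subset_samples(clear),
                min_count=cfg.min_count,
                min_cpm=cfg.min_cpm,
                prior=cfg.prior,
            )
            levels = sorted(set(conditions))
            cond_group = np.array([1 if c == levels[1] else 0 for c in conditions])
            cond_batches = None
            if cfg.include_batch and labels.batches is not None:
                cond_batches = [labels.batches[label_pos[s]] for s in clear]
                if len(set(cond_batches)) < 2:
                    cond_batches = None
            de_cond = fit_group_model(
                clear_norm.log2cpm, clear_norm.mirna_ids, cond_group, cond_batches
            )
            de_cond = ebayes_moderate(de_cond)
            de_cond.adj_p = bh_adjust(de_cond.p_value)
            sig = flag_condition_association(de_cond, sig, cfg.fdr_cut)
        else:
            logger.warning(
                "condition labels present but not a two-level contrast with >= 2 "
                "non-haemolysed samples per level; skipping condition flags"
            )
    return sig
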