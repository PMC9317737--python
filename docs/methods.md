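# Methods

## Model and assumptions

Haemolysis adds red-blood-cell (RBC) miRNA content to a plasma sample.
Because sequencing measures composition, not absolute amount, the
contamination has two coupled effects: RBC-associated miRNAs gain share and
every other species is diluted. The haemolysis metric exploits both sides
at once: it contrasts a signature set of RBC-associated miRNAs against the
background of all other retained miRNAs within the same sample, so it needs
no absolute calibration and is insensitive to sequencing depth.

For sample *i*, after normalization, the metric is

    metric_i = GM(Z_x,i | x in signature) - GM(Z_y,i | y in background)

where GM is the geometric mean and Z are log2 CPM values. The geometric
mean is taken of the log2 CPM values themselves (not of the CPM values);
the alternative reading — arithmetic mean of log2 CPM, equivalent to the
log of the geometric mean of CPM — is available as
`AssessConfig(metric_mode="mean_log2cpm")`. The literal form is the
default because the metric is computed only on abundant miRNAs (mean CPM
>= 40), where log2 CPM values are safely positive and the two readings are
monotonically related; the default keeps the published threshold
semantics. Cells undetected in a sample (zero floored count) are excluded
from both geometric means — the geometric mean is undefined at zero — and
the per-sample effective set sizes are reported (`n_signature_used`,
`n_background_used`).

Key assumptions:

- The signature miRNAs rise *as a group* under contamination. Single-miRNA
  anomalies (or condition effects on single members) move the geometric
  mean only weakly; this redundancy is the point of using 20 miRNAs rather
  than the two of the RT-qPCR assay.
- Between-sample comparability after TMM: the background set is assumed to
  be mostly unaffected by contamination, which holds when contamination is
  partial and the signature is a minority of the library.
- Condition-associated miRNAs are excluded from **both** sets
  (`exclude_mode="both"`, the default) so that neither the numerator nor
  the reference can carry the condition signal; a `signature_only` mode
  exists for users who explicitly want the wider background.

## Pipeline and parameters

Fixed order: floor -> abundance filter -> TMM -> log2 CPM -> partition ->
per-sample metric. The order matters: flooring feeds the filter, and the
filter determines the gene set on which TMM factors are computed.

| parameter | default | units | rationale |
|---|---|---|---|
| `min_count` | 5 | reads | cells with fewer reads are set to 0 per sample; removes alignment noise before CPM |
| `min_cpm` | 40 | CPM | a miRNA is kept iff its mean CPM over the filtering group is >= 40 (inclusive); in discovery the group is the haemolysed samples, in assessment all samples |
| TMM trims | 30% / 5% | — | double trimming on M- and A-values, the published defaults of the trimmed-mean-of-M-values estimator |
| `prior` | 0.5 | pseudo-reads | log2((y + prior)/(N' + 2·prior)·1e6) keeps zeros finite and reduces to plain log2 CPM at prior 0; N' is the TMM-adjusted library size |
| `threshold` | 1.9 | metric units | Caution iff metric >= 1.9 (boundary inclusive); the raw metric is always reported so users can re-threshold |
| `min_signature` | 5 | miRNAs | below this the signature geometric mean is too volatile; scoring errors out rather than report a fragile value |
| `top_k` / `top_percent` | 60 / off | miRNAs / % | selection rank cutoffs; the absolute-count reading is the default, the percent reading is provided as an alternative because both conventions appear in practice |
| `lfc_cut` | 0.9 | log2 | strict inequality: log2FC exactly 0.9 is excluded |
| `fdr_cut` | 0.05 | — | BH-adjusted significance for both candidate DE and condition flagging |

The filter uses the **mean** CPM over the designated group. "Low abundance
in the group" could also be read as median or as all-samples; mean is the
conventional reading and the group and threshold are configurable.

TMM follows the reference implementation of the estimator exactly
(reference column by the 0.75 count/library-size quantile closest to its
mean, ties to the first sample; M/A over miRNAs detected in both sample and
reference; precision weights from the asymptotic binomial variance; factors
rescaled to geometric mean 1; factor 1 with a warning for a sample sharing
no detected miRNA with the reference). The test suite checks it against
both an independent brute-force implementation and, where R is available,
edgeR's `calcNormFactors`.

## Differential abundance and selection

Per-miRNA ordinary least squares of log2 CPM on a 0/1 group indicator plus
optional batch dummies gives the log2 fold change (haemolysed minus
non-haemolysed) and residual variance. Variances are shrunk by an
empirical-Bayes hierarchical model: a scaled-inverse-chi-square prior whose
degrees of freedom d0 and scale s0² are estimated by moment matching on the
log residual variances (digamma/trigamma moment equations; the trigamma
inverse is solved by Newton iteration). The posterior variance
(d0·s0² + df·s²)/(d0 + df) yields a moderated t with df + d0 degrees of
freedom. When the observed spread of log variances does not exceed the
sampling term, d0 is infinite and all posterior variances collapse to the
common value (p-values then use the normal limit). At d0 = 0 the moderated
t is algebraically the ordinary t, which the tests assert. Under a null
simulation (2000 features, 6 vs 6) the moderated test holds its type-I
error at 0.05 within Monte-Carlo tolerance.

Selection takes the significantly elevated miRNAs (BH-adjusted p < 0.05
and log2FC > 0) and keeps those simultaneously in the top-k by average
log2 CPM, in the top-k by smallest adjusted p (ranks computed over the full
tested table; ties at the k-th position are all included, making selection
deterministic and monotone in k), and with log2FC strictly above 0.9. Only
positive fold changes can enter: haemolysis adds RBC material, it does not
remove plasma miRNA.

Labels may be given directly or as RT-qPCR ΔCq values; ΔCq < 7 maps to
non-haemolysed, > 7 to haemolysed and exactly 7 to borderline. Both ΔCq
subtraction orientations occur in practice, so ingestion takes an explicit
orientation flag instead of guessing. Borderline samples are excluded from
discovery groups by default (`include_borderline=True` pools them with the
haemolysed group). Condition flags are fitted on non-haemolysed samples
only, so the condition contrast is not itself confounded by haemolysis.

The sequencing proxy of the RT-qPCR assay is reported as
log2 CPM(miR-451a) − log2 CPM(miR-23a-3p), oriented so that larger values
mean more haemolysis, i.e. it correlates positively with the ΔCq
haemolysis scale. It is NaN (never silently zero) when either marker is
absent or undetected.

## Simulator

`simulate_counts` draws, per sample with contamination fraction pi,
expected proportions `(1 - pi)·plasma + pi·rbc` and negative-binomial
counts (gamma-Poisson, variance mu + 0.2·mu²) at a log-normal library size
centred on 3.49 million reads. The plasma profile is log-normal across 200
miRNAs; the RBC profile multiplies the 20-member enriched set (the bundled
signature names, padded with synthetic names if the universe grows) by
2^6 = 64 and renormalizes. Contamination is compositional by construction,
so the simulator reproduces both hallmarks of haemolysed libraries —
elevated RBC miRNAs and global dilution of everything else.

Default calibration, chosen once from the biology and the intended study
conditions:

- `log2_enrichment = 6` (64x in the pure RBC profile). Conservative
  relative to real RBC content, where miR-451a and miR-486-5p alone
  dominate the miRNA pool. After mixture dilution this yields observed
  case/control log2 fold changes of roughly 1.2–1.8 at contamination
  fractions 0.2–0.5, the range in which the published signature's fold
  changes (0.93–1.59) sit.
- `enriched_baseline_log2_boost = 1.0`. RBC-associated miRNAs are abundant
  in clean plasma too (the real signature's average expression spans
  7.2–13.0 log2 CPM, the upper part of the retained distribution). The
  boost reproduces that: clean samples sit at a positive baseline metric
  around 1.0–1.7, below the 1.9 threshold — as real clear samples do —
  and planted signature members occupy top abundance ranks, without which
  no rank-intersection selection could recover them.
- `baseline_logmean_sd = 0.4` (natural log). The simulated universe stands
  in for the abundant *retained* fraction of a plasma profile (the ~200
  miRNAs surviving the 40-CPM filter), not the full detected catalogue, so
  its spread is deliberately narrower than raw plasma dynamic range.
- `nb_dispersion = 0.2`, a typical biological coefficient of overdispersion
  for replicate libraries; one shared scalar for simplicity.

What the simulator does **not** emulate: batch effects, isomiR or
annotation ambiguity, the long tail of sub-filter miRNAs, library-prep
chemistry artefacts, and correlated (profile-level) biological variation
between individuals — each sample deviates from the common profile only by
negative-binomial noise. Passing the simulation-based tests therefore
demonstrates that the statistical machinery recovers a compositional RBC
admixture under realistic depth and dispersion; it does not certify
performance on cohorts whose background biology itself varies.

Test scenarios derived from it: a 50-sample cohort with fractions uniform
on [0, 0.3] for the metric-vs-truth correlation, and a 12-vs-30 cohort
(cases uniform on [0.2, 0.5], controls clean) for discovery recovery —
group sizes mirroring a typical plasma QC cohort where about one sample in
four is haemolysed.

## Numerical choices and degenerate inputs

- Geometric means are computed in log space; any non-positive input is an
  error by contract (callers must exclude undetected cells first).
- A sample with no detected signature miRNA gets metric NaN and
  classification `NA` in the report; the batch continues.
- Duplicate miRNA rows after name canonicalization are summed with a
  warning (they typically arise from species-prefix variants of one mature
  miRNA); fractional counts are rejected rather than rounded so CPM
  semantics stay exact.
- Name canonicalization strips `hsa-` prefixes (repeatedly) and normalizes
  case to the `miR-` convention; it is idempotent. isomiR-level or
  5p/3p-ambiguous identifiers are out of scope.
- Rank-deficient designs (e.g. batch perfectly confounded with group) fail
  with the offending columns named, rather than silently dropping terms.
- All-equal residual variances give an infinite prior df, not an error.
- Sample and miRNA input order is preserved end to end; outputs key by
  sample id, never by position.

## Known limitations

- The 1.9 threshold was calibrated on plasma cohorts of a specific library
  chemistry; for very different protocols users should inspect the metric
  distribution (the report always carries raw metrics) before trusting the
  boundary.
- The metric is relative within a sample: a cohort in which *every* sample
  is equally and heavily haemolysed shifts signature and background
  together less than an outlier does, so uniform contamination is harder
  to flag than sporadic contamination.
- Discovery needs at least two samples per group and honest labels; with
  ΔCq-derived labels the borderline band (exactly 7) is excluded by
  default.
- The moderated-t model treats log2 CPM as approximately normal per
  miRNA, which is adequate for ranking abundant miRNAs but is not an exact
  count model; no exact negative-binomial tests are provided.
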