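# hemosig

In silico haemolysis detection for plasma miRNA sequencing data.

## The problem

Cell-free microRNA in blood plasma is a popular source of minimally
invasive biomarkers, but red blood cells (RBCs) are packed with their own
miRNAs (miR-451a above all). If RBCs lyse during blood collection or
processing — haemolysis — their miRNA content spills into the plasma and
can masquerade as a disease signal. Wet-lab haemolysis assays (the RT-qPCR
ΔCq of miR-23a-3p vs. miR-451a, or A414 spectrophotometry) need the
physical specimen, which is unavailable for most public sequencing data.
`hemosig` detects haemolysis directly from the miRNA count matrix, so
archived and public datasets can be quality-controlled after the fact.

## The method

Counts are floored (cells with fewer than 5 reads are zeroed per sample),
low-abundance miRNAs are removed (mean CPM < 40), libraries are normalized
with TMM scale factors, and values are transformed to log2 CPM. The matrix
rows are then partitioned into a 20-miRNA **haemolysis signature** (RBC-
associated miRNAs, bundled with the package together with their selection
statistics) and the **background** of all other retained miRNAs. For sample
*i*, with Z<sub>x</sub> the signature log2 CPM values (x = 1..p1) and
Z<sub>y</sub> the background log2 CPM values (y = 1..p2), the haemolysis
metric is the difference of geometric means

&nbsp;&nbsp;&nbsp;&nbsp;metric&#8321; = (∏ₓ Z<sub>xi</sub>)<sup>1/p1</sup> − (∏ᵧ Z<sub>yi</sub>)<sup>1/p2</sup>

Samples with metric ≥ 1.9 are classified **Caution** (evidence of RBC
contamination; consider removing or down-weighting), all others **Clear**.
In a case/control study, any miRNA associated with the condition under
study is excluded from *both* sets before scoring, so the metric cannot be
confounded with the biology of interest; ten of the bundled signature
miRNAs carry a pregnancy-association flag for exactly this purpose. A
sequencing proxy of the RT-qPCR assay, log2 CPM(miR-451a) −
log2 CPM(miR-23a-3p), is reported alongside.

The package also re-derives signatures from labelled cohorts (per-miRNA
moderated-t differential abundance on log2 CPM with optional batch
covariates, Benjamini–Hochberg FDR, then the intersection of the top-60
miRNAs by abundance, the top-60 by adjusted p-value, and log2FC > 0.9) and
ships a negative-binomial simulator that plants known per-sample
contamination fractions so every stage can be validated without external
data.

## Worked example

```python
from hemosig import SimulationConfig, assess, load_bundled_signature, simulate_counts

signature = load_bundled_signature()           # 20 miRNAs, 10 flagged
matrix, truth = simulate_counts(SimulationConfig(seed=1))
report = assess(matrix, signature)
```

Running `python examples/assess_cohort.py` (which adds the comparison with
the planted truth) prints:

```
sample      metric  class    true_fraction
S009         2.801  Caution  0.286
S018         2.718  Caution  0.259
S019         2.679  Caution  0.294
S030         2.605  Caution  0.278
S017         2.592  Caution  0.234
...

29 of 50 samples flagged Caution (metric >= 1.9).
Spearman correlation between metric and true contamination: 0.947
```

The most contaminated samples receive the largest metrics and are flagged
Caution; across the cohort the metric tracks the true contamination
fraction almost monotonically. `examples/discover_signature.py` re-derives
a planted 20-miRNA signature from a labelled 12-vs-30 cohort (20/20
recovered, 0 false selections at seed 1), and
`examples/context_specific_exclusion.py` shows the condition-specific
reduction to 10 signature miRNAs. The same pipelines are available from the
shell:

```bash
hemosig simulate --seed 1 --n-samples 50 --out-prefix cohort
hemosig assess --counts cohort.counts.tsv --out report.tsv
hemosig discover --counts cohort.counts.tsv --labels labels.tsv --out signature.tsv
```

Every command writes a `.provenance.json` sidecar (tool version, resolved
parameters, input checksums) so results can be reproduced exactly.

## Layout

- `src/hemosig/io.py` — count-matrix / signature / label / report containers and TSV I/O; miRNA name canonicalization; the bundled signature.
- `src/hemosig/normalize.py` — count flooring, CPM abundance filter, TMM factors, log2 CPM.
- `src/hemosig/metric.py` — partitioning, geometric-mean metric, Clear/Caution classification, proxy ΔCq, the `assess` pipeline.
- `src/hemosig/discovery.py` — moderated-t differential abundance, BH adjustment, rank-intersection signature selection, condition flagging, the `discover` pipeline.
- `src/hemosig/simulate.py` — contamination simulator with ground truth.
- `src/hemosig/cli.py` — `hemosig assess | discover | simulate`.

See `docs/methods.md` for the model, parameter rationale and limitations.
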