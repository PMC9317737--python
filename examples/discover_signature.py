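"""Re-derive a haemolysis signature from a labelled cohort.

Builds a case/control cohort (12 contaminated, 30 clean samples) with a
known planted RBC-enriched miRNA set, runs the discovery pipeline
(floor -> CPM filter -> TMM -> log2 CPM -> moderated t -> BH ->
rank-intersection selection), and checks the selection against the truth.
"""

from hemosig import discover
from hemosig.simulate import discovery_scenario

matrix, labels, truth = discovery_scenario(seed=1)
signature = discover(matrix, labels)

print("selected miRNA       log2FC  avg log2CPM   adj p")
for i, name in enumerate(signature.mirna_ids):
    print(
        f"{name:<18} {signature.log2fc[i]:7.3f}  {signature.avg_expr[i]:11.3f}  "
        f"{signature.adj_p[i]:.2e}"
    )

planted = set(truth.enriched_set)
recovered = planted & set(signature.mirna_ids)
print(f"\nrecovered {len(recovered)} of {len(planted)} planted RBC-enriched miRNAs;")
print(f"{len(set(signature.mirna_ids) - planted)} false selections.")
print(
    "Each selected miRNA is significantly elevated in the haemolysed group\n"
    "(FDR < 0.05), has log2FC > 0.9, and ranks in the top 60 by both\n"
    "abundance and adjusted p-value."
)
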