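"""FDR/TPR evaluation of gene-level screening against simulated truth.

Runs the DM path on a mixed simulation and reports observed FDR and TPR at
the 1%, 5% and 10% nominal thresholds, plus the false-positive breakdown by
simulated gene category.
"""

import pandas as pd

from dtukit import SimParams, simulate_experiment
from dtukit.dm_dtu import adjust_bh, sanitize_pvalues
from dtukit.evaluate import fdr_tpr, fp_breakdown
from dtukit.filters import dm_style_filter
from dtukit.pipeline import build_dtu_dataset, default_filter_config, run_dm_path

params = SimParams(n_genes=400, n_per_group=6, seed=5)
truth, quant, _, samples = simulate_experiment(params)
t2g = pd.DataFrame({"transcript_id": truth.transcript_ids, "gene_id": truth.gene_ids})
ds = dm_style_filter(
    build_dtu_dataset(quant, t2g, samples, "scaledTPM"), default_filter_config(samples)
)

res, _, _ = run_dm_path(ds, seed=5)
adj = adjust_bh(sanitize_pvalues(res.gene["pvalue"]))
is_dtu = res.gene["gene_id"].map(lambda g: bool(truth.gene_dtu.get(g, False))).to_numpy()

table = fdr_tpr(adj, is_dtu)
print("gene-level screening against the usage truth:")
print(table.to_string(index=False))

cats = res.gene["gene_id"].map(truth.gene_label).to_numpy()
print("\nfalse-positive breakdown by simulated gene category (5% threshold):")
print(fp_breakdown(adj <= 0.05, is_dtu, cats).to_string(index=False))
# observed FDR near its nominal target and TPR rising with the threshold is
# the expected profile; false positives should not concentrate in any one
# simulated category
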