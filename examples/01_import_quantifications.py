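"""Import Salmon-format quantifications and derive counts from abundance.

Builds a small simulated experiment, writes per-sample quant.sf files,
reads them back, and compares the three counts-from-abundance modes.
"""

import tempfile

import numpy as np

from dtukit import SimParams, counts_from_abundance, read_salmon_quant, simulate_experiment
from dtukit.simulate import write_quant_files

params = SimParams(n_genes=50, n_per_group=3, seed=1)
truth, quant, _, samples = simulate_experiment(params)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_quant_files(quant, tmp)
    q = read_salmon_quant(paths)

print(f"{q.n_transcripts} transcripts x {q.n_samples} samples")
print("TPM column sums (per million):", np.round(q.tpm.sum(axis=0) / 1e6, 6))

for mode in ("raw", "scaledTPM", "lengthScaledTPM"):
    cm = counts_from_abundance(q, mode)
    print(f"{mode:>17}: first column sum = {cm.counts[:, 0].sum():.1f}")

# scaledTPM columns sum to the mapped-read total of each library, and the
# counts no longer scale with transcript length within a gene - this is the
# recommended input for differential transcript usage testing.
print("mapped reads, sample 1:", q.est_reads[:, 0].sum().round(1))
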