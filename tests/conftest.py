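import numpy as np
import pandas as pd
import pytest

from dtukit.filters import DTUDataset
from dtukit.quant_io import TranscriptQuantSet


def make_quant(tpm, eff_length, est_reads, length=None, tx_prefix="T", sample_prefix="s"):
    """Assemble a TranscriptQuantSet from raw arrays."""
    tpm = np.asarray(tpm, dtype=float)
    n_tx, n_s = tpm.shape
    if length is None:
        length = np.full(n_tx, 1000)
    return TranscriptQuantSet(
        transcript_ids=[f"{tx_prefix}{i+1}" for i in range(n_tx)],
        sample_ids=[f"{sample_prefix}{j+1}" for j in range(n_s)],
        tpm=tpm,
        eff_length=np.asarray(eff_length, dtype=float),
        est_reads=np.asarray(est_reads, dtype=float),
        length=np.asarray(length),
    )


def make_dataset(gene_ids, counts, conditions):
    """Assemble a DTUDataset with auto-generated transcript ids."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    counts = np.asarray(counts, dtype=float)
    seen = {}
    tx_ids = []
    for g in gene_ids:
        seen[g] = seen.get(g, 0) + 1
        tx_ids.append(f"{g}.T{seen[g]}")
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j+1}" for j in range(counts.shape[1])],
            "condition": [str(c) for c in conditions],
        }
    )
    return DTUDataset(gene_ids, np.array(tx_ids, dtype=object), counts, samples)


def sample_dm_counts(rng, pi, gamma, totals):
    """Draw Dirichlet-multinomial counts: one row per sample."""
    out = np.empty((len(totals), len(pi)), dtype=float)
    for i, n in enumerate(totals):
        p = rng.dirichlet(gamma * np.asarray(pi))
        out[i] = rng.multinomial(int(n), p)
    return out


TINY_GTF = """\
chr1\thavana\tgene\t100\t5000\t.\t+\t.\tgene_id "ENSG00000000001.14";
chr1\thavana\ttranscript\t100\t5000\t.\t+\t.\tgene_id "ENSG00000000001.14"; transcript_id "ENST00000000001.4";
chr1\thavana\texon\t100\t900\t.\t+\t.\tgene_id "ENSG00000000001.14"; transcript_id "ENST00000000001.4";
chr1\thavana\ttranscript\t100\t4000\t.\t+\t.\tgene_id "ENSG00000000001.14"; transcript_id "ENST00000000002.1";
chr1\thavana\texon\t100\t800\t.\t+\t.\tgene_id "ENSG00000000001.14"; transcript_id "ENST00000000002.1";
chr2\thavana\tgene\t200\t9000\t.\t-\t.\tgene_id "ENSG00000000002.5";
chr2\thavana\ttranscript\t200\t9000\t.\t-\t.\tgene_id "ENSG00000000002.5"; transcript_id "ENST00000000003.2";
chr2\thavana\texon\t200\t700\t.\t-\t.\tgene_id "ENSG00000000002.5"; transcript_id "ENST00000000003.2";
"""


@pytest.fixture
def tiny_gtf(tmp_path):
    path = tmp_path / "tiny.gtf"
    path.write_text(TINY_GTF)
    return str(path)
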