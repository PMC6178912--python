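import numpy as np
import pandas as pd
import pytest

from dtukit import quant_io
from dtukit.quant_io import (
    QuantConsistencyError,
    QuantFormatError,
    build_tx2gene,
    counts_from_abundance,
    read_salmon_quant,
    summarize_to_gene,
)

from conftest import make_quant


def _write_quant(path, rows):
    with open(path, "w") as fh:
        fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


ROWS_A = [("T1", 1000, 800.0, 500000.0, 40.0), ("T2", 500, 300.0, 300000.0, 9.0), ("T3", 2000, 1800.0, 200000.0, 36.0)]
ROWS_B = [("T1", 1000, 810.0, 250000.0, 21.0), ("T2", 500, 290.0, 250000.0, 7.5), ("T3", 2000, 1750.0, 500000.0, 90.0)]


class TestReadSalmonQuant:
    def test_two_files_in_order(self, tmp_path):
        pa, pb = tmp_path / "a.sf", tmp_path / "b.sf"
        _write_quant(pa, ROWS_A)
        _write_quant(pb, ROWS_B)
        q = read_salmon_quant({"sA": str(pa), "sB": str(pb)})
        assert q.transcript_ids == ["T1", "T2", "T3"]
        assert q.sample_ids == ["sA", "sB"]
        np.testing.assert_allclose(q.tpm[:, 0], [500000, 300000, 200000])
        np.testing.assert_allclose(q.est_reads[:, 1], [21.0, 7.5, 90.0])

    def test_reordered_file_realigned_by_name(self, tmp_path):
        pa, pb = tmp_path / "a.sf", tmp_path / "b.sf"
        _write_quant(pa, ROWS_A)
        _write_quant(pb, [ROWS_B[2], ROWS_B[0], ROWS_B[1]])
        q = read_salmon_quant({"sA": str(pa), "sB": str(pb)})
        # per-cell lookup oracle: every value indexed by (Name, sample)
        oracle = {("sA", r[0]): r for r in ROWS_A} | {("sB", r[0]): r for r in ROWS_B}
        for j, sid in enumerate(q.sample_ids):
            for i, tx in enumerate(q.transcript_ids):
                assert q.eff_length[i, j] == oracle[(sid, tx)][2]
                assert q.tpm[i, j] == oracle[(sid, tx)][3]
                assert q.est_reads[i, j] == oracle[(sid, tx)][4]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.sf"
        p.write_text("Name\tLength\tEffectiveLength\tNumReads\nT1\t100\t80\t5\n")
        with pytest.raises(QuantFormatError, match="TPM"):
            read_salmon_quant({"s1": str(p)})

    def test_differing_transcript_sets_rejected(self, tmp_path):
        pa, pb = tmp_path / "a.sf", tmp_path / "b.sf"
        _write_quant(pa, ROWS_A)
        _write_quant(pb, ROWS_B[:2])
        with pytest.raises(QuantConsistencyError):
            read_salmon_quant({"sA": str(pa), "sB": str(pb)})

    def test_nonpositive_effective_length_rejected(self, tmp_path):
        p = tmp_path / "a.sf"
        _write_quant(p, [("T1", 100, 0.0, 1e6, 5.0)])
        with pytest.raises(ValueError, match="EffectiveLength"):
            read_salmon_quant({"s1": str(p)})


class TestBuildTx2Gene:
    def test_fixture_gtf(self, tiny_gtf):
        t2g = build_tx2gene(tiny_gtf)
        assert list(t2g["transcript_id"]) == [
            "ENST00000000001.4", "ENST00000000002.1", "ENST00000000003.2",
        ]
        assert list(t2g["gene_id"]) == [
            "ENSG00000000001.14", "ENSG00000000001.14", "ENSG00000000002.5",
        ]
        assert list(t2g["ntx"]) == [2, 2, 1]

    def test_version_suffixes_retained(self, tiny_gtf):
        t2g = build_tx2gene(tiny_gtf)
        assert all("." in t for t in t2g["transcript_id"])
        assert all("." in g for g in t2g["gene_id"])

    def test_transcript_under_two_genes_rejected(self, tmp_path):
        gtf = tmp_path / "dup.gtf"
        gtf.write_text(
            'chr1\tx\ttranscript\t1\t10\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr1\tx\ttranscript\t1\t10\t.\t+\t.\tgene_id "G2"; transcript_id "T1";\n'
        )
        with pytest.raises(QuantConsistencyError, match="two genes"):
            build_tx2gene(str(gtf))


class TestCountsFromAbundance:
    def test_single_transcript_scaled_equals_mapped_total(self):
        q = make_quant([[1e6, 1e6]], [[100, 100]], [[55.0, 70.0]])
        cm = counts_from_abundance(q, "scaledTPM")
        np.testing.assert_allclose(cm.counts[0], [55.0, 70.0])

    def test_proportional_scaling(self):
        q = make_quant([[750000.0], [250000.0]], [[100], [100]], [[600.0], [400.0]])
        cm = counts_from_abundance(q, "scaledTPM")
        np.testing.assert_allclose(cm.counts[:, 0], [750.0, 250.0])

    def test_equal_mean_efflen_makes_modes_agree(self):
        tpm = [[4e5, 3e5], [6e5, 7e5]]
        q = make_quant(tpm, [[200, 200], [200, 200]], [[80, 30], [120, 70]])
        a = counts_from_abundance(q, "scaledTPM")
        b = counts_from_abundance(q, "lengthScaledTPM")
        np.testing.assert_allclose(a.counts, b.counts)

    def test_cellwise_oracle_three_tx_two_samples(self):
        tpm = np.array([[5e5, 2e5], [3e5, 3e5], [2e5, 5e5]])
        el = np.array([[100.0, 120.0], [400.0, 380.0], [1000.0, 900.0]])
        reads = np.array([[50.0, 21.0], [120.0, 100.0], [200.0, 390.0]])
        q = make_quant(tpm, el, reads)
        # spreadsheet-style oracle applying the formulas cell by cell
        R = reads.sum(axis=0)
        expect_s = np.empty_like(tpm)
        for j in range(2):
            for i in range(3):
                expect_s[i, j] = tpm[i, j] / tpm[:, j].sum() * R[j]
        mean_el = el.mean(axis=1)
        scaled = tpm * mean_el[:, None]
        expect_l = np.empty_like(tpm)
        for j in range(2):
            for i in range(3):
                expect_l[i, j] = scaled[i, j] / scaled[:, j].sum() * R[j]
        np.testing.assert_allclose(counts_from_abundance(q, "scaledTPM").counts, expect_s, rtol=1e-12)
        np.testing.assert_allclose(counts_from_abundance(q, "lengthScaledTPM").counts, expect_l, rtol=1e-12)

    def test_zero_tpm_sample_rejected(self):
        q = make_quant([[0.0, 1e6]], [[100, 100]], [[0.0, 10.0]])
        with pytest.raises(ValueError, match="zero total TPM"):
            counts_from_abundance(q, "scaledTPM")

    def test_column_sums_match_mapped_reads(self):
        rng = np.random.default_rng(0)
        tpm = rng.uniform(0, 1, (20, 4))
        tpm = tpm / tpm.sum(axis=0) * 1e6
        q = make_quant(tpm, rng.uniform(100, 2000, (20, 4)), rng.uniform(0, 500, (20, 4)))
        for mode in ("scaledTPM", "lengthScaledTPM"):
            cm = counts_from_abundance(q, mode)
            np.testing.assert_allclose(cm.counts.sum(axis=0), q.est_reads.sum(axis=0), rtol=1e-9)

    def test_raw_mode_is_identity_on_nonzero_rows(self):
        reads = np.array([[5.0, 2.0], [0.0, 0.0], [7.0, 1.0]])
        q = make_quant([[4e5] * 2, [0e5] * 2, [6e5] * 2], np.full((3, 2), 100.0), reads)
        cm = counts_from_abundance(q, "raw")
        assert cm.row_ids == ["T1", "T3"]
        np.testing.assert_array_equal(cm.counts, reads[[0, 2]])


class TestSummarizeToGene:
    t2g = pd.DataFrame(
        {"transcript_id": ["T1", "T2", "T3"], "gene_id": ["G1", "G1", "G2"], "ntx": [2, 2, 1]}
    )

    def test_single_transcript_gene(self):
        q = make_quant([[1e5, 2e5], [4e5, 3e5], [5e5, 5e5]],
                       [[100, 110], [300, 310], [700, 650]],
                       [[10, 20], [40, 30], [50, 50]])
        cm = summarize_to_gene(q, self.t2g, "raw")
        i = cm.row_ids.index("G2")
        np.testing.assert_allclose(cm.counts[i], [50, 50])
        np.testing.assert_allclose(cm.offsets[i], [700, 650])

    def test_equal_tpm_offset_is_plain_mean(self):
        q = make_quant([[5e5, 5e5], [5e5, 5e5]], [[100, 100], [300, 300]], [[10, 10], [30, 30]])
        t2g = pd.DataFrame({"transcript_id": ["T1", "T2"], "gene_id": ["G1", "G1"], "ntx": [2, 2]})
        cm = summarize_to_gene(q, t2g, "raw")
        np.testing.assert_allclose(cm.offsets[0], [200.0, 200.0])

    def test_weighted_mean_oracle_and_mass_conservation(self):
        rng = np.random.default_rng(1)
        tpm = rng.uniform(0, 1, (3, 2))
        tpm = tpm / tpm.sum(axis=0) * 1e6
        el = rng.uniform(100, 1000, (3, 2))
        reads = rng.uniform(1, 100, (3, 2))
        q = make_quant(tpm, el, reads)
        cm = summarize_to_gene(q, self.t2g, "raw")
        g1 = cm.row_ids.index("G1")
        for j in range(2):
            w = tpm[:2, j] / tpm[:2, j].sum()
            assert cm.offsets[g1, j] == pytest.approx(np.sum(w * el[:2, j]))
        np.testing.assert_allclose(cm.counts.sum(axis=0), reads.sum(axis=0), rtol=1e-12)

    def test_zero_tpm_gene_falls_back_to_plain_mean(self):
        q = make_quant([[0.0, 5e5], [0.0, 5e5], [1e6, 0.0]],
                       [[100, 100], [300, 300], [500, 500]],
                       [[0, 10], [0, 30], [90, 0]])
        cm = summarize_to_gene(q, self.t2g, "raw")
        assert cm.offsets[cm.row_ids.index("G1"), 0] == pytest.approx(200.0)

    def test_unmapped_transcript_rejected(self):
        q = make_quant([[1e6]], [[100]], [[5]])
        bad = pd.DataFrame({"transcript_id": ["X9"], "gene_id": ["G1"], "ntx": [1]})
        with pytest.raises(QuantConsistencyError, match="T1"):
            summarize_to_gene(q, bad, "raw")

    def test_scaled_mode_conserves_mass(self):
        rng = np.random.default_rng(2)
        tpm = rng.uniform(0.1, 1, (3, 2))
        tpm = tpm / tpm.sum(axis=0) * 1e6
        q = make_quant(tpm, rng.uniform(100, 1000, (3, 2)), rng.uniform(1, 100, (3, 2)))
        cm = summarize_to_gene(q, self.t2g, "scaledTPM")
        tx = counts_from_abundance(q, "scaledTPM")
        np.testing.assert_allclose(cm.counts.sum(axis=0), tx.counts.sum(axis=0), rtol=1e-12)
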