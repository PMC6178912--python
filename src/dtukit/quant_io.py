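"""Import of Salmon-format quantifications and transcript-to-gene maps.

Salmon writes one ``quant.sf`` table per sample with the estimated relative
abundance (TPM), effective length and estimated fragment count for every
annotated transcript.  This module assembles those per-sample tables into
matrices, derives "counts from abundance" on the scale expected by the
downstream usage tests, and summarizes to the gene level with
average-transcript-length offsets for gene-expression analysis.

Counts-from-abundance modes
---------------------------
``raw``
    The estimated fragment counts as written by the quantifier.  Fragment
    counts scale with transcript length, so for gene-level analysis they
    should be paired with the average-transcript-length offsets produced by
    :func:`summarize_to_gene`.
``scaledTPM``
    TPM rescaled per sample so each column sums to that sample's total
    mapped reads.  These counts do *not* scale with transcript length within
    a gene, which is why they are the recommended input for differential
    transcript usage.
``lengthScaledTPM``
    TPM first multiplied by the across-sample mean effective length of the
    transcript, then rescaled per sample as above.  Appropriate for
    gene-level analysis without offsets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptQuantSet",
    "CountMatrix",
    "QuantFormatError",
    "QuantConsistencyError",
    "read_salmon_quant",
    "build_tx2gene",
    "counts_from_abundance",
    "summarize_to_gene",
]

SALMON_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]

COUNT_MODES = ("raw", "scaledTPM", "lengthScaledTPM")


class QuantFormatError(ValueError):
    """A quantification or annotation file does not match the expected format."""


class QuantConsistencyError(ValueError):
    """Per-sample inputs disagree with one another (e.g. transcript sets differ)."""


@dataclass
class TranscriptQuantSet:
    """Per-transcript, per-sample quantification matrices.

    All matrices are ``[transcripts x samples]`` and share identical row and
    column ordering.  TPM columns sum to 1e6 (up to quantifier rounding).
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    tpm: np.ndarray
    eff_length: np.ndarray
    est_reads: np.ndarray
    length: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        self.eff_length = np.asarray(self.eff_length, dtype=float)
        self.est_reads = np.asarray(self.est_reads, dtype=float)
        self.length = np.asarray(self.length)
        shape = (len(self.transcript_ids), len(self.sample_ids))
        for name in ("tpm", "eff_length", "est_reads"):
            if getattr(self, name).shape != shape:
                raise QuantConsistencyError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise QuantConsistencyError("transcript_ids are not unique")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class CountMatrix:
    """A transcript- or gene-level count matrix.

    ``offsets`` (gene level only, mode ``raw``) holds the abundance-weighted
    average transcript length per gene and sample, the statistical offset for
    count-based gene-expression models.
    """

    row_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    mode: str
    offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.mode not in COUNT_MODES:
            raise ValueError(f"unknown counts-from-abundance mode {self.mode!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_ids, columns=self.sample_ids)


def _read_one_quant(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SALMON_COLUMNS if c not in df.columns]
    if missing:
        raise QuantFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if (df["EffectiveLength"] <= 0).any():
        bad = df.loc[df["EffectiveLength"] <= 0, "Name"].iloc[0]
        raise ValueError(f"{path}: non-positive EffectiveLength (e.g. {bad})")
    return df


def read_salmon_quant(paths: dict[str, str]) -> TranscriptQuantSet:
    """Read Salmon ``quant.sf`` files, one per sample, into aligned matrices.

    Parameters
    ----------
    paths
        Mapping from sample id to ``quant.sf`` path.  Row order of the result
        follows the first file; later files may list transcripts in any order
        but must cover exactly the same set (rows are aligned by ``Name``).
    """
    if not paths:
        raise ValueError("no quantification files given")
    sample_ids = list(paths)
    first = _read_one_quant(paths[sample_ids[0]])
    tx_ids = first["Name"].tolist()
    if len(set(tx_ids)) != len(tx_ids):
        raise QuantConsistencyError(f"{paths[sample_ids[0]]}: duplicate transcript names")
    n_tx, n_s = len(tx_ids), len(sample_ids)
    tpm = np.empty((n_tx, n_s))
    eff_len = np.empty((n_tx, n_s))
    reads = np.empty((n_tx, n_s))
    length = first["Length"].to_numpy()

    ref_index = pd.Index(tx_ids)
    for j, sid in enumerate(sample_ids):
        df = first if j == 0 else _read_one_quant(paths[sid])
        if j > 0:
            if set(df["Name"]) != set(tx_ids):
                raise QuantConsistencyError(
                    f"{paths[sid]}: transcript set differs from {paths[sample_ids[0]]}"
                )
            df = df.set_index("Name").loc[ref_index].reset_index()
        tpm[:, j] = df["TPM"].to_numpy()
        eff_len[:, j] = df["EffectiveLength"].to_numpy()
        reads[:, j] = df["NumReads"].to_numpy()

    return TranscriptQuantSet(tx_ids, sample_ids, tpm, eff_len, reads, length)


def build_tx2gene(gtf_path: str) -> pd.DataFrame:
    """Build a transcript-to-gene table from a GTF annotation.

    Returns a DataFrame with columns ``transcript_id``, ``gene_id`` and
    ``ntx`` (the number of annotated transcripts of the gene).  Version
    suffixes on identifiers are retained verbatim.  Only the attribute fields
    of transcript/exon records are used.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    mapping: dict[str, str] = {}
    order: list[str] = []
    for ftype in ("transcript", "exon"):
        for feat in db.features_of_type(ftype):
            if "transcript_id" not in feat.attributes:
                continue
            txid = feat.attributes["transcript_id"][0]
            if "gene_id" not in feat.attributes or not feat.attributes["gene_id"][0]:
                raise QuantFormatError(
                    f"{gtf_path}: record for transcript {txid} lacks gene_id"
                )
            gid = feat.attributes["gene_id"][0]
            if txid in mapping:
                if mapping[txid] != gid:
                    raise QuantConsistencyError(
                        f"transcript {txid} listed under two genes: "
                        f"{mapping[txid]} and {gid}"
                    )
            else:
                mapping[txid] = gid
                order.append(txid)
    if not mapping:
        raise QuantFormatError(f"{gtf_path}: no transcript records with transcript_id")
    table = pd.DataFrame(
        {"transcript_id": order, "gene_id": [mapping[t] for t in order]}
    )
    ntx = table["gene_id"].value_counts()
    table["ntx"] = table["gene_id"].map(ntx).astype(int)
    return table


def _mapped_reads(q: TranscriptQuantSet) -> np.ndarray:
    # tximport convention: per-sample mapped total = column sum of NumReads
    return q.est_reads.sum(axis=0)


def counts_from_abundance(q: TranscriptQuantSet, mode: str = "scaledTPM") -> CountMatrix:
    """Derive a transcript count matrix under the selected convention.

    Rows that are all-zero across samples are dropped (they carry no
    information for any downstream test).
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown counts-from-abundance mode {mode!r}")
    reads_total = _mapped_reads(q)
    if mode == "raw":
        counts = q.est_reads.copy()
    else:
        abundance = q.tpm
        if mode == "lengthScaledTPM":
            abundance = q.tpm * q.eff_length.mean(axis=1, keepdims=True)
        col_tot = abundance.sum(axis=0)
        if np.any(col_tot <= 0):
            bad = q.sample_ids[int(np.argmin(col_tot))]
            raise ValueError(f"sample {bad} has zero total TPM; rescaling undefined")
        counts = abundance / col_tot * reads_total
    keep = counts.sum(axis=1) > 0
    row_ids = [t for t, k in zip(q.transcript_ids, keep) if k]
    return CountMatrix(row_ids, list(q.sample_ids), counts[keep], mode)


def summarize_to_gene(
    q: TranscriptQuantSet, tx2gene: pd.DataFrame, mode: str = "raw"
) -> CountMatrix:
    """Summarize transcript quantifications to the gene level.

    Gene counts are sums of member-transcript counts under the chosen
    counts-from-abundance mode.  The returned ``offsets`` matrix holds the
    abundance-weighted mean effective transcript length per gene and sample
    (falling back to the unweighted mean when the gene has zero TPM in a
    sample), for use as a statistical offset with ``raw`` counts.
    """
    lookup = dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
    missing = [t for t in q.transcript_ids if t not in lookup]
    if missing:
        raise QuantConsistencyError(
            "transcripts absent from tx2gene map: " + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    gene_of = np.array([lookup[t] for t in q.transcript_ids])
    genes = list(dict.fromkeys(gene_of))  # first-appearance order
    gene_index = {g: i for i, g in enumerate(genes)}
    rows = np.array([gene_index[g] for g in gene_of])
    n_g, n_s = len(genes), q.n_samples

    if mode == "raw":
        tx_counts = q.est_reads
    else:
        # recompute on the full transcript set (no zero-row dropping here so
        # that mass is conserved exactly against the transcript matrix)
        cm = counts_from_abundance(q, mode)
        full = np.zeros((q.n_transcripts, n_s))
        pos = {t: i for i, t in enumerate(q.transcript_ids)}
        for rid, row in zip(cm.row_ids, cm.counts):
            full[pos[rid]] = row
        tx_counts = full

    counts = np.zeros((n_g, n_s))
    np.add.at(counts, rows, tx_counts)

    tpm_tot = np.zeros((n_g, n_s))
    np.add.at(tpm_tot, rows, q.tpm)
    weighted = np.zeros((n_g, n_s))
    np.add.at(weighted, rows, q.tpm * q.eff_length)
    mean_len = np.zeros((n_g, n_s))
    np.add.at(mean_len, rows, q.eff_length)
    n_members = np.bincount(rows, minlength=n_g).astype(float)
    mean_len /= n_members[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        offsets = np.where(tpm_tot > 0, weighted / np.where(tpm_tot > 0, tpm_tot, 1.0), mean_len)

    return CountMatrix(genes, list(q.sample_ids), counts, mode if mode in COUNT_MODES else "raw", offsets=offsets)


def write_counts_tsv(cm: CountMatrix, path: str) -> None:
    """Serialize a count matrix as TSV with the row id as first column."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    cm.to_frame().rename_axis("row_id").to_csv(path, sep="\t")
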