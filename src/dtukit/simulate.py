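"""Count-level RNA-seq benchmark generator with DGE/DTE/DTU ground truth.

The generator builds a two-group experiment from a baseline of per-transcript
abundances (TPM scale).  Genes are assigned to four categories:

``null``
    Abundance identical in both groups.
``DGE``
    All expressed isoforms multiplied by one gene-wide fold change (drawn as
    2^U, U uniform on the log2 fold-change range, default [1, 2.58], i.e.
    fold changes between 2 and 6) in a randomly chosen group.  Within-gene
    proportions are untouched.
``DTE``
    A single randomly chosen expressed isoform receives the fold change.
    Total gene expression changes, so these genes are also differentially
    expressed; when other isoforms are expressed the proportions change too
    and the gene is additionally a true differential-usage gene.
``DTU``
    The abundances of two expressed isoforms with distinct TPM are exchanged
    in one group (or, for a single-expressed-isoform gene, the expressed
    isoform is swapped with an unexpressed one).  Gene totals are conserved
    exactly; individual transcript expression changes, so DTU genes are also
    differential-transcript-expression genes, but not differential at the
    gene level.

Fragment counts are negative binomial around ``mu proportional to
TPM x effective length`` scaled to the library size, with the dispersion
drawn from a mean-dispersion trend times log-normal jitter: per transcript
("main" regime) or shared within a gene matched on the gene-level mean
("fixed per-gene dispersion" regime).  Transcripts whose expected baseline
count falls below ``expressed_count_threshold`` have abundance set to zero
and do not count as expressed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .quant_io import TranscriptQuantSet, CountMatrix

__all__ = ["SimParams", "SimTruth", "simulate_truth", "simulate_counts", "write_quant_files", "simulate_experiment"]

# isoform-number distribution over 1..7 (annotation-like: most genes carry
# few isoforms; the right tail is thin)
DEFAULT_ISOFORM_PROBS = np.array([0.30, 0.28, 0.17, 0.11, 0.07, 0.05, 0.02])


def default_log_tpm(rng: np.random.Generator, size: int) -> np.ndarray:
    """Baseline natural-log TPM draw: heavy-tailed, median a few TPM."""
    return rng.normal(np.log(5.0), 1.8, size=size)


def default_mean_dispersion(mu: np.ndarray) -> np.ndarray:
    """Mean-dispersion trend alpha(mu) = 4/mu + 0.05 (bulk-RNA-seq-like)."""
    return 4.0 / np.maximum(mu, 1e-8) + 0.05


@dataclass
class SimParams:
    """Simulation parameters; defaults mirror the benchmark construction."""

    n_genes: int
    n_per_group: int = 12
    frac_dge: float = 0.1
    frac_dte: float = 0.1
    frac_dtu: float = 0.1
    lfc_range: tuple[float, float] = (1.0, 2.58)  # log2; fold changes in [2, 6]
    expressed_count_threshold: float = 10.0
    isoform_probs: np.ndarray = field(default_factory=lambda: DEFAULT_ISOFORM_PROBS.copy())
    log_tpm_fn: Callable = default_log_tpm
    mean_dispersion_fn: Callable = default_mean_dispersion
    dispersion_jitter_sdlog: float = 0.3
    dispersion_mode: str = "main"  # or "fixed_per_gene"
    library_sizes: np.ndarray | None = None  # per sample; default scales 31.4-38.5M to n_genes
    seed: int | None = None

    def validate(self) -> None:
        if self.frac_dge + self.frac_dte + self.frac_dtu > 1.0 + 1e-12:
            raise ValueError("differential fractions must sum to at most 1")
        if self.dispersion_mode not in ("main", "fixed_per_gene"):
            raise ValueError("dispersion_mode must be 'main' or 'fixed_per_gene'")
        if not (0 < self.lfc_range[0] <= self.lfc_range[1]):
            raise ValueError("lfc_range must be positive and ordered")

    def default_library_sizes(self, rng: np.random.Generator, n_samples: int) -> np.ndarray:
        # 31.4-38.5 million mapped reads for a 15,017-gene transcriptome,
        # scaled proportionally for smaller simulations
        scale = self.n_genes / 15017.0
        return rng.uniform(31.4e6, 38.5e6, size=n_samples) * scale


@dataclass
class SimTruth:
    """Ground truth: per-gene labels, per-transcript flags and abundances."""

    gene_ids: np.ndarray          # per transcript
    transcript_ids: np.ndarray
    length: np.ndarray            # annotated length per transcript
    eff_length: np.ndarray        # effective length per transcript
    tpm_group1: np.ndarray        # abundance per transcript (TPM scale)
    tpm_group2: np.ndarray
    gene_label: pd.Series         # constructed category per gene: null/DGE/DTE/DTU
    gene_dge: pd.Series           # effective truth per analysis level
    gene_dte: pd.Series
    gene_dtu: pd.Series
    dge_tx: np.ndarray            # per-transcript flags
    dte_tx: np.ndarray
    dtu_tx: np.ndarray
    expressed: np.ndarray

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "transcript_id": self.transcript_ids,
                "gene_label": self.gene_label.loc[self.gene_ids].to_numpy(),
                "expressed": self.expressed,
                "dge_tx": self.dge_tx,
                "dte_tx": self.dte_tx,
                "dtu_tx": self.dtu_tx,
            }
        )


def _category_sizes(n_genes: int, params: SimParams) -> tuple[int, int, int, int]:
    n_dge = int(np.floor(params.frac_dge * n_genes))
    n_dte = int(np.floor(params.frac_dte * n_genes))
    n_dtu = int(np.floor(params.frac_dtu * n_genes))
    return n_dge, n_dte, n_dtu, n_genes - n_dge - n_dte - n_dtu


def simulate_truth(params: SimParams) -> SimTruth:
    """Draw the baseline transcriptome and construct the differential truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes

    iso_probs = np.asarray(params.isoform_probs, dtype=float)
    iso_probs = iso_probs / iso_probs.sum()
    n_iso = rng.choice(np.arange(1, len(iso_probs) + 1), size=n_genes, p=iso_probs)

    gene_names = np.array([f"G{i+1:05d}" for i in range(n_genes)])
    gene_ids = np.repeat(gene_names, n_iso)
    tx_ids = np.array(
        [f"G{g+1:05d}.T{t+1}" for g in range(n_genes) for t in range(n_iso[g])]
    )
    n_tx = len(tx_ids)

    length = np.round(np.exp(rng.normal(np.log(2000.0), 0.6, size=n_tx))).astype(int)
    length = np.clip(length, 300, None)
    eff_length = np.maximum(length - 200.0, 25.0)

    mean_lib = 35.0e6 * n_genes / 15017.0
    if params.library_sizes is not None:
        mean_lib = float(np.mean(params.library_sizes))

    # draw abundances; threshold to zero below the expressed-count cutoff;
    # redraw genes left with no expressed isoform so every gene is expressed
    first = np.searchsorted(np.repeat(np.arange(n_genes), n_iso), np.arange(n_genes))
    tpm = np.exp(params.log_tpm_fn(rng, n_tx))
    for _ in range(200):
        denom = float(np.sum(tpm * eff_length))
        mu0 = mean_lib * tpm * eff_length / denom
        expressed = mu0 >= params.expressed_count_threshold
        tpm = np.where(expressed, tpm, 0.0)
        gene_has = np.zeros(n_genes, dtype=bool)
        np.add.at(gene_has, np.repeat(np.arange(n_genes), n_iso), expressed)
        if gene_has.all():
            break
        for g in np.flatnonzero(~gene_has):
            lo, hi = first[g], first[g] + n_iso[g]
            tpm[lo:hi] = np.exp(params.log_tpm_fn(rng, n_iso[g]))
    else:
        raise RuntimeError("could not produce an expressed isoform for every gene")

    n_dge, n_dte, n_dtu, _ = _category_sizes(n_genes, params)
    multi_iso = np.flatnonzero(n_iso >= 2)
    if len(multi_iso) < n_dtu:
        raise ValueError("not enough multi-isoform genes for the requested DTU fraction")

    perm_multi = rng.permutation(multi_iso)
    dtu_genes = perm_multi[:n_dtu]
    remaining = np.setdiff1d(np.arange(n_genes), dtu_genes)
    perm_rest = rng.permutation(remaining)
    dge_genes = perm_rest[:n_dge]
    dte_genes = perm_rest[n_dge : n_dge + n_dte]

    label = np.array(["null"] * n_genes, dtype=object)
    label[dge_genes] = "DGE"
    label[dte_genes] = "DTE"
    label[dtu_genes] = "DTU"

    tpm1 = tpm.copy()
    tpm2 = tpm.copy()
    dge_tx = np.zeros(n_tx, dtype=bool)
    dte_tx = np.zeros(n_tx, dtype=bool)
    dtu_tx = np.zeros(n_tx, dtype=bool)
    gene_dge = np.zeros(n_genes, dtype=bool)
    gene_dte = np.zeros(n_genes, dtype=bool)
    gene_dtu = np.zeros(n_genes, dtype=bool)

    def gene_rows(g: int) -> np.ndarray:
        return np.arange(first[g], first[g] + n_iso[g])

    def fold_change() -> float:
        return float(2.0 ** rng.uniform(*params.lfc_range))

    for g in dge_genes:
        rows = gene_rows(g)
        fc = fold_change()
        target = tpm2 if rng.random() < 0.5 else tpm1
        target[rows] = target[rows] * fc
        expr = rows[expressed[rows]]
        dge_tx[expr] = True
        dte_tx[expr] = True
        gene_dge[g] = gene_dte[g] = True

    for g in dte_genes:
        rows = gene_rows(g)
        expr = rows[expressed[rows]]
        chosen = rng.choice(expr)
        fc = fold_change()
        target = tpm2 if rng.random() < 0.5 else tpm1
        target[chosen] = target[chosen] * fc
        dte_tx[chosen] = True
        dge_tx[chosen] = True
        gene_dge[g] = gene_dte[g] = True  # gene total always changes
        if len(expr) > 1:
            gene_dtu[g] = True            # proportions change too
            dtu_tx[chosen] = True

    for g in dtu_genes:
        rows = gene_rows(g)
        expr = rows[expressed[rows]]
        changed = rng.random() < 0.5  # which group carries the swap
        target = tpm2 if changed else tpm1
        if len(expr) >= 2:
            # pick a pair with distinct abundances (equal-abundance swaps
            # would be no-ops; ties have probability ~0 with continuous TPM)
            pair = rng.choice(expr, size=2, replace=False)
            tries = 0
            while np.isclose(target[pair[0]], target[pair[1]]) and tries < 20:
                pair = rng.choice(expr, size=2, replace=False)
                tries += 1
        else:
            unexpr = rows[~expressed[rows]]
            pair = np.array([expr[0], rng.choice(unexpr)])
        a, b = pair
        target[a], target[b] = target[b], target[a]
        dtu_tx[a] = dtu_tx[b] = True
        dte_tx[a] = dte_tx[b] = True
        gene_dtu[g] = gene_dte[g] = True

    # A transcript participates in usage change iff its within-gene
    # proportion differs between the groups: in a DTE gene with several
    # expressed isoforms the untouched isoforms' proportions shift too
    # (the gene total changed), whereas in a DTU swap the gene total is
    # conserved and only the swapped pair moves.  Deriving the flag from
    # the constructed abundances makes the transcript-level truth agree
    # with the gene-level categories in every case.
    for g in range(n_genes):
        rows = gene_rows(g)
        t1, t2 = tpm1[rows].sum(), tpm2[rows].sum()
        if t1 <= 0 or t2 <= 0:
            continue
        prop_change = ~np.isclose(tpm1[rows] / t1, tpm2[rows] / t2, rtol=1e-9, atol=1e-15)
        dtu_tx[rows] = prop_change
        gene_dtu[g] = bool(prop_change.any())

    idx = pd.Index(gene_names)
    return SimTruth(
        gene_ids=gene_ids,
        transcript_ids=tx_ids,
        length=length,
        eff_length=eff_length,
        tpm_group1=tpm1,
        tpm_group2=tpm2,
        gene_label=pd.Series(label, index=idx),
        gene_dge=pd.Series(gene_dge, index=idx),
        gene_dte=pd.Series(gene_dte, index=idx),
        gene_dtu=pd.Series(gene_dtu, index=idx),
        dge_tx=dge_tx,
        dte_tx=dte_tx,
        dtu_tx=dtu_tx,
        expressed=expressed,
    )


def simulate_counts(
    truth: SimTruth, params: SimParams, seed: int | None = None
) -> tuple[TranscriptQuantSet, CountMatrix, pd.DataFrame]:
    """Generate NB fragment counts and a matching quantification set.

    Returns ``(quant, counts, samples)``: the quantification set carries a
    TPM matrix derived from the realized counts (so the counts-from-abundance
    import path is exercisable end to end), the raw fragment-count matrix,
    and the sample table with condition labels.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_per_group
    n_samples = 2 * n
    sample_ids = [f"s{i+1}_{g+1}" for g in range(2) for i in range(n)]
    condition = np.array(["1"] * n + ["2"] * n)

    if params.library_sizes is not None:
        lib = np.asarray(params.library_sizes, dtype=float)
        if lib.size != n_samples:
            raise ValueError("library_sizes must have one entry per sample")
    else:
        lib = params.default_library_sizes(rng, n_samples)

    n_tx = len(truth.transcript_ids)
    mu = np.empty((n_tx, n_samples))
    for j in range(n_samples):
        a = truth.tpm_group1 if condition[j] == "1" else truth.tpm_group2
        w = a * truth.eff_length
        mu[:, j] = lib[j] * w / w.sum()

    # dispersion: trend at the transcript's across-sample mean, with
    # log-normal jitter per transcript (main) or per gene (fixed_per_gene)
    mean_mu = mu.mean(axis=1)
    if params.dispersion_mode == "main":
        jitter = np.exp(rng.normal(0.0, params.dispersion_jitter_sdlog, size=n_tx))
        alpha = params.mean_dispersion_fn(np.maximum(mean_mu, 1e-8)) * jitter
    else:
        genes = pd.Series(truth.gene_ids)
        gene_mean = genes.groupby(genes, sort=False).transform(
            lambda s: mean_mu[s.index].sum()
        ).to_numpy()
        uniq = genes.drop_duplicates()
        gj = dict(zip(uniq, np.exp(rng.normal(0.0, params.dispersion_jitter_sdlog, size=len(uniq)))))
        jitter = genes.map(gj).to_numpy()
        alpha = params.mean_dispersion_fn(np.maximum(gene_mean, 1e-8)) * jitter

    counts = np.zeros((n_tx, n_samples))
    pos = mu > 0
    a_mat = np.broadcast_to(alpha[:, None], mu.shape)
    r = 1.0 / np.maximum(a_mat, 1e-12)
    p = r / (r + np.maximum(mu, 1e-300))
    counts[pos] = rng.negative_binomial(r[pos], p[pos])

    # realized TPM from the counts: abundance proportional to count/efflen
    dens = counts / truth.eff_length[:, None]
    col = dens.sum(axis=0)
    tpm = dens / np.where(col > 0, col, 1.0) * 1e6

    quant = TranscriptQuantSet(
        transcript_ids=list(truth.transcript_ids),
        sample_ids=sample_ids,
        tpm=tpm,
        eff_length=np.broadcast_to(truth.eff_length[:, None], mu.shape).copy(),
        est_reads=counts,
        length=truth.length,
    )
    cm = CountMatrix(list(truth.transcript_ids), sample_ids, counts, "raw")
    samples = pd.DataFrame({"sample_id": sample_ids, "condition": condition})
    return quant, cm, samples


def write_quant_files(q: TranscriptQuantSet, out_dir: str) -> dict[str, str]:
    """Write one Salmon-format ``quant.sf`` per sample; returns the path map.

    Floats are written with 17 significant digits so a round trip through
    :func:`dtukit.quant_io.read_salmon_quant` reproduces TPM and NumReads
    bit for bit.
    """
    paths = {}
    for j, sid in enumerate(q.sample_ids):
        d = os.path.join(out_dir, sid)
        os.makedirs(d, exist_ok=True)
        path = os.path.join(d, "quant.sf")
        with open(path, "w") as fh:
            fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
            for i, tx in enumerate(q.transcript_ids):
                fh.write(
                    f"{tx}\t{int(q.length[i])}\t{q.eff_length[i, j]:.17g}"
                    f"\t{q.tpm[i, j]:.17g}\t{q.est_reads[i, j]:.17g}\n"
                )
        paths[sid] = path
    return paths


def simulate_experiment(params: SimParams):
    """Convenience wrapper: truth plus counts in one call (single seed)."""
    truth = simulate_truth(params)
    rng_seed = None if params.seed is None else params.seed + 1
    quant, cm, samples = simulate_counts(truth, params, seed=rng_seed)
    return truth, quant, cm, samples
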