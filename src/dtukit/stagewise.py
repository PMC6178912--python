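"""Two-stage (screening / confirmation) testing with overall-FDR control.

Stage one screens genes: gene-level p-values are BH-adjusted and genes with
adjusted p at or below the target ``alpha`` pass.  Stage two confirms
transcripts inside each screened gene with a Holm family-wise correction
using the Shaffer logical reduction: because within-gene proportions sum to
one, a usage change in any transcript forces a change in at least one other,
so the smallest p-value is multiplied by K-1 rather than K.  Confirmation is
carried out at the level ``alpha * |S| / G`` (S the screened set, G the
screened universe), reported here equivalently as within-gene adjusted
p-values multiplied by G/|S| and compared against ``alpha``.

The guaranteed error rate is the overall false discovery rate (OFDR): in
expectation no more than ``alpha`` of the screened genes either contain no
differential usage at all or contain a falsely confirmed transcript.  The
target must be fixed before running; the output cannot be re-thresholded at
another level afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dm_dtu import adjust_bh

__all__ = ["StageWiseInput", "StageWiseResult", "strip_version", "stage_wise_adjust"]


def strip_version(identifier: str) -> str:
    """Truncate an identifier to its first 15 characters.

    Drops the version suffix from Ensembl/GENCODE-style ids
    (``ENSG00000001167.14`` -> ``ENSG00000001167``) so that gene and
    transcript tables join on the unversioned id.
    """
    return identifier[:15]


@dataclass
class StageWiseInput:
    """Inputs to the stage-wise procedure.

    ``p_screen`` maps gene id to screening p-value (raw, or already
    FDR-adjusted when ``screen_adjusted``).  ``p_confirmation`` maps
    transcript id to its confirmation p-value; ``tx2gene`` pairs every
    confirmation transcript with a screened-universe gene.  No missing values
    are allowed: sanitize upstream.
    """

    p_screen: pd.Series
    p_confirmation: pd.Series
    tx2gene: pd.DataFrame  # columns: transcript_id, gene_id
    alpha: float = 0.05
    screen_adjusted: bool = False


@dataclass
class StageWiseResult:
    """Adjusted p-values for screened genes and their transcripts."""

    table: pd.DataFrame  # geneID, txID, gene_adj_p, transcript_adj_p
    alpha: float

    @property
    def screened_genes(self) -> np.ndarray:
        return self.table["geneID"].unique()

    def confirmed(self) -> pd.DataFrame:
        return self.table[self.table["transcript_adj_p"] <= self.alpha]


def _holm_shaffer(p: np.ndarray) -> np.ndarray:
    """Within-gene step-down adjustment with the Shaffer reduction.

    For K ordered p-values the multipliers are max(K-i, 1) for the i-th
    smallest (i = 1..K): the usual Holm sequence shifted down by one because
    the proportions constraint rules out exactly one false null.  Adjusted
    values are the running maximum of p * multiplier, capped at 1.  K = 2
    leaves both transcripts at their raw p-values.
    """
    p = np.asarray(p, dtype=float)
    K = p.size
    order = np.argsort(p, kind="stable")
    mult = np.maximum(K - 1 - np.arange(K), 1)
    adj = np.minimum(np.maximum.accumulate(p[order] * mult), 1.0)
    out = np.empty(K)
    out[order] = adj
    return out


def stage_wise_adjust(inp: StageWiseInput) -> StageWiseResult:
    """Run screening and confirmation; return adjusted p-values.

    Raises on missing values.  An empty screened set yields an empty table.
    """
    if not 0 < inp.alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p_screen = inp.p_screen.astype(float)
    p_conf = inp.p_confirmation.astype(float)
    if p_screen.isna().any() or p_conf.isna().any():
        raise ValueError(
            "missing p-values: sanitize upstream (e.g. dm_dtu.sanitize_pvalues) "
            "before stage-wise adjustment"
        )
    tx2gene = inp.tx2gene[["transcript_id", "gene_id"]].copy()
    unknown = set(tx2gene["gene_id"]) - set(p_screen.index)
    if unknown:
        raise ValueError(f"confirmation transcripts map to unscreened genes: {sorted(unknown)[:5]}")

    G = len(p_screen)
    screen_adj = p_screen if inp.screen_adjusted else pd.Series(
        adjust_bh(p_screen.to_numpy()), index=p_screen.index
    )
    screened = screen_adj.index[screen_adj <= inp.alpha]
    if len(screened) == 0:
        empty = pd.DataFrame(columns=["geneID", "txID", "gene_adj_p", "transcript_adj_p"])
        return StageWiseResult(table=empty, alpha=inp.alpha)

    scale = G / len(screened)
    rows = []
    by_gene = tx2gene.groupby("gene_id", sort=False)
    for gene in screened:
        txs = by_gene.get_group(gene)["transcript_id"].to_numpy()
        within = _holm_shaffer(p_conf.loc[txs].to_numpy())
        tx_adj = np.minimum(within * scale, 1.0)
        for tx, q in zip(txs, tx_adj):
            rows.append((gene, tx, float(screen_adj.loc[gene]), float(q)))
    table = pd.DataFrame(rows, columns=["geneID", "txID", "gene_adj_p", "transcript_adj_p"])
    table = table.sort_values(["geneID", "txID"], kind="stable").reset_index(drop=True)
    return StageWiseResult(table=table, alpha=inp.alpha)
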