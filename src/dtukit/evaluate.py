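"""Scoring of DTU calls against simulated ground truth.

FDR here is the realized false discovery proportion among calls at a
threshold, TPR the fraction of true features recovered.  The stage-wise
procedure is scored by its own contract, the overall false discovery rate
(OFDR): the fraction of screened genes that either contain no true usage
change at all, or contain a confirmed transcript that did not participate in
the constructed switch.  The evaluation universe is the post-filter gene and
transcript set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["fdr_tpr", "ofdr_sensitivity", "fp_breakdown", "EvalReport"]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.10)
CATEGORIES = ("DGE", "DTE", "DTU", "null")


@dataclass
class EvalReport:
    """Bundle of evaluation tables for one method run."""

    gene_fdr_tpr: pd.DataFrame
    transcript_fdr_tpr: pd.DataFrame
    ofdr: float
    sensitivity: float
    fp_by_category: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "gene": self.gene_fdr_tpr.to_dict(orient="records"),
            "transcript": self.transcript_fdr_tpr.to_dict(orient="records"),
            "ofdr": self.ofdr,
            "sensitivity": self.sensitivity,
            "fp_by_category": self.fp_by_category.to_dict(orient="records"),
        }


def fdr_tpr(adj_p, truth, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Observed FDR and TPR at each adjusted-p threshold.

    FDR uses the empty-call convention FP / max(1, calls); TPR is
    TP / positives (0 when there are no positives).
    """
    adj_p = np.asarray(adj_p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if adj_p.shape != truth.shape:
        raise ValueError("adj_p and truth must align")
    positives = int(truth.sum())
    rows = []
    for t in thresholds:
        called = adj_p <= t
        tp = int((called & truth).sum())
        fp = int((called & ~truth).sum())
        fdr = fp / max(1, fp + tp)
        tpr = tp / positives if positives else 0.0
        rows.append((t, fp + tp, tp, fp, fdr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "called", "tp", "fp", "fdr", "tpr"])


def ofdr_sensitivity(
    result, truth, alpha: float | None = None, universe_tx=None
) -> tuple[float, float]:
    """Observed OFDR and DTU-transcript sensitivity of a stage-wise result.

    ``result`` is a :class:`dtukit.stagewise.StageWiseResult`; ``truth`` a
    :class:`dtukit.simulate.SimTruth`.  Identifiers are compared after
    15-character truncation, mirroring the stage-wise tables.  A screened
    gene counts as a false discovery if it is not DTU-true, or if any of its
    confirmed transcripts (transcript_adj_p <= alpha) does not participate in
    the constructed usage change.  Sensitivity is the fraction of true DTU
    transcripts in the evaluation universe that were confirmed;
    ``universe_tx`` should be the post-filter transcript ids (defaults to the
    transcripts of the screened genes only).
    """
    alpha = result.alpha if alpha is None else alpha
    table = result.table
    gene_dtu = {g[:15]: bool(v) for g, v in truth.gene_dtu.items()}
    tx_dtu = {
        t[:15]: bool(v) for t, v in zip(truth.transcript_ids, truth.dtu_tx)
    }

    screened = table["geneID"].unique()
    if len(screened) == 0:
        return 0.0, 0.0
    confirmed = table[table["transcript_adj_p"] <= alpha]
    false_genes = 0
    for g in screened:
        if not gene_dtu.get(g, False):
            false_genes += 1
            continue
        conf_tx = confirmed.loc[confirmed["geneID"] == g, "txID"]
        if any(not tx_dtu.get(t, False) for t in conf_tx):
            false_genes += 1
    ofdr = false_genes / len(screened)

    if universe_tx is None:
        universe_tx = table["txID"].unique()
    else:
        universe_tx = pd.unique(pd.Series(universe_tx).map(lambda t: t[:15]))
    true_dtu_universe = [t for t in universe_tx if tx_dtu.get(t, False)]
    if not true_dtu_universe:
        return ofdr, 0.0
    confirmed_true = confirmed["txID"].map(lambda t: tx_dtu.get(t, False)).sum()
    sensitivity = float(confirmed_true) / len(true_dtu_universe)
    return ofdr, sensitivity


def fp_breakdown(calls, truth_flags, gene_categories) -> pd.DataFrame:
    """Partition false-positive calls by the simulated category of their gene."""
    calls = np.asarray(calls, dtype=bool)
    truth_flags = np.asarray(truth_flags, dtype=bool)
    cats = np.asarray(gene_categories, dtype=object)
    if not (calls.shape == truth_flags.shape == cats.shape):
        raise ValueError("calls, truth and categories must align")
    fp = calls & ~truth_flags
    counts = {c: int((fp & (cats == c)).sum()) for c in CATEGORIES}
    return pd.DataFrame([counts])
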