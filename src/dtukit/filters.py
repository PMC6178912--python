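"""Expression and proportion filters applied before and after DTU modeling.

Three pre-modeling rules (thresholds named as in the DRIMSeq-style filter):

1. transcript count rule — count >= ``min_feature_expr`` in at least
   ``min_samps_feature_expr`` samples;
2. transcript proportion rule — within-gene relative abundance >=
   ``min_feature_prop`` in at least ``min_samps_feature_prop`` samples;
3. gene count rule — gene total count >= ``min_gene_expr`` in at least
   ``min_samps_gene_expr`` samples.

Proportions are computed against the gene total over all transcripts present
before any removal; genes left with fewer than two surviving transcripts are
dropped entirely (a single-isoform gene cannot show usage change).

A separate post-hoc filter masks transcripts whose per-sample proportion has
small standard deviation; callers set the masked transcripts' p-values and
adjusted p-values to 1 without recomputing the adjustment.  This non-specific
effect-size filter is recommended for the Dirichlet-multinomial path only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterConfig", "DTUDataset", "dm_style_filter", "proportion_sd_mask"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three pre-modeling filters.

    Sample-count thresholds are typically ``n.small`` (smallest group size)
    for the transcript rules and ``n`` (total samples) for the gene rule.
    """

    min_samps_feature_expr: int = 6
    min_feature_expr: float = 10.0
    min_samps_feature_prop: int = 6
    min_feature_prop: float = 0.1
    min_samps_gene_expr: int = 12
    min_gene_expr: float = 10.0

    def validate(self, n_samples: int) -> None:
        for name in ("min_samps_feature_expr", "min_samps_feature_prop", "min_samps_gene_expr"):
            if getattr(self, name) > n_samples:
                raise ValueError(f"{name}={getattr(self, name)} exceeds sample count {n_samples}")
        if not 0 <= self.min_feature_prop <= 1:
            raise ValueError("min_feature_prop must lie in [0, 1]")


@dataclass
class DTUDataset:
    """Transcript counts grouped by gene, with the sample design.

    ``gene_ids`` is aligned to the transcript rows and grouped contiguously
    (first-appearance gene order).  ``samples`` has columns ``sample_id`` and
    ``condition``.
    """

    gene_ids: np.ndarray
    transcript_ids: np.ndarray
    counts: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (len(self.gene_ids) == len(self.transcript_ids) == self.counts.shape[0]):
            raise ValueError("gene_ids, transcript_ids and counts rows must align")
        if self.counts.shape[1] != len(self.samples):
            raise ValueError("counts columns must match the sample table")
        self._regroup()

    def _regroup(self) -> None:
        # stable sort by first appearance of each gene; preserves row order within genes
        first_seen: dict = {}
        for g in self.gene_ids:
            first_seen.setdefault(g, len(first_seen))
        order = np.argsort([first_seen[g] for g in self.gene_ids], kind="stable")
        self.gene_ids = self.gene_ids[order]
        self.transcript_ids = self.transcript_ids[order]
        self.counts = self.counts[order]

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_genes(self) -> int:
        return len(dict.fromkeys(self.gene_ids))

    def gene_groups(self):
        """Yield ``(gene_id, row_index_array)`` in dataset order."""
        idx: dict = {}
        for i, g in enumerate(self.gene_ids):
            idx.setdefault(g, []).append(i)
        for g, rows in idx.items():
            yield g, np.asarray(rows)

    def gene_totals(self) -> np.ndarray:
        """Per-gene, per-sample count totals aligned to transcript rows."""
        totals = np.zeros_like(self.counts)
        for _, rows in self.gene_groups():
            totals[rows] = self.counts[rows].sum(axis=0)
        return totals

    def proportions(self) -> np.ndarray:
        """Within-gene per-sample proportions; 0 where the gene total is 0."""
        totals = self.gene_totals()
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, self.counts / np.where(totals > 0, totals, 1.0), 0.0)
        return props

    def subset_rows(self, keep: np.ndarray) -> "DTUDataset":
        return DTUDataset(
            self.gene_ids[keep], self.transcript_ids[keep], self.counts[keep], self.samples
        )


def dm_style_filter(
    ds: DTUDataset, cfg: FilterConfig, report: bool = False
) -> DTUDataset | tuple[DTUDataset, pd.DataFrame]:
    """Apply the three pre-modeling rules; optionally return a per-row report."""
    cfg.validate(len(ds.samples))
    counts = ds.counts
    props = ds.proportions()
    totals = ds.gene_totals()

    pass_count = (counts >= cfg.min_feature_expr).sum(axis=1) >= cfg.min_samps_feature_expr
    pass_prop = (props >= cfg.min_feature_prop).sum(axis=1) >= cfg.min_samps_feature_prop
    gene_expr_ok = (totals >= cfg.min_gene_expr).sum(axis=1) >= cfg.min_samps_gene_expr

    tx_keep = pass_count & pass_prop & gene_expr_ok
    # gene must retain >= 2 transcripts
    surviving = pd.Series(tx_keep).groupby(pd.Series(ds.gene_ids)).transform("sum").to_numpy()
    final = tx_keep & (surviving >= 2)

    out = ds.subset_rows(final)
    if not report:
        return out
    rep = pd.DataFrame(
        {
            "transcript_id": ds.transcript_ids,
            "gene_id": ds.gene_ids,
            "pass_count_filter": pass_count,
            "pass_prop_filter": pass_prop,
            "gene_pass": gene_expr_ok & (surviving >= 2),
            "final_keep": final,
        }
    )
    return out, rep


def proportion_sd_mask(ds: DTUDataset, threshold: float = 0.1) -> np.ndarray:
    """Mask transcripts whose per-sample proportion SD is below ``threshold``.

    The SD uses the unbiased (n-1) denominator across all samples, ignoring
    group labels.  Callers set p-values and adjusted p-values to 1 where the
    mask is true; the adjustment is deliberately not recomputed.
    """
    props = ds.proportions()
    sd = props.std(axis=1, ddof=1)
    return sd < threshold
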