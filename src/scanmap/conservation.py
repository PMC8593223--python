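"""Correlation of mutational-effect scores with evolutionary conservation.

Positions that matter for partner binding need not be the positions
conserved across homologs; this module quantifies the agreement between the
per-position Asp-substitution binding scores and a pre-computed per-position
conservation table (e.g. a ConSurf export) with both Pearson and Spearman
correlations on the inner join of positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .scan_data import ConservationTable
from .scoring import ScoreTable

__all__ = ["CorrelationReport", "correlate_conservation"]


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson/Spearman correlation of score vs conservation, with the
    paired per-position table and the count of excluded positions."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_positions: int
    n_excluded: int
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for v in (self.pearson_r, self.spearman_rho):
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError("correlation out of [-1, 1]")

    def to_dict(self) -> dict:
        return {"pearson_r": self.pearson_r, "pearson_p": self.pearson_p,
                "spearman_rho": self.spearman_rho, "spearman_p": self.spearman_p,
                "n_positions": self.n_positions, "n_excluded": self.n_excluded}


def correlate_conservation(
    scores: ScoreTable,
    cons: ConservationTable,
    mut_aa: str = "D",
) -> CorrelationReport:
    """Correlate per-position MFI_ratio scores with conservation.

    Scores are restricted to one substitution type (Asp by default) and
    inner-joined with the conservation table on position; positions lacking
    either value are excluded and counted. At least 3 complete pairs are
    required.
    """
    score_series = scores.ratio_by_position(mut_aa).rename("score")
    cons_series = cons.as_series()
    merged = pd.concat([score_series, cons_series], axis=1, join="inner").dropna()
    n_all = len(set(score_series.index) | set(cons_series.index))
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} overlapping positions; need >= 3")
    pear = stats.pearsonr(merged["score"], merged["conservation"])
    spear = stats.spearmanr(merged["score"], merged["conservation"])
    return CorrelationReport(
        pearson_r=float(pear.statistic), pearson_p=float(pear.pvalue),
        spearman_rho=float(spear.statistic), spearman_p=float(spear.pvalue),
        n_positions=n, n_excluded=n_all - n,
        pairs=merged.reset_index().rename(columns={"index": "position"}),
    )
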