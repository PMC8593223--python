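"""Normalized expression and binding-activity scores for scan panels.

Two unitless scores are computed per mutant:

* ``MFI_exp`` — mutant expression MFI divided by WT expression MFI, from
  replicate-mean expression intensities. 1 means WT-like surface expression.
* ``MFI_ratio`` — the mean per-cell binding:expression intensity ratio of the
  mutant divided by that of WT, normalized per replicate against that
  replicate's own WT and then averaged across replicates. 1 means WT-like
  binding; lower values mean reduced ligand binding.

Normalization is per replicate (each replicate's WT is its own reference)
so that instrument-gain differences between experiments cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scan_data import ScanPanel, WT_LABEL

__all__ = ["ScoreTable", "mean_cell_ratio", "compute_mfi_exp",
           "compute_mfi_ratio", "score_panel"]


@dataclass(frozen=True)
class ScoreTable:
    """Per-mutant normalized scores, one row per (position, mut_aa).

    Columns of :attr:`frame`: ``position, wt_aa, mut_aa, mfi_exp,
    mfi_ratio_mean, mfi_ratio_sd, n_replicates``. The WT entry is present
    with both scores exactly 1. Standard deviations use the n-1
    denominator (``sd = |x1 - x2| / sqrt(2)`` for two replicates); with a
    single replicate the sd is NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"position", "wt_aa", "mut_aa", "mfi_exp",
                    "mfi_ratio_mean", "mfi_ratio_sd", "n_replicates"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    def mutant_scores(self, mut_aa: str | None = None) -> pd.DataFrame:
        """Rows for mutants only (WT excluded), optionally one substitution."""
        df = self.frame[self.frame["mut_aa"] != WT_LABEL]
        if mut_aa is not None:
            df = df[df["mut_aa"] == mut_aa]
        return df.reset_index(drop=True)

    def ratio_by_position(self, mut_aa: str) -> pd.Series:
        """MFI_ratio means indexed by position for one substitution type."""
        df = self.mutant_scores(mut_aa)
        return df.set_index("position")["mfi_ratio_mean"].sort_index()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))


def mean_cell_ratio(cells: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Mean over cells of the per-cell binding:expression intensity ratio.

    ``cells`` is a sequence of (expression, binding) pairs or an (n, 2)
    array. All expression values must be positive.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cell list")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("cells must be (expression, binding) pairs")
    expr, bind = arr[:, 0], arr[:, 1]
    if np.any(expr <= 0):
        raise ValueError("non-positive expression intensity")
    return float(np.mean(bind / expr))


def compute_mfi_exp(mut_expression_mfi: float, wt_expression_mfi: float) -> float:
    """Expression score: mutant expression MFI over WT expression MFI."""
    if wt_expression_mfi <= 0:
        raise ValueError(f"WT expression MFI must be > 0, got {wt_expression_mfi}")
    if mut_expression_mfi <= 0:
        raise ValueError(f"mutant expression MFI must be > 0, got {mut_expression_mfi}")
    return mut_expression_mfi / wt_expression_mfi


def compute_mfi_ratio(mut_ratio_mfi: float, wt_ratio_mfi: float) -> float:
    """Binding-activity score: mutant ratio MFI over WT ratio MFI.

    A mutant with zero binding signal scores 0 (not an error).
    """
    if wt_ratio_mfi <= 0:
        raise ValueError(f"WT ratio MFI must be > 0, got {wt_ratio_mfi}")
    if mut_ratio_mfi < 0:
        raise ValueError(f"mutant ratio MFI must be >= 0, got {mut_ratio_mfi}")
    return mut_ratio_mfi / wt_ratio_mfi


def _record_ratio(rec) -> float:
    """The per-record ratio MFI: the exported per-cell mean ratio if present,
    otherwise the channel-MFI quotient as a fallback summary."""
    if rec.ratio_mfi is not None:
        return rec.ratio_mfi
    return rec.binding_mfi / rec.expression_mfi


def score_panel(panel: ScanPanel) -> ScoreTable:
    """Compute the per-mutant score table from a scan panel.

    For each replicate, every mutant's ratio MFI is normalized against that
    replicate's WT ratio MFI; the normalized values are then averaged across
    replicates (mean and n-1 sd). ``mfi_exp`` is the quotient of
    replicate-mean expression MFIs (mutant over WT). The WT row is included
    with both scores exactly 1 and sd 0.
    """
    wt_by_rep = {r.replicate: r for r in panel.wt_records}
    rows: dict[tuple[int, str], dict] = {}
    for rec in panel.mutants():
        wt = wt_by_rep[rec.replicate]
        key = (rec.position, rec.mut_aa)
        entry = rows.setdefault(key, {"wt_aa": rec.wt_aa, "ratios": [], "expr": [],
                                      "wt_expr": []})
        entry["ratios"].append(compute_mfi_ratio(_record_ratio(rec), _record_ratio(wt)))
        entry["expr"].append(rec.expression_mfi)
        entry["wt_expr"].append(wt.expression_mfi)

    wt_rec = panel.wt_records[0]
    out = [{
        "position": wt_rec.position, "wt_aa": wt_rec.wt_aa, "mut_aa": WT_LABEL,
        "mfi_exp": 1.0, "mfi_ratio_mean": 1.0, "mfi_ratio_sd": 0.0,
        "n_replicates": len(wt_by_rep),
    }]
    for (pos, mut_aa), entry in sorted(rows.items()):
        ratios = np.asarray(entry["ratios"], dtype=float)
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else float("nan")
        out.append({
            "position": pos,
            "wt_aa": entry["wt_aa"],
            "mut_aa": mut_aa,
            "mfi_exp": compute_mfi_exp(float(np.mean(entry["expr"])),
                                       float(np.mean(entry["wt_expr"]))),
            "mfi_ratio_mean": float(np.mean(ratios)),
            "mfi_ratio_sd": sd,
            "n_replicates": int(ratios.size),
        })
    return ScoreTable(pd.DataFrame(out))
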