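"""Two-class partitioning of mutational binding scores and interface calls.

Aspartate-substitution MFI_ratio scores are split into a WT-like class and a
binding-defective class by exact 1-D 2-means clustering. Because the optimal
two-cluster partition of scalars is contiguous in sorted order, the global
optimum is found by scanning all n-1 sorted split points — no iterative
(Lloyd) refinement, no seed dependence.

The binding-defective cutoff is ``mean(class1) - sd(class1)`` where class 1 is
the WT-like (higher-mean) class; a residue position is called as part of the
binding interface when any charged substitution (Asp or Arg) at that position
scores strictly below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import ScoreTable

__all__ = ["ClassificationResult", "two_means_1d", "defective_threshold",
           "call_interface_residues", "classify_panel"]


@dataclass(frozen=True)
class ClassificationResult:
    """Two-class split of mutant scores with the derived cutoff.

    Class 1 is the WT-like class (larger mean); class 2 is binding-defective.
    ``labels`` maps each clustered value's index to 1 or 2.
    """

    class1_mean: float
    class1_sd: float
    class2_mean: float
    class2_sd: float
    labels: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.class1_mean > self.class2_mean:
            raise ValueError("class 1 (WT-like) must have the larger mean")

    @property
    def threshold(self) -> float:
        return defective_threshold(self)


def two_means_1d(values) -> tuple[tuple[float, float], np.ndarray, float]:
    """Globally optimal 2-means partition of 1-D data.

    Minimizes the within-cluster sum of squared deviations over all
    contiguous splits of the sorted values (the 1-D optimum is always such
    a split). Deterministic.

    Returns
    -------
    centers : (low_mean, high_mean)
    labels : int array aligned with ``values``; 0 = low cluster, 1 = high
    within_sse : float
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(x == x[0]):
        raise ValueError("degenerate clustering: all values identical")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    # prefix sums -> within-SSE of every sorted split in O(n)
    c1 = np.cumsum(xs)
    c2 = np.cumsum(xs ** 2)
    k = np.arange(1, n)                     # left cluster sizes
    left_sse = c2[:-1] - c1[:-1] ** 2 / k
    right_sum = c1[-1] - c1[:-1]
    right_sq = c2[-1] - c2[:-1]
    right_sse = right_sq - right_sum ** 2 / (n - k)
    total = left_sse + right_sse
    split = int(np.argmin(total))           # first optimum on ties
    low_mean = float(c1[split] / (split + 1))
    high_mean = float(right_sum[split] / (n - split - 1))
    labels = np.zeros(n, dtype=int)
    labels[order[split + 1:]] = 1
    return (low_mean, high_mean), labels, float(total[split])


def defective_threshold(result: ClassificationResult) -> float:
    """Binding-defective cutoff: WT-like class mean minus its sd."""
    return result.class1_mean - result.class1_sd


def classify_scores(values) -> ClassificationResult:
    """Cluster scores into WT-like (class 1) and binding-defective (class 2).

    Standard deviations use the n-1 denominator; a singleton class has sd 0.
    """
    x = np.asarray(values, dtype=float)
    (low, high), lab01, _ = two_means_1d(x)
    high_vals = x[lab01 == 1]
    low_vals = x[lab01 == 0]

    def _sd(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    labels = tuple(1 if l == 1 else 2 for l in lab01)
    return ClassificationResult(
        class1_mean=float(np.mean(high_vals)), class1_sd=_sd(high_vals),
        class2_mean=float(np.mean(low_vals)), class2_sd=_sd(low_vals),
        labels=labels, values=tuple(float(v) for v in x),
    )


def call_interface_residues(
    scores: ScoreTable,
    threshold: float,
    substitutions: tuple[str, ...] = ("D", "R"),
) -> tuple[set[int], set[int]]:
    """Call interface positions from charged-substitution scores.

    A position is called when ANY substitution in ``substitutions`` at that
    position has ``mfi_ratio_mean`` strictly below ``threshold`` ("lower
    than", so ties are not called). Positions inside the panel's scanned
    range with no charged-substitution data are returned separately as
    uncovered, not as negatives.

    Returns
    -------
    (interface_positions, uncovered_positions)
    """
    df = scores.mutant_scores()
    df = df[df["mut_aa"].isin(substitutions)]
    if df.empty:
        raise ValueError("score table has no charged-substitution mutants")
    called = set(df.loc[df["mfi_ratio_mean"] < threshold, "position"].astype(int).tolist())
    covered = set(df["position"].astype(int).tolist())
    all_mut = scores.mutant_scores()
    window = range(int(all_mut["position"].min()), int(all_mut["position"].max()) + 1)
    uncovered = {p for p in window if p not in covered}
    return called, uncovered


def classify_panel(scores: ScoreTable, cluster_on: str = "D") -> dict:
    """Full classification stage: cluster Asp scores, derive the cutoff,
    call interface residues from all charged substitutions.

    Returns a plain-dict report (JSON-serializable) with class statistics,
    threshold, per-mutant labels, interface calls and uncovered positions.
    """
    asp = scores.mutant_scores(cluster_on)
    if asp.empty:
        raise ValueError(f"no {cluster_on!r} substitutions to cluster")
    result = classify_scores(asp["mfi_ratio_mean"].to_numpy())
    thr = result.threshold
    called, uncovered = call_interface_residues(scores, thr)
    return {
        "class1_mean": result.class1_mean,
        "class1_sd": result.class1_sd,
        "class2_mean": result.class2_mean,
        "class2_sd": result.class2_sd,
        "threshold": thr,
        "labels": {f"{p}{a}": int(l) for p, a, l in
                   zip(asp["position"], asp["mut_aa"], result.labels)},
        "interface_positions": sorted(called),
        "uncovered_positions": sorted(uncovered),
        "n_interface": len(called),
    }
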