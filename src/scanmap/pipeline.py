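"""End-to-end orchestration: score -> classify -> periodicity -> titrate ->
conserve, as one reproducible run with a machine-readable report.

Every stage writes plain-text intermediates (CSV/JSON) into the output
directory so each stage can also be re-run standalone on those files and
produce identical numbers. The report embeds a hash of the configuration;
given the same config and seed the report body is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import conservation as _conservation
from . import periodicity as _periodicity
from . import scan_data as _scan_data
from . import scoring as _scoring
from . import synthetic as _synthetic
from . import titration as _titration

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]

log = logging.getLogger("scanmap")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    With ``scan_path`` unset, a synthetic panel (plus titrations) is
    generated from ``seed``. ``breakpoints`` is either an explicit list of
    segment-start positions or ``"auto"`` for the exhaustive scan;
    ``threshold`` is ``"kmeans"`` (derive from two-class clustering) or an
    explicit value in (0, 1.5).
    """

    outdir: str
    scan_path: str | None = None
    titration_paths: tuple[str, ...] = ()
    conservation_path: str | None = None
    detrend_window: int = 5
    breakpoints: tuple[int, ...] | str = (45, 67)
    threshold: float | str = "kmeans"
    seed: int = 0
    ligand_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.detrend_window % 2 == 0 or self.detrend_window < 3:
            raise ConfigError(
                f"detrend_window must be odd and >= 3, got {self.detrend_window}")
        if isinstance(self.threshold, str):
            if self.threshold != "kmeans":
                raise ConfigError(f"threshold mode {self.threshold!r} unknown")
        elif not (0 < float(self.threshold) < 1.5):
            raise ConfigError(f"threshold {self.threshold} outside (0, 1.5)")
        if isinstance(self.breakpoints, str) and self.breakpoints != "auto":
            raise ConfigError(f"breakpoints {self.breakpoints!r} must be a "
                              "position list or 'auto'")
        for p in (self.scan_path, self.conservation_path, *self.titration_paths):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _synthetic_inputs(config: RunConfig):
    """Generate the default synthetic panel and a 9-variant titration set."""
    truth = _synthetic.GroundTruth(seed=config.seed)
    panel, labels = _synthetic.simulate_scan_panel(truth)
    ddgs = np.linspace(0.0, 3.0, 9)
    curves = [_synthetic.simulate_titration(
        truth, float(d), variant_id=f"ddg_{d:.2f}",
        seed=(config.seed * 1000 + i) % (2**31))
        for i, d in enumerate(ddgs)]
    scores_for_curves = {f"ddg_{d:.2f}": _synthetic.expected_mfi_ratio(truth, float(d))
                         for d in ddgs}
    return panel, labels, curves, scores_for_curves


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return (and write) the run report.

    Any stage failure is re-raised as ``RuntimeError`` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config),
                    "config_hash": config.config_hash(),
                    "warnings": []}
    truth_labels = None
    curves: list[_scan_data.TitrationCurve] = []
    curve_scores: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- input ---
    if config.scan_path is None:
        panel, truth_labels, curves, curve_scores = stage("simulate")(
            lambda: _synthetic_inputs(config))
        _scan_data.write_scan_table(panel, outdir / "scan.csv")
        (outdir / "truth.json").write_text(json.dumps(truth_labels, indent=1))
    else:
        panel = stage("read")(lambda: _scan_data.read_scan_table(
            config.scan_path, ligand_conc=config.ligand_conc))
        curves = [stage("read")(lambda p=p: _scan_data.read_titration(p))
                  for p in config.titration_paths]
    log.info("panel: %d records, window %s", len(panel.records),
             panel.sequence_window)

    # --- score ---
    scores = stage("score")(lambda: _scoring.score_panel(panel))
    scores.to_csv(outdir / "scores.csv")

    # --- classify ---
    cls = stage("classify")(lambda: _classify.classify_panel(scores))
    if config.threshold != "kmeans":
        thr = float(config.threshold)
        called, uncovered = _classify.call_interface_residues(scores, thr)
        cls.update(threshold=thr, interface_positions=sorted(called),
                   uncovered_positions=sorted(uncovered), n_interface=len(called))
    report["classification"] = cls

    # --- periodicity ---
    def _periodicity_stage():
        s = scores.ratio_by_position("D")
        series = _periodicity.fill_missing(s.index, s.values, panel.sequence_window)
        corrected = _periodicity.detrend(series, config.detrend_window)
        if config.breakpoints == "auto":
            bps, fits = _periodicity.scan_breakpoints(corrected)
            whole = _periodicity.fit_sinusoid(corrected) if bps else fits[0]
        else:
            bps = tuple(config.breakpoints)
            fits, whole = _periodicity.fit_segments(corrected, bps)
        return corrected, bps, fits, whole
    corrected, bps, fits, whole = stage("periodicity")(_periodicity_stage)
    import pandas as pd
    pd.DataFrame({"position": corrected.positions, "corrected": corrected.values,
                  "filled": corrected.fill_mask}).to_csv(
        outdir / "corrected.csv", index=False)
    report["periodicity"] = {
        "breakpoints": list(bps),
        "segments": [dict(_periodicity.assign_structure(f), a=f.a, c=f.c,
                          r=f.r, sse=f.sse) for f in fits],
        "single_segment": {"b": whole.b, "r": whole.r, "sse": whole.sse},
    }

    # --- titration / calibration ---
    if curves:
        def _titration_stage():
            fits_ = [_titration.fit_one_site(c) for c in curves]
            for f in fits_:
                if f.poorly_constrained:
                    report["warnings"].append(
                        f"Kd poorly constrained for {f.variant_id}")
            pairs = [(curve_scores[f.variant_id], f.kd) for f in fits_
                     if f.variant_id in curve_scores]
            cal = _titration.calibrate_kd(pairs) if len(pairs) >= 3 else None
            return fits_, cal
        tfits, cal = stage("titration")(_titration_stage)
        report["titration"] = {
            f.variant_id: {"kd_nM": f.kd, "se_kd": f.se_kd, "bmax": f.bmax}
            for f in tfits}
        if cal is not None:
            report["calibration"] = {"slope": cal.slope, "intercept": cal.intercept,
                                     "r": cal.r, "n": cal.n}

    # --- conservation ---
    if config.conservation_path is not None:
        cons = stage("conserve")(lambda: _scan_data.read_conservation(
            config.conservation_path))
        rep = stage("conserve")(lambda: _conservation.correlate_conservation(
            scores, cons))
        report["conservation"] = rep.to_dict()

    if truth_labels is not None:
        called = set(report["classification"]["interface_positions"])
        truth_if = {int(p) for p, v in truth_labels.items() if v["interface"]}
        tp = len(called & truth_if)
        prec = tp / len(called) if called else 0.0
        rec = tp / len(truth_if) if truth_if else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        report["truth_evaluation"] = {"precision": prec, "recall": rec, "f1": f1}

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
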