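"""Synthetic scan panels and titrations with recorded ground truth.

The generator emulates a yeast-surface-display charged-scanning experiment
so every pipeline stage can be exercised end-to-end without external data:

* per-cell expression fluorescence is log-normal (display-level spread);
* each mutant has a true binding free-energy penalty ΔΔG laid out along the
  sequence as a rectified sinusoid over one or more interface segments —
  ``ΔΔG(pos) = max(0, base + amp*sin(2π·pos/period + phase))`` — encoding a
  helix with one face contacting the partner (the rectified half of the
  cycle faces away and is unperturbed);
* the mutant dissociation constant is ``Kd = Kd_wt * exp(ΔΔG/RT)`` and the
  fraction bound at probe concentration L is ``f = L/(Kd+L)``;
* per-cell binding fluorescence is ``f × expression`` with multiplicative
  noise plus additive autofluorescence floored at zero;
* two biological replicates of 10,000 cells each are summarized to MFIs
  exactly as the scoring stage expects.

Default effect sizes are calibrated so that a noise-free panel reproduces
the class structure observed in charged scans of a toxin-antitoxin
interface (binding-defective class mean MFI_ratio near 0.6, roughly half
the scanned positions carrying a detectable effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan_data import MutantRecord, ScanPanel, TitrationCurve, WT_LABEL

__all__ = ["InterfaceSegment", "NoiseModel", "GroundTruth", "mutant_ddg",
           "expected_mfi_ratio", "simulate_scan_panel", "simulate_titration",
           "default_concentrations", "SYNTHETIC_WT_SEQUENCE"]

#: Synthetic 82-residue antitoxin-like sequence used for WT residue labels.
#: Asp occurs at four positions (38, 57, 65, 70; 1-based) inside the scanned
#: window, so an Asp scan naturally leaves those positions without data.
SYNTHETIC_WT_SEQUENCE = (
    "MSKTNLAQVREGSLIELAEGQVKRVMTVQAK"   # 1-31
    "AGSLEHDLVAQFNELSAEGNVLMKTDTSGAE"   # 32-62
    "QLDVSGEDLFAEVTGLMKEH"              # 63-82
)
assert len(SYNTHETIC_WT_SEQUENCE) == 82


@dataclass(frozen=True)
class InterfaceSegment:
    """One contiguous ground-truth interface stretch.

    ``ddg_base``/``ddg_amp`` are in kcal/mol; ``period`` in residues per
    cycle; ``phase`` in radians. The per-position penalty is
    ``max(0, ddg_base + ddg_amp*sin(2π·pos/period + phase))``.
    """

    first: int
    last: int
    ddg_base: float
    ddg_amp: float
    period: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("empty segment")
        if self.ddg_base < 0 or self.ddg_amp < 0:
            raise ValueError("ddg_base and ddg_amp must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated cytometry readout.

    ``expr_lognorm_mu``/``sigma`` parameterize per-cell expression
    fluorescence (natural-log scale); ``bind_cv`` is the per-cell
    multiplicative CV of the binding stain; autofluorescence is additive
    Gaussian on the binding channel, floored at zero after summation.
    """

    expr_lognorm_mu: float = float(np.log(1000.0))
    expr_lognorm_sigma: float = 0.5
    bind_cv: float = 0.2
    autofluor_mean: float = 25.0
    autofluor_sd: float = 25.0

    def __post_init__(self) -> None:
        for name in ("expr_lognorm_sigma", "bind_cv", "autofluor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """A noise-free readout (point-mass expression, no stain noise)."""
        return cls(expr_lognorm_sigma=0.0, bind_cv=0.0,
                   autofluor_mean=0.0, autofluor_sd=0.0)


#: Default interface geometry: a distorted N-terminal stretch, a canonical
#: helix, and a weakly contributing C-terminal stretch.
DEFAULT_SEGMENTS = (
    InterfaceSegment(31, 44, ddg_base=0.25, ddg_amp=0.75, period=4.0, phase=0.5),
    InterfaceSegment(45, 66, ddg_base=0.30, ddg_amp=0.90, period=3.6, phase=1.0),
    InterfaceSegment(67, 82, ddg_base=0.10, ddg_amp=0.45, period=3.3, phase=2.0),
)

#: Thermal energy RT at 25 °C, kcal/mol.
RT_KCAL = 0.593


@dataclass(frozen=True)
class GroundTruth:
    """Complete specification of a simulated scanning experiment."""

    kd_wt: float = 1.0                       # nM (dimer)
    probe_conc: float = 1.0                  # nM, binding-stain ligand conc
    rt: float = RT_KCAL                      # kcal/mol
    interface_segments: tuple[InterfaceSegment, ...] = DEFAULT_SEGMENTS
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_cells: int = 10_000
    n_replicates: int = 2
    seed: int = 0
    window: tuple[int, int] = (31, 82)
    ddg_call: float = 0.25                   # kcal/mol; truth-label floor
    bind_scale: float = 1.0                  # binding-channel gain

    def __post_init__(self) -> None:
        if self.kd_wt <= 0 or self.probe_conc <= 0 or self.rt <= 0:
            raise ValueError("kd_wt, probe_conc and rt must be positive")
        if self.n_cells < 100:
            raise ValueError("n_cells must be >= 100")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def kd_of(self, ddg: float) -> float:
        """Mutant Kd (nM) from its binding penalty."""
        return self.kd_wt * float(np.exp(ddg / self.rt))

    def fraction_bound(self, kd: float) -> float:
        return self.probe_conc / (kd + self.probe_conc)


def mutant_ddg(truth: GroundTruth, position: int) -> float:
    """Ground-truth ΔΔG (kcal/mol) of a charged substitution at a position.

    Zero outside every interface segment; inside, the rectified sinusoid of
    the first segment containing the position.
    """
    first, last = truth.window
    if not (first <= position <= last):
        raise ValueError(f"position {position} outside window {first}..{last}")
    for seg in truth.interface_segments:
        if seg.first <= position <= seg.last:
            raw = seg.ddg_base + seg.ddg_amp * np.sin(
                2 * np.pi * position / seg.period + seg.phase)
            return float(max(0.0, raw))
    return 0.0


def expected_mfi_ratio(truth: GroundTruth, ddg: float) -> float:
    """Noise-free expected normalized binding score for a penalty ΔΔG.

    Equals ``f_mut / f_wt`` with ``f = L/(Kd+L)``; 1 for ΔΔG = 0.
    """
    f_mut = truth.fraction_bound(truth.kd_of(ddg))
    f_wt = truth.fraction_bound(truth.kd_wt)
    return f_mut / f_wt


def _simulate_mfis(truth: GroundTruth, f_bound: float,
                   rng: np.random.Generator) -> tuple[float, float, float]:
    """(expression_mfi, binding_mfi, ratio_mfi) for one construct/replicate."""
    nz = truth.noise
    n = truth.n_cells
    if nz.expr_lognorm_sigma > 0:
        expr = rng.lognormal(nz.expr_lognorm_mu, nz.expr_lognorm_sigma, size=n)
    else:
        expr = np.full(n, np.exp(nz.expr_lognorm_mu))
    eps = rng.normal(0.0, nz.bind_cv, size=n) if nz.bind_cv > 0 else 0.0
    auto = (rng.normal(nz.autofluor_mean, nz.autofluor_sd, size=n)
            if nz.autofluor_sd > 0 else nz.autofluor_mean)
    bind = np.maximum(truth.bind_scale * f_bound * expr * (1.0 + eps) + auto, 0.0)
    return float(expr.mean()), float(bind.mean()), float(np.mean(bind / expr))


def _default_design(truth: GroundTruth, substitution: str = "D",
                    fallback: str = "R") -> list[tuple[int, str]]:
    """Asp at every window position; positions whose WT residue is already
    Asp get the opposite charge (Arg) instead, as in a real charged scan."""
    first, last = truth.window
    design = []
    for pos in range(first, last + 1):
        wt = SYNTHETIC_WT_SEQUENCE[pos - 1]
        design.append((pos, substitution if wt != substitution else fallback))
    return design


def simulate_scan_panel(
    truth: GroundTruth,
    design: list[tuple[int, str]] | None = None,
) -> tuple[ScanPanel, dict[int, dict]]:
    """Simulate a full scan panel and return it with per-position truth.

    ``design`` lists (position, substituted_aa) pairs; by default every
    window position is substituted to Asp, except positions whose synthetic
    WT residue is already Asp, which get Arg (an Asp scan cannot probe
    them, but the opposite charge can). Replicates share the ground truth
    but draw independent cells.

    Returns
    -------
    panel : ScanPanel
    labels : {position: {"ddg", "kd", "interface"}} — ``interface`` is True
        where ΔΔG >= ``truth.ddg_call``, the generator's detectable-effect
        floor.
    """
    if design is None:
        design = _default_design(truth)
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    f_wt = truth.fraction_bound(truth.kd_wt)
    first, last = truth.window
    wt_aa_first = SYNTHETIC_WT_SEQUENCE[first - 1]
    records: list[MutantRecord] = []
    for rep in range(1, truth.n_replicates + 1):
        e, b, r = _simulate_mfis(truth, f_wt, rng)
        records.append(MutantRecord(position=first, wt_aa=wt_aa_first,
                                    mut_aa=WT_LABEL, replicate=rep,
                                    expression_mfi=e, binding_mfi=b, ratio_mfi=r))
        for pos, mut_aa in design:
            ddg = mutant_ddg(truth, pos)
            f_mut = truth.fraction_bound(truth.kd_of(ddg))
            e, b, r = _simulate_mfis(truth, f_mut, rng)
            records.append(MutantRecord(
                position=pos, wt_aa=SYNTHETIC_WT_SEQUENCE[pos - 1],
                mut_aa=mut_aa, replicate=rep,
                expression_mfi=e, binding_mfi=b, ratio_mfi=r))
    labels = {}
    for pos in range(first, last + 1):
        ddg = mutant_ddg(truth, pos)
        labels[pos] = {"ddg": ddg, "kd": truth.kd_of(ddg),
                       "interface": ddg >= truth.ddg_call}
    panel = ScanPanel(records=tuple(records), sequence_window=truth.window,
                      ligand_conc=truth.probe_conc)
    return panel, labels


def default_concentrations(n: int = 16, low: float = 3.5e-5,
                           high: float = 500.0) -> np.ndarray:
    """Log-spaced titration design (nM): 16 points, 35 fM to 500 nM."""
    return np.geomspace(low, high, n)


def simulate_titration(
    truth: GroundTruth,
    ddg: float,
    concentrations=None,
    bmax: float = 1000.0,
    noise_cv: float = 0.05,
    variant_id: str = "synthetic",
    seed: int | None = None,
) -> TitrationCurve:
    """Simulate a titration of one variant over a concentration series.

    MFI([L]) = Bmax·[L]/(Kd+[L]) with multiplicative Gaussian noise of CV
    ``noise_cv`` (0 gives the exact hyperbola). Kd comes from the truth's
    ΔΔG→Kd map. ``seed`` defaults to the truth's seed.
    """
    conc = np.asarray(default_concentrations() if concentrations is None
                      else concentrations, dtype=float)
    kd = truth.kd_of(ddg)
    mfi = bmax * conc / (kd + conc)
    if noise_cv > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(truth.seed if seed is None else seed))
        mfi = mfi * (1.0 + rng.normal(0.0, noise_cv, size=conc.size))
    mfi = np.maximum(mfi, 0.0)
    return TitrationCurve(variant_id=variant_id,
                          concentrations=tuple(conc),
                          binding_mfi=tuple(float(v) for v in mfi))
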