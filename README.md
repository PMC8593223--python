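# scanmap

Charged-residue scanning mutagenesis is a fast way to map where an
intrinsically disordered protein (IDP) touches its binding partner and what
local structure it adopts on binding. Each residue of the disordered
segment is mutated to aspartate (and selected positions to arginine), the
mutant is displayed on the yeast cell surface, and binding of a labelled
partner protein is read by flow cytometry alongside surface expression.
Positions where a charged substitution wrecks binding are interface
residues; and because a bound helix contacts the partner with one face,
binding defects oscillate along the sequence with the helical repeat.

`scanmap` is the analysis side of that experiment, built for
toxin–antitoxin-style systems (a disordered antitoxin segment binding its
toxin) but agnostic to the biology. From exported mean fluorescence
intensities (MFIs) it computes, per mutant:

* `MFI_exp = expression MFI(mutant) / expression MFI(WT)` — relative
  surface expression;
* `MFI_ratio` — the mean binding:expression fluorescence ratio normalized
  to WT (1 = WT-like binding), averaged over replicates;

and then:

* **interface calls** — exact 1-D 2-means clustering of Asp scores into a
  WT-like class (mean μ₁, sd σ₁) and a binding-defective class; a residue
  is called when any charged substitution scores below μ₁ − σ₁;
* **local structure** — WT-fill of unmeasured positions, subtraction of a
  5-residue sliding-window mean, and segment-wise least-squares fits of
  `y = a·sin(2πx/b + c)`; periodicity b ≈ 3.6 residues/cycle reads out an
  α-helix, b ≈ 2 a strand-like register;
* **binding energetics** — one-site fits `MFI = Bmax·[L]/(Kd+[L])` to
  titrations over femtomolar–nanomolar ligand (dimer) concentrations, and a
  linear calibration of experimental Kd against `MFI_ratio` that converts
  scores of unmeasured mutants into apparent Kd values;
* **conservation** — Pearson/Spearman correlation of per-position scores
  with a pre-computed conservation table (ConSurf-style export).

A synthetic-data generator simulates the whole measurement (log-normal
per-cell expression, binding proportional to fraction bound, additive
autofluorescence, two replicates of 10,000 cells) from a ground-truth
interface geometry with helical-face ΔΔG modulation, so the entire pipeline
is testable without any experimental data. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Simulate a scan of residues 31–82 with the default ground truth (a
distorted helix at 31–44, a canonical α-helix at 45–66, a weak C-terminal
stretch at 67–82), then score, classify and fit periodicities:

```sh
scanmap run --seed 1 --out out/
python -m json.tool out/report.json | less
```

Key fields of `out/report.json` from this exact command:

```
"classification": {
  "class1_mean": 0.967,  "class1_sd": 0.083,
  "class2_mean": 0.481,  "class2_sd": 0.128,
  "threshold": 0.884,    "n_interface": 24, ...
}
"periodicity": { "segments": [
  {"segment": [31, 44], "periodicity": 3.93, "label": "alpha-helix", "r": 0.99},
  {"segment": [45, 66], "periodicity": 3.64, "label": "alpha-helix", "r": 0.92},
  {"segment": [67, 82], "periodicity": 3.31, "label": "alpha-helix", "r": 0.97}],
  "single_segment": {"b": 3.56, "r": 0.84, ...}}
"truth_evaluation": {"precision": 0.96, "recall": 0.92, "f1": 0.94}
```

Reading it: the 2-means split of Asp scores puts the WT-like class at
0.97 ± 0.08, so mutants scoring below 0.88 are called binding-defective —
24 of the 52 scanned positions, recovering the generator's true interface
with F1 0.94. The three segment fits return periodicities 3.93, 3.64 and
3.31 residues/cycle (generator truth 4.0, 3.6, 3.3) — all in the helical
band — while the single global sinusoid fits worse (r 0.84, with triple
the summed per-segment residual), the signature of phase changes between
segments. Each stage is also available standalone (`scanmap score`,
`classify`, `periodicity`, `titrate`, `calibrate`, `conserve`,
`simulate`) on plain CSV intermediates.

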