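"""Data model and file I/O for mutational scan panels, titrations, and conservation tables.

Scan panels hold per-mutant, per-replicate mean fluorescence intensities (MFI)
from a yeast-surface-display binding assay: an expression channel (epitope-tag
stain) and a binding channel (labelled ligand), or their per-cell ratio. All
downstream scoring, classification, and curve fitting consume the types defined
here.

Units: fluorescence intensities are arbitrary instrument units; ligand
concentrations are held internally in nM (readers convert from a declared
unit column).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MutantRecord",
    "ScanPanel",
    "TitrationCurve",
    "ConservationTable",
    "ScanFormatError",
    "read_scan_table",
    "write_scan_table",
    "read_titration",
    "write_titration",
    "read_conservation",
    "write_conservation",
    "CONC_UNIT_FACTORS",
]

#: Multiplicative factors converting a declared concentration unit to nM.
CONC_UNIT_FACTORS: Mapping[str, float] = {
    "fM": 1e-6,
    "pM": 1e-3,
    "nM": 1.0,
    "uM": 1e3,
    "µM": 1e3,
    "mM": 1e6,
    "M": 1e9,
}

#: Sentinel amino-acid label for the wild-type reference construct.
WT_LABEL = "WT"

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class ScanFormatError(ValueError):
    """Raised when an input table violates the scan-data contract.

    The message names the offending row (1-based, excluding the header)
    and the rule that failed; nothing is silently coerced.
    """


@dataclass(frozen=True)
class MutantRecord:
    """One (mutant, replicate) measurement from a scan panel.

    ``mut_aa`` is a one-letter amino-acid code, or ``"WT"`` for the
    reference construct. ``ratio_mfi`` is the mean over cells of the
    per-cell binding:expression intensity ratio; it is optional when only
    channel MFIs were exported.
    """

    position: int
    wt_aa: str
    mut_aa: str
    replicate: int
    expression_mfi: float
    binding_mfi: float
    ratio_mfi: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ScanFormatError(f"position must be >= 1, got {self.position}")
        if self.wt_aa not in _AA:
            raise ScanFormatError(f"wt_aa {self.wt_aa!r} is not a one-letter amino acid")
        if self.mut_aa != WT_LABEL and self.mut_aa not in _AA:
            raise ScanFormatError(f"mut_aa {self.mut_aa!r} is not a one-letter amino acid or 'WT'")
        if self.mut_aa == self.wt_aa:
            raise ScanFormatError(
                f"mut_aa equals wt_aa ({self.wt_aa!r}) at position {self.position}; "
                f"use mut_aa='WT' for the reference construct"
            )
        if not self.expression_mfi > 0:
            raise ScanFormatError(f"expression_mfi must be > 0, got {self.expression_mfi}")
        if self.binding_mfi < 0:
            raise ScanFormatError(f"binding_mfi must be >= 0, got {self.binding_mfi}")
        if self.ratio_mfi is not None and self.ratio_mfi < 0:
            raise ScanFormatError(f"ratio_mfi must be >= 0, got {self.ratio_mfi}")

    @property
    def is_wt(self) -> bool:
        return self.mut_aa == WT_LABEL


@dataclass(frozen=True)
class ScanPanel:
    """A full scanning-mutagenesis panel: mutant records plus WT references.

    Parameters
    ----------
    records
        All measurements, including the WT reference rows.
    sequence_window
        ``(first, last)`` residue positions covered by the scan, inclusive.
    ligand_conc
        Probe (ligand) concentration used for the binding stain, in nM.
    """

    records: tuple[MutantRecord, ...]
    sequence_window: tuple[int, int]
    ligand_conc: float

    def __post_init__(self) -> None:
        first, last = self.sequence_window
        if first > last:
            raise ScanFormatError(f"empty sequence window {self.sequence_window}")
        replicates = {r.replicate for r in self.records}
        wt_reps = {r.replicate for r in self.records if r.is_wt}
        missing = sorted(replicates - wt_reps)
        if missing:
            raise ScanFormatError(
                f"no WT reference for replicate {', '.join(map(str, missing))}"
            )
        seen: set[tuple[int, str, int]] = set()
        for r in self.records:
            if not r.is_wt and not (first <= r.position <= last):
                raise ScanFormatError(
                    f"position {r.position} outside sequence window {first}..{last}"
                )
            key = (r.position, r.mut_aa, r.replicate)
            if key in seen:
                raise ScanFormatError(
                    f"duplicate record for position {r.position}, mut_aa {r.mut_aa}, "
                    f"replicate {r.replicate}"
                )
            seen.add(key)

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(sorted({r.replicate for r in self.records}))

    @property
    def wt_records(self) -> tuple[MutantRecord, ...]:
        return tuple(r for r in self.records if r.is_wt)

    def mutants(self) -> tuple[MutantRecord, ...]:
        return tuple(r for r in self.records if not r.is_wt)


@dataclass(frozen=True)
class TitrationCurve:
    """Binding MFI versus ligand (dimer) concentration for one variant.

    Concentrations are in nM, strictly positive and strictly increasing;
    at least 4 points are required so a two-parameter saturation model is
    over-determined.
    """

    variant_id: str
    concentrations: tuple[float, ...]
    binding_mfi: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        mfi = np.asarray(self.binding_mfi, dtype=float)
        if conc.size != mfi.size:
            raise ScanFormatError(
                f"{conc.size} concentrations but {mfi.size} MFI values"
            )
        if conc.size < 4:
            raise ScanFormatError(f"need >= 4 titration points, got {conc.size}")
        if np.any(conc <= 0):
            raise ScanFormatError("non-positive ligand concentration")
        if np.any(np.diff(conc) <= 0):
            raise ScanFormatError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(mfi)):
            raise ScanFormatError("non-finite binding MFI")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class ConservationTable:
    """Per-position evolutionary conservation scores (ConSurf-style export)."""

    positions: tuple[int, ...]
    scores: tuple[float, ...]
    aa_frequencies: Mapping[int, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.scores):
            raise ScanFormatError("positions and scores differ in length")
        if len(set(self.positions)) != len(self.positions):
            raise ScanFormatError("duplicate position in conservation table")
        if not np.all(np.isfinite(np.asarray(self.scores, dtype=float))):
            raise ScanFormatError("non-finite conservation score")

    def __len__(self) -> int:
        return len(self.positions)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.positions, name="position"),
                         name="conservation")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ("position", "wt_aa", "mut_aa", "replicate",
                 "expression_mfi", "binding_mfi")


def _remap(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename columns from a user dialect map {canonical: actual}."""
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # round_trip parsing so write->read preserves float64 bit-exactly
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_scan_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sequence_window: tuple[int, int] | None = None,
    ligand_conc: float = 1.0,
) -> ScanPanel:
    """Read a scan-panel CSV/TSV into a validated :class:`ScanPanel`.

    Expected columns: ``position, wt_aa, mut_aa, replicate, expression_mfi,
    binding_mfi[, ratio_mfi]``; WT reference rows use ``mut_aa=WT``.
    ``dialect`` maps canonical column names to the names actually present
    (FACS software exports vary). If ``sequence_window`` is omitted it is
    taken as the min..max mutant position in the file.

    Raises :class:`ScanFormatError` with a row-numbered diagnostic on any
    invariant violation; a missing WT reference or duplicate
    (position, mut_aa, replicate) is a hard error.
    """
    df = _remap(_read_table(path), dialect)
    missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ScanFormatError(f"{path}: missing required column(s) {missing}")
    has_ratio = "ratio_mfi" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ratio = getattr(row, "ratio_mfi", None) if has_ratio else None
            if ratio is not None and (pd.isna(ratio)):
                ratio = None
            records.append(MutantRecord(
                position=int(row.position),
                wt_aa=str(row.wt_aa),
                mut_aa=str(row.mut_aa),
                replicate=int(row.replicate),
                expression_mfi=float(row.expression_mfi),
                binding_mfi=float(row.binding_mfi),
                ratio_mfi=None if ratio is None else float(ratio),
            ))
        except (ScanFormatError, ValueError) as exc:
            raise ScanFormatError(f"{path}: row {i}: {exc}") from exc
    if sequence_window is None:
        muts = [r.position for r in records if not r.is_wt]
        if not muts:
            raise ScanFormatError(f"{path}: no mutant rows")
        sequence_window = (min(muts), max(muts))
    return ScanPanel(records=tuple(records), sequence_window=sequence_window,
                     ligand_conc=ligand_conc)


# %.17g preserves float64 exactly, so write/read round-trips bit-for-bit
_FLOAT_FMT = "%.17g"


def write_scan_table(panel: ScanPanel, path: str | Path) -> None:
    """Write a ScanPanel back to CSV in the canonical column layout."""
    rows = [dataclasses.asdict(r) for r in panel.records]
    df = pd.DataFrame(rows, columns=list(_SCAN_COLUMNS) + ["ratio_mfi"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_titration(
    path: str | Path,
    variant_id: str | None = None,
    dialect: Mapping[str, str] | None = None,
) -> TitrationCurve:
    """Read a titration CSV (columns ``conc, unit, binding_mfi``) into nM.

    Rows may arrive in any order; they are re-sorted by ascending
    concentration with their paired MFIs. A ``unit`` column (fM/pM/nM/uM/...)
    is converted to nM; if absent, concentrations are assumed nM. A
    ``variant_id`` column, or the argument, labels the curve.
    """
    df = _remap(_read_table(path), dialect)
    for col in ("conc", "binding_mfi"):
        if col not in df.columns:
            raise ScanFormatError(f"{path}: missing required column {col!r}")
    conc = df["conc"].astype(float).to_numpy()
    if "unit" in df.columns:
        try:
            factors = df["unit"].map(CONC_UNIT_FACTORS).astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ScanFormatError(f"{path}: unknown concentration unit") from exc
        if np.any(~np.isfinite(factors)):
            bad = df["unit"][~np.isfinite(factors)].iloc[0]
            raise ScanFormatError(f"{path}: unknown concentration unit {bad!r}")
        conc = conc * factors
    if variant_id is None:
        variant_id = str(df["variant_id"].iloc[0]) if "variant_id" in df.columns else Path(path).stem
    order = np.argsort(conc, kind="stable")
    mfi = df["binding_mfi"].astype(float).to_numpy()[order]
    return TitrationCurve(variant_id=variant_id,
                          concentrations=tuple(conc[order]),
                          binding_mfi=tuple(mfi))


def write_titration(curve: TitrationCurve, path: str | Path) -> None:
    pd.DataFrame({
        "variant_id": curve.variant_id,
        "conc": curve.concentrations,
        "unit": "nM",
        "binding_mfi": curve.binding_mfi,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_conservation(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> ConservationTable:
    """Read a per-position conservation TSV (columns ``position, score``)."""
    df = _remap(_read_table(path), dialect)
    for col in ("position", "score"):
        if col not in df.columns:
            raise ScanFormatError(f"{path}: missing required column {col!r}")
    df = df.sort_values("position", kind="stable")
    return ConservationTable(
        positions=tuple(int(p) for p in df["position"]),
        scores=tuple(float(s) for s in df["score"]),
    )


def write_conservation(table: ConservationTable, path: str | Path) -> None:
    pd.DataFrame({"position": table.positions, "score": table.scores}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
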