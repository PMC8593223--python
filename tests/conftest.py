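import numpy as np
import pytest

from scanmap import GroundTruth, InterfaceSegment, NoiseModel
from scanmap.scan_data import MutantRecord, ScanPanel


def make_panel(mutant_rows, wt_rows, window=None, ligand_conc=1.0):
    """Build a ScanPanel from compact tuples.

    mutant_rows: (position, wt_aa, mut_aa, replicate, expr, bind[, ratio])
    wt_rows:     (replicate, expr, bind[, ratio])
    """
    records = []
    for row in wt_rows:
        rep, expr, bind, *ratio = row
        records.append(MutantRecord(position=window[0] if window else 1,
                                    wt_aa="A", mut_aa="WT", replicate=rep,
                                    expression_mfi=expr, binding_mfi=bind,
                                    ratio_mfi=ratio[0] if ratio else None))
    for row in mutant_rows:
        pos, wt, mut, rep, expr, bind, *ratio = row
        records.append(MutantRecord(position=pos, wt_aa=wt, mut_aa=mut,
                                    replicate=rep, expression_mfi=expr,
                                    binding_mfi=bind,
                                    ratio_mfi=ratio[0] if ratio else None))
    if window is None:
        pos = [r.position for r in records if not r.is_wt]
        window = (min(pos), max(pos))
    return ScanPanel(records=tuple(records), sequence_window=window,
                     ligand_conc=ligand_conc)


@pytest.fixture
def zero_noise_truth():
    """Deterministic readout: scores equal the closed-form bound fractions."""
    return GroundTruth(noise=NoiseModel.zero(), n_cells=100, seed=0)


@pytest.fixture
def helix_truth():
    """Single 22-residue canonical-helix interface, default noise."""
    return GroundTruth(interface_segments=(
        InterfaceSegment(45, 66, ddg_base=0.30, ddg_amp=0.90,
                         period=3.6, phase=1.0),), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
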