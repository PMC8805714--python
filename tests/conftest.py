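import numpy as np
import pytest

from complexmr.instruments import HarmonizedInstrument, InstrumentSet


def make_instrument_set(bx, by, sy, sx=None, label="exposure", outcome="outcome"):
    """Build an InstrumentSet directly from effect/SE arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.05) if sx is None else np.asarray(sx, dtype=float)
    insts = tuple(
        HarmonizedInstrument(
            snp_id=f"rs{i + 1}", gene_id="GENE1",
            beta_exp=float(bx[i]), se_exp=float(sx[i]),
            beta_out=float(by[i]), se_out=float(sy[i]), eaf=0.3,
        )
        for i in range(len(bx))
    )
    return InstrumentSet(exposure_label=label, outcome_label=outcome, instruments=insts)


@pytest.fixture
def toy_set():
    """Three instruments with unit ratios (beta_Y = 0.5 * beta_X exactly)."""
    bx = [1.0, 2.0, 0.5]
    return make_instrument_set(bx, [0.5, 1.0, 0.25], [0.1, 0.1, 0.1])


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
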