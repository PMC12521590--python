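import numpy as np
import pytest

from terminome_miner.io_formats import PipelineConfig, ProteinRecord, SampleDesign
from terminome_miner.synthetic_data import (ProteaseSpec, SimulationConfig,
                                            default_proteases, make_design)

AA = "ACDEFGHIKLMNPQRSTVWY"


def quiet_config(**kw) -> SimulationConfig:
    """Simulation conditions for the perfect-recovery limit: no missingness,
    every planted terminus present in every subject, no decoys."""
    specs = [ProteaseSpec(s.model, s.site_rate, {g: 1.0 for g in s.occurrence},
                          s.log2_effect) for s in default_proteases()]
    defaults = dict(seed=1, n_proteins=20, proteases=specs, decoy_rate=0.0,
                    missing_intercept=-50.0, missing_slope=0.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def design8():
    return make_design(8)


@pytest.fixture
def design4():
    return make_design(4)


def random_protein(rng: np.random.Generator, length: int, accession: str = "P1",
                   signal_end: int | None = None) -> ProteinRecord:
    seq = "M" + "".join(AA[i] for i in rng.integers(0, 20, length - 1))
    return ProteinRecord(accession, seq, signal_end)


@pytest.fixture
def osteopontin_like():
    """A secreted-protein stand-in (synthetic sequence): signal peptide ending
    at residue 16 and a known protease-susceptible bond after residue 185
    with a non-K/R P1 residue."""
    rng = np.random.default_rng(10451)
    seq = list("M" + "".join(AA[i] for i in rng.integers(0, 20, 249)))
    seq[184] = "T"  # P1 of the endogenous cleavage (residue 185)
    seq[185:193] = list("AIPVQADR")  # fragment 186..193, tryptic C boundary
    return ProteinRecord("P10451X", "".join(seq), signal_end=16)
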