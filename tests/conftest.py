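import numpy as np
import pandas as pd
import pytest

from clonoscope.simulate import (GroupSpec, NoiseConfig, SyntheticConfig,
                                 simulate_repertoire)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free two-group TCR simulation shared by recovery tests."""
    config = SyntheticConfig(
        groups={"AD": GroupSpec(3, 600), "NC": GroupSpec(2, 600)},
        n_background_clones=400, noise=NoiseConfig(0.0, 0.0, 0.0), seed=11)
    contigs, meta, truth = simulate_repertoire(config)
    return contigs, meta, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Simulation with every noise channel on."""
    config = SyntheticConfig(
        groups={"AD": GroupSpec(2, 1000), "NC": GroupSpec(2, 1000)},
        n_background_clones=500,
        noise=NoiseConfig(0.1, 0.1, 0.05), seed=23)
    contigs, meta, truth = simulate_repertoire(config)
    return contigs, meta, truth


def make_contig_row(**overrides) -> dict:
    """One canonical-schema contig row with sensible defaults."""
    row = dict(barcode="S1_AAAC-1", sample_id="S1", locus="TRB",
               v_gene="TRBV9", d_gene=None, j_gene="TRBJ2-1", c_gene="TRBC2",
               cdr3_aa="CASSL", cdr3_nt="TGTGCAAGCAGCTTA", umis=4, reads=60,
               productive=True, high_confidence=True, full_length=True,
               is_cell=True, raw_contig_id="AAAC-1_contig_1")
    row.update(overrides)
    return row


def contig_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_contig_row(**r) for r in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
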