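import numpy as np
import pandas as pd
import pytest

import phosphoquant as pq


@pytest.fixture(scope="session")
def design1() -> pq.DesignTable:
    """Single 8-plex: 4 cases, tumor on the first channel of each pair."""
    return pq.paired_design(n_plexes=1, cases_per_plex=4)


@pytest.fixture(scope="session")
def design3() -> pq.DesignTable:
    """Three 8-plexes, 12 cases, alternating T/NT orientation."""
    return pq.paired_design(n_plexes=3, cases_per_plex=4)


def make_record(
    design: pq.DesignTable,
    psm_id: str = "psm1",
    sequence: str = "LSESVKAR",
    phospho_positions=(3,),
    accessions=("P0001",),
    plex: str | None = None,
    arm: str = "imac",
    fraction: int = 1,
    run: int = 1,
    q_value: float = 0.01,
    phosphors_probability: float | None = 0.95,
    intensities=None,
) -> pq.PSMRecord:
    """Record factory with complete, positive channels unless overridden."""
    plex = plex or design.plexes[0]
    channels = design.channels(plex)
    if intensities is None:
        intensities = {ch: 100.0 for ch in channels}
    elif not isinstance(intensities, dict):
        intensities = dict(zip(channels, intensities))
    if not phospho_positions:
        phosphors_probability = None
    rec = pq.PSMRecord(
        psm_id=psm_id,
        sequence=sequence,
        phospho_positions=tuple(phospho_positions),
        protein_accessions=tuple(accessions),
        plex=plex,
        arm=arm,
        fraction=fraction,
        run=run,
        q_value=q_value,
        phosphors_probability=phosphors_probability,
        intensities=intensities,
    )
    rec.validate(design)
    return rec


@pytest.fixture(scope="session")
def small_sim() -> pq.SimResult:
    """Modest synthetic dataset shared by integration-style tests."""
    cfg = pq.SimConfig(n_proteins=80, seed=42)
    return pq.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_sim) -> pq.AnalysisResult:
    return pq.analyze(small_sim.records, small_sim.design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
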