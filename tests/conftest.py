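import numpy as np
import pandas as pd
import pytest

import fetoquant as fq
from fetoquant import simulate as sim

PANEL = ("CEACAM1", "CNDP1", "CRP", "IGHG4", "IGHA2")


@pytest.fixture(scope="session")
def registry():
    return fq.build_ups2_registry()


@pytest.fixture(scope="session")
def noise():
    return fq.NoiseModel(seed=20240917)


@pytest.fixture(scope="session")
def replicates(registry, noise):
    return fq.simulate_calibration_replicates(registry, noise=noise)


@pytest.fixture(scope="session")
def fitted_curve(replicates):
    return fq.calibrate(replicates)


@pytest.fixture(scope="session")
def cohort(noise):
    return fq.simulate_cohort(fq.default_group_specs(PANEL), noise=noise)


@pytest.fixture(scope="session")
def manifest(cohort):
    return sim.manifest_from_cohort(cohort)


@pytest.fixture(scope="session")
def peptide_table(cohort, noise):
    return fq.forward_model_intensities(cohort, noise=noise)


@pytest.fixture(scope="session")
def marker_maps():
    pmap = dict(sim.default_peptide_map(PANEL))
    pmap[sim.BACKGROUND_ID] = (sim._BACKGROUND_PEPTIDE,)
    masses = {m: sim.MARKERS[m].mw_da for m in PANEL}
    lengths = {m: sim.MARKERS[m].length_aa for m in PANEL}
    lengths[sim.BACKGROUND_ID] = 500
    return pmap, masses, lengths


@pytest.fixture(scope="session")
def quant_table(fitted_curve, peptide_table, marker_maps):
    pmap, masses, lengths = marker_maps
    return fq.quantify_samples(fitted_curve, peptide_table, pmap, masses,
                               lengths)
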