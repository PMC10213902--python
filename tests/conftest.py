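"""Shared fixtures: small synthetic cohorts with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from radage import synthetic


@pytest.fixture(scope="session")
def marker_disease_design() -> synthetic.DiseaseDesign:
    """Disease cohort with one strong lung-cancer marker and one null gene set.

    Lung cancer gets a generous sampling weight so every split carries
    enough cases for one-vs-rest testing.
    """
    marker = synthetic.MarkerSpec(gene="GENE00001", disease={"lung cancer": 3.0})
    return synthetic.DiseaseDesign(
        n_per_split=(60, 60, 40),
        disease_levels=("control", "TB", "lung cancer"),
        disease_weights=(0.5, 0.25, 0.25),
        ethnicity_levels=("Caucasian", "African", "Indian subcontinent"),
        ethnicity_weights=(0.5, 0.3, 0.2),
        marker_specs=(marker,),
        n_genes=50,
        noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def marker_disease_cohort(marker_disease_design):
    return synthetic.simulate_disease_cohort(marker_disease_design, seed=11)


@pytest.fixture(scope="session")
def radiation_cohort():
    """163-sample irradiated cohort with dose-responsive genes."""
    design, effects = synthetic.radiation_cohort_design(n_genes=120)
    return synthetic.simulate_cohort(design, effects, seed=7)


@pytest.fixture()
def null_matrix():
    """200 null genes x 80 samples, two groups of 40, no signal."""
    rng = np.random.default_rng(42)
    values = rng.normal(8.0, 1.0, size=(200, 80))
    cols = [f"S{i:03d}" for i in range(80)]
    expr = pd.DataFrame(values, index=[f"G{i:04d}" for i in range(200)], columns=cols)
    return expr, cols[:40], cols[40:]
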