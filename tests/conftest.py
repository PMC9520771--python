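"""Shared fixtures: small synthetic cohorts and handcrafted objects."""

import numpy as np
import pandas as pd
import pytest

from dcsp.data import Cohort
from dcsp.pas import PASConfig, pas_matrix
from dcsp.simulate import PlantedTriplet, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_sim():
    """A 6-cancer x 12-sample cohort with one planted (drug, pathway, cancer)."""
    cfg = SimConfig(planted=(PlantedTriplet("D1", "PW1", "C1", 3.0),), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """A pure-null cohort: no planted triplets, no response coupling."""
    return simulate_cohort(SimConfig(seed=11, response_slope=0.0))


@pytest.fixture(scope="session")
def planted_pas(planted_sim):
    return pas_matrix(planted_sim.cohort, planted_sim.pathways,
                      planted_sim.drug_targets, planted_sim.drivers,
                      planted_sim.directed, planted_sim.functional, PASConfig())


@pytest.fixture()
def tiny_cohort():
    """Four genes x four samples with hand-set values for exact algebra."""
    expr = pd.DataFrame(
        [[2.0, 1.0, 0.0, 4.0],
         [3.0, 1.0, 0.0, 1.0],
         [1.0, 2.0, 0.0, 0.5],
         [5.0, 0.5, 0.0, 2.0]],
        index=["A", "B", "C", "D"],
        columns=["s1", "s2", "s3", "s4"])
    labels = pd.Series({"s1": "X", "s2": "X", "s3": "Y", "s4": "Y"})
    return Cohort(expression=expr, labels=labels, name="tiny")
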