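import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sowpop.genotypes import GenotypeMatrix
from sowpop.records import RemovalReason, SowRecord
from sowpop.sampler import BayesMarkerThresholdModel
from sowpop.synthetic import (
    SimulationScenario,
    simulate_binary_trait,
    simulate_genotypes,
    simulate_pop_records,
)


def make_record(
    sow_id="s1",
    farm="A",
    parity=2,
    insem="2016-03-01",
    farrow="2016-06-20",
    removal=None,
    removal_parity=None,
    reason=RemovalReason.NONE,
    sire="sireX",
    dam="damX",
    died=False,
    total_born=12,
):
    return SowRecord(
        sow_id=sow_id,
        farm_id=farm,
        parity=parity,
        insemination_date=dt.date.fromisoformat(insem),
        farrowing_date=dt.date.fromisoformat(farrow) if farrow else None,
        removal_date=dt.date.fromisoformat(removal) if removal else None,
        removal_parity=removal_parity,
        removal_reason=reason,
        total_born=total_born,
        sire_id=sire,
        dam_id=dam,
        died_flag=died,
    )


@pytest.fixture(scope="session")
def tiny_genotypes():
    """3 individuals x 4 markers, hand-checkable."""
    counts = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
        ]
    )
    m = pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3", "m4"],
            "chrom": ["1", "1", "2", "2"],
            "bp": [100, 900_000, 5_000, 1_200_000],
        }
    )
    return GenotypeMatrix(["a", "b", "c"], counts, m)


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic multi-parity cohort shared by records/synthetic tests."""
    scen = SimulationScenario(n_sows=2_000, n_markers=400, n_chromosomes=4, seed=11)
    geno = simulate_genotypes(scen)
    records, truth = simulate_pop_records(geno, scen)
    return scen, geno, records, truth


@pytest.fixture(scope="session")
def fitted_small_chain():
    """A real (short) threshold-model chain on a small simulated trait."""
    geno, y, hyq, truth = simulate_binary_trait(
        n=800, p=400, n_qtl=15, h2=0.4, seed=21, n_chromosomes=4
    )
    model = BayesMarkerThresholdModel(
        prior="bayes_c", pi="estimate", n_iter=1200, burn_in=300, thin=5, seed=22
    ).fit(geno, y, hyq=hyq)
    return geno, y, hyq, truth, model
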