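import pandas as pd
import pytest

import cki
from cki import dge


def _patient_expression(bundle):
    """Genes x patients log2-CPM over primary-tumor samples."""
    em = bundle.expression
    logcpm = dge.cpm_normalize(em)
    tumor = em.tumor_samples
    expr = logcpm.loc[:, tumor].copy()
    expr.columns = [em.patient_id[s] for s in tumor]
    return expr


@pytest.fixture(scope="session")
def patient_expression():
    return _patient_expression


@pytest.fixture(scope="session")
def recovery_sim():
    """Cohort with 20 composite planted genes out of 100: overexpressed
    (log2FC 2), prognostic (hazard ratio 3), stage-trending (0.5/level),
    hotspot-mutated (60% at one residue) and dependent (mean -1.5)."""
    cfg = cki.SimulationConfig(
        n_genes=100, n_tumor=200, n_normal=60, composite_fraction=0.2,
        planted_log2fc=2.0, hazard_ratio_high=3.0, stage_shift=0.5,
        hotspot_concentration=0.6, dep_mean_dependent=-1.5, censor_rate=0.3,
        seed=11,
    )
    return cki.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_scored(recovery_sim):
    bundle, manifest = recovery_sim
    cards, summary = cki.score_cohort(bundle)
    return cards, summary


@pytest.fixture(scope="session")
def null_sim():
    """No planted effects: everything downstream should stay near its
    nominal false-positive rate."""
    return cki.simulate_cohort(
        cki.SimulationConfig(n_genes=300, n_tumor=40, n_normal=40, seed=19)
    )
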