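import numpy as np
import pandas as pd
import pytest

from tescope.annotate import rip_consensus
from tescope.differential import differential_expression
from tescope.efficiency import compute_te, te_change
from tescope.io_core import ExpressionMatrix, Thresholds
from tescope.quantify import counts_to_tpm
from tescope.synthetic_data import SimParams, generate_cohort


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def default_cohort():
    """Aged-vs-young cohort at generator defaults (seed 7), no UTRs."""
    return generate_cohort(SimParams(seed=7), with_utrs=False)


@pytest.fixture(scope="session")
def kd_cohort(default_cohort):
    """Second perturbation of the same genes (reader-knockdown analog)."""
    params = SimParams(seed=1007, conditions=("control", "kd"))
    return generate_cohort(params, with_utrs=False, shared_truth=default_cohort.truth)


def analyze_contrast(cohort, thresholds):
    """counts -> TPM -> TE change + translatome DE for one two-condition cohort."""
    tl = counts_to_tpm(cohort.translatome_counts, cohort.models)
    tx = counts_to_tpm(cohort.transcriptome_counts, cohort.models)
    conds = list(dict.fromkeys(cohort.translatome_counts.condition_of_sample.values()))
    change = te_change(
        compute_te(tl, tx, conds[0], thresholds),
        compute_te(tl, tx, conds[1], thresholds),
        thresholds,
    )
    de_tl = differential_expression(
        tl, tl.samples_of(conds[0]), tl.samples_of(conds[1]), thresholds
    )
    de_tx = differential_expression(
        tx, tx.samples_of(conds[0]), tx.samples_of(conds[1]), thresholds
    )
    return {"tl": tl, "tx": tx, "change": change, "de_tl": de_tl, "de_tx": de_tx}


@pytest.fixture(scope="session")
def aged_analysis(default_cohort, thresholds):
    return analyze_contrast(default_cohort, thresholds)


@pytest.fixture(scope="session")
def kd_analysis(kd_cohort, thresholds):
    return analyze_contrast(kd_cohort, thresholds)


@pytest.fixture(scope="session")
def rip_set(default_cohort):
    return rip_consensus(default_cohort.rip_replicates)


def make_matrix(values, layer="translatome", unit="raw_count", conditions=None):
    """Small ExpressionMatrix from a dict of sample -> per-gene values."""
    df = pd.DataFrame(values)
    if conditions is None:
        conditions = {s: s.rsplit("_", 1)[0] for s in df.columns}
    return ExpressionMatrix(
        values=df.astype(float), layer=layer, unit=unit, condition_of_sample=conditions
    )
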