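"""Shared fixtures: simulated cohorts at two scales.

Session-scoped so the expensive simulations run once; tests must not mutate
fixture records in place.
"""

import pytest

from plastomics import synthetic_data as sd

SCALED = dict(lsc_len=9000, ssc_len=3500, ir_len=6000)


def scaled_params(**kw):
    base = dict(SCALED, gene_catalog=sd.default_catalog(scaled=True))
    base.update(kw)
    return sd.SimulationParams(**base)


@pytest.fixture(scope="session")
def scaled_ancestor():
    params = scaled_params(seed=101, n_taxa=4)
    record, truth = sd.simulate_ancestor(params)
    return params, record, truth


@pytest.fixture(scope="session")
def scaled_cohort():
    params = scaled_params(seed=101, n_taxa=4)
    ancestor, taxa, truth = sd.simulate_cohort(params)
    return params, ancestor, taxa, truth


@pytest.fixture(scope="session")
def full_ancestor():
    params = sd.SimulationParams(seed=202, n_taxa=1, trni_copies=3)
    record, truth = sd.simulate_ancestor(params)
    return params, record, truth


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, scaled_cohort):
    """The scaled cohort written out as GenBank flat files."""
    from plastomics import write_genbank

    _, ancestor, taxa, _ = scaled_cohort
    d = tmp_path_factory.mktemp("cohort")
    write_genbank(ancestor, d / "ancestor.gb")
    for rec in taxa:
        write_genbank(rec, d / f"{rec.taxon_id}.gb")
    return d
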