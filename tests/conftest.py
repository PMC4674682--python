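import warnings

import numpy as np
import pytest

from popepimeth.methio import adjust_mvalues, estimate_cell_proportions, filter_probes
from popepimeth.pipeline import demo_design
from popepimeth.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    design = demo_design(seed=3, n_probes=300, n_snps=1500, n_per_pop=30)
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def processed(small_cohort):
    """Filtered matrix, estimated cell proportions, covariates, adjusted M."""
    c = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, report = filter_probes(c.methyl, c.probe_annot)
        panel_probes = c.probe_annot.index[c.probe_annot["cell_predictor"]]
        props, _ = estimate_cell_proportions(c.methyl.subset_probes(panel_probes), c.panel)
        cov = c.metadata.join(props)
        terms = ["sex", "age"] + list(c.panel.cell_types)[:-1]
        adjusted = adjust_mvalues(filtered, cov, terms)
    return {
        "filtered": filtered,
        "report": report,
        "covariates": cov,
        "terms": terms,
        "adjusted": adjusted,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
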