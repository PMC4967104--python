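import pytest

from etdfallacy import designs
from etdfallacy.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def disjunction_design():
    return designs.disjunction_study()


@pytest.fixture(scope="session")
def conjunction_design():
    return designs.conjunction_study()


def make_cohort(design, experiment, n=100, seed=11, **kwargs):
    """Build a cohort with the study's intended component classes."""
    defaults = dict(
        component_classes=designs.INTENDED_CLASS[experiment],
        venn_mixture=designs.VENN_MIXTURE
        if any(g.venn_task for g in design.groups) else None,
        # CWA weight lives in (0.5, 1) for conjunctions, (0, 0.5) for disjunctions
        beta=0.3 if experiment == "disjunction" else 0.7,
    )
    defaults.update(kwargs)
    config = CohortConfig(design=design, n_participants=n, seed=seed, **defaults)
    return generate_cohort(config)


@pytest.fixture()
def small_cwa_cohort(conjunction_design):
    table, truth = make_cohort(conjunction_design, "conjunction", n=60, seed=5,
                               response_model="cwa", beta=0.7, sigma=0.05)
    return table, truth
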