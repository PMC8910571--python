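import numpy as np
import pytest

import aptapk as ap


@pytest.fixture(scope="session")
def ref_pop() -> ap.PopPKParams:
    """Published population estimates for a 25 g mouse."""
    return ap.PopPKParams.reference()


@pytest.fixture(scope="session")
def ref_ind(ref_pop) -> ap.IndividualParams:
    return ap.apply_allometry(ref_pop, 25.0)


@pytest.fixture(scope="session")
def full_design() -> ap.StudyDesign:
    """Study design with LOQ censoring disabled (all samples quantified)."""
    return ap.StudyDesign(n_animals=6, loq=0.0)


@pytest.fixture(scope="session")
def small_cohort(full_design, ref_pop) -> ap.PKDataset:
    """Six-animal cohort at the reference parameters, full schedule."""
    return ap.generate_pk_cohort(full_design, ref_pop, seed=11)


@pytest.fixture(scope="session")
def noise_free_cohort(ref_pop) -> ap.PKDataset:
    """Deterministic cohort: no BSV, no residual error, no censoring."""
    design = ap.StudyDesign(n_animals=6, loq=0.0)
    return ap.generate_pk_cohort(design, ref_pop, omega_cl=0.0, b=0.0, seed=0)


def random_individual(rng: np.random.Generator) -> ap.IndividualParams:
    """Random valid two-compartment parameter set (log-uniform)."""
    return ap.IndividualParams(
        cl=float(np.exp(rng.uniform(np.log(0.1), np.log(20.0)))),
        v1=float(np.exp(rng.uniform(np.log(5.0), np.log(300.0)))),
        q=float(np.exp(rng.uniform(np.log(0.05), np.log(10.0)))),
        v2=float(np.exp(rng.uniform(np.log(10.0), np.log(600.0)))),
    )
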