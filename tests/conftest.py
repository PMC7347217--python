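import numpy as np
import pytest

from twinherit import CohortDesign, VarianceSpec, simulate_cohort


def make_specs(a2_values, e2_only=False, domains=None, reliability=1.0):
    specs = []
    for i, a2 in enumerate(a2_values):
        dom = domains[i] if domains is not None else ("task" if i % 2 else "questionnaire")
        a2 = 0.0 if e2_only else float(a2)
        specs.append(VarianceSpec(f"m{i:02d}", a2=a2, e2=round(1.0 - a2, 12),
                                  reliability=reliability, domain=dom))
    return specs


@pytest.fixture(scope="session")
def small_cohort():
    """150 MZ + 90 DZ pairs + singletons, 8 measures with graded a2, retest."""
    specs = make_specs(np.linspace(0.1, 0.8, 8))
    design = CohortDesign(n_measures=8, n_mz_pairs=150, n_dz_pairs=90,
                          n_unrelated=220, n_retest=46, seed=11)
    return simulate_cohort(design, specs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort for interface-level tests."""
    specs = make_specs([0.6, 0.3, 0.0, 0.5])
    design = CohortDesign(n_measures=4, n_mz_pairs=25, n_dz_pairs=15,
                          n_unrelated=20, n_retest=10, seed=7)
    return simulate_cohort(design, specs)
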