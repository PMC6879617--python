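import numpy as np
import pandas as pd
import pytest

from clonehier.cohort_model import attach_cn_states, filter_variants
from clonehier.synthetic_cohort import SimulationConfig, simulate_cohort
from clonehier.tcf_adjust import adjust_table


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 120-patient synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def adjusted_small(small_cohort):
    cohort, _ = small_cohort
    filtered = filter_variants(cohort.mutations)
    return adjust_table(attach_cn_states(filtered, cohort.cn_segments))


def make_two_clone_patient(phi=(0.8, 0.3), n_per_clone=5, depth=600, seed=0,
                           patient_id="P"):
    """One patient with two neutral-region clones at known prevalences."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, p in enumerate(phi):
        for j in range(n_per_clone):
            a = int(rng.binomial(depth, p / 2))
            rows.append(dict(
                patient_id=patient_id, gene=f"G{ci}{j}", chrom="1",
                pos=10_000 * ci + j, ref="A", alt="G", alt_reads=a, depth=depth,
                vaf_obs=a / depth, tcf=min(1.0, 2 * a / depth),
                branch_used="neutral", region_class="neutral", tcn=2.0, ascn=1.0,
                true_label="dominant" if ci == 0 else "secondary",
                true_phi=p,
            ))
    return pd.DataFrame(rows)
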