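import numpy as np
import pytest

from cstdyn.types import CountsTable
from cstdyn.synth import SiteSpec, SynthConfig, simulate_cohort


@pytest.fixture
def two_group_counts():
    """40 samples from two well-separated Dirichlet-Multinomial components."""
    rng = np.random.default_rng(0)
    a1, a2 = np.array([90.0, 5, 5]), np.array([5.0, 5, 90])
    rows = [rng.multinomial(500, rng.dirichlet(a1)) for _ in range(20)]
    rows += [rng.multinomial(500, rng.dirichlet(a2)) for _ in range(20)]
    table = CountsTable([f"s{i}" for i in range(40)], ["o1", "o2", "o3"],
                        np.array(rows))
    labels = np.array([1] * 20 + [2] * 20)
    return table, labels


@pytest.fixture
def overdispersed_toy():
    """4-sample 2-OTU table with strong overdispersion (interior DM MLE)."""
    return CountsTable(["t0", "t1", "t2", "t3"], ["a", "b"],
                       np.array([[14, 1], [1, 14], [12, 3], [2, 13]]))


@pytest.fixture
def small_cohort():
    """Small coupled 2-site cohort with time-free CST dynamics."""
    cfg = SynthConfig(
        n_preterm=6, n_fullterm=6,
        sites={"gut": SiteSpec(n_otus=12, k=3, slopes=[0.0] * 3),
               "nasal": SiteSpec(n_otus=12, k=3, slopes=[0.0] * 3)},
        coupling=0.8, seed=7, followup_weeks=40,
    )
    return simulate_cohort(cfg)


def make_subjects_samples(n=3, sites=("gut",)):
    """Tiny hand-built cohort for io round-trips."""
    from cstdyn.types import SubjectRecord, VisitSample

    subjects = [
        SubjectRecord(f"P{i}", ga_birth=29.0 + 5 * i, delivery_mode="vaginal",
                      birth_season="winter", sex="female")
        for i in range(n)
    ]
    samples = []
    k = 0
    for s in subjects:
        for site in sites:
            samples.append(VisitSample(f"V{k}", s.subject_id, site,
                                       wol=float(k), pma=s.ga_birth + k))
            k += 1
    return subjects, samples
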