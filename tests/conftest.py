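import numpy as np
import pytest

import tivcompare as tc


@pytest.fixture(scope="session")
def full_cohort() -> tc.CohortTable:
    """One default-parameter cohort: 444+444 subjects, 116 regions."""
    return tc.generate_cohort(tc.GeneratorConfig(seed=7))


@pytest.fixture()
def tiny_cohort() -> tc.CohortTable:
    """Six subjects, two regions, hand-checkable numbers."""
    return tc.CohortTable(
        subject_id=np.array(["s1", "s2", "s3", "s4", "s5", "s6"]),
        sex=np.array(["F", "F", "F", "M", "M", "M"], dtype=object),
        tiv=np.array([1200.0, 1300.0, 1250.0, 1500.0, 1450.0, 1550.0]),
        volumes=np.array(
            [[10.0, 55.0], [11.0, 60.0], [10.5, 57.0],
             [12.5, 70.0], [12.0, 66.0], [13.0, 72.0]]
        ),
        region_names=["hippocampus", "thalamus"],
    )


@pytest.fixture(scope="session")
def classification_run():
    """Reduced-scale classification suite shared by the multivariate tests.

    40 regions and 250 subjects per sex keep the suite fast; the roster is the
    six cheap classifiers with small SVM grids. Returns (results table,
    subsample cohorts dict).
    """
    base = tc.GeneratorConfig(n_female=250, n_male=250, n_regions=40, seed=11)
    original, replication = tc.two_cohort_configs(base, seed=11)
    split = tc.split_cohort(replication, (0.7,), seed=5)
    subs = {
        "train": replication.subset(split.train_ids),
        "test": replication.subset(split.test_ids),
        "external": original.subset(
            tc.split_cohort(original, (1.0,), seed=5, min_per_sex=0).train_ids
        ),
    }
    labels = {k: v.sex for k, v in subs.items()}
    datasets = {"tiv": {k: v.tiv[:, None] for k, v in subs.items()}}
    for method in ("raw", "scaling_surrogate", "proportions", "pcp", "residuals"):
        datasets[method] = {k: tc.adjust(v, method).values for k, v in subs.items()}
    specs = [
        s
        for s in tc.default_specs(svm_c_grid=(0.1, 1, 10), svm_gamma_grid=(0.01, 0.1, 1), cv=5)
        if s.name in ("LDA", "KNN", "LR", "TREE", "RF", "SVM_LIN")
    ]
    results = tc.run_suite(datasets, labels, specs, seed=7)
    return results, subs
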