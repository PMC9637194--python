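import pytest

from epirelapse import pipeline, synthetic

#: small but fully featured cohort used across the suite: two subtypes, two
#: recurring patients each (+ one non-recurrent primary), planted clusters of
#: every kind, PDOX models, coupled expression genes.
TINY = dict(
    n_sites=4000,
    n_cpa_sites=300,
    n_genes=200,
    n_driver_sites=30,
    n_booster_sites=30,
    n_predictor_sites=30,
    n_switch_sites=40,
    n_relapses_per_patient={"RELA": (3, 2), "PFA": (2, 3)},
    n_patients_per_subtype=2,
    mean_coverage=60,
    frac_genes_methylation_coupled=0.05,
    seed=1,
)


@pytest.fixture(scope="session")
def tiny_config():
    return synthetic.CohortConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return synthetic.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_analysis(tiny_cohort):
    """DMC calls, trajectories and discovery results for the tiny cohort."""
    return pipeline.analyze_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_run(tiny_cohort, tmp_path_factory):
    """Full file-based run_all over the tiny cohort."""
    root = tmp_path_factory.mktemp("tiny_run")
    cohort_dir = root / "cohort"
    synthetic.write_cohort(tiny_cohort, cohort_dir)
    cfg = pipeline.PipelineConfig(
        meth_dir=str(cohort_dir / "methylation"),
        sample_sheet=str(cohort_dir / "samples.csv"),
        annotation=str(cohort_dir / "genes.bed"),
        counts=str(cohort_dir / "expression.tsv"),
        out_dir=str(root / "out"),
    )
    summary = pipeline.run_all(cfg)
    return cohort_dir, root / "out", summary
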