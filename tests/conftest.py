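"""Shared fixtures: small simulated cohorts and one demo pipeline run."""

from dataclasses import replace

import pytest

from xenoplasma import pipeline, simdata, xenosplit


def small_config(**overrides) -> simdata.SimConfig:
    """A fast two-arm cohort configuration used across tests."""
    base = dict(
        n_mice_per_arm=3,
        arms=(
            simdata.Arm(False, True, "PBS"),
            simdata.Arm(True, True, "R-CHOP"),
        ),
        expression=replace(
            simdata.ExpressionParams(),
            library_size_mean=40_000.0,
            n_mouse_genes=800,
            n_human_tumor_genes=120,
            n_human_immune_genes=240,
        ),
        seed=7,
    )
    base.update(overrides)
    return simdata.default_config(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simdata.simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_split(small_cohort):
    """Mask-filtered unique reads and gene counts for the small cohort."""
    controls, cmeta = simdata.simulate_controls(
        small_config(), n_per_species=3, library_size=200_000.0
    )
    mask = xenosplit.derive_mask(controls, cmeta.set_index("sample_id")["species"])
    kept = xenosplit.apply_mask(
        xenosplit.select_unique(small_cohort.alignments), mask
    )
    counts = xenosplit.count_by_gene(kept, small_cohort.genes)
    totals = xenosplit.count_species_totals(kept)
    return {"mask": mask, "kept": kept, "counts": counts, "totals": totals}


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The bundled demo pipeline executed twice with the same config."""
    import time

    cfg = pipeline.RunConfig(seed=0)
    d1 = tmp_path_factory.mktemp("demo_run1")
    d2 = tmp_path_factory.mktemp("demo_run2")
    t0 = time.time()
    state = pipeline.run_all(cfg, d1)
    t1 = time.time() - t0
    t0 = time.time()
    pipeline.run_all(cfg, d2)
    t2 = time.time() - t0
    return {"state": state, "dir1": d1, "dir2": d2, "seconds": (t1, t2)}
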