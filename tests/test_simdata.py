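"""Synthetic-cohort generator: growth law, read emission, truth consistency."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from xenoplasma import quant, simdata
from xenoplasma.simdata import Arm, ExpressionParams, Timepoint

from conftest import small_config


def gompertz_oracle(v0, k, a, t):
    # independent closed-form evaluation
    import math

    return k * math.exp(math.log(v0 / k) * math.exp(-a * t))


class TestGrowth:
    def test_matches_closed_form(self):
        days = np.arange(0, 41)
        _, vol = simdata.simulate_growth(10, 2000, 0.08, days, endpoint_volume=np.inf)
        expected = np.array([gompertz_oracle(10, 2000, 0.08, t) for t in days])
        np.testing.assert_allclose(vol, expected, rtol=1e-9)

    def test_non_xenografted_is_zero(self):
        _, vol = simdata.simulate_growth(0, 2000, 0.08, [0, 10, 20])
        assert (vol == 0).all()

    def test_zero_rate_freezes_volume(self):
        _, vol = simdata.simulate_growth(50, 2000, 0.0, [0, 5, 30])
        np.testing.assert_allclose(vol, 50.0)

    def test_immune_control_zeroes_trajectory(self):
        _, vol = simdata.simulate_growth(50, 2000, 0.1, [0, 30], immune_controlled=True)
        assert (vol == 0).all()

    def test_treatment_decay_after_start(self):
        days = np.array([0, 14, 21, 28])
        _, treated = simdata.simulate_growth(
            50, 2000, 0.1, days, treated=True, treatment_start_day=14, treatment_decay=0.2
        )
        _, untreated = simdata.simulate_growth(50, 2000, 0.1, days)
        assert treated[1] == untreated[1]  # decay only after the start day
        assert treated[2] < untreated[2] and treated[3] < treated[2]
        v14 = gompertz_oracle(50, 2000, 0.1, 14)
        np.testing.assert_allclose(treated[3], v14 * np.exp(-0.2 * 14), rtol=1e-9)

    def test_resistant_mouse_keeps_growing(self):
        days = np.array([0, 28])
        _, res = simdata.simulate_growth(50, 2000, 0.1, days, treated=True, resistant=True)
        _, unt = simdata.simulate_growth(50, 2000, 0.1, days)
        np.testing.assert_allclose(res, unt)

    def test_endpoint_truncation(self):
        days = np.arange(0, 120)
        t, vol = simdata.simulate_growth(100, 5000, 0.1, days)
        assert vol[-1] > 1500 and (vol[:-1] <= 1500).all()
        assert len(t) < len(days)

    @pytest.mark.parametrize("bad", [dict(v0=np.nan), dict(rate=np.inf), dict(v0=-1),
                                     dict(carrying_capacity=0)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(v0=10.0, carrying_capacity=2000.0, rate=0.1)
        kw.update(bad)
        with pytest.raises(ValueError):
            simdata.simulate_growth(kw["v0"], kw["carrying_capacity"], kw["rate"], [0, 1])


class TestConfigValidation:
    def test_empty_arms_rejected(self):
        with pytest.raises(ValueError):
            small_config(arms=())

    def test_unsorted_timepoints_rejected(self):
        with pytest.raises(ValueError):
            small_config(
                timepoints=(Timepoint("pre_treatment", 14), Timepoint("pre_PDTX", 0))
            )

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            replace(simdata.GrowthParams(), immune_control_prob=1.5)

    def test_misassign_rate_must_be_below_one(self):
        with pytest.raises(ValueError):
            simdata.CrossmapParams(hotspot_misassign_rate=1.0)


class TestCohort:
    def test_seed_determinism(self):
        c1 = simdata.simulate_cohort(small_config(n_mice_per_arm=1))
        c2 = simdata.simulate_cohort(small_config(n_mice_per_arm=1))
        pd.testing.assert_frame_equal(c1.alignments, c2.alignments)
        pd.testing.assert_frame_equal(c1.truth.samples, c2.truth.samples)
        pd.testing.assert_frame_equal(c1.meta, c2.meta)

    def test_read_conservation_by_true_species(self, small_cohort):
        per = small_cohort.alignments.groupby("sample_id", observed=True)
        by_true = small_cohort.alignments.groupby(
            ["sample_id", "true_species"], observed=True
        ).size()
        for sid, total in per.size().items():
            assert by_true[sid].sum() == total

    def test_no_human_source_means_no_human_reads(self):
        cfg = small_config(
            arms=(Arm(False, False, "PBS"),),
            n_mice_per_arm=2,
        )
        cohort = simdata.simulate_cohort(cfg)
        truth_sp = cohort.alignments.true_species.astype(str)
        assert (truth_sp != "human").all()
        assert (cohort.truth.samples.true_human_pg == 0).all()

    def test_clean_crossmap_maps_equal_truth(self):
        cfg = small_config(
            n_mice_per_arm=1,
            crossmap=simdata.CrossmapParams(
                n_hotspots=0, hotspot_misassign_rate=0.0, multimap_fraction=0.0
            ),
        )
        cohort = simdata.simulate_cohort(cfg)
        a = cohort.alignments
        assert (a.mapped_species.astype(str) == a.true_species.astype(str)).all()
        assert (a.n_hits == 1).all()

    def test_expected_human_reads_monotone_in_tumor_mass_coeff(self):
        lo = simdata.simulate_cohort(small_config(tumor_mass_coeff=0.012, n_mice_per_arm=2))
        hi = simdata.simulate_cohort(small_config(tumor_mass_coeff=0.03, n_mice_per_arm=2))
        a = lo.truth.samples.set_index("sample_id")
        b = hi.truth.samples.set_index("sample_id")
        assert (b.expected_human_reads >= a.expected_human_reads.reindex(b.index) - 1e-9).all()
        # same design randomness: volumes and library sizes agree exactly
        np.testing.assert_allclose(a.true_volume_mm3, b.reindex(a.index).true_volume_mm3)

    def test_truth_mass_tracks_volume(self, small_cohort):
        truth = small_cohort.truth.samples
        meta = small_cohort.meta.set_index("sample_id")
        pbs = truth[truth.sample_id.str.startswith("nonHIS-PDTX-PBS")]
        # mass is an affine function of volume: rank correlation exactly 1
        r, _ = quant.spearman(pbs.true_volume_mm3, pbs.true_human_pg)
        assert r == pytest.approx(1.0)
        # caliper dimensions invert back to the volume
        for sid, row in meta.iterrows():
            v = quant.tumor_volume(row.tumor_length_mm, row.tumor_width_mm)
            t = truth.set_index("sample_id").loc[sid, "true_volume_mm3"]
            assert v == pytest.approx(t, abs=1e-9)

    def test_realized_human_reads_track_volume(self, small_cohort):
        a = small_cohort.alignments
        human = (
            a[a.true_species == "human"].groupby("sample_id", observed=True).size()
        )
        truth = small_cohort.truth.samples.set_index("sample_id")
        pbs = [s for s in truth.index if s.startswith("nonHIS-PDTX-PBS")]
        r, _ = quant.spearman(
            truth.loc[pbs, "true_volume_mm3"],
            human.reindex(pbs).fillna(0).to_numpy(),
        )
        assert r >= 0.8

    def test_meta_invariants(self, small_cohort):
        meta = small_cohort.meta
        non_his = meta[~meta.humanized]
        assert not (non_his.timepoint == "pre_humanization").any()
        for _, grp in meta.groupby("mouse_id"):
            days = grp.day.to_numpy()
            assert (np.diff(days) > 0).all()
        assert (meta.plasma_volume_ml > 0).all()

    def test_cell_fraction_truth_valid(self, small_cohort):
        cf = small_cohort.truth.cell_fractions.dropna()
        assert ((cf >= 0) & (cf <= 1)).all().all()
        np.testing.assert_allclose(cf.sum(axis=1), 1.0, rtol=1e-9)


class TestFixtureIO:
    def test_round_trip(self, small_cohort, tmp_path):
        simdata.write_fixture(small_cohort, tmp_path)
        back = simdata.read_fixture(tmp_path)
        assert len(back["alignments"]) == len(small_cohort.alignments)
        got = back["meta"]
        pd.testing.assert_frame_equal(
            got, small_cohort.meta, check_dtype=False, check_categorical=False
        )
        pd.testing.assert_frame_equal(
            back["truth_samples"], small_cohort.truth.samples,
            check_dtype=False, check_categorical=False,
        )
        # spot-check alignment content equality on a sample
        sid = small_cohort.meta.sample_id.iloc[0]
        orig = small_cohort.alignments.query("sample_id == @sid")
        rt = back["alignments"].query("sample_id == @sid")
        assert (rt.start.to_numpy() == orig.start.to_numpy()).all()
        assert (rt.mapped_species.to_numpy() == orig.mapped_species.astype(str).to_numpy()).all()

    def test_row_counts_match_records(self, small_cohort, tmp_path):
        simdata.write_fixture(small_cohort, tmp_path)
        n_lines = sum(1 for _ in open(tmp_path / "alignments.tsv")) - 1
        assert n_lines == len(small_cohort.alignments)

    def test_empty_cohort_headers_only(self, tmp_path):
        cols = ["sample_id", "read_id", "mapped_species", "contig", "start",
                "end", "n_hits", "true_species"]
        empty = simdata.Cohort(
            alignments=pd.DataFrame(columns=cols),
            meta=pd.DataFrame(columns=["sample_id", "mouse_id"]),
            truth=simdata.SimTruth(
                samples=pd.DataFrame(columns=["sample_id"]),
                cell_fractions=pd.DataFrame(),
                hotspots=pd.DataFrame(columns=["pair", "mouse_contig", "mouse_start",
                                               "mouse_end", "human_contig",
                                               "human_start", "human_end"]),
                signature_multipliers=pd.Series(dtype=float),
            ),
            genes=pd.DataFrame(columns=["gene_id", "species", "contig", "start",
                                        "end", "biotype"]),
            config=small_config(),
        )
        simdata.write_fixture(empty, tmp_path)
        assert sum(1 for _ in open(tmp_path / "alignments.tsv")) == 1

    def test_controls_are_pure_species(self):
        controls, cmeta = simdata.simulate_controls(
            small_config(), n_per_species=2, library_size=50_000
        )
        sp = cmeta.set_index("sample_id")["species"]
        true = controls.true_species.astype(str)
        own = controls.sample_id.astype(str).map(sp)
        assert (true == own).all()
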