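import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vtatrace.colabel import (
    DA_RULE,
    GABA_RULE,
    SEROTONIN_RULE,
    ColabelRule,
    apply_colabel_rule,
    da_colabel_fraction,
    da_total_estimate,
    gaba_composition,
    serotonin_summary,
)
from vtatrace.synthetic import BrainDataset, Cohort, GeneratorConfig, generate_cohort


def make_brain(cells, brain_id="b0"):
    """Brain from a list of dicts with marker flags."""
    defaults = dict(
        brain_id=brain_id, region="SNr", hemisphere="ipsi",
        x_ml=np.nan, y_dv=np.nan, gfp=True, tc66t=False,
        gad=False, th=False, tph2=False, is_starter=False,
    )
    rows = [dict(defaults, **c) for c in cells]
    df = pd.DataFrame(rows)
    starters = df[df["is_starter"]].reset_index(drop=True)
    inputs = df[~df["is_starter"]].reset_index(drop=True)
    return BrainDataset(brain_id=brain_id, starters=starters, inputs=inputs)


class TestColabelRule:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ColabelRule(require={"gad"}, exclude={"gad"})

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ColabelRule(require={"vglut2"})

    @pytest.mark.parametrize(
        "cell,rule,kept",
        [
            (dict(gfp=True, gad=True, tc66t=False), GABA_RULE, True),
            (dict(gfp=True, gad=True, tc66t=True), GABA_RULE, False),
            (dict(gfp=True, gad=False, tc66t=False), GABA_RULE, False),
            (dict(gfp=True, th=True, tc66t=False), DA_RULE, True),
            (dict(gfp=True, th=True, tc66t=True), DA_RULE, False),
            (dict(gfp=True, tph2=True), SEROTONIN_RULE, True),
            (dict(gfp=True, tph2=False), SEROTONIN_RULE, False),
        ],
    )
    def test_rule_filtering(self, cell, rule, kept):
        brain = make_brain([cell])
        assert len(apply_colabel_rule(brain, rule)) == (1 if kept else 0)

    def test_starters_never_pass(self):
        brain = make_brain(
            [dict(gfp=True, gad=True, tc66t=False, th=True, is_starter=True,
                  region="PBP")]
        )
        assert len(apply_colabel_rule(brain, GABA_RULE)) == 0
        assert len(apply_colabel_rule(brain, DA_RULE)) == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        require=st.sets(st.sampled_from(["gfp", "gad", "th", "tph2"]), max_size=2),
        exclude_tc=st.booleans(),
        flags=st.lists(
            st.fixed_dictionaries(
                {m: st.booleans() for m in ("gfp", "tc66t", "gad", "th", "tph2")}
            ),
            min_size=1,
            max_size=8,
        ),
    )
    def test_filters_idempotent_and_order_independent(
        self, require, exclude_tc, flags
    ):
        """Applying a rule twice, or its require/exclude halves in either
        order, selects the same cells."""
        brain = make_brain(flags)
        exclude = {"tc66t"} if exclude_tc else set()
        rule = ColabelRule(require=require, exclude=exclude)
        once = apply_colabel_rule(brain, rule)
        twice = apply_colabel_rule(
            BrainDataset("b0", brain.starters, once), rule
        )
        pd.testing.assert_frame_equal(once, twice)
        req_only = ColabelRule(require=require)
        exc_only = ColabelRule(exclude=exclude)
        via_req_first = apply_colabel_rule(
            BrainDataset("b0", brain.starters,
                         apply_colabel_rule(brain, req_only)),
            exc_only,
        )
        via_exc_first = apply_colabel_rule(
            BrainDataset("b0", brain.starters,
                         apply_colabel_rule(brain, exc_only)),
            req_only,
        )
        pd.testing.assert_frame_equal(via_req_first, via_exc_first)
        pd.testing.assert_frame_equal(once, via_req_first)


class TestGabaComposition:
    def test_shares_sum_to_100(self, cohort4, catalog):
        comp = gaba_composition(cohort4, catalog)
        assert comp["mean_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_snr_is_largest_source(self, cohort50, catalog):
        comp = gaba_composition(cohort50, catalog)
        assert comp["mean_percent"].idxmax() == "SNr"

    def test_shares_recover_reference_under_multinomial(
        self, cohort50_multinomial, catalog
    ):
        """With no planted covariance the generator's GAD rates reproduce the
        reference composition of local inhibition."""
        comp = gaba_composition(cohort50_multinomial, catalog)
        assert comp.loc["SNr", "mean_percent"] == pytest.approx(20.1, abs=1.5)
        assert comp.loc["PBP", "mean_percent"] == pytest.approx(19.3, abs=1.5)
        assert comp.loc["SNc", "mean_percent"] == pytest.approx(10.5, abs=1.5)

    def test_hemisphere_separated_mode(self, cohort4, catalog):
        comp = gaba_composition(cohort4, catalog, hemispheres="separate")
        labels = comp.index.str.split("|", expand=False)
        assert all(len(parts) == 2 for parts in labels)
        # midline GABA sources (MnR, RMg) never split by hemisphere
        for label in comp.index:
            region, hemi = label.split("|")
            if region in ("MnR", "RMg"):
                assert hemi == "midline"

    def test_pooled_mode_close_to_per_brain_mean(self, cohort4, catalog):
        per_brain = gaba_composition(cohort4, catalog)
        pooled = gaba_composition(cohort4, catalog, pooled=True)
        diff = (per_brain["mean_percent"] - pooled["mean_percent"]).abs()
        assert diff.max() < 5.0

    def test_zero_gaba_brain_rejected(self, catalog):
        brain = make_brain([dict(gad=False)])
        with pytest.raises(ValueError, match="zero rule-passing"):
            gaba_composition(Cohort(brains=[brain]), catalog)


class TestDaColabel:
    def test_all_eligible_th_positive(self, catalog):
        cells = [
            dict(region="PBP", th=True, x_ml=1200.0, y_dv=-4300.0)
            for _ in range(10)
        ]
        frac = da_colabel_fraction(Cohort(brains=[make_brain(cells)]), catalog)
        assert frac.loc["VTA_lateral", "mean_th_fraction"] == 1.0

    def test_th_rate_recovered_in_each_roi(self, cohort50, catalog):
        frac = da_colabel_fraction(cohort50, catalog)
        for roi in frac.index:
            assert frac.loc[roi, "mean_th_fraction"] == pytest.approx(
                0.40, abs=0.05
            )

    def test_cells_inside_tva_sphere_excluded(self, catalog):
        inside = dict(region="PBP", th=True, x_ml=400.0, y_dv=-4300.0)
        outside = dict(region="PBP", th=False, x_ml=1500.0, y_dv=-4300.0)
        cohort = Cohort(brains=[make_brain([inside, outside])])
        frac = da_colabel_fraction(cohort, catalog, tva_radius=500.0)
        # only the outside cell is eligible, and it is TH-
        assert frac.loc["VTA_lateral", "mean_th_fraction"] == 0.0

    def test_sphere_filter_monotone_in_radius(self, cohort4, catalog):
        """Growing the exclusion sphere never adds eligible cells."""
        sizes = []
        for radius in (0.0, 250.0, 500.0, 1000.0, 2000.0):
            _, per_brain = da_colabel_fraction(
                cohort4, catalog, tva_radius=radius, return_per_brain=True
            )
            sizes.append(per_brain.notna().sum().sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_empty_roi_reported_missing(self, catalog):
        cells = [dict(region="PBP", th=True, x_ml=1200.0, y_dv=-4300.0)]
        frac = da_colabel_fraction(Cohort(brains=[make_brain(cells)]), catalog)
        assert np.isnan(frac.loc["RRF", "mean_th_fraction"])
        assert frac.loc["RRF", "n_brains"] == 0


class TestDaTotalEstimate:
    def test_published_worked_example(self):
        assert da_total_estimate(0.11, 0.40) == pytest.approx(4.4)

    @pytest.mark.parametrize("share,frac,expected", [(0.0, 0.7, 0.0), (1.0, 1.0, 100.0)])
    def test_boundaries(self, share, frac, expected):
        assert da_total_estimate(share, frac) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            da_total_estimate(1.2, 0.4)
        with pytest.raises(ValueError):
            da_total_estimate(0.4, -0.1)


class TestSerotoninSummary:
    def test_arithmetic_on_fixture(self, catalog):
        cells = [dict(region="DR", tph2=True, hemisphere="midline")] * 30
        cells += [dict(region="DR", tph2=False, hemisphere="midline")] * 70
        cells += [dict(region="SNr", tph2=False)] * 9900
        summary = serotonin_summary(Cohort(brains=[make_brain(cells)]), catalog)
        assert summary.loc["DR|midline", "tph2_fraction_mean"] == pytest.approx(0.30)
        assert summary.loc["DR|midline", "per_10k_mean"] == pytest.approx(30.0)

    def test_midline_groups_not_split(self, cohort4, catalog):
        summary = serotonin_summary(cohort4, catalog)
        for label in summary.index:
            region, hemi = label.split("|")
            if region in ("DR", "MnR", "RMg"):
                assert hemi == "midline"
            else:
                assert hemi in ("ipsi", "contra")

    def test_tph2_rates_recovered(self, cohort50, catalog):
        """Generator rates in [0.25, 0.31] are recovered within +/-0.04."""
        summary, frac, _ = serotonin_summary(
            cohort50, catalog, return_per_brain=True
        )
        expected = {"DR": 0.30, "mRT": 0.30, "MnR": 0.31, "RMg": 0.30,
                    "PnO": 0.29, "SPTg": 0.25}
        for label in summary.index:
            region = label.split("|")[0]
            assert summary.loc[label, "tph2_fraction_mean"] == pytest.approx(
                expected[region], abs=0.04
            )

    def test_region_with_no_inputs_is_missing_not_zero(self, catalog):
        cells = [dict(region="DR", tph2=True, hemisphere="midline")] * 10
        summary = serotonin_summary(Cohort(brains=[make_brain(cells)]), catalog)
        assert np.isnan(summary.loc["mRT|ipsi", "tph2_fraction_mean"])
        assert summary.loc["mRT|ipsi", "per_10k_mean"] == 0.0
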