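import numpy as np
import pytest

from lcsm.model_zoo import (
    DesignError,
    StudyDesign,
    build_gfactor_lcs,
    build_investment_lcs,
    build_mutualism_lcs,
    build_no_coupling_lcs,
    build_parallel_process,
    build_riclpm,
    design_from_data,
    edit_constraint,
    reliability_residual_variance,
)
from lcsm.sem_core import (
    CompiledModel,
    SemError,
    fit,
    likelihood_ratio_test,
    rmsea,
)
from lcsm.synthetic_data import (
    gfactor_generating_preset,
    mutualism_generating_preset,
    simulate_dataset,
)

ALL_BUILDERS = [
    build_mutualism_lcs,
    build_investment_lcs,
    build_no_coupling_lcs,
    build_gfactor_lcs,
    build_parallel_process,
    build_riclpm,
]


class TestReliabilityAdjustment:
    @pytest.mark.parametrize(
        "s2,rxx,expected", [(4.0, 1.0, 0.0), (4.0, 0.75, 1.0), (2.5, 0.9, 0.25)]
    )
    def test_residual_variance_formula(self, s2, rxx, expected):
        assert reliability_residual_variance(s2, rxx) == pytest.approx(expected)

    @pytest.mark.parametrize("rxx", [0.0, -0.1, 1.2])
    def test_reliability_out_of_range_rejected(self, rxx):
        with pytest.raises(ValueError):
            reliability_residual_variance(4.0, rxx)

    def test_design_validates_reliabilities_and_loadings(self):
        with pytest.raises(DesignError):
            StudyDesign(reliabilities={"vocabulary": {"T1": 1.5}})
        with pytest.raises(DesignError):
            StudyDesign(slope_loadings=(0.0, 2.0, 1.0))


class TestDegreesOfFreedom:
    def test_every_builder_free_plus_df_is_27(self, design):
        for b in ALL_BUILDERS:
            spec = b(design)
            assert spec.n_moments == 27
            assert spec.n_free + spec.df == 27, spec.name

    def test_mutualism_df_is_8(self, design):
        assert build_mutualism_lcs(design).df == 8

    def test_investment_has_one_fewer_free_parameter(self, design):
        assert (
            build_mutualism_lcs(design).n_free - build_investment_lcs(design).n_free
            == 1
        )

    def test_constrained_vocab_intercept_differs_by_one_df(self, design):
        free_icpt = build_mutualism_lcs(design)
        constrained = build_mutualism_lcs(design, free_vocab_change_intercept=False)
        assert free_icpt.df + 1 == constrained.df

    def test_parallel_process_df_is_9_and_matthew_adds_2(self, design):
        cross = build_parallel_process(design)
        assert cross.df == 9
        within = build_parallel_process(design, cross_domain_only=False)
        assert within.n_free - cross.n_free == 2

    def test_gfactor_measurement_invariance_shares_labels_across_waves(self, design):
        """The reasoning loading and intercept each occur once per wave but
        carry a single shared label, so invariance costs 4 fewer parameters
        than a configural (wave-specific) variant would."""
        spec = build_gfactor_lcs(design)
        loading_occurrences = [
            p for p in spec.paths.values() if p.free and p.label == "lambda_reasoning"
        ]
        intercept_occurrences = [
            p for p in spec.means.values() if p.free and p.label == "tau_reasoning"
        ]
        assert len(loading_occurrences) == 3
        assert len(intercept_occurrences) == 3
        # shared labels count once each: 3+3 occurrences -> 2 free parameters
        n_if_configural = spec.n_free + (3 - 1) + (3 - 1)
        assert n_if_configural - spec.n_free == 4

    def test_riclpm_count_matches_hand_enumeration(self, design):
        # 6 means + 2 RI var + 1 RI cov + 2 within-T1 var + 1 within-T1 cov
        # + 2 AR + 2 cross-lagged + 2 within residual var + 2 residual cov = 20
        assert build_riclpm(design).n_free == 20

    def test_wrong_wave_count_raises_supported_design_error(self):
        two_waves = StudyDesign(wave_labels=("T1", "T2"), slope_loadings=(0.0, 1.0))
        for b in ALL_BUILDERS:
            with pytest.raises(DesignError):
                b(two_waves)


class TestSpecStructure:
    def test_builders_emit_positive_definite_start_moments(self, mutualism_design):
        for b in ALL_BUILDERS:
            spec = b(mutualism_design)
            comp = CompiledModel(spec)
            _, sigma = comp.implied(comp.start_vector())
            assert np.all(np.linalg.eigvalsh(sigma) > 0), spec.name

    def test_investment_collapses_to_no_coupling_when_fixed(self, design):
        inv = build_investment_lcs(design)
        collapsed = edit_constraint(
            inv, "fix", ["gamma_reasoning_to_vocabulary"], 0.0
        )
        assert collapsed.n_free == build_no_coupling_lcs(design).n_free

    def test_riclpm_zero_cross_lags_leaves_residual_links_only(self, design):
        spec = build_riclpm(design)
        fixed0 = edit_constraint(
            spec, "fix", ["cl_vocabulary_to_reasoning", "cl_reasoning_to_vocabulary"], 0.0
        )
        comp = CompiledModel(fixed0)
        theta = comp.start_vector()
        # cross-domain entries of A must all be zero once cross-lags are fixed
        A, _, _ = comp.matrices(theta)
        vi = {v: i for i, v in enumerate(fixed0.variables)}
        for w_from in ("T1", "T2"):
            for w_to in ("T2", "T3"):
                assert A[vi[f"w_reasoning_{w_to}"], vi[f"w_vocabulary_{w_from}"]] == 0.0
                assert A[vi[f"w_vocabulary_{w_to}"], vi[f"w_reasoning_{w_from}"]] == 0.0


class TestEditConstraint:
    def test_fix_then_free_round_trips(self, design):
        spec = build_mutualism_lcs(design)
        edited = edit_constraint(spec, "fix", ["beta_vocabulary"], 0.0)
        back = edit_constraint(edited, "free", ["beta_vocabulary"])
        assert back.free_labels == spec.free_labels
        assert back.n_free == spec.n_free

    def test_equate_two_labels_reduces_count_by_one(self, design):
        spec = build_mutualism_lcs(design)
        eq = edit_constraint(spec, "equate", ["beta_vocabulary", "beta_reasoning"])
        assert eq.n_free == spec.n_free - 1

    def test_unknown_label_lists_alternatives(self, design):
        spec = build_mutualism_lcs(design)
        with pytest.raises(SemError, match="available"):
            edit_constraint(spec, "free", ["no_such_label"])

    def test_fixing_parallel_cross_path_changes_df_by_one(self, design):
        spec = build_parallel_process(design)
        edited = edit_constraint(
            spec, "fix", ["b_int_vocabulary_to_slope_reasoning"], 0.0
        )
        assert edited.df == spec.df + 1


class TestBuildersOnGeneratedData:
    def test_gfactor_spec_fits_its_own_data_well(self):
        """True-model calibration: RMSEA below .08 in most replicates."""
        ok = 0
        reps = 25
        for r in range(reps):
            cfg = gfactor_generating_preset(0.1, 227, seed=700 + r)
            data = simulate_dataset(cfg)
            des = design_from_data(data, reliabilities=cfg.design.reliabilities)
            f = fit(build_gfactor_lcs(des), data, compute_se=False, standardized=False)
            if f.converged and rmsea(f.chisq, f.spec.df, f.n) < 0.08:
                ok += 1
        assert ok >= 0.85 * reps

    def test_mutualism_beats_gfactor_on_mutualism_data(self):
        wins = 0
        reps = 25
        for r in range(reps):
            cfg = mutualism_generating_preset(0.3, 227, seed=800 + r)
            data = simulate_dataset(cfg)
            des = design_from_data(data, reliabilities=cfg.design.reliabilities)
            fm = fit(build_mutualism_lcs(des), data, compute_se=False, standardized=False)
            fg = fit(build_gfactor_lcs(des), data, compute_se=False, standardized=False)
            wins += fm.aic < fg.aic
        assert wins >= 0.95 * reps

    def test_lrt_rejects_investment_under_strong_vocab_coupling(self):
        rejections = 0
        reps = 25
        for r in range(reps):
            cfg = mutualism_generating_preset(0.3, 227, seed=900 + r)
            data = simulate_dataset(cfg)
            des = design_from_data(data, reliabilities=cfg.design.reliabilities)
            fi = fit(build_investment_lcs(des), data, compute_se=False, standardized=False)
            fm = fit(build_mutualism_lcs(des), data, compute_se=False, standardized=False)
            rejections += likelihood_ratio_test(fi, fm).p < 0.05
        assert rejections >= 0.95 * reps

    def test_removing_couplings_worsens_aic_on_mutualism_data(
        self, mutualism_data, mutualism_design
    ):
        full = fit(
            build_mutualism_lcs(mutualism_design), mutualism_data,
            compute_se=False, standardized=False,
        )
        none = fit(
            build_no_coupling_lcs(mutualism_design), mutualism_data,
            compute_se=False, standardized=False,
        )
        assert full.aic < none.aic

    def test_riclpm_recovers_positive_bidirectional_coupling(self):
        pos = 0
        reps = 25
        for r in range(reps):
            cfg = mutualism_generating_preset(0.3, 227, seed=1000 + r)
            data = simulate_dataset(cfg)
            des = design_from_data(data, reliabilities=cfg.design.reliabilities)
            f = fit(build_riclpm(des), data, compute_se=False, standardized=False)
            pos += (
                f.converged
                and f.estimates["cl_vocabulary_to_reasoning"] > 0
                and f.estimates["cl_reasoning_to_vocabulary"] > 0
            )
        assert pos >= 0.9 * reps


def test_design_from_data_reads_sample_moments(mutualism_data):
    des = design_from_data(mutualism_data)
    col = mutualism_data.scores["vocabulary_T2"]
    assert des.variance("vocabulary", "T2") == pytest.approx(col.var())
    assert des.mean("vocabulary", "T2") == pytest.approx(col.mean())
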