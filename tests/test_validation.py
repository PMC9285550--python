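"""Stacking, the beta-binomial probit regression, and residual summaries."""

import numpy as np
import pandas as pd
import pytest

from prevharm.conversion import Z_to_prevalence, prevalence_to_Z
from prevharm.synthetic import PopulationSpec, simulate_prevalence_dataset
from prevharm.validation import (
    PairedPrevalenceRecord,
    bland_altman,
    fit_slope,
    mean_grouped_slopes,
    read_dataset_csv,
    residual_summary,
    stack_records,
    variance_explained,
    write_dataset_csv,
)


def _make_record(Z_A, dz, n=10_000, category="overweight", source="s",
                 b_true=1.0, noise=0.0, rng=None):
    """A record lying on (or near) the line dZ = b_true*dz."""
    sign = -1 if category == "thinness" else 1
    Z_B = Z_A + b_true * dz + noise
    p_A = Z_to_prevalence(Z_A, sign)
    p_B = Z_to_prevalence(Z_B, sign)
    if rng is not None:
        p_A = rng.binomial(n, p_A) / n
        p_B = rng.binomial(n, p_B) / n
    return PairedPrevalenceRecord(
        group="g", source=source, sex="male", mean_age=8.0, n=n,
        category=category, label_A="A", label_B="B", p_A=p_A, p_B=p_B,
        dz=dz, Z_A=prevalence_to_Z(p_A, sign, n=n),
        Z_B=prevalence_to_Z(p_B, sign, n=n),
    )


def _line_records(b_true=1.0, n=10_000, noise_rng=None):
    recs = []
    for Z_A in np.linspace(0.3, 1.4, 12):
        for dz in (0.2, 0.45, 0.7):
            recs.append(_make_record(Z_A, dz, n=n, b_true=b_true,
                                     rng=noise_rng))
    return recs


class TestStacking:
    def test_study_shaped_dataset_stacks_to_302(self, stacked_records):
        assert len(stacked_records) == 302  # 52*2 + 22*9

    def test_both_orientations_doubles_to_604(self, paper_shaped, lookup_table,
                                              registry):
        recs = stack_records(paper_shaped, lookup_table, registry=registry,
                             both_orientations=True)
        assert len(recs) == 604

    def test_records_oriented_to_positive_dz(self, stacked_records):
        assert all(r.dz > 0 for r in stacked_records)

    def test_negative_dz_row_is_flipped(self, paper_shaped, lookup_table,
                                        registry):
        """A row entered with the pair in the downhill direction comes back
        with labels, prevalences and probits swapped and dz negated."""
        row = paper_shaped.iloc[[0]].copy()
        swapped = row.copy()
        swapped["cutoff_A"], swapped["cutoff_B"] = (
            row["cutoff_B"].values, row["cutoff_A"].values)
        swapped["prev_A"], swapped["prev_B"] = (
            row["prev_B"].values, row["prev_A"].values)
        (rec,) = stack_records(row, lookup_table, registry=registry)
        (rec_sw,) = stack_records(swapped, lookup_table, registry=registry)
        assert rec_sw == rec

    def test_net_overweight_made_inclusive(self, lookup_table, registry):
        rows = pd.DataFrame([
            dict(group="g1", source="s", sex="male", mean_age=8.0, n=1000,
                 category="overweight", cutoff_A="IOTF25", cutoff_B="WHO+1",
                 prev_A=15.0, prev_B=20.0, overweight_is_net=True),
            dict(group="g1", source="s", sex="male", mean_age=8.0, n=1000,
                 category="obesity", cutoff_A="IOTF30", cutoff_B="WHO+2",
                 prev_A=5.0, prev_B=9.0, overweight_is_net=False),
        ])
        recs = stack_records(rows, lookup_table, registry=registry)
        ow = next(r for r in recs if r.category == "overweight")
        assert {round(ow.p_A, 3), round(ow.p_B, 3)} == {0.20, 0.29}

    def test_bad_rows_reported_together(self, lookup_table, registry):
        rows = pd.DataFrame([
            dict(group="g1", source="s", sex="male", mean_age=8.0, n=1000,
                 category="overweight", cutoff_A="IOTF25", cutoff_B="WHO+1",
                 prev_A=np.nan, prev_B=20.0, overweight_is_net=False),
            dict(group="g2", source="s", sex="male", mean_age=8.0, n=1000,
                 category="obesity", cutoff_A="NOPE", cutoff_B="WHO+2",
                 prev_A=5.0, prev_B=9.0, overweight_is_net=False),
        ])
        with pytest.raises(ValueError, match="row 0(.|\n)*row 1"):
            stack_records(rows, lookup_table, registry=registry)

    def test_dataset_csv_roundtrip(self, paper_shaped, tmp_path):
        path = tmp_path / "data.csv"
        write_dataset_csv(paper_shaped, path)
        back = read_dataset_csv(path)
        pd.testing.assert_frame_equal(back, paper_shaped)


class TestFitSlope:
    def test_zero_noise_line_recovers_unit_slope(self):
        fit = fit_slope(_line_records(b_true=1.0))
        assert fit.b == pytest.approx(1.0, abs=1e-3)

    def test_fixed_b1_evaluates_at_one(self, stacked_records):
        fit = fit_slope(stacked_records, model="fixed_b1")
        assert fit.b == 1.0 and fit.ci is None

    def test_beta_binomial_recovery_within_ci(self, zshift_bench):
        """300-group beta-binomial data generated at b = 0.78."""
        pop = PopulationSpec(
            "base", zshift_bench["groups"], z_shift=0.6,
            s_inflation=1 / 0.78, extra_dispersion=0.05, seed=78,
        )
        df = simulate_prevalence_dataset(
            pop, zshift_bench["refs"], zshift_bench["registry"],
            zshift_bench["pairs"])
        recs = stack_records(df, zshift_bench["table"])
        fit = fit_slope(recs)
        lo, hi = fit.ci
        assert lo < 0.78 < hi
        assert fit.dispersion > 0  # overdispersion detected

    def test_grouped_slopes_one_per_source_category(self, stacked_records):
        fit = fit_slope(stacked_records, model="grouped_slopes")
        assert set(fit.b_by_cell) == {
            ("survey", "overweight"), ("survey", "obesity"),
            ("cohort", "overweight"), ("cohort", "obesity"),
            ("cohort", "thinness"),
        }
        for cell, (lo, hi) in fit.ci_by_cell.items():
            assert lo < fit.b_by_cell[cell] < hi

    def test_bic_prefers_estimated_slope_when_b_differs_from_one(
            self, zshift_bench):
        pop = PopulationSpec("base", zshift_bench["groups"][:100],
                             z_shift=0.6, s_inflation=1 / 0.75, seed=3)
        df = simulate_prevalence_dataset(
            pop, zshift_bench["refs"], zshift_bench["registry"],
            zshift_bench["pairs"])
        recs = stack_records(df, zshift_bench["table"])
        bic_fixed = fit_slope(recs, model="fixed_b1").bic
        bic_common = fit_slope(recs, model="common_slope").bic
        assert bic_common < bic_fixed

    def test_mean_of_five_grouped_slopes(self):
        """Equal-weight averaging of the five source-by-category slopes."""
        assert round(mean_grouped_slopes([1.02, 0.96, 0.82, 0.74, 0.68]), 2) \
            == 0.84

    def test_all_zero_dz_unidentifiable(self):
        recs = [_make_record(z, 0.0) for z in (0.4, 0.8)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_slope(recs)

    def test_fixed_b1_zscale_residuals_antisymmetric(self, stacked_records):
        """Reversibility: each record's z-scale residual changes sign when
        the A and B roles are exchanged."""
        for rec in stacked_records[:20]:
            fwd = rec.Z_B - (rec.Z_A + rec.dz)
            flipped = rec.flipped()
            rev = flipped.Z_B - (flipped.Z_A + flipped.dz)
            assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_slope_recovery_mean_over_replicates(self, zshift_bench):
        """Over 20 seeded replicates of the 300-group design the mean
        estimate sits within 0.02 of the truth, for three slope regimes."""
        for truth, seed0 in ((0.7, 700), (0.85, 850), (1.0, 1000)):
            estimates = []
            for rep in range(20):
                pop = PopulationSpec(
                    "base", zshift_bench["groups"], z_shift=0.6,
                    s_inflation=1 / truth, seed=seed0 + rep)
                df = simulate_prevalence_dataset(
                    pop, zshift_bench["refs"], zshift_bench["registry"],
                    zshift_bench["pairs"])
                recs = stack_records(df, zshift_bench["table"])
                estimates.append(fit_slope(recs).b)
            assert np.mean(estimates) == pytest.approx(truth, abs=0.02)


class TestResidualSummary:
    def test_perfect_prediction(self):
        recs = _line_records(b_true=1.0, n=10_000_000)
        summ = residual_summary(recs, b=1.0)
        assert summ.rsd_prev["all"] == pytest.approx(0.0, abs=1e-4)
        assert summ.var_explained["all"] == pytest.approx(100.0, abs=1e-4)

    def test_baseline_model_explains_nothing(self):
        """Predicting each prevalence by the other one unchanged (b such that
        predictions equal the paired observation) gives RSD = baseline SD."""
        recs = _line_records(b_true=1.0)
        # b ~ 0 switches the shift off: the prediction collapses to the
        # other observed prevalence
        summ = residual_summary(recs, b=1e-12)
        assert summ.rsd_prev["all"] == pytest.approx(summ.baseline_sd["all"],
                                                     rel=1e-6)
        assert summ.var_explained["all"] == pytest.approx(0.0, abs=1e-4)

    def test_variance_explained_formula(self):
        assert variance_explained(3.0, 6.0) == pytest.approx(75.0)
        assert variance_explained(0.0, 6.0) == pytest.approx(100.0)
        assert variance_explained(6.0, 6.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.0)

    def test_invariant_to_relabeling(self, stacked_records):
        summ = residual_summary(stacked_records, b=1.0)
        summ_flip = residual_summary([r.flipped() for r in stacked_records],
                                     b=1.0)
        assert summ.var_explained["all"] == pytest.approx(
            summ_flip.var_explained["all"], abs=1e-9)

    def test_categories_reported_separately(self, stacked_records):
        summ = residual_summary(stacked_records)
        assert set(summ.rsd_prev) == {"thinness", "overweight", "obesity", "all"}
        assert summ.n_points["all"] == 2 * len(stacked_records)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            residual_summary([])


class TestBlandAltman:
    def test_perfect_prediction_gives_zero_differences(self):
        recs = _line_records(b_true=1.0, n=10_000_000)
        ba = bland_altman(recs, b=1.0)
        alg = ba[ba["kind"] == "algorithm"]
        assert np.allclose(alg["diff"], 0.0, atol=1e-2)

    def test_baseline_pairs_symmetric_about_zero(self, stacked_records):
        ba = bland_altman(stacked_records)
        base = ba[ba["kind"] == "baseline"]
        # each pair contributes +d and -d at the same mean
        assert base.groupby("mean")["diff"].sum().abs().max() < 1e-12

    def test_unadjusted_residuals_fan_out_with_dz_when_b_below_one(self):
        """Data generated with b_true < 1: residuals of the unadjusted
        conversion grow with |dz|; multiplying dz by b_true removes the
        trend (the rationale for the bias-adjusted algorithm)."""
        rng = np.random.default_rng(11)
        recs = []
        for Z_A in np.linspace(0.2, 1.2, 20):
            for dz in (0.1, 0.5, 0.9, 1.3):
                recs.append(_make_record(Z_A, dz, n=200_000, b_true=0.8,
                                         rng=rng))
        slopes = {}
        for b in (1.0, 0.8):
            ba = bland_altman(recs, b=b)
            alg = ba[ba["kind"] == "algorithm"]
            slopes[b] = np.polyfit(np.abs(alg["dz"]), np.abs(alg["diff"]), 1)[0]
        assert slopes[1.0] > 3 * abs(slopes[0.8])
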