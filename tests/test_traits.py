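"""Trait design matrix, OLS fit, bootstrap CIs, sequence utilities."""

import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias.traits import DESIGN_COLUMNS


class TestDesignMatrix:
    def test_packaged_table_dimensions_and_values(self, traits, design):
        X = mb.build_design_matrix(traits, list(design.taxa), "fwhF2-fwhR2n")
        assert X.shape == (16, 6)
        assert list(X.columns) == list(DESIGN_COLUMNS)
        row = X.loc["Carpophilus davidsoni"]
        assert row["hard"] == 1.0 and row["soft"] == 0.0 and row["intermediate"] == 0.0
        assert row["log_volume"] == pytest.approx(np.log(3.80))
        assert row["mismatch"] == pytest.approx(0.12 + 0.09)
        assert row["gc"] == pytest.approx(0.37)
        # second primer pair differs in the molecular columns only
        X2 = mb.build_design_matrix(traits, list(design.taxa), "fwhF2-HexCOIR4")
        assert X2.loc["Carpophilus davidsoni", "mismatch"] == pytest.approx(0.12 + 0.06)
        assert np.allclose(X["log_volume"], X2["log_volume"])

    def test_hardness_indicators_partition_taxa(self, traits, design):
        X = mb.build_design_matrix(traits, list(design.taxa), "fwhF2-fwhR2n")
        assert np.allclose(X[["soft", "intermediate", "hard"]].sum(axis=1), 1.0)
        soft_only = [t for t in design.taxa if X.loc[t, "soft"] == 1.0]
        Xs = mb.build_design_matrix(traits, soft_only, "fwhF2-fwhR2n")
        assert (Xs["hard"] == 0).all() and (Xs["intermediate"] == 0).all()

    def test_reference_encoding_has_intercept(self, traits, design):
        X = mb.build_design_matrix(
            traits, list(design.taxa), "fwhF2-fwhR2n", encoding="reference"
        )
        assert "intercept" in X.columns and "soft" not in X.columns

    def test_missing_taxon_rejected(self, traits):
        with pytest.raises(KeyError):
            mb.build_design_matrix(traits, ["Nonexistent species"], "fwhF2-fwhR2n")


@pytest.fixture
def fixture_X(traits, design):
    return mb.build_design_matrix(traits, list(design.taxa), "fwhF2-fwhR2n")


class TestFit:
    def test_noiseless_recovery_is_exact(self, fixture_X):
        beta = np.array([1.0, 0.5, -0.5, 0.3, -2.0, 3.0])
        y = pd.Series(fixture_X.to_numpy() @ beta, index=fixture_X.index)
        fit = mb.fit_trait_model(y, fixture_X)
        assert np.allclose(fit.coefficients["estimate_log"], beta, atol=1e-10)
        assert np.allclose(fit.coefficients["estimate"], np.exp(beta), atol=1e-9)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-9)
        # full-dummy encoding spans the constant: F tested against intercept-only
        assert fit.df_num == 5
        assert fit.df_den == 10

    def test_constant_response_gives_zero_continuous_coefficients(self, fixture_X):
        y = pd.Series(2.0, index=fixture_X.index)
        fit = mb.fit_trait_model(y, fixture_X)
        for term in ("log_volume", "mismatch", "gc"):
            assert fit.coefficients.loc[term, "estimate_log"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, fixture_X):
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=len(fixture_X)), index=fixture_X.index)
        fit = mb.fit_trait_model(y, fixture_X)
        X = fixture_X.to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert np.allclose(fit.coefficients["estimate_log"], oracle, atol=1e-8)
        # residuals orthogonal to every design column
        resid = y.to_numpy() - X @ oracle
        assert np.abs(X.T @ resid).max() < 1e-8 * len(y)

    def test_rank_deficient_design_names_columns(self, fixture_X):
        X = fixture_X.copy()
        X["gc_copy"] = X["gc"]
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=len(X)), index=X.index)
        with pytest.raises(ValueError, match="gc_copy"):
            mb.fit_trait_model(y, X)


class TestBootstrapCis:
    def test_identical_replicates_collapse_to_point(self, fixture_X):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=len(fixture_X)), index=fixture_X.index)
        reps = np.tile(y.to_numpy(), (10, 1))
        fit = mb.bootstrap_trait_cis(y, fixture_X, reps)
        assert np.allclose(fit.coefficients["ci_lo"], fit.coefficients["estimate"], atol=1e-9)
        assert np.allclose(fit.coefficients["ci_hi"], fit.coefficients["estimate"], atol=1e-9)

    def test_deterministic_given_replicates(self, fixture_X):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=len(fixture_X)), index=fixture_X.index)
        reps = y.to_numpy() + rng.normal(0, 0.2, size=(50, len(y)))
        a = mb.bootstrap_trait_cis(y, fixture_X, reps)
        b = mb.bootstrap_trait_cis(y, fixture_X, reps)
        assert a.coefficients.equals(b.coefficients)

    def test_nan_rows_are_refit_on_subset(self, fixture_X):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=len(fixture_X)), index=fixture_X.index)
        reps = y.to_numpy() + rng.normal(0, 0.2, size=(40, len(y)))
        reps[::2, 0] = np.nan  # a taxon absent from half the resamples
        fit = mb.bootstrap_trait_cis(y, fixture_X, reps)
        assert np.isfinite(fit.coefficients[["ci_lo", "ci_hi"]]).all().all()

    def test_requires_two_replicates(self, fixture_X):
        y = pd.Series(0.0, index=fixture_X.index)
        with pytest.raises(ValueError):
            mb.bootstrap_trait_cis(y, fixture_X, y.to_numpy()[None, :])


class TestMismatchProportion:
    def test_perfect_match(self):
        assert mb.mismatch_proportion("ACGT", "ACGT") == 0.0

    def test_degenerate_base_covers_template(self):
        assert mb.mismatch_proportion("GGD", "GGA") == 0.0  # D = A/G/T

    def test_three_mismatches_in_26(self):
        primer = "GGDACWGGWTGAACWGTWTAYCCHCC"  # 26 nt
        template = list(primer.replace("D", "A").replace("W", "A")
                        .replace("Y", "C").replace("H", "A"))
        # force incompatibility at three positions
        template[0] = "T"   # G vs T
        template[1] = "T"   # G vs T
        template[-1] = "A"  # C vs A
        assert mb.mismatch_proportion(primer, "".join(template)) == pytest.approx(0.12)

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            mb.mismatch_proportion("AZG", "ACG")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mb.mismatch_proportion("ACGT", "ACG")


@pytest.mark.parametrize(
    "start, end, length",
    [(346, 551, 205), (346, 560, 214), (0, 0, 0)],
)
def test_amplicon_length(start, end, length):
    assert mb.amplicon_length(start, end) == length


def test_amplicon_length_rejects_reversed_coordinates():
    with pytest.raises(ValueError):
        mb.amplicon_length(551, 346)
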