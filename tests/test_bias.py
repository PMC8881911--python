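"""Bias estimator: identity, invariances, bootstrap behaviour, prediction."""

import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias.bias import GroupError


def _noiseless_group(design, bias, pools, n_reps=2, scale=1e6):
    """Counts built as close(expected x bias) at a large fixed depth."""
    cols = {}
    rows = []
    for pool in pools:
        expected = design.expected_composition(pool)
        obs = mb.close(expected * bias[expected.index]) * scale
        for rep in range(1, n_reps + 1):
            sid = f"pool{pool}.run{rep}"
            col = pd.Series(0.0, index=design.taxa)
            col[obs.index] = obs
            cols[sid] = col
            rows.append(
                {
                    "sample": sid,
                    "pool": pool,
                    "stage": "insect",
                    "extraction": "dneasy",
                    "primer": "p",
                    "run": rep,
                }
            )
    counts = pd.DataFrame(cols)
    meta = pd.DataFrame(rows).set_index("sample")
    return counts, meta


GROUP = {"stage": "insect"}


def test_estimator_recovers_known_bias_noiselessly(design):
    rng = np.random.default_rng(1)
    bias = pd.Series(np.exp(rng.normal(0, 1, 16)), index=design.taxa)
    counts, meta = _noiseless_group(design, bias, pools=[5, 7])
    est = mb.estimate_bias(counts, meta, design, GROUP)
    expected = mb.center(bias)
    assert np.allclose(
        np.log(est.efficiency.reindex(expected.index)), np.log(expected), atol=1e-9
    )


def test_estimator_identity_when_observed_equals_expected(design):
    ones = pd.Series(1.0, index=design.taxa)
    counts, meta = _noiseless_group(design, ones, pools=[1, 2, 3, 4])
    est = mb.estimate_bias(counts, meta, design, GROUP)
    assert np.allclose(est.efficiency.to_numpy(), 1.0, atol=1e-9)


def test_estimator_geometric_mean_of_errors():
    """Two samples with per-taxon errors (2,1,.5) and (8,1,.125) -> gm (4,1,.25)."""
    taxa = list("abc")
    design = mb.MockDesign(pd.DataFrame({1: [1, 1, 1]}, index=taxa))
    expected = design.expected_composition(1)
    errs = [pd.Series([2.0, 1.0, 0.5], index=taxa), pd.Series([8.0, 1.0, 0.125], index=taxa)]
    counts = pd.DataFrame(
        {f"s{i}": mb.close(expected * e) * 1e6 for i, e in enumerate(errs)}
    )
    meta = pd.DataFrame(
        {
            "pool": [1, 1],
            "stage": ["insect"] * 2,
            "extraction": ["dneasy"] * 2,
            "primer": ["p"] * 2,
            "run": [1, 2],
        },
        index=["s0", "s1"],
    )
    est = mb.estimate_bias(counts, meta, design, GROUP)
    assert np.allclose(est.efficiency.to_numpy(), [4.0, 1.0, 0.25], atol=1e-9)


def test_scale_invariance_per_sample(design):
    rng = np.random.default_rng(2)
    bias = pd.Series(np.exp(rng.normal(0, 0.5, 16)), index=design.taxa)
    counts, meta = _noiseless_group(design, bias, pools=[5, 7])
    est1 = mb.estimate_bias(counts, meta, design, GROUP)
    scaled = counts.copy()
    scaled.iloc[:, 0] *= 37.5  # sequencing depth is arbitrary
    est2 = mb.estimate_bias(scaled, meta, design, GROUP)
    assert np.allclose(est1.efficiency, est2.efficiency, atol=1e-12)


def test_global_bias_rescaling_invisible(design):
    rng = np.random.default_rng(3)
    b = pd.Series(np.exp(rng.normal(0, 0.5, 16)), index=design.taxa)
    c1, meta = _noiseless_group(design, b, pools=[5, 7])
    c2, _ = _noiseless_group(design, 3.0 * b, pools=[5, 7])
    e1 = mb.estimate_bias(c1, meta, design, GROUP)
    e2 = mb.estimate_bias(c2, meta, design, GROUP)
    assert np.allclose(e1.efficiency, e2.efficiency, atol=1e-9)


def test_empty_group_rejected(design):
    counts, meta = _noiseless_group(design, pd.Series(1.0, index=design.taxa), [1])
    with pytest.raises(GroupError):
        mb.estimate_bias(counts, meta, design, {"stage": "pcr"})


class TestBootstrap:
    def test_same_seed_is_bit_identical(self, design, experiment):
        group = {"stage": "dna", "primer": "fwhF2-fwhR2n"}
        kwargs = dict(n_boot=50, seed=123)
        a = mb.bootstrap_bias(experiment.counts, experiment.meta, design, group, **kwargs)
        b = mb.bootstrap_bias(experiment.counts, experiment.meta, design, group, **kwargs)
        assert a.efficiency.equals(b.efficiency)
        assert a.se_log.equals(b.se_log)
        assert np.array_equal(a.log_replicates, b.log_replicates)

    def test_point_estimate_matches_plain_estimator(self, design, experiment):
        group = {"stage": "pcr", "primer": "fwhF2-fwhR2n"}
        boot = mb.bootstrap_bias(experiment.counts, experiment.meta, design, group,
                                 n_boot=10, seed=0)
        point = mb.estimate_bias(experiment.counts, experiment.meta, design, group)
        assert np.allclose(boot.efficiency, point.efficiency)

    def test_single_replicate_gives_zero_se(self, design):
        bias = pd.Series(1.0, index=design.taxa)
        counts, meta = _noiseless_group(design, bias, pools=[5, 7])
        est = mb.bootstrap_bias(counts, meta, design, GROUP, n_boot=1, seed=1)
        assert np.allclose(est.se_log, 0.0)

    def test_single_sample_group_warns(self, design):
        bias = pd.Series(1.0, index=design.taxa)
        counts, meta = _noiseless_group(design, bias, pools=[5], n_reps=1)
        with pytest.warns(UserWarning, match="single sample"):
            est = mb.bootstrap_bias(counts, meta, design, GROUP, n_boot=20, seed=1)
        assert np.allclose(est.se_log, 0.0)

    def test_ci_brackets_point_estimate(self, design, experiment):
        group = {"stage": "insect", "extraction": "dneasy", "primer": "fwhF2-fwhR2n"}
        est = mb.bootstrap_bias(experiment.counts, experiment.meta, design, group,
                                n_boot=300, seed=5)
        inside = (est.ci_lower <= est.efficiency) & (est.efficiency <= est.ci_upper)
        assert inside.mean() >= 0.95
        assert (est.ci_lower <= est.ci50_lower).all()
        assert (est.ci50_upper <= est.ci_upper).all()


def test_estimator_error_shrinks_with_depth(design):
    """Log-scale estimation error should fall as sequencing depth grows."""
    rng = np.random.default_rng(8)
    taxa = design.taxa
    bias = mb.center(pd.Series(np.exp(rng.normal(0, 0.5, 16)), index=taxa))
    pools = [5, 7]

    def mean_log_rmse(depth, n_rep=30):
        errs = []
        for _ in range(n_rep):
            cols, rows = {}, []
            for pool in pools:
                expected = design.expected_composition(pool)
                p = mb.close(expected * bias[expected.index])
                for rep in range(4):
                    sid = f"p{pool}r{rep}"
                    col = pd.Series(0, index=taxa, dtype=np.int64)
                    col[p.index] = rng.multinomial(depth, p.to_numpy())
                    cols[sid] = col
                    rows.append({"sample": sid, "pool": pool, "stage": "insect",
                                 "extraction": "dneasy", "primer": "p", "run": rep})
            counts = pd.DataFrame(cols)
            meta = pd.DataFrame(rows).set_index("sample")
            est = mb.estimate_bias(counts, meta, design, GROUP)
            delta = np.log(est.efficiency) - np.log(bias.reindex(est.taxa))
            errs.append(float(np.sqrt(np.mean(delta**2))))
        return np.mean(errs)

    assert mean_log_rmse(200_000) < mean_log_rmse(2_000)


class TestPredictComposition:
    def test_identity_bias(self):
        exp = pd.Series([0.3, 0.7], index=["a", "b"])
        ones = pd.Series([1.0, 1.0], index=["a", "b"])
        assert np.allclose(mb.predict_composition(exp, ones), exp)

    def test_forced_example(self):
        exp = pd.Series([0.5, 0.5], index=["a", "b"])
        bias = pd.Series([3.0, 1.0], index=["a", "b"])
        assert np.allclose(mb.predict_composition(exp, bias).to_numpy(), [0.75, 0.25])

    def test_mismatched_taxa_rejected(self):
        with pytest.raises(mb.CompositionError):
            mb.predict_composition(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )

    def test_round_trip_on_noiseless_data(self, design):
        rng = np.random.default_rng(4)
        bias = pd.Series(np.exp(rng.normal(0, 0.5, 16)), index=design.taxa)
        counts, meta = _noiseless_group(design, bias, pools=[5, 7])
        est = mb.estimate_bias(counts, meta, design, GROUP)
        obs, pred = mb.observed_expected_pairs(
            counts, meta, design, GROUP, bias=est.efficiency
        )
        assert mb.rmse(obs, pred) == pytest.approx(0.0, abs=1e-6)
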