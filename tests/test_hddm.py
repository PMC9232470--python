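"""Hierarchical sampler mechanics, diagnostics and model comparison."""

import numpy as np
import pytest

from dualsource import hddm
from dualsource.behavior_stats import preprocess
from dualsource.hddm import (
    VARIANTS,
    PosteriorSamples,
    VariantSpec,
    gelman_rubin,
    posterior_prob_greater,
    prepare_data,
    sample_posterior,
)
from dualsource.synthetic_data import CohortSpec, generate_cohort


def make_samples(group_mean_v, rng=None, n=800, m=3):
    """Hand-built PosteriorSamples with only a condition-varying v."""
    rng = rng or np.random.default_rng(0)
    variant = VARIANTS["v+a"]
    gm = {
        "v": np.stack([np.column_stack([rng.normal(mu, sd, n) for mu, sd in group_mean_v])
                       for _ in range(m)]),
        "a": rng.normal(1.5, 0.1, size=(m, n, 4)),
        "ter": rng.normal(0.3, 0.02, size=(m, n, 1)),
    }
    return PosteriorSamples(
        variant=variant,
        group_mean=gm,
        group_sd={k: np.abs(rng.normal(0.3, 0.05, v.shape)) for k, v in gm.items()},
        subject={k: np.repeat(v[:, :, None, :], 2, axis=2) for k, v in gm.items()},
        loglik=rng.normal(-500, 5, size=(m, n)),
        subject_ids=(0, 1), outlier_frac=0.05, t_max=4.0, n_burn=0,
    )


class TestVariantSpec:
    def test_the_four_variants(self):
        assert set(VARIANTS) == {"v+a", "v+ter", "a+ter", "v+a+ter"}
        assert VARIANTS["v+a+ter"].n_levels("v") == 4
        assert VARIANTS["v+a"].n_levels("ter") == 1

    def test_invalid_subsets_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec(frozenset({"v"}))
        with pytest.raises(ValueError):
            VariantSpec(frozenset({"v", "z"}))


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        s = make_samples([(1.0, 0.2)] * 4)
        rhat = gelman_rubin(s)
        assert max(rhat.values()) == pytest.approx(1.0, abs=0.01)

    def test_offset_chain_flagged(self):
        s = make_samples([(1.0, 0.2)] * 4)
        # shift one chain of v[CON] by 5 SD: clearly divergent
        s.group_mean["v"][0, :, 0] += 1.0
        rhat = gelman_rubin(s)
        assert rhat["mean_v[CON]"] > 1.1

    def test_single_chain_rejected(self):
        s = make_samples([(1.0, 0.2)] * 4, m=1)
        with pytest.raises(ValueError):
            gelman_rubin(s)


class TestPosteriorProbGreater:
    def test_identical_draws_give_zero_paired(self):
        s = make_samples([(1.0, 0.2)] * 4)
        s.group_mean["v"][:, :, 1] = s.group_mean["v"][:, :, 0]
        assert posterior_prob_greater(s, ("v", "CON_BSL"), ("v", "CON")) == 0.0

    def test_identical_distributions_permuted_near_half(self):
        s = make_samples([(1.0, 0.2)] * 4)
        p = posterior_prob_greater(s, ("v", "CON_BSL"), ("v", "CON"),
                                   method="permuted", rng=1)
        assert p == pytest.approx(0.5, abs=0.03)

    def test_separated_posteriors_near_one(self):
        s = make_samples([(5.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)])
        assert posterior_prob_greater(s, ("v", "CON"), ("v", "CON_BSL")) > 0.999

    def test_absent_parameter_rejected(self):
        s = make_samples([(1.0, 0.2)] * 4)
        with pytest.raises(KeyError):
            posterior_prob_greater(s, ("ter", "CON"), ("ter", "CON_BSL"))


@pytest.fixture(scope="module")
def tiny_fit():
    """A deliberately small end-to-end fit reused across tests."""
    spec = CohortSpec(n_per_group=4, group_angles=(20,), seed=5)
    trials, truth = generate_cohort(spec)
    trials = trials[trials.block <= 2]
    kept, _ = preprocess(trials)
    data = prepare_data(kept)
    fit = sample_posterior(data, "v+a", n_samples=1000, n_burn=400,
                           n_chains=2, seed=9)
    return data, fit, truth


class TestSampler:
    def test_determinism_under_fixed_seed(self, tiny_fit):
        data, fit, _ = tiny_fit
        again = sample_posterior(data, "v+a", n_samples=1000, n_burn=400,
                                 n_chains=2, seed=9)
        np.testing.assert_array_equal(fit.group_mean["v"], again.group_mean["v"])
        np.testing.assert_array_equal(fit.loglik, again.loglik)

    def test_positivity_of_constrained_draws(self, tiny_fit):
        _, fit, _ = tiny_fit
        assert (fit.subject["a"] > 0).all()
        assert (fit.subject["ter"] > 0).all()
        assert (fit.group_sd["v"] > 0).all()

    def test_posterior_mean_in_plausible_range(self, tiny_fit):
        _, fit, truth = tiny_fit
        v_hat = fit.group_mean["v"].mean(axis=(0, 1))
        v_true = truth.groupby("condition").v.mean().reindex(
            ["CON", "CON_BSL", "INC", "INC_BSL"]).to_numpy()
        # loose band: tiny data, tiny chains - this is a smoke check
        assert np.all(np.abs(v_hat - v_true) < 0.8)

    def test_dic_identical_for_identical_fit(self, tiny_fit):
        data, fit, _ = tiny_fit
        assert hddm.dic(fit, data) == hddm.dic(fit, data)

    def test_burn_in_validation(self, tiny_fit):
        data, _, _ = tiny_fit
        with pytest.raises(ValueError):
            sample_posterior(data, "v+a", n_samples=100, n_burn=100, n_chains=2)

    def test_single_subject_flagged_prior_dominated(self):
        spec = CohortSpec(n_per_group=2, group_angles=(20,), seed=3)
        trials, _ = generate_cohort(spec)
        trials = trials[(trials.subject_id == 0) & (trials.block <= 2)]
        kept, _ = preprocess(trials)
        with pytest.warns(UserWarning, match="prior-dominated"):
            data = prepare_data(kept)
        assert data.n_subjects == 1


class TestModelSelection:
    def test_dic_prefers_a_variant_containing_v_when_only_v_varies(self):
        """Data generated with only the drift varying by condition (a and ter
        shared) should be best described by a variant that lets v vary."""
        means = {
            "v": {"CON": 0.40, "CON_BSL": 1.40, "INC": 0.90, "INC_BSL": 0.90},
            "a": {c: 1.60 for c in ("CON", "CON_BSL", "INC", "INC_BSL")},
            "ter": {c: 0.35 for c in ("CON", "CON_BSL", "INC", "INC_BSL")},
        }
        spec = CohortSpec(n_per_group=8, group_angles=(20,), group_means=means,
                          seed=55)
        trials, _ = generate_cohort(spec)
        trials = trials[trials.block <= 2]
        kept, _ = preprocess(trials)
        data = prepare_data(kept)
        dics = {}
        for name in VARIANTS:
            fit = sample_posterior(data, name, n_samples=1500, n_burn=500,
                                   n_chains=2, seed=66)
            dics[name] = hddm.dic(fit, data)
        best = min(dics, key=dics.get)
        assert "v" in VARIANTS[best].varies_by_condition, dics


class TestPosteriorPredict:
    def test_schema_and_quantile_monotonicity(self, tiny_fit):
        data, fit, _ = tiny_fit
        example, summary = hddm.posterior_predict(fit, data, n_sims=3, rng=2)
        assert set(summary.condition) == {"CON", "CON_BSL", "INC", "INC_BSL"}
        assert (summary.rt_q10 < summary.rt_q50).all()
        assert (summary.rt_q50 < summary.rt_q90).all()
        assert len(example) == data.n_trials

    def test_predictive_accuracy_tracks_data(self, tiny_fit):
        data, fit, _ = tiny_fit
        _, summary = hddm.posterior_predict(fit, data, n_sims=10, rng=4)
        for c, cond in enumerate(("CON", "CON_BSL", "INC", "INC_BSL")):
            accs = []
            for s in range(data.n_subjects):
                cid = data.cell(s, c)
                sl = slice(data.cell_start[cid], data.cell_end[cid])
                accs.append(data.upper[sl].mean())
            observed = float(np.mean(accs))
            predicted = float(summary.loc[summary.condition == cond, "accuracy"].iloc[0])
            assert predicted == pytest.approx(observed, abs=0.08)
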