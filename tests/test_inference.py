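import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmasplit.inference import (
    assemble_model,
    build_contrast_transform,
    build_re_covariance,
    gelman_rubin,
    sample_posterior,
    PosteriorSamples,
)
from nmasplit.model_gen import consistency_structure, make_priors, nodesplit_structure
from nmasplit.network_core import (
    ArmMeasurement,
    ComparisonPair,
    ContrastMeasurement,
    Network,
    NetworkError,
    Study,
)

from conftest import make_arm_study, make_network


def pair(text):
    return ComparisonPair.parse(text)


class TestReCovariance:
    def test_two_contrasts(self):
        np.testing.assert_allclose(
            build_re_covariance(2, 1.0), [[1.0, 0.5], [0.5, 1.0]]
        )

    def test_single_contrast(self):
        np.testing.assert_allclose(build_re_covariance(1, 2.0), [[4.0]])

    def test_split_first_row(self):
        np.testing.assert_allclose(
            build_re_covariance(3, 1.0, split_index=0),
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.5], [0.0, 0.5, 1.0]],
        )

    def test_sigma_must_be_positive(self):
        with pytest.raises(NetworkError):
            build_re_covariance(2, 0.0)

    @given(
        n=st.integers(min_value=2, max_value=8),
        sigma=st.floats(min_value=0.01, max_value=10.0),
    )
    @settings(max_examples=50)
    def test_eigenvalues(self, n, sigma):
        cov = build_re_covariance(n, sigma)
        eig = np.sort(np.linalg.eigvalsh(cov))
        np.testing.assert_allclose(eig[:-1], sigma**2 / 2, rtol=1e-9)
        np.testing.assert_allclose(eig[-1], sigma**2 * (n + 1) / 2, rtol=1e-9)
        assert eig[0] > 0

    def test_split_positive_definite(self):
        cov = build_re_covariance(4, 0.7, split_index=2)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert np.allclose(cov, cov.T)


class _PlanStub:
    def __init__(self, reference, nonref):
        self.reference = reference
        self.nonref = tuple(nonref)


class TestContrastTransform:
    def test_two_arm_identity(self):
        study = Study(
            "s", (ContrastMeasurement("P"), ContrastMeasurement("Q", 1.2, 0.5))
        )
        spec = build_contrast_transform(study, _PlanStub("P", ["Q"]))
        np.testing.assert_allclose(spec.A, [[1.0]])
        np.testing.assert_allclose(spec.Sigma, [[0.25]])
        np.testing.assert_allclose(spec.observed, [1.2])

    def test_three_arm_rereferencing(self):
        # reported against t, desired reference b, third arm c:
        # d'_tb = -d_bt ; d'_tc = d_bc - d_bt
        study = Study(
            "s",
            (
                ContrastMeasurement("t", base_std_err=0.2),
                ContrastMeasurement("b", -0.5, 0.3),
                ContrastMeasurement("c", 0.4, 0.4),
            ),
        )
        spec = build_contrast_transform(study, _PlanStub("b", ["t", "c"]))
        np.testing.assert_allclose(spec.A, [[-1.0, 0.0], [-1.0, 1.0]])

    def test_sigma_construction_and_spd(self):
        study = Study(
            "s",
            (
                ContrastMeasurement("a", base_std_err=0.2),
                ContrastMeasurement("b", 0.1, 0.3),
                ContrastMeasurement("c", 0.2, 0.4),
            ),
        )
        spec = build_contrast_transform(study, _PlanStub("a", ["b", "c"]))
        np.testing.assert_allclose(spec.Sigma, [[0.09, 0.04], [0.04, 0.16]])
        assert np.all(np.linalg.eigvalsh(spec.Sigma) > 0)

    def test_arm_study_rejected(self):
        study = make_arm_study(1, ("a", "b"))
        with pytest.raises(NetworkError):
            build_contrast_transform(study, _PlanStub("a", ["b"]))


class TestAssembleModel:
    def test_parkinson_consistency_counts(self, parkinson):
        priors = make_priors(parkinson)
        model = assemble_model(parkinson, consistency_structure(parkinson), priors)
        mus = [n for n in model.names if n.startswith("mu.")]
        ds = [n for n in model.names if n.startswith("d.")]
        assert len(mus) == 7 and len(ds) == 4
        assert model.n_obs == 15  # total arms: 2+2+3+2+2+2+2

    def test_parkinson_split_bd_counts(self, parkinson):
        priors = make_priors(parkinson)
        structure = nodesplit_structure(parkinson, pair("B:D"))
        model = assemble_model(parkinson, structure, priors)
        mus = [n for n in model.names if n.startswith("mu.")]
        assert len(mus) == 7  # study 3's single-arm remainder dropped
        assert "d.dir.B.D" in model.names
        assert sum(n.startswith("d.") for n in model.names) == 5

    def test_degenerate_two_treatment(self):
        net = make_network(("x", "y"), ("x", "y"))
        model = assemble_model(net, consistency_structure(net), make_priors(net))
        assert sorted(model.names) == ["d.x.y", "mu.1", "mu.2"]

    def test_structure_network_mismatch(self, parkinson):
        other = make_network(("x", "y"))
        with pytest.raises(NetworkError):
            assemble_model(other, consistency_structure(parkinson), make_priors(other))

    def test_within_trial_coherence(self, parkinson):
        """Consistency-contrast expressions obey the tree algebra exactly."""
        from nmasplit.model_gen import express_functional

        priors = make_priors(parkinson)
        structure = consistency_structure(parkinson)
        model = assemble_model(parkinson, structure, priors)
        col = {n: i for i, n in enumerate(model.names)}
        for plan, blk in zip(structure.plans, model.blocks):
            for j, t in enumerate(plan.nonref):
                expected = np.zeros(len(model.names))
                for (a, b), c in express_functional(structure, (plan.reference, t)).items():
                    expected[col[f"d.{a}.{b}"]] = c
                np.testing.assert_array_equal(blk.W[j], expected)


class TestSampler:
    def test_deterministic_given_seed(self, parkinson):
        priors = make_priors(parkinson)
        model = assemble_model(parkinson, consistency_structure(parkinson), priors)
        a = sample_posterior(model, n_chains=2, n_adapt=50, n_iter=100, seed=7)
        b = sample_posterior(model, n_chains=2, n_adapt=50, n_iter=100, seed=7)
        assert np.array_equal(a.draws, b.draws)
        c = sample_posterior(model, n_chains=2, n_adapt=50, n_iter=100, seed=8)
        assert not np.array_equal(a.draws, c.draws)

    def test_fixed_sigma_matches_fixed_effect_oracle(self):
        studies = (
            Study("1", (ArmMeasurement("P", 0.1, 2.0, 100), ArmMeasurement("Q", 0.9, 2.0, 100))),
            Study("2", (ArmMeasurement("P", -0.2, 2.0, 100), ArmMeasurement("Q", 0.5, 2.0, 100))),
        )
        net = Network(studies)
        priors = make_priors(net)
        model = assemble_model(net, consistency_structure(net), priors)
        smp = sample_posterior(
            model, n_chains=2, n_adapt=200, n_iter=4000, seed=3, sigma_fixed=0.01
        )
        d = smp.pooled("d.P.Q")
        se2 = 2 * (2.0**2 / 100)
        oracle = (0.8 + 0.7) / 2  # equal weights
        mcse = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - oracle) < 3 * mcse

    def test_contrast_arm_equivalence(self):
        """A 2-arm arm-based study converted to contrast form gives the
        same posterior for d within Monte-Carlo error."""
        arm_net = Network(
            (
                Study("1", (ArmMeasurement("P", 0.1, 2.0, 100), ArmMeasurement("Q", 0.9, 2.0, 100))),
                Study("2", (ArmMeasurement("P", -0.2, 2.0, 100), ArmMeasurement("Q", 0.5, 2.0, 100))),
            )
        )
        pooled_se = np.sqrt(2 * 2.0**2 / 100)
        con_net = Network(
            (
                Study("1", (ContrastMeasurement("P"), ContrastMeasurement("Q", 0.8, pooled_se))),
                Study("2", (ContrastMeasurement("P"), ContrastMeasurement("Q", 0.7, pooled_se))),
            )
        )
        priors = make_priors(arm_net)
        draws = {}
        for label, net in (("arm", arm_net), ("contrast", con_net)):
            model = assemble_model(net, consistency_structure(net), priors)
            smp = sample_posterior(model, n_chains=2, n_adapt=300, n_iter=4000, seed=5)
            draws[label] = smp.pooled("d.P.Q")
        mcse = np.sqrt(
            draws["arm"].var() / draws["arm"].size
            + draws["contrast"].var() / draws["contrast"].size
        )
        assert abs(draws["arm"].mean() - draws["contrast"].mean()) < 4 * mcse

    def test_delta_sampling_records_columns(self, parkinson):
        priors = make_priors(parkinson)
        model = assemble_model(parkinson, consistency_structure(parkinson), priors)
        smp = sample_posterior(
            model, n_chains=2, n_adapt=50, n_iter=200, seed=1, sample_delta=True
        )
        delta_names = [n for n in smp.names if n.startswith("delta.")]
        # one delta per non-reference arm: 15 arms - 7 references
        assert len(delta_names) == 8
        assert np.all(np.isfinite(smp.draws))

    def test_split_model_records_dir_and_ind(self, parkinson):
        priors = make_priors(parkinson)
        structure = nodesplit_structure(parkinson, pair("B:D"))
        model = assemble_model(parkinson, structure, priors)
        smp = sample_posterior(model, n_chains=2, n_adapt=100, n_iter=300, seed=2)
        assert "d.dir.B.D" in smp.names and "d.ind.B.D" in smp.names
        # d.ind is the recorded linear combination of basic draws
        expected = smp.linear_combination(
            {name: coef for name, coef in model.indirect_expression.items()}
        )
        np.testing.assert_allclose(smp.pooled("d.ind.B.D"), expected)

    def test_sigma_draws_within_prior_support(self, parkinson):
        priors = make_priors(parkinson)
        model = assemble_model(parkinson, consistency_structure(parkinson), priors)
        smp = sample_posterior(model, n_chains=2, n_adapt=100, n_iter=500, seed=4)
        sigma = smp.pooled("sigma")
        assert np.all(sigma >= 0) and np.all(sigma <= priors.heterogeneity_upper)

    def test_requires_two_chains(self, parkinson):
        priors = make_priors(parkinson)
        model = assemble_model(parkinson, consistency_structure(parkinson), priors)
        with pytest.raises(NetworkError):
            sample_posterior(model, n_chains=1, n_adapt=10, n_iter=10, seed=1)

    def test_export_csv(self, parkinson, tmp_path):
        priors = make_priors(parkinson)
        model = assemble_model(parkinson, consistency_structure(parkinson), priors)
        smp = sample_posterior(model, n_chains=2, n_adapt=20, n_iter=50, seed=1)
        out = tmp_path / "draws.csv"
        smp.to_csv(out)
        import pandas as pd

        frame = pd.read_csv(out)
        assert {"chain", "iteration", "sigma"} <= set(frame.columns)
        assert len(frame) == 2 * 50


class TestGelmanRubin:
    def _samples(self, draws):
        draws = np.asarray(draws, dtype=float)
        return PosteriorSamples(
            names=("p",), draws=draws[:, :, None], seed=0, n_adapt=0,
            n_iter=draws.shape[1],
        )

    def test_identical_chains_near_one(self, rng):
        chain = rng.standard_normal(500)
        report = gelman_rubin(self._samples([chain, chain]))
        assert report.psrf["p"] == pytest.approx(1.0, abs=0.02)
        assert report.passed

    def test_shifted_chains_flagged(self, rng):
        a = rng.standard_normal(500)
        report = gelman_rubin(self._samples([a, a + 10.0]))
        assert report.psrf["p"] > 3.0
        assert not report.passed
        assert report.failures == ["p"]

    def test_single_chain_error(self, rng):
        with pytest.raises(NetworkError):
            gelman_rubin(self._samples([rng.standard_normal(100)]))

    def test_too_few_draws_error(self, rng):
        with pytest.raises(NetworkError):
            gelman_rubin(self._samples(rng.standard_normal((2, 5))))

    def test_constant_parameter_passes(self):
        report = gelman_rubin(self._samples(np.ones((2, 100))))
        assert report.psrf["p"] == 1.0
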