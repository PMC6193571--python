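import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import pedvar as pv
from pedvar.containers import LabeledMatrix
from pedvar.reml import FitResult

from conftest import make_pedigree


def contrast_loglik(theta, y, X, Gs):
    """Independent REML oracle: likelihood of error contrasts K'y, K'X = 0.

    Differs from the package's profiled form by the parameter-free constant
    -0.5 * log|X'X|.
    """
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], Gs):
        V = V + t * G
    Q, _ = np.linalg.qr(X, mode="complete")
    K = Q[:, X.shape[1] :]
    M = K.T @ V @ K
    _, ld = np.linalg.slogdet(M)
    z = K.T @ y
    return -0.5 * (ld + z @ np.linalg.solve(M, z))


def toy_model(seed=0, va=1.0, vr=1.0, n_generations=3, size=(16, 20)):
    """Small one-genetic-term model with A from a simulated pedigree."""
    cfg = pv.PedigreeConfig(n_generations=n_generations, size_range=size)
    ped = pv.simulate_pedigree(cfg, seed=seed)
    A = pv.build_relatedness(ped)
    rng = np.random.default_rng(seed + 1)
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(len(A)))
    y = np.sqrt(va) * (L @ rng.standard_normal(len(A))) + np.sqrt(vr) * rng.standard_normal(len(A))
    traits = pd.DataFrame({"id": ped["id"], "y": y})
    spec = pv.ModelSpec("y", (pv.RandomTerm("additive", "A"),))
    return pv.assemble(spec, traits, ped, {"A": A})


class TestAssemble:
    def test_self_carrier_is_identity_incidence(self, small_population, small_matrices):
        spec = pv.ModelSpec(
            "y1", (pv.RandomTerm("additive", "A"), pv.RandomTerm("env", "Sn"))
        )
        model = pv.assemble(
            spec, small_population.traits, small_population.pedigree, small_matrices
        )
        for k in range(2):
            Z = model.incidence(k)
            np.testing.assert_array_equal(Z, np.eye(model.n))
            assert np.all(Z.sum(axis=1) == 1.0)

    def test_dam_carrier_groups_full_sibs(self, small_population, small_matrices):
        spec = pv.ModelSpec(
            "y2",
            (
                pv.RandomTerm("additive", "A"),
                pv.RandomTerm("maternal_env", "Sn", "dam"),
            ),
        )
        pop = small_population
        model = pv.assemble(spec, pop.traits, pop.pedigree, small_matrices)
        ped = pop.pedigree.set_index("id")
        dams = ped.loc[model.record_ids, "dam"].to_numpy()
        # one column per distinct dam, phantom dams included
        assert len(model.levels[1]) == len(np.unique(dams))
        # full sibs share a column
        sibs = np.where(dams == dams[0])[0]
        assert len(set(model.level_index[1][sibs])) == 1
        assert np.all(model.incidence(1).sum(axis=1) == 1.0)

    def test_missing_matrix_rejected(self, small_population):
        spec = pv.ModelSpec("y1", (pv.RandomTerm("env", "Sn"),))
        with pytest.raises(KeyError):
            pv.assemble(spec, small_population.traits, small_population.pedigree, {})


class TestRestrictedLoglik:
    def test_matches_contrast_oracle_up_to_constant(self):
        model = toy_model(seed=0)
        const = -0.5 * np.linalg.slogdet(model.X.T @ model.X)[1]
        for theta in ([1.0, 1.0], [0.3, 2.0], [2.5, 0.4]):
            ours = pv.restricted_loglik(theta, model)
            oracle = contrast_loglik(np.array(theta), model.y, model.X, model.G)
            assert ours == pytest.approx(oracle + const, rel=1e-10)

    def test_five_record_textbook_value(self):
        # tiny hand-checkable model: direct dense-algebra computation
        y = np.array([1.0, 2.0, 0.5, -1.0, 0.3])
        G = np.array(
            [
                [1.0, 0.5, 0.0, 0.0, 0.0],
                [0.5, 1.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0, 0.5],
                [0.0, 0.0, 0.0, 0.5, 1.0],
            ]
        )
        ped = make_pedigree([(i, 0, 0, 0, "F") for i in range(1, 6)])
        traits = pd.DataFrame({"id": ped["id"], "y": y})
        spec = pv.ModelSpec("y", (pv.RandomTerm("g", "G"),))
        model = pv.assemble(
            spec, traits, ped, {"G": LabeledMatrix(ped["id"].to_numpy(), G)}
        )
        theta = np.array([0.7, 1.3])
        V = 0.7 * G + 1.3 * np.eye(5)
        X = np.ones((5, 1))
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        expected = -0.5 * (
            np.linalg.slogdet(V)[1]
            + np.log((X.T @ Vi @ X).item())
            + (y @ P @ y).item()
        )
        assert pv.restricted_loglik(theta, model) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_translation_of_response(self):
        model = toy_model(seed=6)
        base = pv.restricted_loglik([0.8, 1.1], model)
        model.y = model.y + 57.3
        assert pv.restricted_loglik([0.8, 1.1], model) == pytest.approx(base, rel=1e-9)

    def test_rejects_nonpositive_params(self):
        model = toy_model(seed=0)
        with pytest.raises(ValueError):
            pv.restricted_loglik([0.0, 1.0], model)


class TestRemlFit:
    def test_matches_direct_likelihood_maximization(self):
        """AI-REML optimum agrees with a derivative-free search of the
        restricted likelihood (independent contrast-based evaluation)."""
        model = toy_model(seed=4)
        fit = pv.reml_fit(model)

        def neg(logtheta):
            return -contrast_loglik(np.exp(logtheta), model.y, model.X, model.G)

        res = optimize.minimize(
            neg, np.log(fit.estimates), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        oracle = np.exp(res.x)
        np.testing.assert_allclose(fit.estimates, oracle, rtol=1e-3)

    def test_loglik_nondecreasing_along_iterates(self):
        model = toy_model(seed=9)
        fit = pv.reml_fit(model)
        lls = [l for l, _ in fit.trace]
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_identity_covariance_partitions_sample_variance(self):
        """With S = I and one term the optimum is unidentifiable up to the
        split; the total must match the ANOVA variance and the likelihood
        is maximal along probed points."""
        rng = np.random.default_rng(5)
        n = 80
        ped = make_pedigree([(i, 0, 0, 0, "F") for i in range(1, n + 1)])
        y = rng.standard_normal(n) * 1.5
        traits = pd.DataFrame({"id": ped["id"], "y": y})
        spec = pv.ModelSpec("y", (pv.RandomTerm("grp", "identity"),))
        model = pv.assemble(spec, traits, ped, {})
        fit = pv.reml_fit(model)
        assert fit.total_variance == pytest.approx(np.var(y, ddof=1), rel=1e-6)
        for probe in ([0.5, 0.5], [1.0, 2.0], [2.0, 0.3]):
            assert fit.loglik >= pv.restricted_loglik(probe, model) - 1e-8

    def test_scale_equivariance(self):
        model = toy_model(seed=2)
        fit1 = pv.reml_fit(model)
        h2_1, _ = pv.heritability(fit1)
        c = 3.7
        model.y = model.y * c
        fit2 = pv.reml_fit(model)
        h2_2, _ = pv.heritability(fit2)
        np.testing.assert_allclose(fit2.estimates, c**2 * fit1.estimates, rtol=1e-5)
        assert h2_2 == pytest.approx(h2_1, rel=1e-5)

    def test_permutation_invariance(self, small_population, small_matrices):
        pop = small_population
        spec = pv.ModelSpec(
            "y1", (pv.RandomTerm("additive", "A"), pv.RandomTerm("env", "Sn"))
        )
        m1 = pv.assemble(spec, pop.traits, pop.pedigree, small_matrices)
        f1 = pv.reml_fit(m1)
        rng = np.random.default_rng(0)
        shuffled = pop.traits.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = pv.assemble(spec, shuffled, pop.pedigree, small_matrices)
        f2 = pv.reml_fit(m2)
        np.testing.assert_allclose(f1.estimates, f2.estimates, rtol=1e-4)

    def test_rejects_constant_response(self):
        ped = make_pedigree([(i, 0, 0, 0, "F") for i in range(1, 10)])
        traits = pd.DataFrame({"id": ped["id"], "y": np.ones(9)})
        spec = pv.ModelSpec("y", (pv.RandomTerm("grp", "identity"),))
        model = pv.assemble(spec, traits, ped, {})
        with pytest.raises(ValueError):
            pv.reml_fit(model)


def _dummy_fit(names, estimates, loglik=0.0, vcov=None):
    k = len(estimates)
    vcov = np.eye(k) * 0.01 if vcov is None else vcov
    return FitResult(
        term_names=list(names),
        estimates=np.asarray(estimates, dtype=float),
        se=np.sqrt(np.diag(vcov)),
        vcov=vcov,
        loglik=loglik,
        converged=True,
        n_iter=1,
        trace=[],
        at_bound=np.zeros(k, dtype=bool),
        n=100,
    )


class TestHeritability:
    def test_matches_reported_arithmetic(self):
        # Va=1.1, Vn=0.986, Vr=0.894 -> h2 = 1.1 / 2.98 ~ 0.369
        fit = _dummy_fit(["additive", "env", "residual"], [1.1, 0.986, 0.894])
        h2, _ = pv.heritability(fit)
        assert h2 == pytest.approx(1.1 / 2.98, abs=1e-12)
        assert h2 == pytest.approx(0.369, abs=0.001)

    def test_no_residual_variance_gives_unit_heritability(self):
        fit = _dummy_fit(["additive", "residual"], [2.0, 0.0])
        h2, _ = pv.heritability(fit)
        assert h2 == pytest.approx(1.0)

    def test_delta_method_se_close_to_parametric_bootstrap(self):
        model = toy_model(seed=1, n_generations=4, size=(32, 36))
        fit = pv.reml_fit(model)
        h2, se = pv.heritability(fit)
        rng = np.random.default_rng(11)
        V = fit.estimates[0] * model.G[0] + fit.estimates[1] * np.eye(model.n)
        L = np.linalg.cholesky(V)
        boots = []
        for _ in range(200):
            model.y = L @ rng.standard_normal(model.n)
            bfit = pv.reml_fit(model)
            boots.append(pv.heritability(bfit)[0])
        boot_se = np.std(boots, ddof=1)
        assert se == pytest.approx(boot_se, rel=0.25)


class TestLrt:
    def test_equal_likelihood_gives_p_one(self):
        full = _dummy_fit(["a", "b", "residual"], [1, 1, 1], loglik=-10.0)
        red = _dummy_fit(["a", "residual"], [1, 1], loglik=-10.0)
        stat, p = pv.lrt(full, red)
        assert stat == 0.0 and p == 1.0

    def test_boundary_mixture_quantile(self):
        # statistic 2.706 is the 5% point of the 0.5*chi2_0 + 0.5*chi2_1 mix
        full = _dummy_fit(["a", "b", "residual"], [1, 1, 1], loglik=-8.647)
        red = _dummy_fit(["a", "residual"], [1, 1], loglik=-10.0)
        stat, p = pv.lrt(full, red)
        assert stat == pytest.approx(2.706, abs=1e-9)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_rejects_higher_reduced_likelihood(self):
        full = _dummy_fit(["a", "b", "residual"], [1, 1, 1], loglik=-12.0)
        red = _dummy_fit(["a", "residual"], [1, 1], loglik=-10.0)
        with pytest.raises(ValueError):
            pv.lrt(full, red)

    def test_type_one_error_at_most_nominal(self):
        """Null simulation: no environmental effect in y, test the env term.

        The boundary-corrected LRT should reject at 5% at most ~5% of the
        time (it is conservative if anything).
        """
        cfg = pv.SimulationConfig(
            pedigree=pv.PedigreeConfig(n_generations=3, size_range=(35, 45)),
            grid=pv.GridSpec(20, 20),
        )
        reps = 200
        rejections = 0
        for seed in range(reps):
            pop = pv.simulate_population(
                cfg, seed=seed, include_epialleles=False, include_network=False
            )
            mats = pv.build_all_matrices(pop)
            null = pop.traits.copy()
            null["y"] = null["a"] + null["r1"]  # genetic + residual only
            full = pv.reml_fit(
                pv.assemble(
                    pv.ModelSpec(
                        "y",
                        (pv.RandomTerm("additive", "A"), pv.RandomTerm("env", "Sn")),
                    ),
                    null,
                    pop.pedigree,
                    mats,
                )
            )
            red = pv.reml_fit(
                pv.assemble(
                    pv.ModelSpec("y", (pv.RandomTerm("additive", "A"),)),
                    null,
                    pop.pedigree,
                    mats,
                )
            )
            try:
                _, p = pv.lrt(full, red)
            except ValueError:
                continue
            rejections += p < 0.05
        rate = rejections / reps
        bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
        assert rate <= bound
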