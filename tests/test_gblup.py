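import numpy as np
import pandas as pd
import pytest

from oracles import gls_blup, random_mme_instance
from snp_prior_gs.gblup import (LITERATURE_VARCOMP, MaternalGBLUP,
                                ModelSpecificationError, VarianceComponents,
                                build_incidence)

LINE1_BW = LITERATURE_VARCOMP["line1"]["BW"]


class TestVarianceComponents:
    def test_non_positive_definite_rejected(self):
        with pytest.raises(ModelSpecificationError, match="positive definite"):
            VarianceComponents(10.0, 1.0, -5.0, 3.0)

    def test_maternal_dropped_requires_zero_covariance(self):
        with pytest.raises(ModelSpecificationError, match="cov_am"):
            VarianceComponents(10.0, 0.0, -1.0, 3.0)

    def test_literature_presets_are_valid(self):
        for pop in LITERATURE_VARCOMP.values():
            for vc in pop.values():
                assert vc.sigma_a2 > 0 and vc.sigma_e2 > 0


class TestIncidence:
    def _tables(self):
        ped = pd.DataFrame({"id": ["D", "A"], "sire": ["0", "0"],
                            "dam": ["0", "D"], "sex": ["F", "M"],
                            "birth_year": [2000, 2005]})
        ph = pd.DataFrame({"id": ["A"], "trait": ["BW"], "value": [40.0],
                           "sex": ["M"], "cg": ["2005x1"]})
        return ped, ph

    def test_z_selects_self_w_selects_dam(self):
        ped, ph = self._tables()
        des = build_incidence(ph, ped, ["D", "A"])
        assert des.Z.toarray().tolist() == [[0.0, 1.0]]
        assert des.W.toarray().tolist() == [[1.0, 0.0]]

    def test_unknown_dam_gives_zero_row(self):
        ped, ph = self._tables()
        ped.loc[1, "dam"] = "0"
        des = build_incidence(ph, ped, ["D", "A"])
        assert des.W.toarray().tolist() == [[0.0, 0.0]]
        assert des.n_missing_dam == 1

    def test_fixed_design_full_rank_after_drop(self):
        ped = pd.DataFrame({"id": list("ABCDE"), "sire": "0", "dam": "0",
                            "sex": ["M", "F", "M", "F", "M"],
                            "birth_year": 2000})
        ph = pd.DataFrame({"id": list("ABCDE"), "trait": "BW",
                           "value": [1.0, 2, 3, 4, 5],
                           "sex": ["M", "F", "M", "F", "M"],
                           "cg": ["a", "a", "b", "b", "b"]})
        des = build_incidence(ph, ped, list("ABCDE"))
        # oracle: rank of the explicit small matrix
        assert np.linalg.matrix_rank(des.X) == des.X.shape[1] == 3

    def test_phenotyped_animal_missing_from_grm_is_error(self):
        ped, ph = self._tables()
        with pytest.raises(ModelSpecificationError, match="absent"):
            build_incidence(ph, ped, ["D"])


class TestSolveAgainstOracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_full_maternal_model_matches_gls(self, seed):
        """MME solution equals brute-force GLS/BLUP via V inversion."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(15, 45))
        m = int(rng.integers(60, 200))
        g, f, grm, ped, ph = random_mme_instance(rng, n, m, LINE1_BW)
        model = MaternalGBLUP.from_tables(ph, ped, grm, LINE1_BW, trait="BW")
        res = model.fit(method="direct")
        b, a, mm = gls_blup(model.y, model.X, model.design.Z.toarray(),
                            model.design.W.toarray(), grm.values,
                            LINE1_BW.sigma_a2, LINE1_BW.sigma_m2,
                            LINE1_BW.cov_am, LINE1_BW.sigma_e2)
        np.testing.assert_allclose(res.fixed_estimates.to_numpy(), b, atol=1e-6)
        np.testing.assert_allclose(res.direct_gebv.to_numpy(), a, atol=1e-6)
        np.testing.assert_allclose(res.maternal_gebv.to_numpy(), mm, atol=1e-6)

    def test_single_effect_model_matches_direct_blup(self):
        """sigma_m2 = 0 reduces to standard GBLUP: a = sa2 G Z' V^-1 (y - Xb)."""
        rng = np.random.default_rng(7)
        vc = VarianceComponents(100.24, 0.0, 0.0, 150.32)
        g, f, grm, ped, ph = random_mme_instance(rng, 30, 120, vc)
        model = MaternalGBLUP.from_tables(ph, ped, grm, vc, trait="BW")
        res = model.fit(method="direct")
        Z = model.design.Z.toarray()
        V = vc.sigma_a2 * Z @ grm.values @ Z.T + vc.sigma_e2 * np.eye(len(model.y))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(model.X.T @ Vi @ model.X, model.X.T @ Vi @ model.y)
        a = vc.sigma_a2 * grm.values @ Z.T @ Vi @ (model.y - model.X @ b)
        np.testing.assert_allclose(res.direct_gebv.to_numpy(), a, atol=1e-6)
        np.testing.assert_allclose(res.maternal_gebv.to_numpy(), 0.0, atol=0)

    def test_no_genetics_limit_recovers_ols(self):
        """Vanishing genetic variance: GEBV -> 0 and b -> OLS estimates."""
        rng = np.random.default_rng(11)
        vc_tiny = VarianceComponents(1e-8, 0.0, 0.0, 150.0)
        g, f, grm, ped, ph = random_mme_instance(rng, 25, 100, vc_tiny)
        model = MaternalGBLUP.from_tables(ph, ped, grm, vc_tiny, trait="BW")
        res = model.fit()
        ols, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
        np.testing.assert_allclose(res.direct_gebv.to_numpy(), 0.0, atol=1e-5)
        np.testing.assert_allclose(res.fixed_estimates.to_numpy(), ols,
                                   atol=1e-5)

    def test_iterative_solver_agrees_with_direct(self):
        rng = np.random.default_rng(23)
        g, f, grm, ped, ph = random_mme_instance(rng, 35, 150, LINE1_BW)
        model = MaternalGBLUP.from_tables(ph, ped, grm, LINE1_BW, trait="BW")
        direct = model.fit(method="direct")
        cg = model.fit(method="cg")
        assert cg.converged
        np.testing.assert_allclose(cg.direct_gebv.to_numpy(),
                                   direct.direct_gebv.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(cg.fixed_estimates.to_numpy(),
                                   direct.fixed_estimates.to_numpy(), atol=1e-6)


class TestModelProperties:
    def test_shrinkage_monotone_in_noise_ratio(self):
        """Growing se2/sa2 shrinks the direct GEBV norm monotonically."""
        rng = np.random.default_rng(31)
        g, f, grm, ped, ph = random_mme_instance(
            rng, 30, 120, VarianceComponents(100.0, 0.0, 0.0, 50.0))
        norms = []
        for se2 in (50.0, 150.0, 450.0, 1350.0):
            vc = VarianceComponents(100.0, 0.0, 0.0, se2)
            res = MaternalGBLUP.from_tables(ph, ped, grm, vc, trait="BW").fit()
            norms.append(np.linalg.norm(res.direct_gebv.to_numpy()))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_record_order_invariance(self):
        rng = np.random.default_rng(41)
        g, f, grm, ped, ph = random_mme_instance(rng, 28, 110, LINE1_BW)
        res1 = MaternalGBLUP.from_tables(ph, ped, grm, LINE1_BW,
                                         trait="BW").fit()
        shuffled = ph.sample(frac=1.0, random_state=5)
        res2 = MaternalGBLUP.from_tables(shuffled, ped, grm, LINE1_BW,
                                         trait="BW").fit()
        np.testing.assert_allclose(res1.direct_gebv.to_numpy(),
                                   res2.direct_gebv.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(res1.fixed_estimates.to_numpy(),
                                   res2.fixed_estimates.to_numpy(), atol=1e-8)

    def test_summary_mentions_solver_and_components(self):
        rng = np.random.default_rng(43)
        g, f, grm, ped, ph = random_mme_instance(rng, 20, 80, LINE1_BW)
        res = MaternalGBLUP.from_tables(ph, ped, grm, LINE1_BW, trait="BW").fit()
        text = res.summary()
        assert "100.24" in text and "direct" in text.lower()


class TestCorrectedPhenotypes:
    def _fitted(self, rng=None):
        rng = rng or np.random.default_rng(53)
        g, f, grm, ped, ph = random_mme_instance(rng, 25, 90, LINE1_BW)
        res = MaternalGBLUP.from_tables(ph, ped, grm, LINE1_BW,
                                        trait="BW").fit()
        return res, ph

    def test_zero_fixed_effects_return_raw_values(self):
        res, ph = self._fitted()
        res.fixed_estimates[:] = 0.0
        yc = res.corrected_phenotypes(ph)
        np.testing.assert_allclose(yc.to_numpy(), ph["value"].to_numpy())

    def test_global_mean_gives_deviations(self):
        res, ph = self._fitted()
        res.fixed_estimates[:] = 0.0
        for name in res.fixed_estimates.index:
            if name.startswith("cg:"):
                res.fixed_estimates[name] = 10.0
        yc = res.corrected_phenotypes(ph)
        np.testing.assert_allclose(yc.to_numpy(), ph["value"].to_numpy() - 10.0)

    def test_hand_set_sex_contrast(self):
        res, ph = self._fitted()
        res.fixed_estimates[:] = 0.0
        sex_cols = [n for n in res.fixed_estimates.index if n.startswith("sex:")]
        assert sex_cols, "instance should have a sex contrast"
        res.fixed_estimates[sex_cols[0]] = 3.0
        lv = sex_cols[0].split(":", 1)[1]
        yc = res.corrected_phenotypes(ph)
        shift = (ph["sex"] == lv).to_numpy() * 3.0
        np.testing.assert_allclose(yc.to_numpy(), ph["value"].to_numpy() - shift)

    def test_unseen_level_dropped(self):
        res, ph = self._fitted()
        ph2 = ph.copy()
        ph2.loc[ph2.index[0], "cg"] = "never_seen"
        yc = res.corrected_phenotypes(ph2)
        assert len(yc) == len(ph2) - 1

    def test_all_unseen_is_an_error(self):
        res, ph = self._fitted()
        ph2 = ph.copy()
        ph2["cg"] = "never_seen"
        ph2["sex"] = "X"
        with pytest.raises(ModelSpecificationError, match="dropped"):
            res.corrected_phenotypes(ph2)
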