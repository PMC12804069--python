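import numpy as np
import pandas as pd
import pytest

from oracles import recursive_inbreeding
from snp_prior_gs.fst import compute_fst
from snp_prior_gs.gblup import VarianceComponents
from snp_prior_gs.io import UNKNOWN_PARENT
from snp_prior_gs.simulate import (PedigreeIntegrityError, SimScenario,
                                   SimulationConfigError, drop_genotypes,
                                   pedigree_inbreeding, simulate_dataset,
                                   simulate_pedigree)


def _tiny(**overrides):
    base = dict(n_founders=12, n_generations=4, sires_per_generation=2,
                dams_per_generation=5, offspring_per_generation=20,
                n_chromosomes=2, markers_per_chromosome=50, n_qtl=10,
                seed=1)
    base.update(overrides)
    return SimScenario(**base)


class TestPedigree:
    def test_zero_generations_gives_founders_only(self):
        ped = simulate_pedigree(_tiny(n_generations=0))
        assert len(ped) == 12
        assert (ped["sire"] == UNKNOWN_PARENT).all()
        assert (ped["dam"] == UNKNOWN_PARENT).all()

    def test_parents_always_appear_earlier(self):
        ped = simulate_pedigree(_tiny())
        seen = set()
        for row in ped.itertuples():
            for parent in (row.sire, row.dam):
                assert parent == UNKNOWN_PARENT or parent in seen
            seen.add(row.id)

    def test_inbreeding_accumulates_in_small_line(self):
        """Recursive-oracle inbreeding rises from generation 5 to 15."""
        sc = _tiny(n_generations=15, seed=2)
        ped = simulate_pedigree(sc)
        F = recursive_inbreeding(ped)
        by_gen = F.groupby(ped.set_index("id")["generation"]).mean()
        assert by_gen[15] > by_gen[5] > 0.0

    def test_tabular_inbreeding_matches_recursive_oracle(self):
        ped = simulate_pedigree(_tiny(n_generations=6, seed=5))
        np.testing.assert_allclose(pedigree_inbreeding(ped).to_numpy(),
                                   recursive_inbreeding(ped).to_numpy(),
                                   atol=1e-12)

    def test_composite_never_mates_full_sibs(self):
        sc = SimScenario.preset(
            "composite", n_founders=20, n_generations=6,
            sires_per_generation=4, dams_per_generation=8,
            offspring_per_generation=24, markers_per_chromosome=20,
            n_chromosomes=2, n_qtl=5, seed=9)
        ped = simulate_pedigree(sc)
        parents = {r.id: (r.sire, r.dam) for r in ped.itertuples()}
        for row in ped.itertuples():
            if row.sire == UNKNOWN_PARENT:
                continue
            ps, pd_ = parents[row.sire], parents[row.dam]
            assert not (ps == pd_ and ps[0] != UNKNOWN_PARENT)

    def test_impossible_design_rejected(self):
        with pytest.raises(SimulationConfigError):
            _tiny(sires_per_generation=0)
        with pytest.raises(SimulationConfigError):
            _tiny(dams_per_generation=1, sires_per_generation=2)

    def test_birth_years_span_study_window(self):
        ped = simulate_pedigree(_tiny(n_generations=4))
        assert ped["birth_year"].min() == 1990
        assert ped["birth_year"].max() == 2023


class TestGeneDropping:
    def test_zero_map_length_cosegregates(self):
        """L = 0: each gamete copies a single parental haplotype per chromosome."""
        sc = _tiny(chromosome_length_morgans=0.0)
        ped = simulate_pedigree(sc)
        g, haps = drop_genotypes(ped, sc, return_haplotypes=True)
        lut = {iid: i for i, iid in enumerate(ped["id"])}
        mc = sc.markers_per_chromosome
        for row in ped.itertuples():
            if row.sire == UNKNOWN_PARENT:
                continue
            i = lut[row.id]
            for parent, hap_idx in ((row.sire, 0), (row.dam, 1)):
                for c in range(sc.n_chromosomes):
                    sl = slice(c * mc, (c + 1) * mc)
                    block = haps[i, hap_idx, sl]
                    par = haps[lut[parent], :, sl]
                    assert (np.array_equal(block, par[0])
                            or np.array_equal(block, par[1]))

    def test_fixed_founder_allele_stays_fixed(self):
        sc = _tiny()
        ped = simulate_pedigree(sc)
        m = sc.n_chromosomes * sc.markers_per_chromosome
        g = drop_genotypes(ped, sc, founder_p=np.ones(m))
        assert np.all(g.dosage == 2)

    def test_heterozygosity_erodes_under_drift(self):
        sc = _tiny(n_generations=15, seed=4)
        ped = simulate_pedigree(sc)
        g = drop_genotypes(ped, sc)
        gen = ped.set_index("id")["generation"]

        def mean_het(generation):
            rows = [i for i, iid in enumerate(g.individual_ids)
                    if gen[iid] == generation]
            p = g.dosage[rows, :].mean(axis=0) / 2.0
            return float(np.mean(2 * p * (1 - p)))

        assert mean_het(15) < mean_het(1)

    def test_unknown_parent_reference_rejected(self):
        sc = _tiny()
        ped = simulate_pedigree(sc)
        ped.loc[ped.index[-1], "sire"] = "GHOST"
        with pytest.raises(PedigreeIntegrityError, match="GHOST"):
            drop_genotypes(ped, sc)


class TestPhenotypes:
    def test_qtl_breeding_value_identity_is_exact(self, small_dataset):
        """QTL component of the true BV equals centered QTL dosage x effects."""
        Q = small_dataset.qtl_dosage
        Qc = Q - Q.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(
            small_dataset.truth["a_qtl"].to_numpy(),
            Qc @ small_dataset.qtl_effects_direct, atol=1e-9)
        np.testing.assert_allclose(
            small_dataset.truth["m_qtl"].to_numpy(),
            Qc @ small_dataset.qtl_effects_maternal, atol=1e-9)

    def test_realized_variances_match_components(self):
        """2000+ animals: realized var/cov of (a, m) sit at the target values."""
        sc = _tiny(n_generations=5, offspring_per_generation=400,
                   n_founders=20, dams_per_generation=8, seed=6)
        ds = simulate_dataset(sc)
        t = ds.truth
        n = len(t)
        assert n >= 2000
        vc = sc.varcomp
        se_cov = np.sqrt((vc.sigma_a2 * vc.sigma_m2 + vc.cov_am ** 2) / (n - 1))
        cov_am = np.cov(t["a_true"], t["m_true"], ddof=1)[0, 1]
        assert abs(cov_am - vc.cov_am) <= 3 * se_cov
        assert t["a_true"].var(ddof=1) == pytest.approx(vc.sigma_a2, rel=0.15)
        assert t["m_true"].var(ddof=1) == pytest.approx(vc.sigma_m2, rel=0.15)

    def test_null_genetics_gives_pure_noise(self):
        """Vanishing genetic variance: phenotype variance ~ se2 = 1."""
        sc = _tiny(n_generations=5, offspring_per_generation=400,
                   n_founders=20, seed=8, cg_sd_kg=0.0, sex_effect_kg=0.0,
                   trait_mean_kg=0.0,
                   varcomp=VarianceComponents(1e-10, 0.0, 0.0, 1.0))
        ds = simulate_dataset(sc)
        y = ds.phenotypes["value"]
        assert y.mean() == pytest.approx(0.0, abs=0.1)
        assert y.var(ddof=1) == pytest.approx(1.0, rel=0.1)

    def test_zero_qtl_fraction_leaves_markers_unassociated(self):
        """All genetic variance polygenic: marker regressions average ~0."""
        sc = _tiny(n_generations=4, offspring_per_generation=200,
                   n_founders=20, qtl_variance_fraction=0.0, seed=10,
                   markers_per_chromosome=100)
        ds = simulate_dataset(sc)
        y = ds.phenotypes["value"].to_numpy()
        X = ds.genotypes.dosage.astype(float)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        with np.errstate(invalid="ignore"):
            slopes = Xc.T @ yc / (Xc ** 2).sum(axis=0)
        slopes = slopes[np.isfinite(slopes)]
        # phenotype sd ~ 20 kg; slopes should scatter around zero
        assert abs(np.mean(slopes)) < 0.5
        assert ds.truth["a_qtl"].abs().max() == 0.0

    def test_temporal_drift_yields_positive_fst(self, small_dataset):
        ped = small_dataset.pedigree
        gen = ped.set_index("id")["generation"]
        g = small_dataset.genotypes
        last = gen.max()
        labels = pd.Series(
            ["before" if gen[i] <= 1 else "after" for i in g.individual_ids],
            index=g.individual_ids)
        keep = [i for i in g.individual_ids
                if gen[i] <= 1 or gen[i] == last]
        r = compute_fst(g.subset_individuals(keep), labels.loc[keep])
        assert np.nanmean(r.fst_clipped) > 0.0


class TestDeterminism:
    def test_identical_scenarios_give_bit_identical_datasets(self):
        sc = _tiny(seed=42)
        d1 = simulate_dataset(sc)
        d2 = simulate_dataset(_tiny(seed=42))
        assert np.array_equal(d1.genotypes.dosage, d2.genotypes.dosage)
        pd.testing.assert_frame_equal(d1.pedigree, d2.pedigree)
        pd.testing.assert_frame_equal(d1.phenotypes, d2.phenotypes)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)
        assert d1.qtl_ids == d2.qtl_ids

    def test_different_seeds_differ(self):
        d1 = simulate_dataset(_tiny(seed=1))
        d2 = simulate_dataset(_tiny(seed=2))
        assert not np.array_equal(d1.genotypes.dosage, d2.genotypes.dosage)


class TestRoundTripToDisk:
    def test_write_creates_loadable_files(self, tmp_path, small_dataset):
        from snp_prior_gs.io import read_plink, read_tables
        small_dataset.write(tmp_path)
        g = read_plink(tmp_path / "genotypes")
        assert np.array_equal(g.dosage, small_dataset.genotypes.dosage)
        ped, ph = read_tables(tmp_path / "pedigree.csv",
                              tmp_path / "phenotypes.csv",
                              genotyped_ids=g.individual_ids)
        assert len(ped) == len(small_dataset.pedigree)
        assert len(ph) == len(small_dataset.phenotypes)
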