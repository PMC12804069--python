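"""Closed-population simulator with direct + maternal genetic effects.

Emulates the two study population structures so every pipeline stage can be
exercised against known truth:

* ``inbred_line`` — a small-Ne, highly inbred closed line (two sires per
  generation, full-sib mating allowed), patterned on a closed Hereford line
  with inbreeding around 0.3 and effective population size near 8;
* ``composite`` — a larger closed composite herd (no full-sib matings,
  inbreeding around 0.1).

The simulation is drift-only gene dropping: founders receive
Hardy-Weinberg genotypes at uniformly drawn allele frequencies, gametes
recombine under a Haldane (interference-free) map, and no outside animals
enter after the founders. True breeding values are the sum of a QTL part
(dosage-weighted QTL effects) and a pedigree-transmitted polygenic part;
realized (direct, maternal) covariances are calibrated exactly to the
scenario's variance components (a shared linear transform, so pedigree
additivity and the QTL-dosage identity are preserved). Phenotypes add sex,
contemporary-group and residual terms on top.

Generation g maps linearly onto birth years 1990-2023 so a 2010 temporal
cohort split is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gblup import LITERATURE_VARCOMP, VarianceComponents
from .io import MISSING, GenotypeMatrix, UNKNOWN_PARENT, write_plink

YEAR_MIN, YEAR_MAX = 1990, 2023


class SimulationConfigError(ValueError):
    pass


class PedigreeIntegrityError(ValueError):
    pass


@dataclass
class SimScenario:
    """Breeding-design and genetic-architecture knobs for one simulation."""

    n_founders: int = 20
    n_generations: int = 8
    sires_per_generation: int = 2
    dams_per_generation: int = 8
    offspring_per_generation: int = 40
    n_chromosomes: int = 5
    markers_per_chromosome: int = 400
    chromosome_length_morgans: float = 1.0
    n_qtl: int = 100
    qtl_on_panel: bool = True
    founder_maf_min: float = 0.05
    varcomp: VarianceComponents = field(
        default_factory=lambda: LITERATURE_VARCOMP["line1"]["BW"])
    qtl_variance_fraction: float = 0.5
    allow_full_sib_mating: bool = True
    trait: str = "BW"
    trait_mean_kg: float = 38.0
    sex_effect_kg: float = 2.5
    cg_sd_kg: float = 3.0
    cohort_cutoff_generation: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sires_per_generation < 1 or self.dams_per_generation < 1:
            raise SimulationConfigError(
                "need at least one sire and one dam per generation")
        if self.dams_per_generation < self.sires_per_generation:
            raise SimulationConfigError(
                "dams_per_generation must be >= sires_per_generation")
        if not (0 < self.founder_maf_min <= 0.5):
            raise SimulationConfigError("founder_maf_min outside (0, 0.5]")
        if not (0 <= self.qtl_variance_fraction <= 1):
            raise SimulationConfigError("qtl_variance_fraction outside [0, 1]")
        n_mark = self.n_chromosomes * self.markers_per_chromosome
        if self.qtl_on_panel and self.n_qtl > n_mark:
            raise SimulationConfigError(
                f"n_qtl={self.n_qtl} exceeds panel size {n_mark}")
        if not self.qtl_on_panel and self.n_qtl >= n_mark:
            raise SimulationConfigError(
                "off-panel QTL must leave at least one panel marker")
        if self.chromosome_length_morgans < 0:
            raise SimulationConfigError("chromosome length must be >= 0")
        if self.n_generations > 0:
            per_sex_founders = self.n_founders // 2
            per_sex_offspring = self.offspring_per_generation // 2
            if per_sex_founders < self.dams_per_generation:
                raise SimulationConfigError(
                    f"{self.n_founders} founders cannot supply "
                    f"{self.dams_per_generation} dams (sexes are balanced)")
            if self.n_generations > 1 and per_sex_offspring < self.dams_per_generation:
                raise SimulationConfigError(
                    f"{self.offspring_per_generation} offspring per generation "
                    f"cannot supply {self.dams_per_generation} dams")

    def birth_year(self, generation: int) -> int:
        if self.n_generations == 0:
            return YEAR_MIN
        span = YEAR_MAX - YEAR_MIN
        return YEAR_MIN + round(generation * span / self.n_generations)

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimScenario":
        """Named study-population presets: "inbred_line" or "composite"."""
        if name == "inbred_line":
            base = dict(
                n_founders=20, n_generations=8, sires_per_generation=2,
                dams_per_generation=8, offspring_per_generation=150,
                allow_full_sib_mating=True,
                varcomp=LITERATURE_VARCOMP["line1"]["BW"],
                trait_mean_kg=34.0)
        elif name == "composite":
            base = dict(
                n_founders=120, n_generations=12, sires_per_generation=20,
                dams_per_generation=60, offspring_per_generation=220,
                allow_full_sib_mating=False,
                varcomp=LITERATURE_VARCOMP["cgc"]["BW"],
                trait_mean_kg=39.0)
        else:
            raise SimulationConfigError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class SimulatedDataset:
    """Pedigree, genotypes, phenotypes and the truth behind them."""

    scenario: SimScenario
    pedigree: pd.DataFrame      # id, sire, dam, sex, birth_year, generation
    genotypes: GenotypeMatrix   # panel markers (off-panel QTL excluded)
    phenotypes: pd.DataFrame    # id, trait, value, sex, cg
    truth: pd.DataFrame         # id, a_true, m_true, a_qtl, m_qtl, a_poly, m_poly
    qtl_ids: list
    qtl_effects_direct: np.ndarray
    qtl_effects_maternal: np.ndarray
    qtl_dosage: np.ndarray      # individuals x QTL, for truth checks

    def write(self, outdir) -> None:
        """PLINK triplet + pedigree/phenotype/truth CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_plink(self.genotypes, outdir / "genotypes")
        self.pedigree[["id", "sire", "dam", "sex", "birth_year"]].to_csv(
            outdir / "pedigree.csv", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        pd.DataFrame({"qtl_id": self.qtl_ids,
                      "effect_direct": self.qtl_effects_direct,
                      "effect_maternal": self.qtl_effects_maternal}).to_csv(
            outdir / "qtl.csv", index=False)


# ---------------------------------------------------------------------------
# pedigree

def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sexes = np.array(["M"] * (n // 2 + n % 2) + ["F"] * (n // 2), dtype=object)
    return rng.permutation(sexes)


def _are_full_sibs(ped_lut: dict, a: str, b: str) -> bool:
    sa, da = ped_lut[a]
    sb, db = ped_lut[b]
    return (sa != UNKNOWN_PARENT and da != UNKNOWN_PARENT
            and sa == sb and da == db)


def simulate_pedigree(scenario: SimScenario,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Discrete-generation closed-population pedigree.

    Every non-founder's parents appear in the previous generation; sexes are
    balanced within each cohort so the mating design stays feasible. The
    "composite" rule forbids full-sib matings.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    rows = []
    parents_lut: dict[str, tuple[str, str]] = {}

    founder_sexes = _balanced_sexes(scenario.n_founders, rng)
    prev_ids, prev_sexes = [], []
    for i in range(scenario.n_founders):
        iid = f"G00_{i:04d}"
        rows.append((iid, UNKNOWN_PARENT, UNKNOWN_PARENT, founder_sexes[i],
                     scenario.birth_year(0), 0))
        parents_lut[iid] = (UNKNOWN_PARENT, UNKNOWN_PARENT)
        prev_ids.append(iid)
        prev_sexes.append(founder_sexes[i])

    for g in range(1, scenario.n_generations + 1):
        males = [i for i, s in zip(prev_ids, prev_sexes) if s == "M"]
        females = [i for i, s in zip(prev_ids, prev_sexes) if s == "F"]
        if len(males) < scenario.sires_per_generation:
            raise SimulationConfigError(
                f"generation {g}: only {len(males)} males available for "
                f"{scenario.sires_per_generation} sires")
        if len(females) < scenario.dams_per_generation:
            raise SimulationConfigError(
                f"generation {g}: only {len(females)} females available for "
                f"{scenario.dams_per_generation} dams")
        sires = list(rng.choice(males, scenario.sires_per_generation,
                                replace=False))
        dams = list(rng.choice(females, scenario.dams_per_generation,
                               replace=False))

        n_off = scenario.offspring_per_generation
        sexes = _balanced_sexes(n_off, rng)
        new_ids, new_sexes = [], []
        for k in range(n_off):
            dam = dams[k % len(dams)]
            candidates = sires
            if not scenario.allow_full_sib_mating:
                candidates = [s for s in sires
                              if not _are_full_sibs(parents_lut, s, dam)]
                if not candidates:
                    raise SimulationConfigError(
                        f"generation {g}: every sire is a full sib of dam "
                        f"{dam}; increase sires_per_generation")
            sire = candidates[rng.integers(len(candidates))]
            iid = f"G{g:02d}_{k:04d}"
            rows.append((iid, sire, dam, sexes[k], scenario.birth_year(g), g))
            parents_lut[iid] = (sire, dam)
            new_ids.append(iid)
            new_sexes.append(sexes[k])
        prev_ids, prev_sexes = new_ids, new_sexes

    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex",
                                       "birth_year", "generation"])


def pedigree_inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficients F from the pedigree numerator relationship matrix.

    Tabular method: individuals in pedigree order (parents first), unknown
    parents contribute nothing.
    """
    ids = ped["id"].to_numpy(dtype=object)
    lut = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    sidx = np.array([lut.get(s, -1) for s in ped["sire"]], dtype=int)
    didx = np.array([lut.get(d, -1) for d in ped["dam"]], dtype=int)
    if np.any((sidx >= np.arange(n)) & (sidx >= 0)) or np.any(
            (didx >= np.arange(n)) & (didx >= 0)):
        raise PedigreeIntegrityError("pedigree not sorted parents-first")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sidx[i], didx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return pd.Series(np.diag(A) - 1.0, index=pd.Index(ids, name="id"), name="F")


# ---------------------------------------------------------------------------
# gene dropping

def _meiosis(haps: np.ndarray, chrom_slices, gpos, length: float,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes under a Haldane map."""
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    for sl, gp in zip(chrom_slices, gpos):
        start = int(rng.integers(2))
        n_co = int(rng.poisson(length)) if length > 0 else 0
        if n_co == 0:
            gamete[sl] = haps[start, sl]
        else:
            points = np.sort(rng.uniform(0.0, length, n_co))
            seg = (start + np.searchsorted(points, gp)) % 2
            gamete[sl] = np.where(seg == 0, haps[0, sl], haps[1, sl])
    return gamete


def drop_genotypes(pedigree: pd.DataFrame, scenario: SimScenario,
                   rng: np.random.Generator | None = None,
                   founder_p: np.ndarray | None = None,
                   return_haplotypes: bool = False):
    """Gene-drop genotypes through the pedigree.

    Founders get Hardy-Weinberg genotypes at frequencies drawn uniformly in
    [founder_maf_min, 1 - founder_maf_min] (or ``founder_p`` if given);
    descendants inherit recombinant gametes (Haldane model, no
    interference). Dosages are complete — missingness for QC exercises is
    masked afterwards with :func:`mask_missing`.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(2)[1])
    mc = scenario.markers_per_chromosome
    n_chrom = scenario.n_chromosomes
    m = mc * n_chrom
    L = scenario.chromosome_length_morgans

    ids = pedigree["id"].to_numpy(dtype=object)
    lut = {iid: i for i, iid in enumerate(ids)}
    for col in ("sire", "dam"):
        bad = [p for p in pedigree[col] if p != UNKNOWN_PARENT and p not in lut]
        if bad:
            raise PedigreeIntegrityError(
                f"pedigree references unknown {col}(s): {sorted(set(bad))[:5]}")

    if founder_p is None:
        founder_p = rng.uniform(scenario.founder_maf_min,
                                1.0 - scenario.founder_maf_min, m)
    founder_p = np.asarray(founder_p, dtype=float)
    if founder_p.shape != (m,):
        raise SimulationConfigError(f"founder_p must have length {m}")

    chrom_slices = [slice(c * mc, (c + 1) * mc) for c in range(n_chrom)]
    gpos = [(np.arange(mc) + 0.5) / mc * L if L > 0 else np.zeros(mc)
            for _ in range(n_chrom)]

    n = len(ids)
    haps = np.empty((n, 2, m), dtype=np.int8)
    sire_arr = pedigree["sire"].to_numpy(dtype=object)
    dam_arr = pedigree["dam"].to_numpy(dtype=object)
    for i in range(n):
        s, d = sire_arr[i], dam_arr[i]
        if s == UNKNOWN_PARENT or d == UNKNOWN_PARENT:
            haps[i] = (rng.random((2, m)) < founder_p).astype(np.int8)
        else:
            haps[i, 0] = _meiosis(haps[lut[s]], chrom_slices, gpos, L, rng)
            haps[i, 1] = _meiosis(haps[lut[d]], chrom_slices, gpos, L, rng)

    dosage = haps.sum(axis=1, dtype=np.int8)
    spacing = max(1, int(round(L * 1e8 / mc))) if L > 0 else 1
    marker_ids = np.array([f"C{c + 1}_M{j:05d}" for c in range(n_chrom)
                           for j in range(mc)], dtype=object)
    chromosome = np.array([str(c + 1) for c in range(n_chrom)
                           for _ in range(mc)], dtype=object)
    position_bp = np.array([(j + 1) * spacing for _ in range(n_chrom)
                            for j in range(mc)], dtype=np.int64)
    sex = pedigree["sex"].to_numpy(dtype=object)
    g = GenotypeMatrix(individual_ids=ids.copy(), marker_ids=marker_ids,
                       chromosome=chromosome, position_bp=position_bp,
                       dosage=dosage, sex=sex.copy())
    if return_haplotypes:
        return g, haps
    return g


def mask_missing(g: GenotypeMatrix, rate: float,
                 seed: int = 0) -> GenotypeMatrix:
    """Mask a random fraction of calls as missing (for QC exercises)."""
    rng = np.random.default_rng(seed)
    dosage = g.dosage.copy()
    mask = rng.random(dosage.shape) < rate
    dosage[mask] = MISSING
    return replace(g, dosage=dosage)


# ---------------------------------------------------------------------------
# genetic effects and phenotypes

def _calibrating_transform(B: np.ndarray, target: np.ndarray) -> np.ndarray:
    """2x2 transform T with cov(B @ T.T, ddof=1) == target exactly.

    Falls back to per-column variance scaling when the sample covariance is
    singular (e.g. a single QTL).
    """
    S = np.cov(B, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    try:
        Ls = np.linalg.cholesky(S)
        Lt = np.linalg.cholesky(target)
        return Lt @ np.linalg.inv(Ls)
    except np.linalg.LinAlgError:
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.sqrt(np.diag(target) / np.diag(S))
        scale[~np.isfinite(scale)] = 0.0
        return np.diag(scale)


def simulate_phenotypes(pedigree: pd.DataFrame, genotypes: GenotypeMatrix,
                        scenario: SimScenario,
                        rng: np.random.Generator | None = None):
    """Simulate true breeding values and phenotypes on top of the genotypes.

    Returns (phenotypes, truth, qtl_index, effects_direct, effects_maternal).
    The maternal effect of an animal's DAM enters its record; records of
    animals with unknown dams carry no maternal contribution.
    """
    vc = scenario.varcomp
    if vc.sigma_m2 > 0:
        det = vc.sigma_a2 * vc.sigma_m2 - vc.cov_am ** 2
        if det <= 0:
            raise SimulationConfigError(
                f"direct-maternal covariance not positive definite "
                f"(sigma_a2={vc.sigma_a2}, sigma_m2={vc.sigma_m2}, "
                f"cov_am={vc.cov_am})")
    if rng is None:
        seqs = np.random.SeedSequence(scenario.seed).spawn(4)
        rng = np.random.default_rng(seqs[2])

    ids = pedigree["id"].to_numpy(dtype=object)
    n = len(ids)
    m = genotypes.n_markers
    G0 = vc.G0
    qf = scenario.qtl_variance_fraction
    rho = (vc.cov_am / np.sqrt(vc.sigma_a2 * vc.sigma_m2)
           if vc.sigma_m2 > 0 else 0.0)

    # --- QTL part
    n_qtl = min(scenario.n_qtl, m)
    qtl_idx = np.sort(rng.choice(m, n_qtl, replace=False))
    Q = genotypes.dosage[:, qtl_idx].astype(float)
    Qc = Q - Q.mean(axis=0, keepdims=True)
    z1 = rng.standard_normal(n_qtl)
    z2 = rng.standard_normal(n_qtl)
    e_a = z1
    e_m = rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z2
    B_q = np.column_stack([Qc @ e_a, Qc @ e_m])
    genic_zero = qf == 0 or n_qtl == 0 or np.allclose(B_q.std(axis=0), 0)
    if genic_zero:
        eff = np.zeros((n_qtl, 2))
        B_q = np.zeros((n, 2))
    else:
        T = _calibrating_transform(B_q, qf * G0)
        eff = np.column_stack([e_a, e_m]) @ T.T
        B_q = B_q @ T.T
    if vc.sigma_m2 == 0:
        eff[:, 1] = 0.0
        B_q[:, 1] = 0.0

    # --- pedigree-transmitted polygenic part
    pf = 1.0 - qf
    P = np.zeros((n, 2))
    if pf > 0:
        C_base = G0.copy()
        L_base = (np.linalg.cholesky(C_base) if vc.sigma_m2 > 0
                  else np.diag([np.sqrt(vc.sigma_a2), 0.0]))
        lut = {iid: i for i, iid in enumerate(ids)}
        sidx = np.array([lut.get(s, -1) for s in pedigree["sire"]], dtype=int)
        didx = np.array([lut.get(d, -1) for d in pedigree["dam"]], dtype=int)
        F = pedigree_inbreeding(pedigree).to_numpy()
        z = rng.standard_normal((n, 2))
        for i in range(n):
            s, d = sidx[i], didx[i]
            if s < 0 or d < 0:
                P[i] = z[i] @ L_base.T
            else:
                ms_scale = np.sqrt(max(0.0, 0.5 * (1.0 - 0.5 * (F[s] + F[d]))))
                P[i] = 0.5 * (P[s] + P[d]) + ms_scale * (z[i] @ L_base.T)
        if np.allclose(P.std(axis=0)[0], 0):
            P[:] = 0.0
        else:
            Tp = _calibrating_transform(P, pf * G0) if vc.sigma_m2 > 0 else None
            if Tp is not None:
                P = (P - P.mean(axis=0)) @ Tp.T
            else:
                P[:, 0] = ((P[:, 0] - P[:, 0].mean())
                           * np.sqrt(pf * vc.sigma_a2 / P[:, 0].var(ddof=1)))
                P[:, 1] = 0.0

    a_true = B_q[:, 0] + P[:, 0]
    m_true = B_q[:, 1] + P[:, 1]

    # --- fixed effects and residual
    resid_rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed).spawn(4)[3])
    sex = pedigree["sex"].to_numpy(dtype=object)
    birth_year = pedigree["birth_year"].to_numpy()
    dam_year = {iid: y for iid, y in zip(ids, birth_year)}
    dam_age = np.array(
        [max(1, birth_year[i] - dam_year.get(pedigree["dam"].iloc[i], birth_year[i] - 3))
         if pedigree["dam"].iloc[i] != UNKNOWN_PARENT else 3
         for i in range(n)])
    age_class = np.minimum((dam_age - 1) // 3 + 1, 4)
    cg = np.array([f"{y}x{a}" for y, a in zip(birth_year, age_class)],
                  dtype=object)
    cg_levels = sorted(set(cg))
    cg_effects = dict(zip(cg_levels,
                          resid_rng.normal(0.0, scenario.cg_sd_kg,
                                           len(cg_levels))))
    dam_lut = {iid: i for i, iid in enumerate(ids)}
    m_of_dam = np.array([m_true[dam_lut[d]] if d in dam_lut else 0.0
                         for d in pedigree["dam"]])
    e = resid_rng.normal(0.0, np.sqrt(vc.sigma_e2), n)
    y = (scenario.trait_mean_kg
         + np.where(sex == "M", scenario.sex_effect_kg, 0.0)
         + np.array([cg_effects[c] for c in cg])
         + a_true + m_of_dam + e)

    phenotypes = pd.DataFrame({"id": ids, "trait": scenario.trait, "value": y,
                               "sex": sex, "cg": cg})
    truth = pd.DataFrame({"id": ids, "a_true": a_true, "m_true": m_true,
                          "a_qtl": B_q[:, 0], "m_qtl": B_q[:, 1],
                          "a_poly": P[:, 0], "m_poly": P[:, 1]})
    return phenotypes, truth, qtl_idx, eff[:, 0], eff[:, 1]


def simulate_dataset(scenario: SimScenario) -> SimulatedDataset:
    """Full pipeline: pedigree -> gene dropping -> effects and phenotypes.

    Deterministic: identical scenarios (including seed) give bit-identical
    datasets. Child seeds are derived per stage from the master seed.
    """
    seqs = np.random.SeedSequence(scenario.seed).spawn(4)
    ped = simulate_pedigree(scenario, np.random.default_rng(seqs[0]))
    geno = drop_genotypes(ped, scenario, np.random.default_rng(seqs[1]))
    phenotypes, truth, qtl_idx, eff_a, eff_m = simulate_phenotypes(
        ped, geno, scenario, np.random.default_rng(seqs[2]))
    qtl_ids = list(geno.marker_ids[qtl_idx])
    qtl_dosage = geno.dosage[:, qtl_idx].astype(float)
    if not scenario.qtl_on_panel:
        panel = [mid for mid in geno.marker_ids if mid not in set(qtl_ids)]
        geno = geno.subset_markers(panel)
    return SimulatedDataset(
        scenario=scenario, pedigree=ped, genotypes=geno,
        phenotypes=phenotypes, truth=truth, qtl_ids=qtl_ids,
        qtl_effects_direct=eff_a, qtl_effects_maternal=eff_m,
        qtl_dosage=qtl_dosage)
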