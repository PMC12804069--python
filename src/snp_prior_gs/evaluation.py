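"""Replicated cross-validation of the five G-matrix scenarios.

Each replicate randomly splits the phenotyped animals 2/3 : 1/3 into
training and validation, builds the scenario's relationship matrix, solves
the maternal-effects model on training records only, and scores validation
animals by

* accuracy — Pearson correlation of direct GEBV with corrected phenotypes
  (y - Xb, fixed effects estimated in training);
* inflation slope — OLS slope of GEBV regressed on corrected phenotype
  (slope < 1 reads as deflated/shrunken predictions);
* MSE — mean squared difference of the two.

Scenarios: ``all_snp`` (plain G), ``preselect_fst`` / ``preselect_effect``
(top-fraction marker subsets), ``weighted_fst`` / ``weighted_effect``
(per-SNP weights in G), plus a ``random_subset`` control. The temporal-Fst
arm ranks markers on all genotyped animals (birth year is not a phenotype);
the effect-based arm uses training phenotypes only. Partitions depend only
on the master seed and replicate index, so scenario contrasts are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import assign_temporal_groups, compute_fst, fst_weights, \
    select_top_fraction
from .gblup import MaternalGBLUP, MaternalGBLUPResults, VarianceComponents
from .io import GenotypeMatrix
from .qc import AlleleFrequencyTable, compute_allele_frequencies
from .relationship import (MarkerWeights, RelationshipMatrix, build_grm,
                           build_subset_grm, center_genotypes, condition_grm)
from .snp_effects import iterate_weights, select_top_effects

logger = logging.getLogger(__name__)

SCENARIOS = ("all_snp", "preselect_fst", "preselect_effect",
             "weighted_fst", "weighted_effect", "random_subset")


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# splitting and metrics

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_validation(ids, train_fraction: float = 2.0 / 3.0,
                           seed: int = 0) -> tuple[list, list]:
    """Random disjoint exhaustive partition; training size is
    round-half-up(train_fraction * n). Deterministic given the seed."""
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise EvaluationError(f"need at least 3 phenotyped animals, got {n}")
    n_train = _round_half_up(train_fraction * n)
    if n_train < 1 or n_train >= n:
        raise EvaluationError(
            f"degenerate partition: {n_train} training of {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_set = set(perm[:n_train])
    train = [ids[i] for i in range(n) if i in train_set]
    valid = [ids[i] for i in range(n) if i not in train_set]
    return train, valid


def split_family_blocked(ids, pedigree: pd.DataFrame,
                         train_fraction: float = 2.0 / 3.0,
                         seed: int = 0) -> tuple[list, list]:
    """Partition whole full-sib families, so sibs never straddle the split.

    Optional alternative to the plain random split (which lets full sibs,
    half sibs and parent/offspring pairs end up on both sides); default off
    in the pipeline.
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise EvaluationError(f"need at least 3 phenotyped animals, got {n}")
    fam_of = {str(r.id): (r.sire, r.dam) for r in pedigree.itertuples()}
    families: dict[tuple, list] = {}
    for iid in ids:
        families.setdefault(fam_of.get(str(iid), (iid, iid)), []).append(iid)
    keys = sorted(families, key=str)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    target = _round_half_up(train_fraction * n)
    train: list = []
    for k in keys:
        if len(train) < target:
            train.extend(families[k])
    train_set = set(train)
    valid = [i for i in ids if i not in train_set]
    if not valid or not train:
        raise EvaluationError("family-blocked split left one side empty")
    return [i for i in ids if i in train_set], valid


def _paired(gebv, corrected):
    g = np.asarray(gebv, dtype=float)
    c = np.asarray(corrected, dtype=float)
    if g.shape != c.shape:
        raise EvaluationError("gebv/corrected length mismatch")
    return g, c


def accuracy(gebv, corrected) -> float:
    """Pearson correlation of validation GEBV with corrected phenotypes."""
    g, c = _paired(gebv, corrected)
    if len(g) < 3:
        raise EvaluationError("fewer than 3 validation pairs")
    if np.std(g) == 0 or np.std(c) == 0:
        raise EvaluationError("zero variance in GEBV or corrected phenotypes")
    return float(np.corrcoef(g, c)[0, 1])


def inflation_slope(gebv, corrected) -> float:
    """OLS slope of GEBV (response) on corrected phenotype (predictor)."""
    g, c = _paired(gebv, corrected)
    var_c = np.var(c)
    if var_c == 0:
        raise EvaluationError("zero predictor variance for the slope")
    return float(np.cov(g, c, ddof=0)[0, 1] / var_c)


def mse(gebv, corrected) -> float:
    """Mean squared difference (kg^2)."""
    g, c = _paired(gebv, corrected)
    return float(np.mean((g - c) ** 2))


# ---------------------------------------------------------------------------
# scenario machinery

@dataclass
class TrainingArtifacts:
    """Everything the training stage produced (for the model and for
    leakage auditing: nothing here may depend on validation phenotypes)."""

    grm: RelationshipMatrix
    results: MaternalGBLUPResults
    weights: MarkerWeights | None
    selected: list | None
    n_markers_used: int


def build_scenario_grm(genotypes: GenotypeMatrix, freqs: AlleleFrequencyTable,
                       scenario: str, ph_train: pd.DataFrame | None = None,
                       pedigree: pd.DataFrame | None = None,
                       vc: VarianceComponents | None = None,
                       trait: str | None = None,
                       top_fraction: float = 0.10, ridge: float = 0.01,
                       n_weight_iterations: int = 10,
                       fst_result=None,
                       rng: np.random.Generator | None = None):
    """Build (grm, weights, selected, n_markers_used) for one scenario.

    The all-SNP and Fst scenarios depend only on the genotypes (and birth
    years), so the result can be shared across cross-validation replicates;
    the effect-based and random-control scenarios depend on the training
    phenotypes / rng and must be rebuilt per replicate.
    """
    if scenario not in SCENARIOS:
        raise EvaluationError(f"unknown scenario {scenario!r}")
    weights = None
    selected = None
    if scenario in ("preselect_fst", "weighted_fst"):
        if fst_result is None:
            raise EvaluationError(f"{scenario} needs a precomputed FstResult")
        if scenario == "preselect_fst":
            selected = select_top_fraction(
                fst_result.marker_ids, fst_result.fst_clipped, top_fraction,
                chromosome=fst_result.chromosome,
                position_bp=fst_result.position_bp)
        else:
            weights = fst_weights(fst_result)
    elif scenario == "preselect_effect":
        _, _, first = iterate_weights(genotypes, freqs, ph_train, pedigree,
                                      vc, n_iter=1, ridge=ridge, trait=trait)
        selected = select_top_effects(first, top_fraction)
    elif scenario == "weighted_effect":
        weights, _, _ = iterate_weights(genotypes, freqs, ph_train, pedigree,
                                        vc, n_iter=n_weight_iterations,
                                        ridge=ridge, trait=trait)
    elif scenario == "random_subset":
        if rng is None:
            raise EvaluationError("random_subset control needs an rng")
        m = genotypes.n_markers
        k = int(np.floor(top_fraction * m))
        selected = list(genotypes.marker_ids[
            np.sort(rng.choice(m, k, replace=False))])

    if selected is not None:
        grm = build_subset_grm(genotypes, freqs, selected)
        n_used = len(selected)
    else:
        M = center_genotypes(genotypes, freqs)
        grm = build_grm(M, freqs, genotypes.individual_ids, weights)
        n_used = genotypes.n_markers
    grm = condition_grm(grm, ridge=ridge)
    return grm, weights, selected, n_used


def training_stage(genotypes: GenotypeMatrix, freqs: AlleleFrequencyTable,
                   ph_train: pd.DataFrame, pedigree: pd.DataFrame,
                   vc: VarianceComponents, scenario: str,
                   trait: str | None = None,
                   top_fraction: float = 0.10, ridge: float = 0.01,
                   n_weight_iterations: int = 10,
                   fst_result=None, rng: np.random.Generator | None = None,
                   prebuilt=None) -> TrainingArtifacts:
    """Build the scenario's G and fit the model on training records only.

    ``fst_result`` must be supplied for the Fst scenarios (it is computed
    once from all genotyped animals' birth-year cohorts). ``rng`` drives the
    random control subset. ``prebuilt`` short-circuits G construction with a
    tuple from :func:`build_scenario_grm` (only valid for the
    split-independent scenarios).
    """
    if prebuilt is None:
        prebuilt = build_scenario_grm(
            genotypes, freqs, scenario, ph_train=ph_train, pedigree=pedigree,
            vc=vc, trait=trait, top_fraction=top_fraction, ridge=ridge,
            n_weight_iterations=n_weight_iterations, fst_result=fst_result,
            rng=rng)
    grm, weights, selected, n_used = prebuilt
    model = MaternalGBLUP.from_tables(ph_train, pedigree, grm, vc, trait=trait)
    return TrainingArtifacts(grm=grm, results=model.fit(), weights=weights,
                             selected=selected, n_markers_used=n_used)


@dataclass
class ReplicateMetrics:
    accuracy: float
    slope: float
    mse: float
    n_validation: int
    seed: int
    accuracy_true: float | None = None
    failed: str | None = None


@dataclass
class CVReport:
    """Per-replicate and aggregated metrics for one scenario x trait."""

    scenario: str
    trait: str
    replicate_metrics: list[ReplicateMetrics]
    n_markers_used: int
    seeds: list[int]

    def _ok(self):
        return [r for r in self.replicate_metrics if r.failed is None]

    @property
    def n_successful(self) -> int:
        return len(self._ok())

    @property
    def complete(self) -> bool:
        return self.n_successful == len(self.replicate_metrics)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self._ok()]))

    @property
    def sd_accuracy(self) -> float:
        ok = self._ok()
        return float(np.std([r.accuracy for r in ok], ddof=1)) if len(ok) > 1 else float("nan")

    @property
    def mean_slope(self) -> float:
        return float(np.mean([r.slope for r in self._ok()]))

    @property
    def mean_mse(self) -> float:
        return float(np.mean([r.mse for r in self._ok()]))

    @property
    def mean_accuracy_true(self) -> float:
        vals = [r.accuracy_true for r in self._ok() if r.accuracy_true is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.replicate_metrics])

    def summary_row(self) -> dict:
        return {
            "scenario": self.scenario, "nSNPs": self.n_markers_used,
            "trait": self.trait,
            "accuracy": f"{self.mean_accuracy:.3f} ({self.sd_accuracy:.3f})",
            "slope": round(self.mean_slope, 3),
            "mse": round(self.mean_mse, 2),
            "replicates_ok": f"{self.n_successful}/{len(self.replicate_metrics)}",
        }


def run_scenario(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                 pedigree: pd.DataFrame, vc: VarianceComponents,
                 scenario: str, trait: str | None = None,
                 n_replicates: int = 5, master_seed: int = 1,
                 train_fraction: float = 2.0 / 3.0,
                 top_fraction: float = 0.10, ridge: float = 0.01,
                 n_weight_iterations: int = 10, cutoff_year: int = 2010,
                 truth: pd.DataFrame | None = None,
                 family_blocked: bool = False) -> CVReport:
    """Replicated cross-validation of one scenario on one trait.

    Validation animals keep their genotypes (they stay in G) but their
    phenotype records never enter the training stage. When a ``truth``
    table (id, a_true) is given, each replicate also records the
    correlation of validation GEBV with true direct breeding values.
    Failed replicates are reported as failed, never resampled.
    """
    if scenario not in SCENARIOS:
        raise EvaluationError(f"unknown scenario {scenario!r}")
    ph = phenotypes
    if trait is not None:
        ph = ph[ph["trait"].astype(str) == trait]
    if len(ph) == 0:
        raise EvaluationError(f"no phenotype records for trait {trait!r}")
    geno_ids = set(genotypes.individual_ids)
    ph = ph[ph["id"].astype(str).isin(geno_ids)]
    ids = ph["id"].astype(str).tolist()

    freqs = compute_allele_frequencies(genotypes)
    fst_result = None
    if scenario in ("preselect_fst", "weighted_fst"):
        groups = assign_temporal_groups(pedigree, genotypes.individual_ids,
                                        cutoff_year)
        fst_result = compute_fst(genotypes, groups, cutoff_year)

    truth_a = (dict(zip(truth["id"].astype(str), truth["a_true"]))
               if truth is not None else None)

    seed_seq = np.random.SeedSequence(master_seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in seed_seq.spawn(n_replicates)]
    # the plain and Fst-driven matrices do not depend on the split: share them
    shared = None
    if scenario in ("all_snp", "preselect_fst", "weighted_fst"):
        shared = build_scenario_grm(
            genotypes, freqs, scenario, top_fraction=top_fraction,
            ridge=ridge, fst_result=fst_result)
    metrics: list[ReplicateMetrics] = []
    n_markers_used = genotypes.n_markers
    for rep, seed in enumerate(rep_seeds):
        try:
            splitter = split_family_blocked if family_blocked else split_train_validation
            if family_blocked:
                train_ids, val_ids = splitter(ids, pedigree, train_fraction, seed)
            else:
                train_ids, val_ids = splitter(ids, train_fraction, seed)
            ph_train = ph[ph["id"].astype(str).isin(set(train_ids))]
            ph_val = ph[ph["id"].astype(str).isin(set(val_ids))]
            arts = training_stage(
                genotypes, freqs, ph_train, pedigree, vc, scenario,
                trait=trait, top_fraction=top_fraction, ridge=ridge,
                n_weight_iterations=n_weight_iterations,
                fst_result=fst_result,
                rng=np.random.default_rng(seed + 1), prebuilt=shared)
            n_markers_used = arts.n_markers_used
            corrected = arts.results.corrected_phenotypes(ph_val)
            gebv = arts.results.direct_gebv.loc[corrected.index]
            rep_metrics = ReplicateMetrics(
                accuracy=accuracy(gebv, corrected),
                slope=inflation_slope(gebv, corrected),
                mse=mse(gebv, corrected),
                n_validation=len(corrected), seed=seed)
            if truth_a is not None:
                a_true = np.array([truth_a[i] for i in val_ids])
                a_hat = arts.results.direct_gebv.loc[val_ids].to_numpy()
                rep_metrics.accuracy_true = float(np.corrcoef(a_hat, a_true)[0, 1])
            metrics.append(rep_metrics)
        except (EvaluationError, ValueError) as exc:
            logger.warning("replicate %d of scenario %s failed: %s",
                           rep, scenario, exc)
            metrics.append(ReplicateMetrics(
                accuracy=float("nan"), slope=float("nan"), mse=float("nan"),
                n_validation=0, seed=seed, failed=str(exc)))
    report = CVReport(scenario=scenario, trait=trait or str(ph["trait"].iloc[0]),
                      replicate_metrics=metrics,
                      n_markers_used=n_markers_used, seeds=rep_seeds)
    if not report.complete:
        logger.warning("scenario %s finished with %d/%d replicates",
                       scenario, report.n_successful, n_replicates)
    return report


def run_all_scenarios(genotypes, phenotypes, pedigree, vc,
                      scenarios=SCENARIOS[:5], **kwargs) -> pd.DataFrame:
    """Tables-2/3-style summary across scenarios (one trait)."""
    rows = [run_scenario(genotypes, phenotypes, pedigree, vc, sc,
                         **kwargs).summary_row() for sc in scenarios]
    return pd.DataFrame(rows)
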