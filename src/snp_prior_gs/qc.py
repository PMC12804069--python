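"""Marker quality control: allele frequencies, MAF / call-rate / HWE filters,
and mean imputation of residual missingness.

Only markers are ever filtered; individuals always survive QC. The HWE test
is the exact conditional test on observed genotype counts (plain P, not
mid-P), compared against the threshold as P >= hwe_p_min to retain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix


class QCError(ValueError):
    pass


@dataclass
class AlleleFrequencyTable:
    """Per-marker counted-allele (A1) frequencies over non-missing genotypes."""

    marker_ids: np.ndarray
    p: np.ndarray
    n_called: np.ndarray

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.p = np.asarray(self.p, dtype=float)
        self.n_called = np.asarray(self.n_called, dtype=np.int64)
        if not (len(self.marker_ids) == len(self.p) == len(self.n_called)):
            raise ValueError("allele frequency table columns misaligned")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def uncallable(self) -> np.ndarray:
        """Boolean flag for markers with no called genotypes at all."""
        return self.n_called == 0

    def subset(self, marker_ids) -> "AlleleFrequencyTable":
        idx = {mid: j for j, mid in enumerate(self.marker_ids)}
        cols = np.array([idx[m] for m in marker_ids], dtype=int)
        return AlleleFrequencyTable(self.marker_ids[cols], self.p[cols],
                                    self.n_called[cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker_id": self.marker_ids, "p": self.p,
                             "q": self.q, "n_called": self.n_called})


def compute_allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """A1 frequency p_i = (sum of non-missing dosages) / (2 * n_called).

    Markers with every genotype missing get p = NaN and are flagged via
    ``uncallable`` rather than silently dropped.
    """
    if g.n_markers == 0 or g.n_individuals == 0:
        raise QCError("empty genotype matrix")
    called = g.dosage != MISSING
    n_called = called.sum(axis=0)
    dose_sum = np.where(called, g.dosage, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dose_sum / (2.0 * n_called), np.nan)
    return AlleleFrequencyTable(g.marker_ids.copy(), p, n_called)


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test P-value for one biallelic SNP.

    Sums the probabilities of all heterozygote counts (given the allele
    counts) that are no more probable than the observed one. Plain P-value;
    no mid-P correction.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het = h | allele counts), hypergeometric-style conditional
    logp = (hets * np.log(2.0)
            + gammaln(n + 1) - gammaln(hets + 1) - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1)
               - gammaln(2 * n - n_rare + 1)))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


@dataclass
class QCLog:
    """Per-filter removal attribution (first-failing filter) and marker detail."""

    n_input: int
    n_retained: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    detail: pd.DataFrame  # marker, maf, call_rate, hwe_p, verdict, reason

    @property
    def n_removed(self) -> int:
        return self.removed_call_rate + self.removed_maf + self.removed_hwe


def qc_metrics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, call rate and exact HWE P (MAF after call-rate masking)."""
    f = compute_allele_frequencies(g)
    call_rate = f.n_called / g.n_individuals
    maf = np.minimum(f.p, 1.0 - f.p)
    n_a1hom = (g.dosage == 2).sum(axis=0)
    n_het = (g.dosage == 1).sum(axis=0)
    n_a2hom = (g.dosage == 0).sum(axis=0)
    hwe_p = np.array([hwe_exact_p(int(h), int(h1), int(h2))
                      for h, h1, h2 in zip(n_het, n_a1hom, n_a2hom)])
    return pd.DataFrame({
        "marker": g.marker_ids, "maf": maf, "call_rate": call_rate,
        "hwe_p": hwe_p,
    })


def apply_qc(g: GenotypeMatrix, maf_min: float = 0.05,
             call_rate_min: float = 0.90,
             hwe_p_min: float = 1e-5) -> tuple[GenotypeMatrix, QCLog]:
    """Retain markers with MAF >= maf_min AND call rate >= call_rate_min AND
    exact HWE P >= hwe_p_min.

    Retention is a logical AND (order-independent); the removal log
    attributes each lost marker to its first failing filter in the order
    call rate, MAF, HWE.
    """
    for name, thr in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                      ("hwe_p_min", hwe_p_min)):
        if not (0 < thr < 1):
            raise QCError(f"{name}={thr} outside (0, 1)")
    met = qc_metrics(g)
    fail_cr = met["call_rate"].to_numpy() < call_rate_min
    fail_maf = ~fail_cr & ((met["maf"].to_numpy() < maf_min)
                           | ~np.isfinite(met["maf"].to_numpy()))
    fail_hwe = ~fail_cr & ~fail_maf & (met["hwe_p"].to_numpy() < hwe_p_min)
    # retention itself re-evaluates every filter (logical AND)
    keep = ((met["call_rate"].to_numpy() >= call_rate_min)
            & np.isfinite(met["maf"].to_numpy())
            & (met["maf"].to_numpy() >= maf_min)
            & (met["hwe_p"].to_numpy() >= hwe_p_min))

    reason = np.where(fail_cr, "call_rate",
                      np.where(fail_maf, "maf",
                               np.where(fail_hwe, "hwe", "")))
    detail = met.assign(verdict=np.where(keep, "keep", "remove"), reason=reason)
    if not keep.any():
        raise QCError("no markers survive QC at the given thresholds")
    out = g.subset_markers(g.marker_ids[keep])
    log = QCLog(
        n_input=g.n_markers, n_retained=int(keep.sum()),
        removed_call_rate=int(fail_cr.sum()), removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()), detail=detail,
    )
    return out, log


def impute_missing_mean(g: GenotypeMatrix,
                        f: AlleleFrequencyTable) -> GenotypeMatrix:
    """Replace each missing dosage by its marker's mean dosage 2p (float matrix).

    Returns a GenotypeMatrix whose ``dosage`` is float64; non-missing entries
    are untouched.
    """
    if list(f.marker_ids) != list(g.marker_ids):
        raise QCError("frequency table does not align with genotype markers")
    out = g.dosage.astype(np.float64)
    miss = g.dosage == MISSING
    if miss.any():
        fill = np.broadcast_to(2.0 * f.p, out.shape)
        out[miss] = fill[miss]
    return GenotypeMatrix(
        individual_ids=g.individual_ids.copy(), marker_ids=g.marker_ids.copy(),
        chromosome=g.chromosome.copy(), position_bp=g.position_bp.copy(),
        dosage=out, a1=g.a1.copy(), a2=g.a2.copy(), sex=g.sex.copy())
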