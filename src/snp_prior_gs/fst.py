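"""Per-SNP Weir & Cockerham (1984) Fst between two temporal cohorts, and its
conversion to marker subsets or marker weights.

The two cohorts are animals born up to and including the cutoff year versus
animals born after it (the boundary year goes to the "before" group). The
estimator is the two-population diploid theta-hat = a/(a+b+c) with the
heterozygosity term, matching PLINK 1.9's per-SNP --fst output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .relationship import MarkerWeights


class FstError(ValueError):
    pass


@dataclass
class FstResult:
    """Per-marker raw and zero-clipped Fst between two cohorts."""

    marker_ids: np.ndarray
    fst: np.ndarray           # raw theta-hat; may be negative or NaN
    group_sizes: tuple[int, int]
    cutoff_year: int | None = None
    chromosome: np.ndarray | None = None
    position_bp: np.ndarray | None = None

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.fst = np.asarray(self.fst, dtype=float)
        if len(self.marker_ids) != len(self.fst):
            raise ValueError("fst vector misaligned with marker IDs")
        if min(self.group_sizes) < 2:
            raise ValueError("both cohorts need at least 2 animals")

    @property
    def fst_clipped(self) -> np.ndarray:
        """Raw estimates clipped to zero from below; NaN preserved."""
        return np.where(np.isnan(self.fst), np.nan, np.clip(self.fst, 0.0, None))

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.fst)

    def to_frame(self) -> pd.DataFrame:
        """PLINK-style per-SNP table (CHR, SNP, BP, FST) for Manhattan plotting."""
        chrom = self.chromosome if self.chromosome is not None else np.full(
            len(self.marker_ids), "0", dtype=object)
        bp = self.position_bp if self.position_bp is not None else np.zeros(
            len(self.marker_ids), dtype=int)
        return pd.DataFrame({"CHR": chrom, "SNP": self.marker_ids,
                             "BP": bp, "FST": self.fst})


def assign_temporal_groups(pedigree: pd.DataFrame, genotyped_ids,
                           cutoff_year: int = 2010) -> pd.Series:
    """Label genotyped animals "before" (birth year <= cutoff) or "after".

    Animals born exactly in the cutoff year join the "before" group. Raises
    if either cohort would be empty, with a hint to move the cutoff.
    """
    years = dict(zip(pedigree["id"].astype(str), pedigree["birth_year"].astype(int)))
    ids = [str(i) for i in genotyped_ids]
    missing = [i for i in ids if i not in years]
    if missing:
        raise FstError(f"birth year unknown for genotyped animals: {missing[:5]}")
    labels = pd.Series(
        ["before" if years[i] <= cutoff_year else "after" for i in ids],
        index=pd.Index(ids, name="id"), name="cohort")
    n_before = int((labels == "before").sum())
    n_after = len(labels) - n_before
    if n_before == 0 or n_after == 0:
        raise FstError(
            f"temporal cohort empty at cutoff {cutoff_year} "
            f"(before={n_before}, after={n_after}); choose another cutoff_year")
    return labels


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) a, b, c variance components, two populations.

    n_i: called sample sizes; p_i: allele frequencies; h_i: observed
    heterozygote proportions. Vectorized over markers.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def compute_fst(g: GenotypeMatrix, groups: pd.Series,
                cutoff_year: int | None = None) -> FstResult:
    """Per-SNP Weir-Cockerham theta-hat between the two cohorts in ``groups``.

    Markers with fewer than 2 called genotypes in either cohort, or with a
    zero total variance denominator (a+b+c = 0, e.g. monomorphic overall),
    get NaN and are excluded from ranking downstream.
    """
    levels = [lv for lv in ("before", "after") if lv in set(groups)]
    if len(levels) != 2:
        levels = sorted(set(groups))
    if len(levels) != 2:
        raise FstError(f"need exactly two cohorts, got {levels}")
    lut = {iid: i for i, iid in enumerate(g.individual_ids)}
    try:
        rows = {lv: np.array([lut[i] for i in groups.index[groups == lv]], dtype=int)
                for lv in levels}
    except KeyError as exc:
        raise FstError(f"cohort animal {exc} has no genotype row") from exc
    sizes = (len(rows[levels[0]]), len(rows[levels[1]]))
    if min(sizes) < 2:
        raise FstError(f"cohort sizes too small: {sizes}")

    stats = {}
    for lv in levels:
        dos = g.dosage[rows[lv], :]
        called = dos != MISSING
        n = called.sum(axis=0).astype(float)
        dose_sum = np.where(called, dos, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, dose_sum / (2.0 * n), np.nan)
            h = np.where(n > 0, np.where(called, dos == 1, False).sum(axis=0) / n, np.nan)
        stats[lv] = (n, p, h)

    (n1, p1, h1), (n2, p2, h2) = stats[levels[0]], stats[levels[1]]
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    fst = np.where((n1 < 2) | (n2 < 2), np.nan, fst)
    return FstResult(g.marker_ids.copy(), fst, sizes, cutoff_year,
                     chromosome=g.chromosome.copy(),
                     position_bp=g.position_bp.copy())


def select_top_fraction(marker_ids, scores, fraction: float = 0.10,
                        chromosome=None, position_bp=None) -> list:
    """The floor(fraction * n_ranked) marker IDs with the largest scores.

    Markers with NaN scores are excluded from ranking. Ties break
    deterministically by (score desc, chromosome, position, marker ID).
    """
    if not (0 < fraction <= 1):
        raise FstError(f"fraction {fraction} outside (0, 1]")
    marker_ids = np.asarray(marker_ids, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if chromosome is None:
        chromosome = np.full(len(marker_ids), "", dtype=object)
    if position_bp is None:
        position_bp = np.zeros(len(marker_ids), dtype=int)
    ranked = np.isfinite(scores)
    n_select = int(np.floor(fraction * ranked.sum()))
    if n_select < 1:
        raise FstError(
            f"fraction {fraction} of {int(ranked.sum())} ranked markers selects none")
    df = pd.DataFrame({
        "marker": marker_ids[ranked], "score": scores[ranked],
        "chrom": np.asarray(chromosome, dtype=object)[ranked],
        "bp": np.asarray(position_bp)[ranked],
    })
    df = df.sort_values(["score", "chrom", "bp", "marker"],
                        ascending=[False, True, True, True],
                        kind="mergesort")
    return df["marker"].head(n_select).tolist()


def fst_weights(r: FstResult) -> MarkerWeights:
    """Marker weights proportional to zero-clipped Fst, mean-normalized to 1.

    Markers with undefined Fst enter at the panel-average weight. If every
    clipped value is zero the weights collapse to uniform (plain G) with a
    warning.
    """
    clipped = r.fst_clipped
    defined = np.isfinite(clipped)
    raw = np.where(defined, clipped, np.nan)
    if not defined.any() or np.nansum(raw) <= 0:
        warnings.warn("all clipped Fst values are zero; weights reduce to "
                      "uniform (plain G)", stacklevel=2)
        return MarkerWeights.uniform(r.marker_ids)
    mean_defined = float(np.nanmean(raw))
    d = np.where(defined, raw / mean_defined, 1.0)
    return MarkerWeights.from_raw(r.marker_ids, d)
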