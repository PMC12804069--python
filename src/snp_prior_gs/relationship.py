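"""Genomic relationship matrices: plain G = MM'/sum(2pq), marker subsets,
and the weighted form Gw = M D M'/sum(2pq), plus ridge conditioning.

Centering and the denominator both use the observed allele frequencies of
the analyzed animals. Weights are normalized to mean 1 so the weighted
denominator stays on the plain-G scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .io import MISSING, GenotypeMatrix
from .qc import AlleleFrequencyTable


class RelationshipError(ValueError):
    pass


@dataclass
class MarkerWeights:
    """Nonnegative per-SNP weights d_i (the diagonal of D), mean-normalized."""

    marker_ids: np.ndarray
    d: np.ndarray
    normalization: str = "mean1"

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.d = np.asarray(self.d, dtype=float)
        if len(self.marker_ids) != len(self.d):
            raise ValueError("weights misaligned with marker IDs")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite marker weights")
        if np.any(self.d < 0):
            raise ValueError("marker weights must be nonnegative")

    @classmethod
    def uniform(cls, marker_ids) -> "MarkerWeights":
        ids = np.asarray(marker_ids, dtype=object)
        return cls(ids, np.ones(len(ids)), normalization="uniform")

    @classmethod
    def from_raw(cls, marker_ids, raw) -> "MarkerWeights":
        """Normalize raw nonnegative weights to mean 1 (so sum(d) = n markers)."""
        raw = np.asarray(raw, dtype=float)
        if np.any(raw < 0):
            raise ValueError("raw weights must be nonnegative")
        mean = raw.mean()
        if mean <= 0:
            warnings.warn("all raw weights zero; falling back to uniform weights",
                          stacklevel=2)
            return cls.uniform(marker_ids)
        return cls(np.asarray(marker_ids, dtype=object), raw / mean)

    def align_to(self, marker_ids) -> np.ndarray:
        idx = {m: j for j, m in enumerate(self.marker_ids)}
        try:
            cols = [idx[m] for m in marker_ids]
        except KeyError as exc:
            raise RelationshipError(f"weight missing for marker {exc}") from exc
        return self.d[list(cols)]


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship matrix with its construction metadata."""

    individual_ids: np.ndarray
    values: np.ndarray
    kind: str  # plain | subset | weighted
    denominator: float
    ridge_applied: float = 0.0

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def mean_diagonal(self) -> float:
        return float(np.diag(self.values).mean())

    def index_of(self, ids) -> np.ndarray:
        lut = {iid: i for i, iid in enumerate(self.individual_ids)}
        return np.array([lut[i] for i in ids], dtype=int)

    def write_tsv(self, path) -> None:
        """Lower-triangle gzip-friendly TSV export (id_i, id_j, value)."""
        import gzip
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for i in range(self.n):
                for j in range(i + 1):
                    fh.write(f"{self.individual_ids[i]}\t{self.individual_ids[j]}\t"
                             f"{self.values[i, j]:.10g}\n")


def center_genotypes(g: GenotypeMatrix, f: AlleleFrequencyTable) -> np.ndarray:
    """Centered allele content M[i, j] = dosage[i, j] - 2 p_j.

    Requires a missingness-free matrix (impute first). When the frequencies
    come from the same individuals the column means of M are ~0; frequencies
    from a training subset applied to other animals give nonzero column
    means by design (documented behaviour, not an error).
    """
    if list(f.marker_ids) != list(g.marker_ids):
        raise RelationshipError("frequency table does not align with genotype markers")
    dos = np.asarray(g.dosage, dtype=float)
    if np.any(dos == float(MISSING)):
        raise RelationshipError("missing dosages present; impute before centering")
    return dos - 2.0 * f.p[np.newaxis, :]


def build_grm(M: np.ndarray, f: AlleleFrequencyTable, individual_ids,
              weights: MarkerWeights | None = None) -> RelationshipMatrix:
    """G = M diag(d) M' / sum_j 2 p_j q_j, with d = 1 when no weights are given.

    The weighted matrix with d identically 1 equals the plain matrix exactly.
    """
    if M.shape[1] != len(f.marker_ids):
        raise RelationshipError("M columns do not match frequency table")
    denom = float(np.sum(2.0 * f.p * (1.0 - f.p)))
    if denom <= 0:
        raise RelationshipError(
            "degenerate panel: all markers fixed (sum 2pq = 0)")
    if weights is None:
        values = (M @ M.T) / denom
        kind = "plain"
    else:
        d = weights.align_to(f.marker_ids)
        if np.all(d == 1.0):
            # identical code path so Gw == G bit-for-bit when D = I
            values = (M @ M.T) / denom
        else:
            values = (M * d[np.newaxis, :]) @ M.T / denom
        kind = "weighted"
    values = 0.5 * (values + values.T)  # exact symmetry
    return RelationshipMatrix(np.asarray(individual_ids, dtype=object),
                              values, kind, denom)


def build_subset_grm(g: GenotypeMatrix, f: AlleleFrequencyTable,
                     selected) -> RelationshipMatrix:
    """Plain G over a marker subset.

    The full-panel frequencies of the retained markers are reused for
    centering and the denominator (identical to recomputation when the
    frequencies come from the same animals); the denominator sums 2pq over
    the subset only.
    """
    selected = list(selected)
    if len(selected) == 0:
        raise RelationshipError("empty marker selection for subset G")
    gs = g.subset_markers(selected)
    fs = f.subset(gs.marker_ids)
    M = center_genotypes(gs, fs)
    out = build_grm(M, fs, g.individual_ids)
    return replace(out, kind="subset" if len(selected) < g.n_markers else "plain")


def condition_grm(G: RelationshipMatrix, ridge: float = 0.01,
                  min_eigenvalue: float = 1e-8) -> RelationshipMatrix:
    """Add ridge*I iff the smallest eigenvalue is <= min_eigenvalue.

    Subset and weighted panels are frequently rank-deficient; a ridge keeps
    the matrix invertible without importing pedigree information. The
    applied ridge is recorded on the result.
    """
    if ridge < 0:
        raise RelationshipError("ridge must be nonnegative")
    lam_min = float(scipy.linalg.eigvalsh(
        G.values, subset_by_index=(0, 0))[0])
    if lam_min > min_eigenvalue:
        return replace(G, ridge_applied=0.0)
    values = G.values + ridge * np.eye(G.n)
    return replace(G, values=values, ridge_applied=float(ridge))
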