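"""Independent brute-force oracles used by the tests.

Everything here is coded directly from first principles (generalized least
squares, the 1984 two-population variance components, recursive kinship,
exact enumeration) and never calls the package's own implementations of the
quantities it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd


def gls_blup(y, X, Z, W, G, sigma_a2, sigma_m2, cov_am, sigma_e2):
    """Maternal-model BLUP via direct inversion of the record covariance.

    V = Z G Z' sa2 + (Z G W' + W G Z') sam + W G W' sm2 + I se2;
    b = (X'V^-1 X)^-1 X'V^-1 y;  [a; m] = Cov([a;m], y) V^-1 (y - Xb).
    Returns (b, a, m) with a, m covering every animal in G.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    W = np.asarray(W, float)
    G = np.asarray(G, float)
    V = (sigma_a2 * Z @ G @ Z.T
         + cov_am * (Z @ G @ W.T + W @ G @ Z.T)
         + sigma_m2 * W @ G @ W.T
         + sigma_e2 * np.eye(len(y)))
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ b
    cov_a_y = sigma_a2 * G @ Z.T + cov_am * G @ W.T
    cov_m_y = cov_am * G @ Z.T + sigma_m2 * G @ W.T
    return b, cov_a_y @ Vi @ r, cov_m_y @ Vi @ r


def wc_theta_from_counts(counts1, counts2):
    """Weir & Cockerham (1984) theta-hat for two populations of diploids.

    ``counts1``/``counts2`` are (n_dosage0, n_dosage1, n_dosage2) genotype
    counts. Returns the raw estimator a/(a+b+c) (NaN when the denominator
    is zero). Scalar re-derivation, independent of the package's
    vectorized version.
    """
    c1 = np.asarray(counts1, float)
    c2 = np.asarray(counts2, float)
    n1, n2 = c1.sum(), c2.sum()
    p1 = (2 * c1[2] + c1[1]) / (2 * n1)
    p2 = (2 * c2[2] + c2[1]) / (2 * n2)
    h1 = c1[1] / n1
    h2 = c2[1] / n2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    return float(a / denom) if denom != 0 else float("nan")


def recursive_inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Inbreeding via Wright's recursive coancestry f(i,j); F_i = f(sire, dam)."""
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    order = {iid: k for k, iid in enumerate(ped["id"])}
    memo: dict[tuple, float] = {}

    def f(i, j):
        if i == "0" or j == "0" or i not in order or j not in order:
            return 0.0
        if order[i] > order[j]:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            # j is the younger: recurse through j's parents
            val = 0.5 * (f(i, sire[j]) + f(i, dam[j]))
        memo[key] = val
        return val

    F = [f(sire[i], dam[i]) for i in ped["id"]]
    return pd.Series(F, index=pd.Index(ped["id"], name="id"), name="F")


def hwe_exact_enumeration(n_het, n_hom1, n_hom2) -> float:
    """Exact HWE P by full enumeration with rational arithmetic."""
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het  # counts of one allele
    probs = {}
    total = Fraction(0)
    h = n_a % 2
    while h <= min(n_a, 2 * n - n_a):
        hom1 = (n_a - h) // 2
        hom2 = n - h - hom1
        if hom1 >= 0 and hom2 >= 0:
            w = (Fraction(factorial(n), factorial(h) * factorial(hom1)
                          * factorial(hom2)) * 2 ** h)
            probs[h] = w
            total += w
        h += 2
    obs = probs[n_het]
    p = sum(w for w in probs.values() if w <= obs) / total
    return float(p)


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd)))


def random_mme_instance(rng: np.random.Generator, n_animals: int,
                        n_markers: int, vc, ridge: float = 0.01,
                        n_phenotyped: int | None = None):
    """A random small maternal-model instance for MME-vs-GLS checks.

    Builds iid genotypes, the conditioned plain G, a parents-first pedigree
    with known dams, and phenotype records for a subset of animals (the rest
    are predicted through G).
    """
    from snp_prior_gs.io import GenotypeMatrix
    from snp_prior_gs.qc import compute_allele_frequencies
    from snp_prior_gs.relationship import (build_grm, center_genotypes,
                                           condition_grm)

    ids = [f"A{i:03d}" for i in range(n_animals)]
    # keep markers polymorphic so the GRM denominator is healthy
    p_true = rng.uniform(0.15, 0.85, n_markers)
    dosage = (rng.random((n_animals, n_markers)) < p_true).astype(np.int8)
    dosage += (rng.random((n_animals, n_markers)) < p_true).astype(np.int8)
    g = GenotypeMatrix(
        individual_ids=ids,
        marker_ids=[f"M{j:04d}" for j in range(n_markers)],
        chromosome=["1"] * n_markers,
        position_bp=np.arange(1, n_markers + 1),
        dosage=dosage)
    f = compute_allele_frequencies(g)
    grm = condition_grm(build_grm(center_genotypes(g, f), f, ids), ridge=ridge)

    sires, dams = [], []
    for i in range(n_animals):
        if i < 4 or rng.random() < 0.2:
            sires.append("0")
            dams.append("0")
        else:
            sires.append(ids[int(rng.integers(0, i))])
            dams.append(ids[int(rng.integers(0, i))])
    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams,
                        "sex": rng.choice(["M", "F"], n_animals),
                        "birth_year": rng.integers(1990, 2024, n_animals)})

    if n_phenotyped is None:
        n_phenotyped = max(6, int(0.7 * n_animals))
    who = sorted(rng.choice(n_animals, n_phenotyped, replace=False))
    ph = pd.DataFrame({
        "id": [ids[i] for i in who],
        "trait": "BW",
        "value": rng.normal(40.0, 12.0, n_phenotyped),
        "sex": [ped["sex"].iloc[i] for i in who],
        "cg": rng.choice(["2005x1", "2012x2"], n_phenotyped),
    })
    return g, f, grm, ped, ph
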