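"""Maternal-effects animal model GBLUP.

The model is  y = Xb + Za + Wm + e  with

* b  — fixed effects: contemporary group (birth year x dam age class, with
  the intercept absorbed) and sex (as a contrast);
* a  — direct additive genetic effects,  m — maternal genetic effects, with
  joint prior [a; m] ~ N(0, G0 (x) G) where G0 = [[sa2, sam], [sam, sm2]]
  and G is a genomic relationship matrix;
* e ~ N(0, I se2).

``W`` links each record to its DAM's maternal effect; records with an
unknown dam get a zero maternal link. Variance components are fixed inputs
(assigned from the literature, never estimated here). Solving Henderson's
mixed-model equations yields fixed-effect estimates and GEBV for every
animal in G — animals without phenotypes (validation animals) are predicted
through the inverse-G coupling.

Usage follows the Model/Results convention::

    model = MaternalGBLUP.from_tables(phenos, pedigree, grm, vc, trait="BW")
    res = model.fit()
    res.direct_gebv          # pd.Series indexed by animal ID
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io import UNKNOWN_PARENT
from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)

# above this coefficient-matrix dimension the solver switches from a dense
# factorization to preconditioned conjugate gradients
DIRECT_MAX_DIM = 3000
CG_TOL = 1e-10


class ModelSpecificationError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """Fixed (co)variance components for one trait, all in kg^2.

    ``sigma_m2 = 0`` (with ``cov_am = 0``) drops the maternal block and the
    model reduces to single-effect GBLUP.
    """

    sigma_a2: float
    sigma_m2: float
    cov_am: float
    sigma_e2: float

    def __post_init__(self):
        if self.sigma_a2 <= 0:
            raise ModelSpecificationError(f"sigma_a2 = {self.sigma_a2} must be > 0")
        if self.sigma_e2 <= 0:
            raise ModelSpecificationError(f"sigma_e2 = {self.sigma_e2} must be > 0")
        if self.sigma_m2 < 0:
            raise ModelSpecificationError(f"sigma_m2 = {self.sigma_m2} must be >= 0")
        if self.sigma_m2 == 0:
            if self.cov_am != 0:
                raise ModelSpecificationError(
                    "cov_am must be 0 when sigma_m2 is 0 (no maternal effect)")
        else:
            det = self.sigma_a2 * self.sigma_m2 - self.cov_am ** 2
            if det <= 0:
                raise ModelSpecificationError(
                    f"direct-maternal covariance matrix not positive definite: "
                    f"sigma_a2={self.sigma_a2}, sigma_m2={self.sigma_m2}, "
                    f"cov_am={self.cov_am} (determinant {det:g})")

    @property
    def has_maternal(self) -> bool:
        return self.sigma_m2 > 0

    @property
    def G0(self) -> np.ndarray:
        return np.array([[self.sigma_a2, self.cov_am],
                         [self.cov_am, self.sigma_m2]], dtype=float)


# literature-assigned components used in the study populations (kg^2);
# Line 1 = highly inbred closed Hereford line, CGC = closed composite herd
LITERATURE_VARCOMP: dict[str, dict[str, VarianceComponents]] = {
    "line1": {
        "BW": VarianceComponents(100.24, 95.18, -56.31, 150.32),
        "WW": VarianceComponents(137.5, 93.4, -48.0, 302.1),
        "YW": VarianceComponents(563.0, 154.0, -151.0, 240.0),
    },
    "cgc": {
        "BW": VarianceComponents(120.74, 37.63, -27.00, 250.7476),
        "WW": VarianceComponents(298.0, 168.0, -165.0, 258.0),
        "YW": VarianceComponents(563.0, 154.0, -151.0, 240.0),
    },
}


@dataclass
class DesignMatrices:
    """Incidence structures X (fixed), Z (direct), W (maternal) for one trait."""

    X: np.ndarray
    x_names: list[str]
    Z: sp.csr_matrix
    W: sp.csr_matrix
    record_ids: np.ndarray
    cg_levels: list[str]
    sex_levels: list[str]
    n_missing_dam: int = 0


def build_incidence(ph: pd.DataFrame, ped: pd.DataFrame,
                    ids) -> DesignMatrices:
    """Build X, Z, W for phenotype records against the animal ordering ``ids``.

    X holds one column per contemporary-group level (intercept absorbed)
    plus sex contrasts against the first sex level. Z selects each record's
    own animal; W selects the record's dam (zero row when the dam is
    unknown or not among ``ids``, counted and logged).
    """
    ids = np.asarray(ids, dtype=object)
    lut = {iid: i for i, iid in enumerate(ids)}
    n_animals = len(ids)
    n_rec = len(ph)
    if n_rec == 0:
        raise ModelSpecificationError("no phenotype records")

    missing_animals = sorted(set(ph["id"].astype(str)) - set(lut))
    if missing_animals:
        raise ModelSpecificationError(
            f"phenotyped animals absent from the relationship matrix: "
            f"{missing_animals[:5]}")

    cg = ph["cg"].astype(str).to_numpy()
    sex = ph["sex"].astype(str).to_numpy()
    cg_levels = sorted(set(cg))
    sex_levels = sorted(set(sex))

    X_cols = [(cg == lv).astype(float) for lv in cg_levels]
    x_names = [f"cg:{lv}" for lv in cg_levels]
    for lv in sex_levels[1:]:
        X_cols.append((sex == lv).astype(float))
        x_names.append(f"sex:{lv}")
    X = np.column_stack(X_cols)

    rows = np.arange(n_rec)
    own = np.array([lut[i] for i in ph["id"].astype(str)], dtype=int)
    Z = sp.csr_matrix((np.ones(n_rec), (rows, own)), shape=(n_rec, n_animals))

    dam_of = dict(zip(ped["id"].astype(str), ped["dam"].astype(str)))
    w_rows, w_cols = [], []
    n_missing_dam = 0
    for r, iid in enumerate(ph["id"].astype(str)):
        dam = dam_of.get(iid, UNKNOWN_PARENT)
        if dam != UNKNOWN_PARENT and dam in lut:
            w_rows.append(r)
            w_cols.append(lut[dam])
        else:
            n_missing_dam += 1
    if n_missing_dam:
        logger.warning("%d records have no maternal link (unknown dam or dam "
                       "not in the relationship matrix)", n_missing_dam)
    W = sp.csr_matrix((np.ones(len(w_rows)), (w_rows, w_cols)),
                      shape=(n_rec, n_animals))

    return DesignMatrices(X=X, x_names=x_names, Z=Z, W=W,
                          record_ids=ph["id"].astype(str).to_numpy(dtype=object),
                          cg_levels=cg_levels, sex_levels=sex_levels,
                          n_missing_dam=n_missing_dam)


def _rank_repair(X: np.ndarray, names: list[str]):
    """Drop aliased fixed-effect columns via pivoted QR; report dropped names."""
    if X.shape[1] == 0:
        raise ModelSpecificationError("empty fixed-effects design")
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in sorted(piv[rank:])]
    if dropped:
        logger.info("dropped aliased fixed-effect levels: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


class MaternalGBLUP:
    """Maternal-effects GBLUP model over a genomic relationship matrix.

    Parameters
    ----------
    y : record phenotype vector (kg)
    design : DesignMatrices for those records
    grm : conditioned (invertible) RelationshipMatrix over all animals
    varcomp : fixed VarianceComponents for the trait
    """

    def __init__(self, y, design: DesignMatrices, grm: RelationshipMatrix,
                 varcomp: VarianceComponents):
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != design.X.shape[0]:
            raise ModelSpecificationError("y length does not match design rows")
        self.design = design
        self.grm = grm
        self.varcomp = varcomp
        self.X, self.x_names, self.dropped_fixed = _rank_repair(
            design.X, design.x_names)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:  # pragma: no cover
            raise ModelSpecificationError(
                f"fixed-effects design still singular after dropping "
                f"{self.dropped_fixed}")

    @classmethod
    def from_tables(cls, phenotypes: pd.DataFrame, pedigree: pd.DataFrame,
                    grm: RelationshipMatrix, varcomp: VarianceComponents,
                    trait: str | None = None) -> "MaternalGBLUP":
        ph = phenotypes
        if trait is not None:
            ph = ph[ph["trait"].astype(str) == trait]
            if len(ph) == 0:
                raise ModelSpecificationError(f"no records for trait {trait!r}")
        elif ph["trait"].nunique() > 1:
            raise ModelSpecificationError(
                "phenotype table holds several traits; pass trait=...")
        design = build_incidence(ph, pedigree, grm.individual_ids)
        return cls(ph["value"].to_numpy(dtype=float), design, grm, varcomp)

    # -- solving ----------------------------------------------------------

    def _assemble(self):
        """Henderson's MME coefficient blocks and right-hand side."""
        vc = self.varcomp
        X = self.X
        Z, W = self.design.Z, self.design.W
        n_anim = self.grm.n
        Ginv = scipy.linalg.inv(self.grm.values)
        Ginv = 0.5 * (Ginv + Ginv.T)
        y = self.y

        XtX = X.T @ X
        XtZ = X.T @ Z.toarray()
        Xty = X.T @ y
        ZtZ = (Z.T @ Z).toarray()
        Zty = Z.T @ y

        if vc.has_maternal:
            K = vc.sigma_e2 * scipy.linalg.inv(vc.G0)
            kaa, kam, kmm = K[0, 0], K[0, 1], K[1, 1]
            XtW = X.T @ W.toarray()
            ZtW = (Z.T @ W).toarray()
            WtW = (W.T @ W).toarray()
            Wty = W.T @ y
            C = np.block([
                [XtX, XtZ, XtW],
                [XtZ.T, ZtZ + Ginv * kaa, ZtW + Ginv * kam],
                [XtW.T, ZtW.T + Ginv * kam, WtW + Ginv * kmm],
            ])
            rhs = np.concatenate([Xty, Zty, Wty])
        else:
            lam = vc.sigma_e2 / vc.sigma_a2
            C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + Ginv * lam]])
            rhs = np.concatenate([Xty, Zty])
        return C, rhs, n_anim

    def fit(self, method: str = "auto", cg_tol: float = CG_TOL,
            cg_maxiter: int = 50000) -> "MaternalGBLUPResults":
        """Solve the MME.

        ``method`` is "direct" (dense Cholesky), "cg" (Jacobi-preconditioned
        conjugate gradients, relative residual < ``cg_tol``), or "auto"
        (direct below :data:`DIRECT_MAX_DIM` unknowns).
        """
        C, rhs, n_anim = self._assemble()
        dim = C.shape[0]
        if method == "auto":
            method = "direct" if dim <= DIRECT_MAX_DIM else "cg"

        converged = True
        if method == "direct":
            try:
                cho = scipy.linalg.cho_factor(C)
                sol = scipy.linalg.cho_solve(cho, rhs)
                report = f"direct Cholesky, dim={dim}"
            except scipy.linalg.LinAlgError:
                sol, *_ = scipy.linalg.lstsq(C, rhs)
                report = f"direct least-squares fallback, dim={dim}"
        elif method == "cg":
            dpre = np.abs(np.diag(C))
            dpre[dpre == 0] = 1.0
            Mpre = spla.LinearOperator((dim, dim), matvec=lambda v: v / dpre)
            sol, info = spla.cg(C, rhs, rtol=cg_tol, atol=0.0,
                                maxiter=cg_maxiter, M=Mpre)
            converged = info == 0
            rel = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
            report = f"pcg, dim={dim}, info={info}, rel_residual={rel:.3e}"
            if not converged:
                logger.warning("conjugate gradients did not converge: %s", report)
        else:
            raise ValueError(f"unknown method {method!r}")

        p = self.X.shape[1]
        b_hat = sol[:p]
        a_hat = sol[p:p + n_anim]
        m_hat = (sol[p + n_anim:p + 2 * n_anim] if self.varcomp.has_maternal
                 else np.zeros(n_anim))
        return MaternalGBLUPResults(
            model=self,
            fixed_estimates=pd.Series(b_hat, index=self.x_names, name="estimate"),
            direct_gebv=pd.Series(a_hat, index=pd.Index(self.grm.individual_ids,
                                                        name="id"), name="direct_gebv"),
            maternal_gebv=pd.Series(m_hat, index=pd.Index(self.grm.individual_ids,
                                                          name="id"), name="maternal_gebv"),
            converged=converged, solver_report=report,
        )


@dataclass
class MaternalGBLUPResults:
    """Fitted fixed effects and GEBV (direct + maternal) for every animal in G."""

    model: MaternalGBLUP
    fixed_estimates: pd.Series
    direct_gebv: pd.Series
    maternal_gebv: pd.Series
    converged: bool
    solver_report: str = ""

    def fixed_effect_vector(self, ph: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Xb-hat for new records, with a keep-mask for records whose
        fixed-effect levels were seen in training.

        Levels dropped during rank repair contribute 0 (their effect is
        absorbed by the retained columns' estimates).
        """
        cg = ph["cg"].astype(str).to_numpy()
        sex = ph["sex"].astype(str).to_numpy()
        des = self.model.design
        seen = (np.isin(cg, des.cg_levels) & np.isin(sex, des.sex_levels))
        est = self.fixed_estimates
        xb = np.zeros(len(ph))
        for lv in des.cg_levels:
            key = f"cg:{lv}"
            if key in est.index:
                xb += (cg == lv) * est[key]
        for lv in des.sex_levels[1:]:
            key = f"sex:{lv}"
            if key in est.index:
                xb += (sex == lv) * est[key]
        return xb, seen

    def corrected_phenotypes(self, ph: pd.DataFrame) -> pd.Series:
        """y - Xb-hat for the given records, using the training-estimated b.

        Records whose contemporary-group or sex level was unseen in training
        are dropped (count logged). Raises if nothing survives.
        """
        xb, seen = self.fixed_effect_vector(ph)
        n_drop = int((~seen).sum())
        if n_drop:
            logger.warning("dropping %d records with fixed-effect levels "
                           "unseen in training", n_drop)
        if not seen.any():
            raise ModelSpecificationError(
                "all records dropped: no fixed-effect level seen in training")
        yc = ph["value"].to_numpy(dtype=float) - xb
        return pd.Series(yc[seen],
                         index=pd.Index(ph["id"].astype(str).to_numpy()[seen],
                                        name="id"),
                         name="corrected_phenotype")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"direct_gebv": self.direct_gebv,
                             "maternal_gebv": self.maternal_gebv})

    def summary(self) -> str:
        vc = self.model.varcomp
        lines = [
            "Maternal-effects GBLUP (fixed variance components)",
            "=" * 54,
            f"records:              {len(self.model.y)}",
            f"animals in G:         {self.model.grm.n}",
            f"G kind / ridge:       {self.model.grm.kind} / "
            f"{self.model.grm.ridge_applied:g}",
            f"sigma_a2, sigma_m2:   {vc.sigma_a2:g}, {vc.sigma_m2:g} kg^2",
            f"cov_am, sigma_e2:     {vc.cov_am:g}, {vc.sigma_e2:g} kg^2",
            f"solver:               {self.solver_report}",
            f"converged:            {self.converged}",
            "",
            "fixed effects",
            "-" * 34,
        ]
        for name, val in self.fixed_estimates.items():
            lines.append(f"{name:<24s} {val:>9.4f}")
        if self.model.dropped_fixed:
            lines.append(f"(aliased, dropped: {', '.join(self.model.dropped_fixed)})")
        lines += [
            "",
            f"sd(direct GEBV):      {self.direct_gebv.std():.4f} kg",
            f"sd(maternal GEBV):    {self.maternal_gebv.std():.4f} kg",
        ]
        return "\n".join(lines)


def corrected_phenotypes(ph: pd.DataFrame,
                         results: MaternalGBLUPResults) -> pd.Series:
    """Functional alias for :meth:`MaternalGBLUPResults.corrected_phenotypes`."""
    return results.corrected_phenotypes(ph)
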