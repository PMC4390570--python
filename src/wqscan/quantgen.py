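"""Quantitative genetics: family variance components, genomic heritability,
and mixed-model association scans.

Two statsmodels-style model objects carry the layer:

* :class:`FamilyVarianceModel` fits the multi-environment family model

      y_ijk = mu + g_i + l_j + gl_ij + b_k(j) + e_ijk

  with environment ``l_j`` and replicate-within-environment ``b_k(j)``
  fixed, family ``g_i ~ N(0, sigma2_G)`` and family-by-environment
  ``gl_ij ~ N(0, sigma2_GE)`` random, by REML; its results expose the
  components, per-family BLUPs and broad-sense heritability on a
  family-mean basis,

      H = sigma2_G / (sigma2_G + sigma2_GE/e + sigma2_e/(r e)).

* :class:`GBLUP` fits y = X b + Z u + e with u ~ N(0, G sigma2_u) for a
  marker-derived genomic relationship matrix G, via a single eigen-rotation
  of G and one-dimensional REML profiling of the variance ratio; genomic
  heritability is h2_G = sigma2_u / (sigma2_u + sigma2_e).  Its results
  drive the per-marker association scan (marker added as a fixed covariate,
  null-model variance components re-used — the standard
  population-parameters-previously-determined approximation).

REML is maximized by an EM-started Average-Information algorithm
(quadratic convergence near the optimum, EM fallback whenever an AI step
misbehaves), converging on relative parameter change below 1e-10 within
500 iterations.  Negative components are truncated at zero on return.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genio import GenotypeMatrix

__all__ = [
    "FamilyVarianceModel",
    "VarianceComponents",
    "fit_family_varcomps",
    "broad_sense_H",
    "genomic_relationship_matrix",
    "GBLUP",
    "GblupFit",
    "gblup_reml",
    "AssociationResult",
    "association_scan",
]


# ---------------------------------------------------------------------------
# family variance components


def _design_matrices(df: pd.DataFrame, trait: str, family: str,
                     environment: str, replicate: str):
    for col in (family, environment, replicate, trait):
        if col not in df.columns:
            raise KeyError(f"column {col!r} missing from the phenotype table")
    data = df.dropna(subset=[trait])
    y = data[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    fam = pd.Categorical(data[family])
    env = pd.Categorical(data[environment])
    rep = pd.Categorical(data[replicate])
    n = len(data)

    X_parts = [np.ones((n, 1))]
    if len(env.categories) > 1:
        X_parts.append(pd.get_dummies(env, drop_first=True).to_numpy(dtype=float))
    # replicate nested within environment: one dummy per (env, rep>first)
    if len(rep.categories) > 1:
        er = pd.get_dummies(
            pd.Series(env.astype(str)) + ":" + pd.Series(rep.astype(str)),
            drop_first=False).to_numpy(dtype=float)
        # drop the first replicate column within each environment
        cols = pd.get_dummies(
            pd.Series(env.astype(str)) + ":" + pd.Series(rep.astype(str))).columns
        keep = [i for i, c in enumerate(cols)
                if c.split(":", 1)[1] != str(rep.categories[0])]
        if keep:
            X_parts.append(er[:, keep])
    X = np.column_stack(X_parts)
    # guard against rank deficiency in the fixed design
    qr_rank = np.linalg.matrix_rank(X)
    if qr_rank < X.shape[1]:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        X = u[:, :qr_rank] * s[:qr_rank]

    Z1 = pd.get_dummies(fam).to_numpy(dtype=float)
    fe = pd.Series(fam.astype(str)) + "|" + pd.Series(env.astype(str))
    Z2 = pd.get_dummies(pd.Categorical(fe)).to_numpy(dtype=float)
    return y, X, Z1, Z2, fam, env, rep


def _reml_ai(y, X, Z_list, max_iter=500, tol=1e-10, n_em=3):
    """EM-started average-information REML for V = sum_i th_i Z_i Z_i' + th_e I.

    Works on Henderson's mixed-model equations: the coefficient matrix
    C = [[X'X, X'Z], [Z'X, Z'Z + diag(lambda_i I)]] with
    lambda_i = th_e / th_i is factorized once per iteration, and all REML
    quantities come from MME identities (u_hat_i = th_i Z_i' P y,
    tr(P Z_i Z_i') = (q_i - lambda_i tr C^{ii}) / th_i, and
    -2 l_R = (n-p-q) ln th_e + sum_i q_i ln th_i + ln|C| + y'e_hat/th_e).
    EM steps open the run, AI steps finish it quadratically; negative AI
    proposals are clamped at a small positive floor (a component pinned
    there is reported as zero).  Returns (theta, loglik, n_iter, converged,
    u_hats, Py).
    """
    n, p = X.shape
    q = [Z.shape[1] for Z in Z_list]
    m = len(Z_list) + 1
    W = np.column_stack([X] + Z_list)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    offsets = np.cumsum([p] + q)
    blocks = [slice(offsets[i], offsets[i + 1]) for i in range(len(q))]
    vary = float(np.var(y)) or 1.0
    floor = 1e-10 * vary
    theta = np.full(m, vary / m)

    def crunch(th):
        th_e = th[-1]
        C = WtW.copy()
        for i, blk in enumerate(blocks):
            idx = np.arange(blk.start, blk.stop)
            C[idx, idx] += th_e / th[i]
        cf = linalg.cho_factor(C)
        sol = linalg.cho_solve(cf, Wty)
        ehat = y - W @ sol
        ytPy_scaled = yty - float(Wty @ sol)  # = y'e_hat = th_e * y'Py
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]))
        logdetC = 2.0 * float(np.log(np.diag(cf[0])).sum())
        neg2ll = ((n - p - sum(q)) * np.log(th_e)
                  + sum(qi * np.log(th[i]) for i, qi in enumerate(q))
                  + logdetC + ytPy_scaled / th_e)
        uhats = [sol[blk] for blk in blocks]
        trCii = [float(np.trace(Cinv[blk, blk])) for blk in blocks]
        return sol, uhats, ehat, trCii, Cinv, -0.5 * neg2ll

    def derived(th, uhats, ehat, trCii):
        """(yPVPy_i, trPV_i) for each component, residual last."""
        th_e = th[-1]
        Py = ehat / th_e
        yPVPy, trPV = [], []
        for i, qi in enumerate(q):
            yPVPy.append(float(uhats[i] @ uhats[i]) / th[i] ** 2)
            trPV.append((qi - (th_e / th[i]) * trCii[i]) / th[i])
        yPVPy.append(float(Py @ Py))
        trPV.append((n - p - sum(
            qi - (th_e / th[i]) * trCii[i] for i, qi in enumerate(q))) / th_e)
        return np.asarray(yPVPy), np.asarray(trPV), Py

    def project(v, cf_cache):
        """P v = (v - W C^{-1} W' v) / th_e, using the cached factor."""
        cf, th_e = cf_cache
        return (v - W @ linalg.cho_solve(cf, W.T @ v)) / th_e

    sol, uhats, ehat, trCii, Cinv, ll = crunch(theta)
    qarr = np.array(q + [n], dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        yPVPy, trPV, Py = derived(theta, uhats, ehat, trCii)
        em_new = np.maximum(theta + (theta ** 2 / qarr) * (yPVPy - trPV), floor)
        if it <= n_em:
            new = em_new
        else:
            # AI matrix: 0.5 * (V_dot_i P y)' P (V_dot_j P y)
            th_e = theta[-1]
            C = WtW.copy()
            for i, blk in enumerate(blocks):
                idx = np.arange(blk.start, blk.stop)
                C[idx, idx] += th_e / theta[i]
            cf = linalg.cho_factor(C)
            vs = [np.zeros(n) for _ in range(m)]
            for i, Z in enumerate(Z_list):
                vs[i] = Z @ (uhats[i] / theta[i])
            vs[-1] = Py
            Pvs = [project(v, (cf, th_e)) for v in vs]
            AI = 0.5 * np.array([[float(vs[i] @ Pvs[j]) for j in range(m)]
                                 for i in range(m)])
            score = 0.5 * (yPVPy - trPV)
            try:
                step = np.linalg.solve(AI + 1e-12 * np.eye(m), score)
                new = theta + step
                # pin components proposed non-positive at the floor and
                # re-solve the reduced system for the free ones
                pinned = new <= floor
                if pinned.any() and not pinned.all():
                    free = ~pinned
                    step_p = floor - theta[pinned]
                    rhs = score[free] - AI[np.ix_(free, pinned)] @ step_p
                    sub = AI[np.ix_(free, free)] + 1e-12 * np.eye(free.sum())
                    new = theta.copy()
                    new[pinned] = floor
                    new[free] = theta[free] + np.linalg.solve(sub, rhs)
                new = np.maximum(new, floor)
            except np.linalg.LinAlgError:
                new = em_new
        res = crunch(new)
        if it > n_em and res[-1] < ll - 1e-8:
            new = em_new
            res = crunch(new)
        delta = np.max(np.abs(new - theta) / np.maximum(theta, floor * 10))
        theta = new
        sol, uhats, ehat, trCii, Cinv, ll = res
        if it > n_em and delta < tol:
            converged = True
            break
    Py = ehat / theta[-1]
    theta = np.where(theta <= floor * 1.001, 0.0, theta)
    return theta, ll, it, converged, uhats, Py


@dataclass
class VarianceComponents:
    """REML results of the family model (also the results object of
    :class:`FamilyVarianceModel`)."""

    sigma2_G: float
    sigma2_GE: float
    sigma2_e: float
    e: int
    r: float
    blups: pd.Series
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    single_environment: bool = False
    trait: str = "trait"

    @property
    def H(self) -> float:
        return broad_sense_H(self)

    def summary(self) -> str:
        rows = [
            ("sigma2_G (family)", self.sigma2_G),
            ("sigma2_GE (family x env)", self.sigma2_GE),
            ("sigma2_e (residual)", self.sigma2_e),
            ("environments (e)", self.e),
            ("replicates per env (r)", self.r),
            ("broad-sense H (family-mean)", self.H),
            ("REML loglik", self.loglik),
        ]
        width = max(len(k) for k, _ in rows)
        lines = [f"Family variance components [{self.trait}]",
                 "=" * (width + 14)]
        for k, v in rows:
            lines.append(f"{k:<{width}}  {v: .6g}")
        lines.append(f"converged: {self.converged} ({self.n_iter} iterations)")
        if self.single_environment:
            lines.append("note: single environment; sigma2_GE structurally zero")
        return "\n".join(lines)


class FamilyVarianceModel:
    """Mixed model for multi-environment family trials.

    Construct from a long-format phenotype table with one row per plot
    (family, environment, replicate, trait value); ``fit`` runs REML and
    returns :class:`VarianceComponents`.
    """

    def __init__(self, data: pd.DataFrame, trait: str, family: str = "family",
                 environment: str = "environment", replicate: str = "replicate"):
        self.data = data
        self.trait = trait
        (self.y, self.X, self.Z1, self.Z2,
         self.families, self.envs, self.reps) = _design_matrices(
            data, trait, family, environment, replicate)
        if len(self.families.categories) < 2:
            raise ValueError("need at least 2 families")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, **cols) -> "FamilyVarianceModel":
        return cls(data, trait, **cols)

    def fit(self, max_iter: int = 500, tol: float = 1e-10) -> VarianceComponents:
        n_env = len(self.envs.categories)
        single_env = n_env < 2
        Z_list = [self.Z1] if single_env else [self.Z1, self.Z2]
        if single_env:
            warnings.warn("single environment: sigma2_GE is inestimable and "
                          "returned as structurally zero")
        theta, ll, it, conv, uhats, Py = _reml_ai(
            self.y, self.X, Z_list, max_iter=max_iter, tol=tol)
        s2g = float(theta[0])
        s2ge = 0.0 if single_env else float(theta[1])
        s2e = float(theta[-1])
        blup_vals = uhats[0]
        blups = pd.Series(blup_vals, index=list(self.families.categories),
                          name=f"blup_{self.trait}")
        # replicate count per environment (mean, for the H denominator)
        counts = (pd.DataFrame({"e": self.envs, "r": self.reps})
                  .groupby("e", observed=True)["r"].nunique())
        return VarianceComponents(
            sigma2_G=s2g, sigma2_GE=s2ge, sigma2_e=s2e,
            e=n_env, r=float(counts.mean()),
            blups=blups, loglik=ll, n_iter=it, converged=conv,
            single_environment=single_env, trait=self.trait,
        )


def fit_family_varcomps(pheno: pd.DataFrame, trait: str, **cols) -> VarianceComponents:
    """Convenience wrapper: build :class:`FamilyVarianceModel` and fit."""
    return FamilyVarianceModel(pheno, trait, **cols).fit()


def broad_sense_H(vc) -> float:
    """Broad-sense heritability on a family-mean basis,
    H = sigma2_G / (sigma2_G + sigma2_GE/e + sigma2_e/(r e))."""
    s2g, s2ge, s2e = vc.sigma2_G, vc.sigma2_GE, vc.sigma2_e
    e, r = vc.e, vc.r
    if e < 1 or r < 1:
        raise ValueError("need e >= 1 and r >= 1")
    denom = s2g + s2ge / e + s2e / (r * e)
    if denom == 0:
        raise ValueError("all variance components are zero; H undefined")
    return float(min(max(s2g / denom, 0.0), 1.0))


# ---------------------------------------------------------------------------
# genomic relationship matrix and G-BLUP


def genomic_relationship_matrix(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix G = Wc Wc' / (2 sum p q).

    ``Wc`` is the dosage matrix column-centered by twice the allele
    frequency (computed from the same samples).  Monomorphic loci contribute
    nothing to either numerator or denominator and are dropped; missing
    genotypes must be imputed beforehand.
    """
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; impute first")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci are monomorphic; G undefined")
    Xp = X[:, poly]
    pp = p[poly]
    Wc = Xp - 2.0 * pp
    return (Wc @ Wc.T) / (2.0 * np.sum(pp * (1.0 - pp)))


@dataclass
class GblupFit:
    """REML results of the G-BLUP model."""

    sigma2_u: float
    sigma2_res: float
    h2_g: float
    fixed_effects: pd.Series
    loglik: float
    converged: bool
    n_obs: int

    def summary(self) -> str:
        lines = [
            "G-BLUP REML fit",
            "===============",
            f"n                 {self.n_obs}",
            f"sigma2_u          {self.sigma2_u: .6g}",
            f"sigma2_res        {self.sigma2_res: .6g}",
            f"h2_G              {self.h2_g: .4f}",
            f"REML loglik       {self.loglik: .6g}",
            f"converged         {self.converged}",
            "fixed effects:",
        ]
        lines += [f"  {k:<12} {v: .6g}" for k, v in self.fixed_effects.items()]
        return "\n".join(lines)


class GBLUP:
    """Genomic BLUP model y = X b + Z u + e with u ~ N(0, G sigma2_u).

    ``G`` is a symmetric positive semi-definite relationship matrix aligned
    with ``y`` (Z = I).  ``X`` defaults to an intercept; pass a design
    matrix or DataFrame of fixed covariates (cycle/year effects).  The fit
    rotates the model by the eigenvectors of G once and profiles the REML
    log-likelihood over the ratio lambda = sigma2_u / sigma2_e.
    """

    def __init__(self, y, G: np.ndarray, X=None, fixed_names=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        G = np.asarray(G, dtype=float)
        if G.shape != (n, n):
            raise ValueError("G must be n x n, aligned with y")
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        if X is None:
            X = np.ones((n, 1))
            fixed_names = fixed_names or ["intercept"]
        elif isinstance(X, pd.DataFrame):
            fixed_names = fixed_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("X and y dimensions disagree")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effects design is singular")
        self.X = X
        self.fixed_names = fixed_names or [f"b{j}" for j in range(X.shape[1])]
        s, U = np.linalg.eigh(G)
        s = np.clip(s, 0.0, None)  # tolerate tiny negative eigenvalues
        self.eigval, self.eigvec = s, U
        self.y_rot = U.T @ self.y
        self.X_rot = U.T @ self.X

    def _profile_neg2ll(self, log_lambda: float) -> float:
        lam = np.exp(log_lambda)
        n, p = self.X_rot.shape
        w = 1.0 / (lam * self.eigval + 1.0)
        Xw = self.X_rot * w[:, None]
        XtWX = self.X_rot.T @ Xw
        c = linalg.cho_factor(XtWX)
        beta = linalg.cho_solve(c, Xw.T @ self.y_rot)
        res = self.y_rot - self.X_rot @ beta
        quad = float(np.sum(w * res * res))
        s2e = quad / (n - p)
        logdetD = float(np.sum(np.log(lam * self.eigval + 1.0)))
        logdetX = 2.0 * float(np.log(np.diag(c[0])).sum())
        return logdetD + logdetX + (n - p) * np.log(s2e), beta, s2e

    def fit(self, max_iter: int = 200) -> GblupFit:
        n, p = self.X_rot.shape
        if n <= p:
            raise ValueError("more fixed effects than observations")
        obj = lambda t: self._profile_neg2ll(t)[0]
        res = optimize.minimize_scalar(
            obj, bounds=(-25.0, 12.0), method="bounded",
            options={"xatol": 1e-10, "maxiter": max_iter})
        t_hat = float(res.x)
        # boundary check: sigma2_u -> 0
        if obj(-25.0) <= res.fun + 1e-12:
            t_hat = -25.0
        neg2ll, beta, s2e = self._profile_neg2ll(t_hat)
        lam = np.exp(t_hat)
        s2u = 0.0 if t_hat <= -24.99 else lam * s2e
        h2 = s2u / (s2u + s2e) if (s2u + s2e) > 0 else 0.0
        return GblupFit(
            sigma2_u=float(s2u), sigma2_res=float(s2e), h2_g=float(h2),
            fixed_effects=pd.Series(beta, index=self.fixed_names),
            loglik=-0.5 * neg2ll, converged=bool(res.success), n_obs=n,
        )


def gblup_reml(y, fixed, G) -> GblupFit:
    """Convenience wrapper: fit :class:`GBLUP` with the given fixed-effects
    design (None for intercept-only)."""
    return GBLUP(y, G, X=fixed).fit()


# ---------------------------------------------------------------------------
# association scan


@dataclass
class AssociationResult:
    """Per-marker mixed-model association results."""

    table: pd.DataFrame  # locus, effect, se, stat, p_value, significant, status
    alpha: float
    h2_g_null: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_loci(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def association_scan(
    y,
    markers: GenotypeMatrix | np.ndarray,
    G: np.ndarray,
    fixed=None,
    alpha: float = 1e-4,
    null_fit: GblupFit | None = None,
    exact: bool = False,
) -> AssociationResult:
    """Per-marker mixed-model scan: each marker enters the G-BLUP model as a
    fixed covariate and its coefficient is tested against zero.

    By default the genetic and residual variance components are taken from
    the marker-free null fit and held fixed across markers (the efficient
    population-parameters-previously-determined scheme); ``exact=True``
    re-estimates them per marker.  Markers with no variation are skipped
    with status ``monomorphic``; markers collinear with the fixed design
    with status ``collinear``; tested markers have status ``ok``.  Markers
    with p < ``alpha`` are flagged significant.
    """
    if isinstance(markers, GenotypeMatrix):
        M = markers.dosages
        names = list(markers.locus_ids)
    else:
        M = np.asarray(markers, dtype=float)
        names = [f"m{j}" for j in range(M.shape[1])]
    if np.isnan(M).any():
        raise ValueError("markers contain missing values; impute first")
    model = GBLUP(y, G, X=fixed)
    if null_fit is None:
        null_fit = model.fit()

    n, p = model.X_rot.shape
    nm = M.shape[1]
    eff = np.full(nm, np.nan)
    se = np.full(nm, np.nan)
    stat = np.full(nm, np.nan)
    pval = np.full(nm, np.nan)
    status = np.array(["ok"] * nm, dtype=object)

    mono = M.std(axis=0) == 0
    status[mono] = "monomorphic"

    if exact:
        for j in range(nm):
            if status[j] != "ok":
                continue
            Xj = np.column_stack([model.X, M[:, j]])
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                status[j] = "collinear"
                continue
            fit_j = GBLUP(y, G, X=Xj).fit()
            lam = fit_j.sigma2_u / fit_j.sigma2_res if fit_j.sigma2_res > 0 else 0.0
            w = 1.0 / (lam * model.eigval + 1.0)
            _wald_fill(model, M[:, j:j + 1], w, [j], eff, se, stat, pval, status)
    else:
        lam = (null_fit.sigma2_u / null_fit.sigma2_res
               if null_fit.sigma2_res > 0 else 0.0)
        w = 1.0 / (lam * model.eigval + 1.0)
        todo = np.flatnonzero(status == "ok")
        _wald_fill(model, M[:, todo], w, todo, eff, se, stat, pval, status)

    significant = np.where(np.isnan(pval), False, pval < alpha)
    table = pd.DataFrame({
        "locus": names, "effect": eff, "se": se, "stat": stat,
        "p_value": pval, "significant": significant, "status": status,
    })
    return AssociationResult(table=table, alpha=alpha, h2_g_null=null_fit.h2_g)


def _wald_fill(model: GBLUP, M: np.ndarray, w: np.ndarray, idx, eff, se,
               stat, pval, status) -> None:
    """Whitened per-marker regression tests, vectorized over markers.

    Whitening uses the rotated model with weights ``w``; the fixed design is
    projected out and each marker tested by a t statistic with the residual
    scale re-estimated per marker (n - p - 1 degrees of freedom).
    """
    sw = np.sqrt(w)
    ys = model.y_rot * sw
    Xs = model.X_rot * sw[:, None]
    Ms = (model.eigvec.T @ M) * sw[:, None]
    Q, _ = np.linalg.qr(Xs)
    ry = ys - Q @ (Q.T @ ys)
    rM = Ms - Q @ (Q.T @ Ms)
    n, p = Xs.shape
    df = n - p - 1
    mss = np.einsum("ij,ij->j", rM, rM)
    raw = np.einsum("ij,ij->j", Ms, Ms)
    collinear = mss <= 1e-10 * np.maximum(raw, 1.0)
    my = rM.T @ ry
    yy = float(ry @ ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = my / mss
        rss = np.maximum(yy - beta * my, 0.0)
        sigma2 = rss / df
        serr = np.sqrt(sigma2 / mss)
        t = beta / serr
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    idx = np.asarray(idx)
    ok = ~collinear
    eff[idx[ok]] = beta[ok]
    se[idx[ok]] = serr[ok]
    stat[idx[ok]] = t[ok]
    pval[idx[ok]] = pv[ok]
    status[idx[~ok]] = "collinear"
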