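"""Linear mixed models for repeated multi-environment trials, fit by REML.

Two model families are supported, matching the two analysis stages of a
two-year replicated trial:

* ``fixed_gxe`` — genotype, year and genotype x year as fixed effects, block
  as a random effect, and a residual that may be heteroscedastic by year and
  correlated across years within a genotype x block cell (the repeated unit
  of a re-randomized trial).  This model feeds the ANOVA, the pseudo-R², the
  adjusted genotype x year cell means and all contrast tests.
* ``all_random`` — intercept plus random genotype, year, genotype x year,
  block, block x year and column-within-block effects with iid residuals.
  Its variance components feed the entry-mean heritability.

The engine maximizes the restricted likelihood of

    y ~ N(X beta, V),    V = sum_f sigma2_f Z_f Z_f' + R(tau)

over log variances (and, for the correlated residual, Fisher-z correlation)
with an analytic gradient, using L-BFGS-B.  Components whose unconstrained
optimum collapses to zero are removed and refit pinned at zero, and reported
with a boundary flag — the published component table has several exact zeros
(year variance for five traits), so the boundary case is routine, not
exceptional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import TrialData

__all__ = [
    "DesignMatrices",
    "VarianceComponents",
    "FixedFit",
    "build_design",
    "reml_fit",
    "fit_trait",
    "wald_anova",
    "pseudo_r2",
    "cell_mean_matrix",
    "MixedModelError",
]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class MixedModelError(RuntimeError):
    """Raised for non-estimable designs or failed fits."""


# --------------------------------------------------------------------- types
@dataclass
class RandomTerm:
    name: str
    Z: np.ndarray  # (n, q) incidence matrix
    levels: list


@dataclass
class ResidualStructure:
    """Residual covariance descriptor.

    kind:
      * ``iid`` — sigma2 * I.
      * ``hetero`` — per-year variances on the diagonal.
      * ``hetero_corr`` — per-year variances plus a common correlation between
        the two observations of each genotype x block cell across years
        (two-year designs only).
    """

    kind: str = "iid"
    year_index: np.ndarray | None = None  # (n,) int codes into year levels
    n_years: int = 1
    pairs: np.ndarray | None = None  # (npair, 2) row indices, year0/year1

    @property
    def n_params(self) -> int:
        return {"iid": 1, "hetero": self.n_years, "hetero_corr": self.n_years + 1}[
            self.kind
        ]


@dataclass
class DesignMatrices:
    """Response, fixed design, random incidence matrices and factor metadata."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    terms: list[RandomTerm]
    residual: ResidualStructure
    term_slices: dict[str, np.ndarray]  # fixed term -> column indices
    genotype_levels: list
    year_levels: list
    trait: str
    model: str
    rows: pd.DataFrame  # accession/year/block/column per observation

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def coefficient_factors(self) -> dict[str, tuple]:
        """Map each coefficient name to its (term, level(s)) interpretation."""
        out: dict[str, tuple] = {"Intercept": ("Intercept", ())}
        for name in self.colnames:
            if name == "Intercept":
                continue
            term, _, lev = name.partition("[")
            out[name] = (term, tuple(lev.rstrip("]").split("|")))
        return out


@dataclass
class VarianceComponents:
    """Named REML variance estimates with convergence diagnostics."""

    components: dict[str, float]
    residual_variances: np.ndarray  # per-year (length 1 for iid)
    residual_corr: float
    residual_kind: str
    loglik: float
    converged: bool
    boundary: set[str] = field(default_factory=set)
    n_iter: int = 0

    @property
    def sigma2_resid(self) -> float:
        """Average residual variance (exact residual variance when iid)."""
        return float(np.mean(self.residual_variances))

    def __getitem__(self, name: str) -> float:
        return self.components[name]


@dataclass
class FixedFit:
    """GLS fixed effects at the REML optimum."""

    beta: np.ndarray
    colnames: list[str]
    cov: np.ndarray
    df_resid: int
    fitted: np.ndarray  # X beta (marginal)
    fitted_conditional: np.ndarray  # X beta + Z u (BLUPs included)
    residuals: np.ndarray  # y - fitted
    y: np.ndarray


# ------------------------------------------------------------- build_design
def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.shape[0], n_levels))
    Z[np.arange(codes.shape[0]), codes] = 1.0
    return Z


def build_design(
    data: TrialData,
    trait: str,
    model: str = "fixed_gxe",
    residual_structure: str = "iid",
    random_factors: tuple[str, ...] | None = None,
) -> DesignMatrices:
    """Assemble design matrices for one trait.

    ``model="fixed_gxe"`` uses reference coding (first genotype, first year)
    for the fixed part and a random block main effect; ``model="all_random"``
    has an intercept-only fixed part and random genotype, year, genotype x
    year, block, block x year and column terms (``random_factors`` can
    restrict that set).  Column levels are nested in year x block.
    """
    df = data.trait_frame(trait)
    if df.empty:
        raise MixedModelError(f"trait {trait!r} has no non-missing observations")
    y = df["value"].to_numpy(dtype=float)

    g_levels = [a for a in data.accessions if a in set(df["accession"])]
    j_levels = [yv for yv in data.years if yv in set(df["year"])]
    k_levels = [b for b in data.blocks if b in set(df["block"])]
    gi = df["accession"].map({v: i for i, v in enumerate(g_levels)}).to_numpy()
    jj = df["year"].map({v: i for i, v in enumerate(j_levels)}).to_numpy()
    kk = df["block"].map({v: i for i, v in enumerate(k_levels)}).to_numpy()
    n_g, n_j, n_k = len(g_levels), len(j_levels), len(k_levels)

    if model == "fixed_gxe":
        if n_j < 2:
            raise MixedModelError(
                "fixed_gxe includes a genotype x year term and needs >= 2 years"
            )
        if n_g < 2:
            raise MixedModelError("fixed_gxe needs >= 2 genotypes")
        cols = [np.ones(len(y))]
        names = ["Intercept"]
        slices: dict[str, list[int]] = {"genotype": [], "year": [], "genotype:year": []}
        for i, lev in enumerate(g_levels[1:], start=1):
            cols.append((gi == i).astype(float))
            slices["genotype"].append(len(names))
            names.append(f"genotype[{lev}]")
        for j, lev in enumerate(j_levels[1:], start=1):
            cols.append((jj == j).astype(float))
            slices["year"].append(len(names))
            names.append(f"year[{lev}]")
        for i, glev in enumerate(g_levels[1:], start=1):
            for j, ylev in enumerate(j_levels[1:], start=1):
                cols.append(((gi == i) & (jj == j)).astype(float))
                slices["genotype:year"].append(len(names))
                names.append(f"genotype:year[{glev}|{ylev}]")
        X = np.column_stack(cols)
        terms = [RandomTerm("block", _dummy(kk, n_k), k_levels)]
        residual = _make_residual(residual_structure, df, jj, n_j)
    elif model == "all_random":
        X = np.ones((len(y), 1))
        names = ["Intercept"]
        slices = {}
        wanted = random_factors or (
            "genotype",
            "year",
            "genotype:year",
            "block",
            "block:year",
            "column",
        )
        terms = []
        for name in wanted:
            if name == "genotype":
                terms.append(RandomTerm("genotype", _dummy(gi, n_g), g_levels))
            elif name == "year":
                terms.append(RandomTerm("year", _dummy(jj, n_j), j_levels))
            elif name == "genotype:year":
                codes = gi * n_j + jj
                levels = [f"{g}|{j}" for g in g_levels for j in j_levels]
                terms.append(RandomTerm("genotype:year", _dummy(codes, n_g * n_j), levels))
            elif name == "block":
                terms.append(RandomTerm("block", _dummy(kk, n_k), k_levels))
            elif name == "block:year":
                codes = kk * n_j + jj
                levels = [f"{b}|{j}" for b in k_levels for j in j_levels]
                terms.append(RandomTerm("block:year", _dummy(codes, n_k * n_j), levels))
            elif name == "column":
                key = (
                    df["year"].astype(str)
                    + "/"
                    + df["block"].astype(str)
                    + "/"
                    + df["column"].astype(str)
                )
                levels = list(pd.unique(key))
                codes = key.map({v: i for i, v in enumerate(levels)}).to_numpy()
                terms.append(RandomTerm("column", _dummy(codes, len(levels)), levels))
            else:
                raise MixedModelError(f"unknown random factor {name!r}")
        if residual_structure != "iid":
            raise MixedModelError("all_random supports only iid residuals")
        residual = ResidualStructure("iid", jj, n_j, None)
    else:
        raise MixedModelError(f"unknown model {model!r}")

    return DesignMatrices(
        y=y,
        X=X,
        colnames=names,
        terms=terms,
        residual=residual,
        term_slices={k: np.array(v, dtype=int) for k, v in slices.items()},
        genotype_levels=g_levels,
        year_levels=j_levels,
        trait=trait,
        model=model,
        rows=df[["accession", "year", "block", "column"]].reset_index(drop=True),
    )


def _make_residual(
    kind: str, df: pd.DataFrame, jj: np.ndarray, n_j: int
) -> ResidualStructure:
    if kind == "iid":
        return ResidualStructure("iid", jj, n_j, None)
    if kind == "hetero":
        return ResidualStructure("hetero", jj, n_j, None)
    if kind == "hetero_corr":
        if n_j != 2:
            raise MixedModelError("hetero_corr requires exactly two years")
        key = list(zip(df["accession"], df["block"]))
        by_cell: dict[tuple, dict[int, int]] = {}
        for row, (cell, year_code) in enumerate(zip(key, jj)):
            by_cell.setdefault(cell, {})[int(year_code)] = row
        pairs = [
            (d[0], d[1]) for d in by_cell.values() if 0 in d and 1 in d and len(d) == 2
        ]
        if not pairs:
            raise MixedModelError(
                "hetero_corr requires genotype x block cells observed in both years"
            )
        return ResidualStructure("hetero_corr", jj, n_j, np.array(pairs, dtype=int))
    raise MixedModelError(f"unknown residual structure {kind!r}")


# ------------------------------------------------------------------ REML fit
def _residual_matrix(res: ResidualStructure, tau: np.ndarray, n: int) -> np.ndarray:
    if res.kind == "iid":
        return np.exp(tau[0]) * np.eye(n)
    s2 = np.exp(tau[: res.n_years])
    R = np.diag(s2[res.year_index])
    if res.kind == "hetero_corr":
        rho = np.tanh(tau[res.n_years])
        i, j = res.pairs[:, 0], res.pairs[:, 1]
        off = rho * np.sqrt(s2[res.year_index[i]] * s2[res.year_index[j]])
        R[i, j] = off
        R[j, i] = off
    return R


def _residual_gradients(
    res: ResidualStructure, tau: np.ndarray, P: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """d(-2 restricted loglik)/d tau contributions: tr(P dR) - r' dR r, halved later."""
    diagP = np.diag(P)
    grads = np.empty(res.n_params)
    if res.kind == "iid":
        s2 = np.exp(tau[0])
        grads[0] = s2 * (diagP.sum() - r @ r)
        return grads
    s2 = np.exp(tau[: res.n_years])
    for j in range(res.n_years):
        mask = res.year_index == j
        g = s2[j] * (diagP[mask].sum() - r[mask] @ r[mask])
        if res.kind == "hetero_corr":
            rho = np.tanh(tau[res.n_years])
            i0, i1 = res.pairs[:, 0], res.pairs[:, 1]
            sprod = np.sqrt(s2[res.year_index[i0]] * s2[res.year_index[i1]])
            # d off/d log s2_j = 0.5 * off for pairs touching year j (each pair
            # touches both years exactly once in a two-year design)
            doff = 0.5 * rho * sprod
            g += 2.0 * (doff * P[i0, i1]).sum() - 2.0 * (doff * r[i0] * r[i1]).sum()
        grads[j] = g
    if res.kind == "hetero_corr":
        rho = np.tanh(tau[res.n_years])
        i0, i1 = res.pairs[:, 0], res.pairs[:, 1]
        sprod = np.sqrt(s2[res.year_index[i0]] * s2[res.year_index[i1]])
        doff = (1.0 - rho**2) * sprod
        grads[res.n_years] = 2.0 * (doff * P[i0, i1]).sum() - 2.0 * (
            doff * r[i0] * r[i1]
        ).sum()
    return grads


class _REMLProblem:
    def __init__(self, dm: DesignMatrices, active: list[int]):
        self.dm = dm
        self.active = active  # indices into dm.terms included in the fit
        self.G = [dm.terms[i].Z @ dm.terms[i].Z.T for i in active]
        self.Zs = [dm.terms[i].Z for i in active]
        self.n_comp = len(active)
        self.n_res = dm.residual.n_params

    def split(self, theta):
        return theta[: self.n_comp], theta[self.n_comp :]

    def _decompose(self, theta):
        dm = self.dm
        lsig, tau = self.split(theta)
        V = _residual_matrix(dm.residual, tau, dm.n)
        for s2, G in zip(np.exp(lsig), self.G):
            V += s2 * G
        cF = linalg.cho_factor(V, lower=True, check_finite=False)
        Vinv_X = linalg.cho_solve(cF, dm.X, check_finite=False)
        Vinv_y = linalg.cho_solve(cF, dm.y, check_finite=False)
        XtVX = dm.X.T @ Vinv_X
        cX = linalg.cho_factor(XtVX, lower=True, check_finite=False)
        beta = linalg.cho_solve(cX, dm.X.T @ Vinv_y, check_finite=False)
        r = Vinv_y - Vinv_X @ beta  # = P y
        logdetV = 2.0 * np.log(np.diag(cF[0])).sum()
        logdetXVX = 2.0 * np.log(np.diag(cX[0])).sum()
        nll = 0.5 * (
            logdetV + logdetXVX + dm.y @ r + (dm.n - dm.p) * _LOG2PI
        )
        return nll, cF, cX, Vinv_X, beta, r

    def value_and_grad(self, theta):
        dm = self.dm
        try:
            nll, cF, cX, Vinv_X, beta, r = self._decompose(theta)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        lsig, tau = self.split(theta)
        Vinv = linalg.cho_solve(cF, np.eye(dm.n), check_finite=False)
        W = linalg.cho_solve(cX, Vinv_X.T, check_finite=False)
        P = Vinv - Vinv_X @ W
        grad = np.empty_like(theta)
        for k, (s2, Z) in enumerate(zip(np.exp(lsig), self.Zs)):
            PZ = P @ Z
            tr = float(np.einsum("ij,ij->", PZ, Z))
            Ztr = Z.T @ r
            grad[k] = 0.5 * s2 * (tr - Ztr @ Ztr)
        grad[self.n_comp :] = 0.5 * _residual_gradients(dm.residual, tau, P, r)
        return float(nll), grad

    def fixed_fit(self, theta) -> tuple[FixedFit, float]:
        dm = self.dm
        nll, cF, cX, Vinv_X, beta, r = self._decompose(theta)
        cov = linalg.cho_solve(cX, np.eye(dm.p), check_finite=False)
        cov = 0.5 * (cov + cov.T)
        fitted = dm.X @ beta
        cond = fitted.copy()
        lsig, _ = self.split(theta)
        for s2, Z in zip(np.exp(lsig), self.Zs):
            cond += s2 * (Z @ (Z.T @ r))  # BLUP contribution
        fit = FixedFit(
            beta=beta,
            colnames=dm.colnames,
            cov=cov,
            df_resid=dm.n - dm.p,
            fitted=fitted,
            fitted_conditional=cond,
            residuals=dm.y - fitted,
            y=dm.y,
        )
        return fit, -nll


def reml_fit(
    dm: DesignMatrices,
    start: dict[str, float] | None = None,
    tol: float = 1e-13,
    max_iter: int = 500,
) -> tuple[VarianceComponents, FixedFit]:
    """Maximize the restricted likelihood; returns components and GLS fit.

    Components whose estimate collapses to (near) zero are refit pinned at
    exactly zero and flagged as boundary estimates.
    """
    if dm.n <= dm.p:
        raise MixedModelError("need more observations than fixed parameters")
    vy = float(np.var(dm.y))
    if vy == 0.0:
        vy = 1.0
    floor = 1e-8 * vy

    active = list(range(len(dm.terms)))
    boundary: set[str] = set()
    total_iter = 0
    while True:
        prob = _REMLProblem(dm, active)
        theta0 = _start_values(dm, active, vy, start)
        bounds = [(np.log(floor), np.log(1e6 * vy))] * prob.n_comp
        if dm.residual.kind == "hetero_corr":
            bounds += [(np.log(floor), np.log(1e6 * vy))] * dm.residual.n_years
            bounds += [(-5.0, 5.0)]
        else:
            bounds += [(np.log(floor), np.log(1e6 * vy))] * dm.residual.n_params
        res = optimize.minimize(
            prob.value_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        total_iter += res.nit
        res.x, res.fun, res.jac = _newton_polish(prob, res.x, bounds)
        lsig, tau = prob.split(res.x)
        s2 = np.exp(lsig)
        collapsed = [i for i, v in zip(active, s2) if v < 10.0 * floor]
        if not collapsed:
            break
        for i in collapsed:
            boundary.add(dm.terms[i].name)
        active = [i for i in active if i not in collapsed]

    components = {t.name: 0.0 for t in dm.terms}
    for i, v in zip(active, s2):
        components[dm.terms[i].name] = float(v)
    if dm.residual.kind == "iid":
        res_var = np.array([np.exp(tau[0])])
        rho = 0.0
    else:
        res_var = np.exp(tau[: dm.residual.n_years])
        rho = float(np.tanh(tau[dm.residual.n_years])) if dm.residual.kind == "hetero_corr" else 0.0

    fit, loglik = prob.fixed_fit(res.x)
    converged = bool(res.success) or res.status == 0
    if not converged:
        # tight ftol can abort the line search at the optimum; accept the
        # iterate when the projected gradient is (near) zero
        grad = np.asarray(res.jac, dtype=float)
        for k, (lo, hi) in enumerate(bounds):
            if (res.x[k] <= lo + 1e-10 and grad[k] > 0) or (
                res.x[k] >= hi - 1e-10 and grad[k] < 0
            ):
                grad[k] = 0.0
        converged = float(np.max(np.abs(grad))) < 1e-3
    if not converged:
        logger.warning(
            "REML did not converge for trait %s (%s): %s",
            dm.trait,
            dm.model,
            res.message,
        )
    vc = VarianceComponents(
        components=components,
        residual_variances=res_var,
        residual_corr=rho,
        residual_kind=dm.residual.kind,
        loglik=float(loglik),
        converged=converged,
        boundary=boundary,
        n_iter=total_iter,
    )
    return vc, fit


def _newton_polish(prob, x, bounds, max_steps=2, gtol=1e-10):
    """Few Newton steps (finite-difference Hessian of the analytic gradient)
    to sharpen the quasi-Newton solution along nearly flat directions."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    f0, g0 = prob.value_and_grad(x)
    for _ in range(max_steps):
        if np.max(np.abs(g0)) < gtol:
            break
        k = x.size
        H = np.empty((k, k))
        eps = 1e-5
        for i in range(k):
            xp = x.copy()
            xp[i] += eps
            _, gp = prob.value_and_grad(xp)
            H[:, i] = (gp - g0) / eps
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(k), g0)
        except np.linalg.LinAlgError:
            break
        xn = np.clip(x - step, lo, hi)
        fn, gn = prob.value_and_grad(xn)
        if not np.isfinite(fn) or fn > f0 + 1e-9:
            break
        x, f0, g0 = xn, fn, gn
    return x, f0, g0


def _start_values(dm, active, vy, start):
    k = len(active) + 1  # + residual
    default = vy / max(k, 2)
    vals = []
    for i in active:
        name = dm.terms[i].name
        v = (start or {}).get(name, default)
        vals.append(np.log(max(v, 1e-6 * vy)))
    res_start = (start or {}).get("residual", default)
    if dm.residual.kind == "iid":
        vals.append(np.log(max(res_start, 1e-6 * vy)))
    else:
        vals.extend([np.log(max(res_start, 1e-6 * vy))] * dm.residual.n_years)
        if dm.residual.kind == "hetero_corr":
            vals.append(0.0)
    return np.array(vals)


def fit_trait(
    data: TrialData,
    trait: str,
    model: str = "fixed_gxe",
    residual_structure: str = "auto",
    **kwargs,
) -> tuple[VarianceComponents, FixedFit, DesignMatrices]:
    """Convenience wrapper: build design, fit, with residual-structure fallback.

    ``residual_structure="auto"`` tries the correlated heteroscedastic
    residual first (the default analysis of the modeled trial), falling back
    to heteroscedastic-only and then iid when the richer structure is not
    estimable or does not converge.  The chosen structure is logged.
    """
    if model == "all_random":
        dm = build_design(data, trait, model, "iid")
        vc, fit = reml_fit(dm, **kwargs)
        return vc, fit, dm
    if residual_structure != "auto":
        dm = build_design(data, trait, model, residual_structure)
        vc, fit = reml_fit(dm, **kwargs)
        return vc, fit, dm
    last_err: Exception | None = None
    for kind in ("hetero_corr", "hetero", "iid"):
        try:
            dm = build_design(data, trait, model, kind)
            vc, fit = reml_fit(dm, **kwargs)
            if vc.converged or kind == "iid":
                logger.info("trait %s: residual structure %s", trait, kind)
                return vc, fit, dm
        except MixedModelError as err:
            last_err = err
            continue
    raise MixedModelError(
        f"no residual structure estimable for trait {trait!r}: {last_err}"
    )


# --------------------------------------------------------- ANOVA / pseudo-R2
def wald_anova(fit: FixedFit, dm: DesignMatrices) -> pd.DataFrame:
    """Wald F tests per fixed term, residual (containment) denominator df."""
    rows = []
    for term, idx in dm.term_slices.items():
        if idx.size == 0:
            continue
        L = np.zeros((idx.size, dm.p))
        L[np.arange(idx.size), idx] = 1.0
        Lb = L @ fit.beta
        M = L @ fit.cov @ L.T
        try:
            sol = linalg.solve(M, Lb, assume_a="pos")
        except linalg.LinAlgError as err:
            aliased = [dm.colnames[i] for i in idx]
            raise MixedModelError(
                f"rank-deficient term {term!r}; aliased columns {aliased}"
            ) from err
        F = float(Lb @ sol) / idx.size
        p = float(stats.f.sf(F, idx.size, fit.df_resid))
        rows.append(
            {"term": term, "F": F, "df_num": int(idx.size), "df_den": fit.df_resid, "p": p}
        )
    return pd.DataFrame(rows)


def pseudo_r2(fit: FixedFit, dm: DesignMatrices) -> float:
    """Squared Pearson correlation of observed vs conditional fitted values."""
    y = fit.y
    yhat = fit.fitted_conditional
    if np.var(y) == 0.0:
        raise MixedModelError("observed values have zero variance")
    if np.var(yhat) <= 1e-14 * np.var(y):
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


# ------------------------------------------------------------- cell means
def cell_mean_matrix(dm: DesignMatrices) -> tuple[np.ndarray, pd.DataFrame]:
    """Matrix L with one row per genotype x year cell: cell mean = L beta.

    Returns the matrix and an index frame (accession, year) in level order.
    Only defined for the fixed_gxe model.
    """
    if dm.model != "fixed_gxe":
        raise MixedModelError("cell means require the fixed_gxe model")
    name_to_col = {n: i for i, n in enumerate(dm.colnames)}
    rows = []
    index = []
    for g in dm.genotype_levels:
        for yv in dm.year_levels:
            row = np.zeros(dm.p)
            row[name_to_col["Intercept"]] = 1.0
            gkey = f"genotype[{g}]"
            ykey = f"year[{yv}]"
            ikey = f"genotype:year[{g}|{yv}]"
            if gkey in name_to_col:
                row[name_to_col[gkey]] = 1.0
            if ykey in name_to_col:
                row[name_to_col[ykey]] = 1.0
            if ikey in name_to_col:
                row[name_to_col[ikey]] = 1.0
            rows.append(row)
            index.append((g, yv))
    L = np.vstack(rows)
    idx = pd.DataFrame(index, columns=["accession", "year"])
    return L, idx


def adjusted_cell_means(fit: FixedFit, dm: DesignMatrices) -> pd.DataFrame:
    """Model-based genotype x year means (equal arithmetic means in balance)."""
    L, idx = cell_mean_matrix(dm)
    out = idx.copy()
    out["mean"] = L @ fit.beta
    return out
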