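"""Animal-model mixed-model equations, EM-REML and genetic parameters.

Model per trait: y = X beta + Z u + e with u ~ N(0, K sigma_a^2) where K is
the relationship matrix whose inverse (A^-1 or the single-step H^-1) is
supplied, and e ~ N(0, I sigma_e^2).  Multi-trait systems use the Kronecker
structure Sigma_a^-1 (x) K^-1 for the random block and require an identical
record set across traits (balanced design).

Variance components come from EM-REML: derivative-free, monotone in the
restricted likelihood, adequate at the problem sizes this package targets.
Two code paths share the same update:

* a generic dense path (any design, single- or multi-trait) that inverts
  the coefficient matrix each round, and
* a canonical-decomposition path for the common single-trait case where
  every animal has exactly one record, which diagonalizes the absorbed
  system once and then iterates in O(n^2) per round.

Updates:  sigma_a^2 <- (u' K^-1 u + tr(K^-1 C^uu)) / q  (C^uu in variance
units), residual via the classic y'(y - X b - Z u) / (n - rank X) form
(symmetrized cross-trait analogue in the multivariate case).  EM keeps
components non-negative naturally; a floor of 1e-10 sigma_p^2 guards the
boundary numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .relationship import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "Design",
    "VarianceComponents",
    "Solutions",
    "GeneticParameters",
    "RemlResult",
    "build_design",
    "solve_mme",
    "em_reml",
    "genetic_parameters",
    "restricted_loglik",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which traits are analyzed and which categorical factors are fitted."""

    traits: tuple[str, ...]
    fixed_effects: tuple[str, ...] = (
        "farm",
        "last_parity",
        "last_farrow_month",
        "last_farrow_year",
    )


@dataclass
class Design:
    """Incidence structures: X (records x fixed columns, intercept plus
    one-hot factors with the first-observed level as reference) and the
    record-to-animal incidence Z."""

    X: np.ndarray
    Z: np.ndarray
    record_ids: tuple[str, ...]
    animal_ids: tuple[str, ...]
    x_columns: tuple[str, ...]

    @property
    def n_records(self) -> int:
        return self.X.shape[0]


def build_design(
    traits_table: pd.DataFrame, spec: ModelSpec, animal_ids
) -> Design:
    """One-hot design with intercept; reference level = first observed level
    of each factor.  ``animal_ids`` fixes the ordering of the random-effect
    vector (normally the pedigree order of the relationship matrix)."""
    record_ids = tuple(str(i) for i in traits_table.index)
    aindex = {a: i for i, a in enumerate(animal_ids)}
    unknown = [r for r in record_ids if r not in aindex]
    if unknown:
        raise KeyError(f"records for animals not in relationship: {unknown[:5]}")
    n = len(record_ids)
    cols = [np.ones(n)]
    names = ["intercept"]
    for factor in spec.fixed_effects:
        if factor not in traits_table.columns:
            raise KeyError(f"fixed factor {factor!r} not in trait table")
        values = traits_table[factor].astype(str).to_numpy()
        seen: list[str] = []
        for v in values:
            if v not in seen:
                seen.append(v)
        for level in seen[1:]:  # first-observed level is the reference
            cols.append((values == level).astype(float))
            names.append(f"{factor}[{level}]")
    X = np.column_stack(cols)
    Z = np.zeros((n, len(animal_ids)))
    for r, rid in enumerate(record_ids):
        Z[r, aindex[rid]] = 1.0
    return Design(
        X=X,
        Z=Z,
        record_ids=record_ids,
        animal_ids=tuple(animal_ids),
        x_columns=tuple(names),
    )


@dataclass
class VarianceComponents:
    """Additive and residual (co)variance matrices over an ordered trait
    list; sigma_p = sigma_a + sigma_e by definition."""

    traits: tuple[str, ...]
    sigma_a: np.ndarray
    sigma_e: np.ndarray

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.sigma_a = np.atleast_2d(np.asarray(self.sigma_a, float))
        self.sigma_e = np.atleast_2d(np.asarray(self.sigma_e, float))
        for name, m in (("sigma_a", self.sigma_a), ("sigma_e", self.sigma_e)):
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if np.abs(m - m.T).max() > 1e-8 * max(1.0, np.abs(m).max()):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8 * max(1.0, np.abs(m).max()):
                raise ValueError(f"{name} must be positive semi-definite")

    @property
    def sigma_p(self) -> np.ndarray:
        return self.sigma_a + self.sigma_e

    @classmethod
    def single(cls, trait: str, sa2: float, se2: float) -> "VarianceComponents":
        return cls(traits=(trait,), sigma_a=[[sa2]], sigma_e=[[se2]])


@dataclass
class Solutions:
    """Fixed-effect estimates (relative to each factor's reference level)
    and breeding values for every animal in the relationship, phenotyped
    or not."""

    beta: pd.DataFrame  # x_columns x traits
    u: pd.DataFrame  # animal_ids x traits

    def gebv(self, animal_ids, trait: str) -> np.ndarray:
        return self.u.loc[list(animal_ids), trait].to_numpy()


def _safe_spd_solve(C: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Symmetric factorization with a pseudo-inverse fallback for
    rank-deficient fixed blocks."""
    try:
        c, low = linalg.cho_factor(C)
        return linalg.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError:
        return linalg.pinvh(C) @ rhs


def _mme_parts(design: Design, kinv: np.ndarray, varcomp: VarianceComponents):
    t = len(varcomp.traits)
    X, Z = design.X, design.Z
    sei = linalg.pinvh(varcomp.sigma_e)
    sai = linalg.pinvh(varcomp.sigma_a)
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    top = np.hstack([np.kron(sei, XtX), np.kron(sei, XtZ)])
    bot = np.hstack(
        [np.kron(sei, XtZ.T), np.kron(sei, ZtZ) + np.kron(sai, kinv)]
    )
    C = np.vstack([top, bot])
    return C, sei, t


def _stack_rhs(design: Design, sei: np.ndarray, Y: np.ndarray):
    """RHS of the MME for trait-major stacking [beta_1..beta_t, u_1..u_t]."""
    X, Z = design.X, design.Z
    XtY = X.T @ Y  # p x t
    ZtY = Z.T @ Y  # q x t
    rhs_b = (XtY @ sei.T).T.reshape(-1)
    rhs_u = (ZtY @ sei.T).T.reshape(-1)
    return np.concatenate([rhs_b, rhs_u])


def solve_mme(
    design: Design,
    relationship_inverse: RelationshipMatrix | np.ndarray,
    varcomp: VarianceComponents,
    Y: pd.DataFrame | np.ndarray,
) -> Solutions:
    """Solve Henderson's mixed-model equations (single- or multi-trait).

    ``Y`` holds one column per trait over the design's records.  Returns
    solutions for all animals in the relationship, including unphenotyped
    ones (predicted through their relatives).
    """
    kinv = (
        relationship_inverse.values
        if isinstance(relationship_inverse, RelationshipMatrix)
        else np.asarray(relationship_inverse, float)
    )
    if kinv.shape[0] != len(design.animal_ids):
        raise ValueError("relationship inverse size inconsistent with design")
    Yv = np.asarray(Y, float).reshape(design.n_records, len(varcomp.traits))
    C, sei, t = _mme_parts(design, kinv, varcomp)
    rhs = _stack_rhs(design, sei, Yv)
    sol = _safe_spd_solve(C, rhs)
    p = design.X.shape[1]
    q = len(design.animal_ids)
    beta = sol[: p * t].reshape(t, p).T
    u = sol[p * t:].reshape(t, q).T
    return Solutions(
        beta=pd.DataFrame(beta, index=design.x_columns, columns=varcomp.traits),
        u=pd.DataFrame(u, index=design.animal_ids, columns=varcomp.traits),
    )


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------


@dataclass
class RemlResult:
    varcomp: VarianceComponents
    converged: bool
    n_rounds: int
    history: list  # (sigma_a, sigma_e) per round


def em_reml(
    design: Design,
    relationship_inverse: RelationshipMatrix | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    start: VarianceComponents,
    max_rounds: int = 1000,
    tol: float = 1e-8,
) -> RemlResult:
    """EM-REML variance components; never fails silently on
    non-convergence (the result carries ``converged=False``)."""
    kinv = (
        relationship_inverse.values
        if isinstance(relationship_inverse, RelationshipMatrix)
        else np.asarray(relationship_inverse, float)
    )
    t = len(start.traits)
    Yv = np.asarray(Y, float).reshape(design.n_records, t)
    if design.n_records <= design.X.shape[1]:
        raise ValueError("need more records than fixed-effect columns")
    if t == 1 and _is_identity_incidence(design):
        return _em_reml_canonical(design, kinv, Yv, start, max_rounds, tol)
    return _em_reml_dense(design, kinv, Yv, start, max_rounds, tol)


def _is_identity_incidence(design: Design) -> bool:
    Z = design.Z
    return Z.shape[0] == Z.shape[1] and np.array_equal(Z, np.eye(Z.shape[0]))


def _floor_components(sa, se, floor_ref):
    floor = 1e-10 * floor_ref
    sa = sa.copy()
    se = se.copy()
    np.fill_diagonal(sa, np.maximum(np.diag(sa), floor))
    np.fill_diagonal(se, np.maximum(np.diag(se), floor))
    return sa, se


def _em_reml_canonical(design, kinv, Yv, start, max_rounds, tol):
    """Single-trait, one record per animal: absorb the fixed block once,
    diagonalize L^-1 S L^-T where K^-1 = L L', then iterate cheaply.

    With S = I - X (X'X)^+ X' the absorbed coefficient matrix is
    S + lambda K^-1 = L (B + lambda I) L', B = U Lam U', giving
    u = T (Lam + lambda)^-1 T' S y with T = L^-T U,
    u' K^-1 u = ||w||^2 and tr(K^-1 C^uu) = sum 1/(Lam_i + lambda).
    """
    y = Yv[:, 0]
    X = design.X
    n = len(y)
    p = np.linalg.matrix_rank(X)
    XtX_pinv = linalg.pinvh(X.T @ X)

    def project_out(v):
        return v - X @ (XtX_pinv @ (X.T @ v))

    Sy = project_out(y)
    L = np.linalg.cholesky(kinv + 1e-12 * np.trace(kinv) / len(kinv) * np.eye(len(kinv)))
    Linv = linalg.solve_triangular(L, np.eye(len(L)), lower=True)
    S = np.eye(n) - X @ XtX_pinv @ X.T
    B = Linv @ S @ Linv.T
    lam_eig, U = np.linalg.eigh(0.5 * (B + B.T))
    lam_eig = np.clip(lam_eig, 0.0, None)
    T = Linv.T @ U
    c = T.T @ Sy

    sa2 = float(start.sigma_a[0, 0])
    se2 = float(start.sigma_e[0, 0])
    sp_ref = sa2 + se2
    history = []
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        lam = se2 / max(sa2, 1e-300)
        w = c / (lam_eig + lam)
        u = T @ w
        quad = float(w @ w)  # u' K^-1 u
        tr = float(np.sum(1.0 / (lam_eig + lam)))
        sa2_new = (quad + se2 * tr) / n
        resid = float(y @ project_out(y - u)) / (n - p)
        se2_new = resid
        sa2_new = max(sa2_new, 1e-10 * sp_ref)
        se2_new = max(se2_new, 1e-10 * sp_ref)
        delta = max(
            abs(sa2_new - sa2) / max(abs(sa2), 1e-300),
            abs(se2_new - se2) / max(abs(se2), 1e-300),
        )
        sa2, se2 = sa2_new, se2_new
        history.append((np.array([[sa2]]), np.array([[se2]])))
        if delta < tol:
            converged = True
            break
    return RemlResult(
        varcomp=VarianceComponents(
            traits=start.traits, sigma_a=[[sa2]], sigma_e=[[se2]]
        ),
        converged=converged,
        n_rounds=rounds,
        history=history,
    )


def _em_reml_dense(design, kinv, Yv, start, max_rounds, tol):
    """Generic EM-REML: rebuild and invert the MME each round."""
    t = Yv.shape[1]
    n = design.n_records
    q = len(design.animal_ids)
    p = design.X.shape[1]
    rank_x = np.linalg.matrix_rank(design.X)
    sa = np.array(start.sigma_a, float)
    se = np.array(start.sigma_e, float)
    sp_ref = float(np.max(np.diag(sa + se)))
    vc = VarianceComponents(traits=start.traits, sigma_a=sa, sigma_e=se)
    history = []
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        C, sei, _ = _mme_parts(design, kinv, vc)
        rhs = _stack_rhs(design, sei, Yv)
        Cinv = linalg.pinvh(C)
        sol = Cinv @ rhs
        beta = sol[: p * t].reshape(t, p).T
        u = sol[p * t:].reshape(t, q).T
        ehat = Yv - design.X @ beta - design.Z @ u
        sa_new = np.empty((t, t))
        se_new = np.empty((t, t))
        for s_ in range(t):
            for t_ in range(s_, t):
                blk = Cinv[
                    p * t + s_ * q: p * t + (s_ + 1) * q,
                    p * t + t_ * q: p * t + (t_ + 1) * q,
                ]
                val = (u[:, s_] @ kinv @ u[:, t_] + np.sum(kinv * blk.T)) / q
                sa_new[s_, t_] = sa_new[t_, s_] = val
                rv = 0.5 * (Yv[:, s_] @ ehat[:, t_] + Yv[:, t_] @ ehat[:, s_])
                se_new[s_, t_] = se_new[t_, s_] = rv / (n - rank_x)
        sa_new, se_new = _floor_components(sa_new, se_new, sp_ref)
        delta = max(
            np.abs(sa_new - sa).max() / max(np.abs(sa).max(), 1e-300),
            np.abs(se_new - se).max() / max(np.abs(se).max(), 1e-300),
        )
        sa, se = sa_new, se_new
        history.append((sa.copy(), se.copy()))
        vc = VarianceComponents(
            traits=start.traits, sigma_a=_psd_guard(sa), sigma_e=_psd_guard(se)
        )
        if delta < tol:
            converged = True
            break
    return RemlResult(varcomp=vc, converged=converged, n_rounds=rounds, history=history)


def _psd_guard(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    return (v * np.clip(w, 1e-12 * max(1.0, w.max()), None)) @ v.T


# ---------------------------------------------------------------------------
# Genetic parameters and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class GeneticParameters:
    h2: pd.Series
    r_g: pd.DataFrame
    r_p: pd.DataFrame


def genetic_parameters(varcomp: VarianceComponents) -> GeneticParameters:
    """Heritabilities and genetic/phenotypic correlations.

    h2_t = sigma_a(t) / (sigma_a(t) + sigma_e(t)); correlations are
    covariances standardized by the corresponding standard deviations, NaN
    where a variance is zero (flagged undefined, not an error)."""
    sa, sp = varcomp.sigma_a, varcomp.sigma_p
    traits = list(varcomp.traits)
    da, dp = np.diag(sa), np.diag(sp)
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(dp > 0, da / dp, np.nan)
        rg = sa / np.sqrt(np.outer(da, da))
        rp = sp / np.sqrt(np.outer(dp, dp))
    rg[~np.isfinite(rg)] = np.nan
    rp[~np.isfinite(rp)] = np.nan
    np.fill_diagonal(rg, np.where(da > 0, 1.0, np.nan))
    np.fill_diagonal(rp, np.where(dp > 0, 1.0, np.nan))
    return GeneticParameters(
        h2=pd.Series(h2, index=traits, name="h2"),
        r_g=pd.DataFrame(rg, index=traits, columns=traits),
        r_p=pd.DataFrame(rp, index=traits, columns=traits),
    )


def restricted_loglik(
    design: Design,
    K: np.ndarray,
    varcomp: VarianceComponents,
    Y: pd.DataFrame | np.ndarray,
) -> float:
    """Restricted log-likelihood computed directly from
    V = Sigma_a (x) Z K Z' + Sigma_e (x) I (dense; diagnostic use at small
    n, e.g. verifying EM monotonicity)."""
    t = len(varcomp.traits)
    Yv = np.asarray(Y, float).reshape(design.n_records, t)
    ZKZ = design.Z @ K @ design.Z.T
    n = design.n_records
    V = np.kron(varcomp.sigma_a, ZKZ) + np.kron(varcomp.sigma_e, np.eye(n))
    Xs = np.kron(np.eye(t), design.X)
    y = Yv.T.reshape(-1)
    Vi = linalg.pinvh(V)
    XtVX = Xs.T @ Vi @ Xs
    P = Vi - Vi @ Xs @ linalg.pinvh(XtVX) @ Xs.T @ Vi
    sign, logdet_v = np.linalg.slogdet(V)
    eig = np.linalg.eigvalsh(XtVX)
    logdet_x = float(np.sum(np.log(eig[eig > 1e-10 * eig.max()])))
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))
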