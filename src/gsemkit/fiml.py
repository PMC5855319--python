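"""Full-information maximum likelihood for GRM-structured AE models.

Under the model, the stacked trait matrix Y (n individuals x t traits,
mean-centered) has covariance

    cov(vec(Y)) = Sigma_g (x) A  +  Sigma_e (x) I_n,

with A the genetic relationship matrix.  Writing A = U diag(d) U^T and
rotating Y_tilde = U^T Y makes the rows of Y_tilde independent, each with
covariance Omega_i = d_i Sigma_g + Sigma_e, so

    -2 log L = sum_i [ t log 2pi + log|Omega_i| + y_i^T Omega_i^{-1} y_i ].

This is the likelihood maximized here, with Sigma_g, Sigma_e parameterized
through the factor loadings of a :class:`~gsemkit.models.ModelSpec`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as _field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .grm import GRM, EigenGRM, eigendecompose_grm
from .models import ModelSpec, cholesky_spec, implied_covariances
from .pheno import PhenotypeTable

__all__ = [
    "RotatedData",
    "FitResult",
    "rotate",
    "neg2_loglik",
    "fit",
    "fit_univariate",
    "standardize_paths",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# optimizer tolerances (configurable per call through fit(**))
DEFAULT_GTOL = 1e-5
DEFAULT_FTOL = 1e-10


@dataclass
class RotatedData:
    """Phenotypes expressed on the GRM eigenbasis, rows independent."""

    y_tilde: np.ndarray
    eigenvalues: np.ndarray
    trait_names: list[str]
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.n_samples == 0:
            self.n_samples = self.y_tilde.shape[0]


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: ModelSpec
    theta_hat: np.ndarray
    minus2LL: float
    param_cov: np.ndarray | None
    se_theta: np.ndarray
    converged: bool
    n_samples: int
    n_observations: int
    diagnostics: dict = _field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.spec.k

    def params(self) -> pd.Series:
        return pd.Series(self.theta_hat, index=self.spec.parameter_names)

    def to_dict(self) -> dict:
        impl = implied_covariances(self.spec, self.theta_hat)
        return {
            "model": {
                "structure": self.spec.structure_kind,
                "traits": list(self.spec.trait_names),
                "k": self.k,
                "parameter_names": self.spec.parameter_names,
            },
            "theta_hat": self.theta_hat.tolist(),
            "se_theta": self.se_theta.tolist(),
            "minus2LL": self.minus2LL,
            "n_samples": self.n_samples,
            "n_observations": self.n_observations,
            "converged": bool(self.converged),
            "sigma_g": impl.sigma_g.tolist(),
            "sigma_e": impl.sigma_e.tolist(),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool, list))},
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def rotate(Y: PhenotypeTable, eig: EigenGRM) -> RotatedData:
    """Project phenotypes onto the GRM eigenvectors: y_tilde = U^T Y."""
    if not np.all(np.isfinite(Y.values)):
        raise ValueError("phenotypes contain missing values; apply complete_cases "
                         "(and align) before rotation")
    if eig.sample_ids and list(Y.sample_ids) != list(eig.sample_ids):
        raise ValueError("phenotype and GRM sample ids are not aligned")
    if Y.n_samples != eig.n_samples:
        raise ValueError("phenotype rows do not match GRM order")
    y_tilde = eig.eigenvectors.T @ Y.values
    return RotatedData(y_tilde=y_tilde, eigenvalues=np.asarray(eig.eigenvalues, float),
                       trait_names=list(Y.trait_names))


def _neg2ll_sigma(sigma_g: np.ndarray, sigma_e: np.ndarray,
                  rotated: RotatedData) -> float:
    """-2 log L for explicit covariance components (+inf if any Omega_i not PD)."""
    d = rotated.eigenvalues
    y = rotated.y_tilde
    n, t = y.shape
    omega = d[:, None, None] * sigma_g + sigma_e
    try:
        L = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        return np.inf
    diag = np.diagonal(L, axis1=1, axis2=2)
    if np.any(diag <= 0):
        return np.inf
    logdet = 2.0 * np.log(diag).sum()
    # z solves L z = y row-wise; quadratic form is ||z||^2
    z = np.linalg.solve(L, y[:, :, None])[:, :, 0]
    quad = float(np.einsum("ij,ij->", z, z))
    return n * t * _LOG_2PI + logdet + quad


def neg2_loglik(spec: ModelSpec, theta: np.ndarray, rotated: RotatedData) -> float:
    """-2 log-likelihood of the rotated data at the given free parameters."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta contains non-finite values")
    if not np.all(np.isfinite(rotated.y_tilde)):
        raise ValueError("rotated data contain non-finite values")
    impl = implied_covariances(spec, theta)
    return _neg2ll_sigma(impl.sigma_g, impl.sigma_e, rotated)


# -- starting values ------------------------------------------------------

def _chol_of(S: np.ndarray) -> np.ndarray:
    """Cholesky factor of a covariance, regularized if needed."""
    S = (S + S.T) / 2.0
    jitter = 1e-8 * max(1.0, float(np.trace(S)) / S.shape[0])
    for _ in range(12):
        try:
            return np.linalg.cholesky(S + jitter * np.eye(S.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError("sample covariance could not be regularized")

def _heuristic_theta(spec: ModelSpec, S: np.ndarray, g_share: float) -> np.ndarray:
    """Structure-aware start: split the sample covariance S into a genetic
    share ``g_share`` and residual share 1 - g_share."""
    t = spec.t
    theta = np.zeros(spec.k)
    names = spec.parameter_names
    vals: dict[str, float] = {}
    if spec.is_common_pathway:
        offdiag = S - np.diag(np.diag(S))
        lam_scale = np.sqrt(np.clip(np.abs(offdiag).sum(axis=1) / max(t - 1, 1), 1e-3, None))
        for i in range(t):
            vals[f"lam{i + 1}"] = lam_scale[i]
            vals[f"as{i + 1}"] = np.sqrt(max(g_share * S[i, i] / 2.0, 1e-4))
            vals[f"es{i + 1}"] = np.sqrt(max((1 - g_share) * S[i, i] / 2.0, 1e-4))
        vals["fg"] = np.sqrt(g_share)
        vals["fe"] = np.sqrt(1.0 - g_share)
    elif spec.structure_kind == "independent_pathway":
        r1 = S[0] / np.sqrt(np.clip(S[0, 0] * np.diag(S), 1e-12, None))
        for i in range(t):
            sgn = 1.0 if r1[i] >= 0 else -1.0
            vals[f"ac{i + 1}"] = sgn * np.sqrt(g_share * S[i, i] / 2.0)
            vals[f"as{i + 1}"] = np.sqrt(g_share * S[i, i] / 2.0)
            vals[f"ec{i + 1}"] = sgn * np.sqrt((1 - g_share) * S[i, i] / 2.0)
            vals[f"es{i + 1}"] = np.sqrt((1 - g_share) * S[i, i] / 2.0)
    else:
        # triangular family (cholesky and its reduced/custom forms)
        La0 = _chol_of(g_share * S)
        Le0 = _chol_of((1.0 - g_share) * S)
        for p in spec.parameters:
            L0 = La0 if p.block == "genetic" else Le0
            j = p.factor
            if j is not None and p.trait is not None and j < t:
                vals[p.name] = L0[p.trait, j]
    for pos, name in enumerate(names):
        theta[pos] = vals.get(name, 0.1)
    return theta


def _default_starts(spec: ModelSpec, S: np.ndarray, n_starts: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    starts = [_heuristic_theta(spec, S, 0.5)]
    if n_starts >= 2:
        starts.append(_heuristic_theta(spec, S, 0.05))
    if n_starts >= 3:
        base = starts[0]
        starts.append(base + 0.25 * np.maximum(1.0, np.abs(base)) *
                      rng.standard_normal(base.shape))
    for i in range(3, n_starts):
        starts.append(starts[0] + 0.5 * rng.standard_normal(spec.k))
    return starts[:n_starts]


# -- numerical derivatives ------------------------------------------------

def _hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate scaled steps."""
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j]
                                 + fmm) / (2.0 * h[i] * h[j])
    return H


def _gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    h = rel_step * np.maximum(1.0, np.abs(x))
    g = np.empty(x.size)
    for i in range(x.size):
        e = np.zeros(x.size); e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


# -- sign convention ------------------------------------------------------

def _canonicalize_signs(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Flip whole factor columns so each leading free loading is nonnegative.

    Likelihood-invariant: Sigma = L L^T is unchanged by negating a column.
    """
    theta = theta.copy()
    infos = spec.parameters
    if spec.is_common_pathway:
        pos = {p.name: i for i, p in enumerate(infos)}
        lam_idx = [pos[p.name] for p in infos if p.name.startswith("lam")]
        if lam_idx and theta[lam_idx[0]] < 0:
            for i in lam_idx:
                theta[i] = -theta[i]
        for nm in ("fg", "fe"):
            if nm in pos:
                theta[pos[nm]] = abs(theta[pos[nm]])
        for p in infos:
            if p.name.startswith(("as", "es")):
                theta[pos[p.name]] = abs(theta[pos[p.name]])
        return theta
    for block in ("genetic", "residual"):
        cols: dict[int, list[int]] = {}
        for i, p in enumerate(infos):
            if p.block == block:
                cols.setdefault(p.factor, []).append(i)
        for idx in cols.values():
            lead = min(idx, key=lambda i: infos[i].trait)
            if theta[lead] < 0:
                for i in idx:
                    theta[i] = -theta[i]
    return theta


# -- fitting --------------------------------------------------------------

def _as_rotated(Y: PhenotypeTable, grm) -> RotatedData:
    if isinstance(grm, RotatedData):
        return grm
    eig = grm if isinstance(grm, EigenGRM) else eigendecompose_grm(grm)
    return rotate(Y, eig)


def fit(spec: ModelSpec, Y: PhenotypeTable, grm: GRM | EigenGRM | RotatedData,
        n_starts: int = 3, seed: int = 0, gtol: float = DEFAULT_GTOL,
        ftol: float = DEFAULT_FTOL, max_iter: int = 2000,
        compute_se: bool = True) -> FitResult:
    """Maximize the FIML likelihood of ``spec`` on aligned data.

    ``grm`` may be a GRM, its eigendecomposition, or already-rotated data
    (the eigendecomposition is the only O(n^3) step and can be reused across
    models).  Multi-start quasi-Newton optimization; standard errors from
    the observed information (central-difference Hessian of -2LL, with the
    factor-2 correction for the -2 scaling).
    """
    rotated = _as_rotated(Y, grm)
    n, t = rotated.y_tilde.shape
    if t != spec.t:
        raise ValueError(f"spec expects {spec.t} traits, data have {t}")
    if n < spec.k + 1:
        raise ValueError(f"need at least k+1={spec.k + 1} samples, have {n}")
    # back-rotated sample covariance equals the phenotypic covariance
    S = rotated.y_tilde.T @ rotated.y_tilde / n
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        impl = implied_covariances(spec, theta)
        return _neg2ll_sigma(impl.sigma_g, impl.sigma_e, rotated)

    best = None
    attempts = []
    for s_idx, x0 in enumerate(_default_starts(spec, S, n_starts, rng)):
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol})
        attempts.append({"start": s_idx, "fun": float(res.fun),
                         "success": bool(res.success), "nit": int(res.nit)})
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = _canonicalize_signs(spec, np.asarray(best.x, float))
    minus2LL = float(objective(theta_hat))
    grad = _gradient(objective, theta_hat)
    grad_norm = float(np.linalg.norm(grad) / max(1.0, abs(minus2LL)))
    converged = bool(np.isfinite(minus2LL)) and (best.success or grad_norm <= 1e-4)

    param_cov = None
    se = np.full(spec.k, np.nan)
    hessian_pd = False
    if compute_se and np.isfinite(minus2LL):
        H = _hessian(objective, theta_hat)
        eigvals = np.linalg.eigvalsh((H + H.T) / 2.0)
        # relative floor: a ridge direction (unidentified combination) shows up
        # as an eigenvalue many orders below the leading curvature
        if np.all(np.isfinite(H)) and eigvals.min() > 1e-7 * max(eigvals.max(), 0.0):
            hessian_pd = True
            param_cov = 2.0 * np.linalg.inv((H + H.T) / 2.0)
            se = np.sqrt(np.clip(np.diag(param_cov), 0.0, None))
        else:
            warnings.warn("observed information not positive definite; standard "
                          "errors unavailable (boundary or degenerate solution)",
                          stacklevel=2)
            param_cov = None
    return FitResult(spec=spec, theta_hat=theta_hat, minus2LL=minus2LL,
                     param_cov=param_cov, se_theta=se, converged=converged,
                     n_samples=n, n_observations=n * t,
                     diagnostics={"attempts": attempts, "grad_norm": grad_norm,
                                  "hessian_pd": hessian_pd,
                                  "best_start": int(best and attempts[
                                      int(np.argmin([a["fun"] for a in attempts]))]["start"])})


def fit_univariate(y: PhenotypeTable | np.ndarray, grm: GRM | EigenGRM,
                   trait_name: str = "trait1", **kwargs) -> FitResult:
    """Univariate AE fit: Var_g = a^2, Var_e = e^2 (SNP-h2 for unit-variance y)."""
    if isinstance(y, PhenotypeTable):
        if y.n_traits != 1:
            raise ValueError("fit_univariate expects a single trait")
        Y = y
    else:
        y = np.asarray(y, float).reshape(-1, 1)
        ids = grm.sample_ids if getattr(grm, "sample_ids", None) else \
            [("F", str(i)) for i in range(y.shape[0])]
        Y = PhenotypeTable(values=y, sample_ids=list(ids), trait_names=[trait_name])
    spec = cholesky_spec(1, [Y.trait_names[0]])
    return fit(spec, Y, grm, **kwargs)


def variance_components(result: FitResult) -> dict:
    """Var_g / Var_e (with delta-method SEs) of a univariate fit."""
    from .inference import delta_method_se

    if result.spec.t != 1:
        raise ValueError("variance_components is defined for univariate fits")
    vg, vg_se = delta_method_se(result, lambda th: float(
        implied_covariances(result.spec, th).sigma_g[0, 0]))
    ve, ve_se = delta_method_se(result, lambda th: float(
        implied_covariances(result.spec, th).sigma_e[0, 0]))
    return {"var_g": vg, "var_g_se": vg_se, "var_e": ve, "var_e_se": ve_se}


def standardize_paths(result: FitResult) -> pd.DataFrame:
    """Loadings rescaled to the model-implied total SD of each trait.

    Each loading on trait j is divided by sqrt((Sigma_g + Sigma_e)_jj), so
    squared standardized loadings across all factors sum to one per trait.
    """
    if not result.converged:
        raise ValueError("standardize_paths requires a converged fit")
    spec = result.spec
    La, Le = spec.loadings(result.theta_hat)
    total = np.diag(La @ La.T + Le @ Le.T)
    if np.any(total <= 0):
        raise ValueError("zero model-implied variance; cannot standardize")
    scale = np.sqrt(total)
    cols_a = [f"A{j + 1}" for j in range(La.shape[1])]
    cols_e = [f"E{j + 1}" for j in range(Le.shape[1])]
    out = pd.DataFrame(np.hstack([La / scale[:, None], Le / scale[:, None]]),
                       index=list(spec.trait_names), columns=cols_a + cols_e)
    return out
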