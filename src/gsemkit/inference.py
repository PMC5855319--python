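"""Post-fit inference: delta-method SEs, genetic correlations, Wald and
likelihood-ratio tests, information criteria, and data-driven stepwise
reduction of genetic factor loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fiml import FitResult, fit as _fit, standardize_paths
from .models import ModelSpec, implied_covariances

__all__ = [
    "DerivedEstimates",
    "ModelComparison",
    "ReductionStep",
    "ReductionResult",
    "delta_method_se",
    "genetic_correlations",
    "genetic_variance_share",
    "wald_test",
    "lrt",
    "aic",
    "bic",
    "compare_models",
    "reduce_model",
]


@dataclass
class DerivedEstimates:
    """Genetic/residual (co)variances and genetic correlations with SEs."""

    sigma_g: np.ndarray
    sigma_g_se: np.ndarray
    sigma_e: np.ndarray
    sigma_e_se: np.ndarray
    r_g: np.ndarray
    r_g_se: np.ndarray
    trait_names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        t = self.sigma_g.shape[0]
        names = self.trait_names or [f"P{i + 1}" for i in range(t)]
        for i in range(t):
            for j in range(i + 1):
                rows.append({
                    "pair": f"{names[j]}:{names[i]}",
                    "sigma_g": self.sigma_g[i, j], "sigma_g_se": self.sigma_g_se[i, j],
                    "sigma_e": self.sigma_e[i, j], "sigma_e_se": self.sigma_e_se[i, j],
                    "r_g": self.r_g[i, j], "r_g_se": self.r_g_se[i, j],
                })
        return pd.DataFrame(rows)


@dataclass
class ModelComparison:
    """One nested-model contrast plus per-model information criteria."""

    delta_chi2: float
    delta_df: int
    p_value: float
    minus2LL_full: float
    minus2LL_nested: float
    k_full: int
    k_nested: int
    aic_full: float
    aic_nested: float
    bic_full: float
    bic_nested: float
    n_used: int


def delta_method_se(result: FitResult, g, rel_step: float = 1e-5) -> tuple[float, float]:
    """First-order SE of a scalar function g(theta) of the fitted parameters.

    The gradient is taken by central differences with step
    rel_step * max(1, |theta_i|) per coordinate.
    """
    if result.param_cov is None:
        raise ValueError("parameter covariance unavailable (information matrix "
                         "was not positive definite)")
    theta = result.theta_hat
    h = rel_step * np.maximum(1.0, np.abs(theta))
    grad = np.empty(theta.size)
    for i in range(theta.size):
        e = np.zeros(theta.size); e[i] = h[i]
        grad[i] = (g(theta + e) - g(theta - e)) / (2.0 * h[i])
    if not np.all(np.isfinite(grad)):
        raise ValueError("non-finite gradient in delta method")
    var = float(grad @ result.param_cov @ grad)
    return float(g(theta)), float(np.sqrt(max(var, 0.0)))


def genetic_correlations(result: FitResult, min_var: float = 1e-10) -> DerivedEstimates:
    """Sigma_g, Sigma_e and r_g with element-wise delta-method SEs.

    r_g(j,k) = Sigma_g(j,k) / sqrt(Sigma_g(j,j) Sigma_g(k,k)); pairs with a
    vanishing genetic variance get a missing correlation with a warning.
    """
    spec = result.spec
    t = spec.t
    impl = implied_covariances(spec, result.theta_hat)

    def entry(which: str, i: int, j: int):
        def g(th):
            m = implied_covariances(spec, th)
            return float(getattr(m, which)[i, j])
        return g

    sg_se = np.zeros((t, t)); se_se = np.zeros((t, t))
    rg = np.eye(t); rg_se = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1):
            _, sg_se[i, j] = delta_method_se(result, entry("sigma_g", i, j))
            _, se_se[i, j] = delta_method_se(result, entry("sigma_e", i, j))
            sg_se[j, i] = sg_se[i, j]; se_se[j, i] = se_se[i, j]
    for i in range(t):
        for j in range(i):
            vi, vj = impl.sigma_g[i, i], impl.sigma_g[j, j]
            if vi <= min_var or vj <= min_var:
                warnings.warn(f"zero genetic variance for trait pair ({j}, {i}); "
                              "genetic correlation undefined", stacklevel=2)
                rg[i, j] = rg[j, i] = np.nan
                rg_se[i, j] = rg_se[j, i] = np.nan
                continue

            def g_r(th, i=i, j=j):
                m = implied_covariances(spec, th).sigma_g
                return float(m[i, j] / np.sqrt(m[i, i] * m[j, j]))

            val, se = delta_method_se(result, g_r)
            rg[i, j] = rg[j, i] = val
            rg_se[i, j] = rg_se[j, i] = se
    return DerivedEstimates(sigma_g=impl.sigma_g, sigma_g_se=sg_se,
                            sigma_e=impl.sigma_e, sigma_e_se=se_se,
                            r_g=rg, r_g_se=rg_se,
                            trait_names=list(spec.trait_names))


def genetic_variance_share(result: FitResult, trait: int,
                           factors: list[int]) -> tuple[float, float]:
    """Share of a trait's genetic variance carried by a subset of factors.

    E.g. the ratio Var_g[A1] / Var_g[A1+A2] for the last trait measures how
    much of its genetic variance traces back to the first factor.
    """
    spec = result.spec

    def g(th):
        La, _ = spec.loadings(th)
        num = float(np.sum(La[trait, factors] ** 2))
        den = float(np.sum(La[trait, :] ** 2))
        return num / den

    return delta_method_se(result, g)


def wald_test(result: FitResult, parameter_name: str,
              one_tailed: bool = False) -> tuple[float, float]:
    """z = theta_hat / SE with a normal reference; returns (z, p)."""
    names = result.spec.parameter_names
    if parameter_name not in names:
        raise KeyError(f"unknown parameter: {parameter_name}")
    i = names.index(parameter_name)
    se = result.se_theta[i]
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"standard error unavailable for {parameter_name}")
    z = float(result.theta_hat[i] / se)
    p = float(stats.norm.sf(abs(z)) * (1 if one_tailed else 2))
    return z, min(p, 1.0)


def _is_nested(full: ModelSpec, nested: ModelSpec) -> bool:
    if full.t != nested.t or full.trait_names != nested.trait_names:
        return False
    if full.k <= nested.k:
        return False
    if full.is_common_pathway != nested.is_common_pathway:
        # independent/common pathway structures are nested in the saturated
        # triangular decomposition by the covariance-structure argument
        return full.structure_kind == "cholesky"
    if full.structure_kind == nested.structure_kind or nested.structure_kind == "custom":
        same_family = set(nested.parameter_names) <= set(full.parameter_names)
        if same_family:
            return True
    return full.structure_kind == "cholesky"


def lrt(fit_full: FitResult, fit_nested: FitResult,
        mixture: bool = False) -> ModelComparison:
    """Likelihood-ratio chi-square test of a nested model against its parent.

    ``mixture=True`` uses a 50:50 chi-square mixture reference with
    delta_df and delta_df - 1 degrees of freedom, a common correction when
    the reduction places variance parameters on the boundary.
    """
    if fit_full.n_samples != fit_nested.n_samples:
        raise ValueError("LRT requires both fits on the same samples")
    if not _is_nested(fit_full.spec, fit_nested.spec):
        raise ValueError("models are not properly nested (or are identical)")
    d_chi2 = fit_nested.minus2LL - fit_full.minus2LL
    if d_chi2 < -1e-4:
        raise ValueError(f"nested model fits better by {-d_chi2:.4g}; "
                         "check optimizer convergence")
    d_chi2 = max(d_chi2, 0.0)
    d_df = fit_full.k - fit_nested.k
    if mixture:
        p_hi = stats.chi2.sf(d_chi2, d_df)
        p_lo = stats.chi2.sf(d_chi2, d_df - 1) if d_df > 1 else float(d_chi2 <= 0)
        p = 0.5 * (p_hi + p_lo)
    else:
        p = stats.chi2.sf(d_chi2, d_df)
    n = fit_full.n_samples
    return ModelComparison(
        delta_chi2=float(d_chi2), delta_df=int(d_df), p_value=float(p),
        minus2LL_full=fit_full.minus2LL, minus2LL_nested=fit_nested.minus2LL,
        k_full=fit_full.k, k_nested=fit_nested.k,
        aic_full=aic(fit_full.minus2LL, fit_full.k),
        aic_nested=aic(fit_nested.minus2LL, fit_nested.k),
        bic_full=bic(fit_full.minus2LL, fit_full.k, n),
        bic_nested=bic(fit_nested.minus2LL, fit_nested.k, n),
        n_used=n)


def aic(minus2LL: float, k: int) -> float:
    """Akaike information criterion: -2LL + 2k."""
    return float(minus2LL + 2.0 * k)


def bic(minus2LL: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2LL + k log(n), n = participants."""
    if n < 2:
        raise ValueError("BIC needs at least 2 participants")
    return float(minus2LL + k * np.log(n))


def compare_models(fits: dict[str, FitResult],
                   baseline: str | None = None) -> pd.DataFrame:
    """Model-comparison table: -2LL, k, delta-chi2/df/p vs baseline, AIC, BIC."""
    if baseline is None:
        saturated = [nm for nm, f in fits.items()
                     if f.spec.structure_kind == "cholesky"]
        baseline = saturated[0] if saturated else max(fits, key=lambda nm: fits[nm].k)
    base = fits[baseline]
    rows = []
    for name, f in fits.items():
        row = {"model": name, "minus2LL": f.minus2LL, "k": f.k,
               "AIC": aic(f.minus2LL, f.k), "BIC": bic(f.minus2LL, f.k, f.n_samples)}
        row.update({"delta_chi2": np.nan, "delta_df": 0, "p": np.nan})
        if name != baseline:
            try:
                cmp_ = lrt(base, f)
                row.update({"delta_chi2": cmp_.delta_chi2,
                            "delta_df": cmp_.delta_df, "p": cmp_.p_value})
            except ValueError:
                warnings.warn(f"model '{name}' is not nested in '{baseline}'; "
                              "no LRT reported", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


# -- stage-II stepwise reduction ------------------------------------------

@dataclass
class ReductionStep:
    dropped: str
    std_value: float
    fit: FitResult
    lrt_vs_start: ModelComparison


@dataclass
class ReductionResult:
    start: FitResult
    steps: list[ReductionStep]
    final: FitResult
    stopped_because: str


def _genetic_candidates(result: FitResult) -> list[tuple[str, float]]:
    """Free genetic loadings with their absolute standardized values."""
    spec = result.spec
    std = standardize_paths(result)
    La_std = std[[c for c in std.columns if c.startswith("A")]].to_numpy()
    out = []
    for p in spec.parameters:
        if p.block != "genetic":
            continue
        if p.trait is None:  # common-pathway latent genetic path f_g
            out.append((p.name, float(np.max(np.abs(La_std[:, 0])))))
        else:
            out.append((p.name, float(abs(La_std[p.trait, p.factor]))))
    return out


def _pick_drop(result: FitResult, cands: list[tuple[str, float]]) -> tuple[str, float]:
    """Smallest |standardized| genetic loading; ties drop the later
    trait/factor position."""
    order = {p.name: (p.factor if p.factor is not None else -1,
                      p.trait if p.trait is not None else -1)
             for p in result.spec.parameters}
    return min(cands, key=lambda c: (c[1], tuple(-x for x in order[c[0]])))


def reduce_model(fit_start: FitResult, Y, grm, alpha: float = 0.05,
                 **fit_kwargs) -> ReductionResult:
    """Successively drop the smallest standardized genetic loading.

    After each drop the reduced model is refitted and compared with the
    starting model by LRT.  The procedure stops when every remaining genetic
    loading is significant at ``alpha`` (two-sided Wald), or when a drop
    would make the cumulative LRT significant (that drop is not accepted).
    Ties on the smallest loading drop the later trait/factor position.
    """
    if not fit_start.converged:
        raise ValueError("reduction requires a converged starting fit")
    from .fiml import _as_rotated

    rotated = _as_rotated(Y, grm)
    current = fit_start
    steps: list[ReductionStep] = []
    reason = "all genetic loadings significant"
    for _ in range(len(_genetic_candidates(fit_start)) + 1):
        cands = _genetic_candidates(current)
        if not cands:
            reason = "no genetic loadings left to drop"
            break
        pvals = {}
        se_ok = True
        for name, _std in cands:
            try:
                pvals[name] = wald_test(current, name)[1]
            except ValueError:
                se_ok = False
        if se_ok and all(p < alpha for p in pvals.values()):
            reason = "all genetic loadings significant"
            break
        name, std_val = _pick_drop(current, cands)
        new_spec = current.spec.drop(name)
        new_fit = _fit(new_spec, Y, rotated, **fit_kwargs)
        comparison = lrt(fit_start, new_fit)
        if comparison.p_value < alpha:
            reason = f"dropping {name} significantly worsens fit"
            break
        steps.append(ReductionStep(dropped=name, std_value=std_val,
                                   fit=new_fit, lrt_vs_start=comparison))
        current = new_fit
    return ReductionResult(start=fit_start, steps=steps, final=current,
                           stopped_because=reason)
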