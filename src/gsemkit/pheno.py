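"""Phenotype preparation: covariate residualization, rank-based inverse
normal transformation, complete-case restriction and sample alignment.

Scores are adjusted for covariates (e.g. sex, age, ancestry principal
components) by ordinary least squares, and the residuals are mapped to
normal quantiles of their offset-adjusted ranks so that each trait is
marginally standard normal before model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "CovariateTable",
    "read_phen",
    "residualize",
    "inverse_normal_transform",
    "complete_cases",
    "align",
    "INT_OFFSETS",
]

# rank offset c in Phi^{-1}((r - c) / (n - 2c + 1))
INT_OFFSETS = {"blom": 0.375, "none": 0.0, "rankit": 0.5}


@dataclass
class PhenotypeTable:
    """n_samples x n_traits real matrix with missing entries allowed."""

    values: np.ndarray
    sample_ids: list[tuple[str, str]]
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, t = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.trait_names) != t or len(set(self.trait_names)) != t:
            raise ValueError("trait_names must be unique and match columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(trait)]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.sample_ids, names=["FID", "IID"])
        return pd.DataFrame(self.values, index=idx, columns=self.trait_names)


@dataclass
class CovariateTable:
    """n_samples x n_covariates design columns (no intercept column)."""

    values: np.ndarray
    sample_ids: list[tuple[str, str]]
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match rows")
        if len(self.covariate_names) != self.values.shape[1]:
            raise ValueError("covariate_names length does not match columns")


def read_phen(path: str | Path, trait_names: list[str] | None = None,
              header: bool = False) -> PhenotypeTable:
    """Read a whitespace/tab-delimited phenotype file (FID IID value...).

    ``NA`` encodes missing.  With ``header=True`` the first line names the
    traits; otherwise traits are labelled trait1..traitT or ``trait_names``.
    """
    df = pd.read_csv(path, sep=r"\s+", header=0 if header else None,
                     na_values=["NA", "-9"])
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected FID, IID and >=1 trait column")
    if header:
        names = list(df.columns[2:].astype(str))
    else:
        names = trait_names or [f"trait{i + 1}" for i in range(df.shape[1] - 2)]
    sample_ids = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    return PhenotypeTable(values=values, sample_ids=sample_ids, trait_names=names)


def _find_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify columns not adding rank, scanning left to right."""
    bad, kept = [], np.ones((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.hstack([kept, X[:, j:j + 1]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(names[j])
        else:
            kept = cand
    return bad


def residualize(y: np.ndarray, covariates: CovariateTable) -> np.ndarray:
    """OLS-residualize ``y`` on the covariates plus an intercept.

    Rows with missing ``y`` or any missing covariate come back missing;
    the regression is fitted on the jointly observed rows.
    """
    y = np.asarray(y, dtype=float)
    X = covariates.values
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and covariates must be row-aligned")
    obs = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_obs = int(obs.sum())
    if n_obs < X.shape[1] + 2:
        raise ValueError("too few complete rows to fit the covariate model")
    design = np.hstack([np.ones((n_obs, 1)), X[obs]])
    names = ["intercept"] + list(covariates.covariate_names)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient covariate design; collinear columns: "
            + ", ".join(_find_collinear(design, names)))
    beta, *_ = np.linalg.lstsq(design, y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    out[obs] = y[obs] - design @ beta
    return out


def inverse_normal_transform(x: np.ndarray, offset: str | float = "blom") -> np.ndarray:
    """Rank-based inverse normal transformation.

    Non-missing values are replaced by Phi^{-1}((r - c) / (n - 2c + 1)) where
    r is the (average-tie) ascending rank and c the offset constant: Blom's
    3/8 by default, 0 ("none") or 1/2 ("rankit").  Missing entries stay
    missing; rank order is preserved.
    """
    c = INT_OFFSETS[offset] if isinstance(offset, str) else float(offset)
    x = np.asarray(x, dtype=float)
    obs = np.isfinite(x)
    vals = x[obs]
    if vals.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(vals) == 0:
        raise ValueError("all values identical: rank transform undefined")
    ranks = stats.rankdata(vals, method="average")
    n = vals.size
    q = (ranks - c) / (n - 2.0 * c + 1.0)
    out = np.full_like(x, np.nan)
    out[obs] = stats.norm.ppf(q)
    return out


def complete_cases(pheno: PhenotypeTable, traits: list[str] | None = None) -> PhenotypeTable:
    """Restrict to samples non-missing on all requested traits (order kept)."""
    traits = traits or list(pheno.trait_names)
    missing = [t for t in traits if t not in pheno.trait_names]
    if missing:
        raise KeyError(f"unknown traits: {missing}")
    cols = [pheno.trait_names.index(t) for t in traits]
    keep = np.all(np.isfinite(pheno.values[:, cols]), axis=1)
    if not keep.any():
        warnings.warn("complete-case restriction removed every sample", stacklevel=2)
    return PhenotypeTable(
        values=pheno.values[keep][:, cols],
        sample_ids=[sid for sid, k in zip(pheno.sample_ids, keep) if k],
        trait_names=list(traits),
    )


def align(*objects):
    """Reorder phenotype/covariate tables and GRMs to a shared sample order.

    The output order is the sorted (FID, IID) intersection of all inputs.
    Accepts PhenotypeTable, CovariateTable and grm.GRM instances.
    """
    from .grm import GRM

    if not objects:
        raise ValueError("nothing to align")
    common = set(objects[0].sample_ids)
    for obj in objects[1:]:
        common &= set(obj.sample_ids)
    if not common:
        raise ValueError("no samples shared across inputs")
    order = sorted(common)
    out = []
    for obj in objects:
        pos = {sid: i for i, sid in enumerate(obj.sample_ids)}
        idx = np.array([pos[sid] for sid in order], dtype=int)
        if isinstance(obj, GRM):
            out.append(obj.subset(idx))
        elif isinstance(obj, PhenotypeTable):
            out.append(PhenotypeTable(values=obj.values[idx], sample_ids=list(order),
                                      trait_names=list(obj.trait_names)))
        elif isinstance(obj, CovariateTable):
            out.append(CovariateTable(values=obj.values[idx], sample_ids=list(order),
                                      covariate_names=list(obj.covariate_names)))
        else:
            raise TypeError(f"cannot align object of type {type(obj).__name__}")
    return tuple(out) if len(out) > 1 else out[0]
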