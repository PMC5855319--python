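"""Latent AE factor structures and their implied covariance matrices.

A model is a pattern of free loadings of t observed traits on latent
additive-genetic factors A_1..A_qa and residual factors E_1..E_qe, all with
unit variance.  The implied trait covariances are

    Sigma_g = La La^T,    Sigma_e = Le Le^T,

with La / Le the genetic and residual loading matrices.  Named structures:

* Cholesky — triangular La and Le, as many factors as traits (saturated,
  k = t(t+1) free parameters);
* independent pathway — one common genetic and one common residual factor
  plus trait-specific factors of each kind (k = 4t);
* common pathway — a single unit-variance latent phenotype with genetic and
  residual paths f_g, f_e and trait loadings lambda_j, plus trait-specific
  factors (k = 3t + 2 in the relaxed parameterization, i.e. without the
  f_g^2 + f_e^2 = 1 constraint, which makes the Hessian singular).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "ImpliedCovariances",
    "cholesky_spec",
    "independent_pathway_spec",
    "common_pathway_spec",
    "custom_spec",
    "drop_loading",
    "implied_covariances",
    "spec_from_config",
]


@dataclass
class ImpliedCovariances:
    sigma_g: np.ndarray
    sigma_e: np.ndarray


@dataclass(frozen=True)
class ParamInfo:
    """One free parameter: its name, block and position.

    ``block`` is "genetic" or "residual"; latent paths of the common pathway
    model count as genetic (f_g) / residual (f_e), and the latent trait
    loadings lambda_j are recorded with block "latent".
    """

    name: str
    block: str
    trait: int | None  # 0-based trait (row) index, None for f_g/f_e
    factor: int | None  # 0-based factor (column) index


def _pname(prefix: str, trait: int, factor: int, t: int) -> str:
    sep = "_" if t > 9 else ""
    return f"{prefix}{trait + 1}{sep}{factor + 1}"


@dataclass(frozen=True)
class ModelSpec:
    """Free-loading pattern of a multivariate AE model.

    ``gen_mask``/``res_mask`` flag the free entries of La / Le.  For the
    common pathway model the masks describe only the trait-specific (diagonal)
    factors; the latent part is carried by ``lam_mask`` and the two path
    flags, and La gains a leading column f_g * lambda (Le: f_e * lambda).
    """

    t: int
    structure_kind: str
    gen_mask: np.ndarray
    res_mask: np.ndarray
    trait_names: tuple[str, ...] = ()
    # common-pathway extras
    lam_mask: np.ndarray | None = None
    fg_free: bool = True
    fe_free: bool = True

    def __post_init__(self) -> None:
        if not self.trait_names:
            object.__setattr__(self, "trait_names",
                               tuple(f"P{i + 1}" for i in range(self.t)))
        if len(self.trait_names) != self.t:
            raise ValueError("trait_names length must equal t")
        for mask in (self.gen_mask, self.res_mask):
            if mask.shape[0] != self.t:
                raise ValueError("mask row count must equal t")

    # -- parameter bookkeeping -------------------------------------------

    @property
    def is_common_pathway(self) -> bool:
        return self.lam_mask is not None

    @property
    def parameters(self) -> list[ParamInfo]:
        out: list[ParamInfo] = []
        t = self.t
        if self.is_common_pathway:
            for i in range(t):
                if self.lam_mask[i]:
                    out.append(ParamInfo(f"lam{i + 1}", "latent", i, 0))
            if self.fg_free:
                out.append(ParamInfo("fg", "genetic", None, 0))
            if self.fe_free:
                out.append(ParamInfo("fe", "residual", None, 0))
            for i in range(t):
                if self.gen_mask[i, i]:
                    out.append(ParamInfo(f"as{i + 1}", "genetic", i, i + 1))
            for i in range(t):
                if self.res_mask[i, i]:
                    out.append(ParamInfo(f"es{i + 1}", "residual", i, i + 1))
            return out
        prefixes = {"independent_pathway": ("ac", "as", "ec", "es")}
        for block, mask, pref in (("genetic", self.gen_mask, "a"),
                                  ("residual", self.res_mask, "e")):
            for j in range(mask.shape[1]):
                for i in range(t):
                    if mask[i, j]:
                        if self.structure_kind == "independent_pathway":
                            c, s = prefixes["independent_pathway"][:2] if block == "genetic" \
                                else prefixes["independent_pathway"][2:]
                            name = f"{c}{i + 1}" if j == 0 else f"{s}{i + 1}"
                        else:
                            name = _pname(pref, i, j, t)
                        out.append(ParamInfo(name, block, i, j))
        return out

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def k(self) -> int:
        return len(self.parameters)

    # -- theta -> loading matrices ---------------------------------------

    def loadings(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map a free-parameter vector to (La, Le)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(f"theta must have length k={self.k}, got {theta.shape}")
        t = self.t
        vals = dict(zip(self.parameter_names, theta))
        if self.is_common_pathway:
            lam = np.array([vals.get(f"lam{i + 1}", 0.0) for i in range(t)])
            fg = vals.get("fg", 0.0)
            fe = vals.get("fe", 0.0)
            a_s = np.array([vals.get(f"as{i + 1}", 0.0) if self.gen_mask[i, i] else 0.0
                            for i in range(t)])
            e_s = np.array([vals.get(f"es{i + 1}", 0.0) if self.res_mask[i, i] else 0.0
                            for i in range(t)])
            La = np.hstack([(fg * lam)[:, None], np.diag(a_s)])
            Le = np.hstack([(fe * lam)[:, None], np.diag(e_s)])
            return La, Le
        La = np.zeros((t, self.gen_mask.shape[1]))
        Le = np.zeros((t, self.res_mask.shape[1]))
        pos = 0
        for mask, L in ((self.gen_mask, La), (self.res_mask, Le)):
            for j in range(mask.shape[1]):
                for i in range(t):
                    if mask[i, j]:
                        L[i, j] = theta[pos]
                        pos += 1
        return La, Le

    def drop(self, parameter_name: str) -> "ModelSpec":
        """Fix one free loading to zero; k decreases by one."""
        infos = {p.name: p for p in self.parameters}
        if parameter_name not in infos:
            raise KeyError(f"unknown or already-fixed parameter: {parameter_name}")
        p = infos[parameter_name]
        if self.is_common_pathway:
            if p.name == "fg":
                return replace(self, fg_free=False)
            if p.name == "fe":
                return replace(self, fe_free=False)
            if p.name.startswith("lam"):
                lam = self.lam_mask.copy()
                lam[p.trait] = False
                return replace(self, lam_mask=lam)
        mask_name = "gen_mask" if p.block == "genetic" else "res_mask"
        mask = getattr(self, mask_name).copy()
        factor = p.factor - 1 if self.is_common_pathway else p.factor
        mask[p.trait, factor] = False
        # structure_kind is kept so parameter naming stays stable under drops
        return replace(self, **{mask_name: mask})


# -- named constructors ---------------------------------------------------

def cholesky_spec(t: int, trait_names: list[str] | None = None) -> ModelSpec:
    """Saturated triangular decomposition: k = t(t+1)."""
    if t < 1:
        raise ValueError("need at least one trait")
    mask = np.tril(np.ones((t, t), dtype=bool))
    return ModelSpec(t=t, structure_kind="cholesky", gen_mask=mask,
                     res_mask=mask.copy(),
                     trait_names=tuple(trait_names or ()))


def independent_pathway_spec(t: int, trait_names: list[str] | None = None) -> ModelSpec:
    """One common genetic + one common residual factor plus specifics: k = 4t."""
    if t < 2:
        raise ValueError("independent pathway model needs at least two traits")
    mask = np.hstack([np.ones((t, 1), dtype=bool), np.eye(t, dtype=bool)])
    return ModelSpec(t=t, structure_kind="independent_pathway", gen_mask=mask,
                     res_mask=mask.copy(),
                     trait_names=tuple(trait_names or ()))


def common_pathway_spec(t: int, trait_names: list[str] | None = None) -> ModelSpec:
    """Single latent phenotype with genetic/residual paths plus specifics.

    Relaxed parameterization: the latent factor's loadings f_g, f_e are both
    free (k = 3t + 2); the scale trade-off between lambda and (f_g, f_e)
    means only the products f_g*lambda_j, f_e*lambda_j are identified.
    """
    if t < 2:
        raise ValueError("common pathway model needs at least two traits")
    diag = np.eye(t, dtype=bool)
    return ModelSpec(t=t, structure_kind="common_pathway", gen_mask=diag,
                     res_mask=diag.copy(), lam_mask=np.ones(t, dtype=bool),
                     trait_names=tuple(trait_names or ()))


def custom_spec(gen_mask: np.ndarray, res_mask: np.ndarray,
                trait_names: list[str] | None = None) -> ModelSpec:
    """Arbitrary free/zero loading pattern."""
    gen_mask = np.asarray(gen_mask, dtype=bool)
    res_mask = np.asarray(res_mask, dtype=bool)
    if gen_mask.shape[0] != res_mask.shape[0]:
        raise ValueError("masks must agree on the number of traits")
    return ModelSpec(t=gen_mask.shape[0], structure_kind="custom",
                     gen_mask=gen_mask, res_mask=res_mask,
                     trait_names=tuple(trait_names or ()))


def spec_from_config(config: dict) -> ModelSpec:
    """Build a ModelSpec from a parsed (YAML/JSON) mapping.

    Keys: ``structure`` (cholesky | independent_pathway | common_pathway |
    custom), ``traits`` (count or list of labels), and for custom structures
    ``genetic_mask`` / ``residual_mask`` as nested lists of 0/1.
    """
    kind = config.get("structure", "cholesky")
    traits = config.get("traits")
    if isinstance(traits, int):
        t, names = traits, None
    elif traits is None:
        raise ValueError("model config must set 'traits'")
    else:
        t, names = len(traits), [str(x) for x in traits]
    builders = {"cholesky": cholesky_spec, "independent_pathway": independent_pathway_spec,
                "common_pathway": common_pathway_spec}
    if kind in builders:
        spec = builders[kind](t, names)
    elif kind == "custom":
        spec = custom_spec(np.asarray(config["genetic_mask"]),
                           np.asarray(config["residual_mask"]), names)
    else:
        raise ValueError(f"unknown structure kind: {kind}")
    for name in config.get("drop", []):
        spec = spec.drop(name)
    return spec


# -- functional wrappers (module-level API) -------------------------------

def drop_loading(spec: ModelSpec, parameter_name: str) -> ModelSpec:
    return spec.drop(parameter_name)


def implied_covariances(spec: ModelSpec, theta: np.ndarray) -> ImpliedCovariances:
    """Sigma_g = La La^T and Sigma_e = Le Le^T for the given parameters."""
    La, Le = spec.loadings(theta)
    return ImpliedCovariances(sigma_g=La @ La.T, sigma_e=Le @ Le.T)
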