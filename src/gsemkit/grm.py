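"""Genetic relationship matrices: estimation, pruning, GCTA binary I/O.

The GRM entry for individuals j, k is the average over SNPs of the product
of standardized dosages,

    A_jk = (1/M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

summed over SNPs i observed in both individuals, with M_jk the number of
such SNPs (the pairwise-complete convention used by the companion
``.grm.N.bin`` file of the GCTA binary format).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("gsemkit")

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "EigenGRM",
    "read_genotypes",
    "compute_grm",
    "prune_related",
    "write_grm_gcta",
    "read_grm_gcta",
    "eigendecompose_grm",
]


class GRMFormatError(ValueError):
    """Raised when a GRM file triple is malformed or inconsistent."""


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (0/1/2, NaN for missing), samples x SNPs.

    ``allele_freq`` is the reference-allele frequency per SNP; when not
    supplied it is computed from the non-missing column mean / 2.
    """

    dosages: np.ndarray
    sample_ids: list[tuple[str, str]]
    snp_ids: list[str]
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        if self.allele_freq is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self.allele_freq = np.nanmean(self.dosages, axis=0) / 2.0
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)
            if self.allele_freq.shape != (m,):
                raise ValueError("allele_freq length does not match snp count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GRM:
    """Realized genetic relationship matrix with per-pair SNP counts."""

    values: np.ndarray
    sample_ids: list[tuple[str, str]]
    pair_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match GRM order")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("GRM must be symmetric (tol 1e-12)")
        if self.pair_counts is None:
            self.pair_counts = np.zeros((n, n), dtype=np.int64)
        else:
            self.pair_counts = np.asarray(self.pair_counts)
            if self.pair_counts.shape != (n, n):
                raise ValueError("pair_counts shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, indices: np.ndarray | list[int]) -> "GRM":
        """Return the GRM restricted to the given sample indices, in order."""
        idx = np.asarray(indices, dtype=int)
        return GRM(
            values=self.values[np.ix_(idx, idx)],
            sample_ids=[self.sample_ids[i] for i in idx],
            pair_counts=self.pair_counts[np.ix_(idx, idx)],
        )


@dataclass
class EigenGRM:
    """Spectral decomposition A = U diag(d) U^T with d nonincreasing."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    sample_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.eigenvalues.shape[0]


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``--recode A``-style dosage table.

    Delimited text with a header line; first two columns are FID and IID,
    remaining columns one SNP each with values 0/1/2/NA.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 3:
        raise GRMFormatError(f"{path}: expected FID, IID and >=1 SNP column")
    fid, iid = df.columns[:2]
    snp_ids = list(df.columns[2:])
    dosages = np.full((df.shape[0], len(snp_ids)), np.nan)
    for j, col in enumerate(snp_ids):
        raw = df[col].str.strip()
        ok = ~raw.isin(["NA", "nan", ".", ""]) & raw.notna()
        try:
            dosages[ok.to_numpy(), j] = raw[ok].astype(float).to_numpy()
        except ValueError as exc:
            bad = raw[ok][~raw[ok].str.fullmatch(r"[012](\.0)?")].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise GRMFormatError(f"{path}: bad dosage at line {line}, column {col}") from exc
    sample_ids = list(zip(df[fid].astype(str), df[iid].astype(str)))
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, snp_ids=snp_ids)


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """Estimate the GRM from standardized dosages, pairwise-complete over SNPs.

    Monomorphic SNPs (frequency 0 or 1) are excluded — the standardization
    denominator vanishes there — and the exclusion count is logged.
    """
    X = genotypes.dosages
    n = genotypes.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to form a GRM")
    all_missing = np.where(np.all(np.isnan(X), axis=1))[0]
    if all_missing.size:
        sid = genotypes.sample_ids[all_missing[0]]
        raise ValueError(f"sample {sid[0]} {sid[1]} has all-missing genotypes")

    p = np.asarray(genotypes.allele_freq, dtype=float)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_excluded = int(np.sum(~poly))
    if n_excluded:
        logger.info("compute_grm: excluded %d monomorphic SNPs", n_excluded)
    if not np.any(poly):
        raise ValueError("no informative SNPs: all SNPs are monomorphic")

    Xp = X[:, poly]
    pp = p[poly]
    denom = np.sqrt(2.0 * pp * (1.0 - pp))
    W = (Xp - 2.0 * pp) / denom
    observed = np.isfinite(W)
    W = np.where(observed, W, 0.0)
    counts = observed.astype(float) @ observed.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = (W @ W.T) / counts
    A[counts == 0] = 0.0
    A = (A + A.T) / 2.0  # exact symmetry against float reduction-order noise
    return GRM(values=A, sample_ids=list(genotypes.sample_ids),
               pair_counts=counts.round().astype(np.int64))


def prune_related(grm: GRM, threshold: float = 0.025) -> list[tuple[str, str]]:
    """Greedily drop individuals until no off-diagonal entry exceeds ``threshold``.

    At each step the individual involved in the most violating pairs is
    removed; ties are broken by dropping the later sample in input order.
    Returns the retained sample ids in original order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = grm.n_samples
    viol = grm.values > threshold
    np.fill_diagonal(viol, False)
    active = np.ones(n, dtype=bool)
    while True:
        deg = (viol & active & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max(initial=0) == 0:
            break
        # argmax of reversed order drops the later sample among ties
        worst = n - 1 - int(np.argmax(deg[::-1]))
        active[worst] = False
    retained = [grm.sample_ids[i] for i in range(n) if active[i]]
    if not retained:
        warnings.warn("relatedness pruning removed every sample", stacklevel=2)
    return retained


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    idx = np.tril_indices(n)
    return values[idx]


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA binary triple ``prefix``.grm.bin / .grm.N.bin / .grm.id.

    The binaries hold the lower triangle (diagonal included) row-major as
    little-endian float32; the id file is tab-delimited FID / IID text.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    _lower_triangle(grm.values).astype("<f4").tofile(Path(str(prefix) + ".grm.bin"))
    _lower_triangle(grm.pair_counts.astype(float)).astype("<f4").tofile(
        Path(str(prefix) + ".grm.N.bin"))
    with open(Path(str(prefix) + ".grm.id"), "w") as fh:
        for fid, iid in grm.sample_ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm_gcta(prefix: str | Path) -> GRM:
    """Read a GCTA binary GRM triple written by :func:`write_grm_gcta` or GCTA."""
    prefix = Path(prefix)
    id_path = Path(str(prefix) + ".grm.id")
    bin_path = Path(str(prefix) + ".grm.bin")
    n_path = Path(str(prefix) + ".grm.N.bin")
    for p in (id_path, bin_path, n_path):
        if not p.exists():
            raise GRMFormatError(f"missing GRM file: {p}")
    sample_ids: list[tuple[str, str]] = []
    with open(id_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                raise GRMFormatError(f"{id_path}: expected two columns per line")
            sample_ids.append((parts[0], parts[1]))
    n = len(sample_ids)
    n_entries = n * (n + 1) // 2
    tri = np.fromfile(bin_path, dtype="<f4")
    if tri.size != n_entries:
        raise GRMFormatError(
            f"{bin_path}: payload has {tri.size} float32 values, "
            f"expected {n_entries} for {n} samples in {id_path}")
    tri_n = np.fromfile(n_path, dtype="<f4")
    if tri_n.size != n_entries:
        raise GRMFormatError(
            f"{n_path}: payload has {tri_n.size} float32 values, expected {n_entries}")
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    idx = np.tril_indices(n)
    values[idx] = tri.astype(float)
    counts[idx] = tri_n.astype(float)
    values = values + np.tril(values, -1).T
    counts = counts + np.tril(counts, -1).T
    return GRM(values=values, sample_ids=sample_ids,
               pair_counts=counts.round().astype(np.int64))


def eigendecompose_grm(grm: GRM, sym_tol: float = 1e-8) -> EigenGRM:
    """Eigendecompose a GRM; eigenvalues returned nonincreasing."""
    A = grm.values
    if not np.allclose(A, A.T, atol=sym_tol, rtol=0.0):
        raise ValueError("GRM is not symmetric within tolerance")
    d, U = np.linalg.eigh((A + A.T) / 2.0)
    order = np.argsort(d)[::-1]
    return EigenGRM(eigenvalues=d[order], eigenvectors=U[:, order],
                    sample_ids=list(grm.sample_ids))
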