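"""Realizations of the genetic covariance matrix Sigma.

A single additive-trait model — phenotypic covariance between individuals
driven by shared ancestry of causal alleles — specializes, under different
observation regimes, to:

* the genotype-based genetic relatedness matrix (GRM), including the
  alpha/LDAK family of effect-size weightings (``grm``);
* the pedigree numerator-relationship matrix 2*theta (``pedigree_kinship``);
* the expected GRM computed from gene trees via shared branch lengths
  (``egrm_from_genetrees``);
* the phylogenetic variance-covariance of a Brownian trait on a species
  tree (``phylo_vcv``).

All constructors return a :class:`CovarianceMatrix`, which carries labels
and a cached, deterministically-signed eigendecomposition — the basis for
eigenvector-covariate corrections and for generalized least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .trees import Tree, shared_path_matrix

__all__ = [
    "CovarianceMatrix",
    "GenotypeMatrix",
    "EffectSizeModel",
    "Pedigree",
    "eigendecompose",
    "grm",
    "pedigree_kinship",
    "egrm_from_genetrees",
    "phylo_vcv",
]

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-9


class CovarianceMatrix:
    """Labelled symmetric PSD matrix with a cached eigendecomposition.

    Eigenvalues are sorted descending.  Eigenvectors are orthonormal
    (LAPACK returns an orthonormal basis within numerically repeated
    eigenvalues) and carry a deterministic sign: each eigenvector's
    largest-magnitude entry is made positive, ties broken by lowest index.
    Eigenvalues in ``(-1e-9 * lambda_1, 0)`` are clipped to zero; anything
    more negative raises.
    """

    def __init__(self, values, labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("covariance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix dimension")
        if not np.array_equal(values, values.T):
            raise ValueError("covariance matrix must be exactly symmetric")
        self.values = values
        self.labels = list(labels)
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def _decompose(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            lam, V = np.linalg.eigh(self.values)
            lam = lam[::-1].copy()
            V = V[:, ::-1].copy()
            top = max(lam[0], 0.0)
            floor = -_PSD_TOL * top if top > 0 else -_PSD_TOL
            if lam[-1] < floor:
                raise ValueError(
                    f"matrix is not PSD: min eigenvalue {lam[-1]:.3e} "
                    f"(tolerance {floor:.3e})"
                )
            np.clip(lam, 0.0, None, out=lam)
            # deterministic sign: largest-|entry| positive, lowest index on ties
            for j in range(V.shape[1]):
                col = V[:, j]
                k = int(np.argmax(np.abs(col)))
                if col[k] < 0:
                    V[:, j] = -col
            self._eig = (lam, V)
        return self._eig

    @property
    def eigenvalues(self) -> np.ndarray:
        return self._decompose()[0]

    @property
    def eigenvectors(self) -> np.ndarray:
        return self._decompose()[1]

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"labels not in covariance matrix: {missing}")
        return np.array([pos[lab] for lab in labels])

    def submatrix(self, labels: Sequence[str]) -> "CovarianceMatrix":
        idx = self.index_of(labels)
        return CovarianceMatrix(self.values[np.ix_(idx, idx)], list(labels))

    def scaled(self, factor: float) -> "CovarianceMatrix":
        return CovarianceMatrix(self.values * float(factor), self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CovarianceMatrix(n={self.n})"


def eigendecompose(sigma: CovarianceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and deterministically-signed orthonormal basis."""
    if not isinstance(sigma, CovarianceMatrix):
        sigma = CovarianceMatrix(np.asarray(sigma), [str(i) for i in range(len(sigma))])
    return sigma.eigenvalues, sigma.eigenvectors


# -- genotypes and the GRM -------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid dosages (individuals x loci, values 0/1/2) with labels.

    ``allele_freqs`` are sample frequencies (column mean / 2).  Loci fixed
    in the sample (p in {0, 1}) are flagged monomorphic and dropped by GRM
    construction, where their standardization is undefined.
    """

    dosages: np.ndarray
    labels: list[str]
    loci: list[str] = field(default_factory=list)
    populations: list[str] | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0/1/2")
        if len(self.labels) != self.dosages.shape[0]:
            raise ValueError("one label per individual required")
        if not self.loci:
            self.loci = [f"l{j}" for j in range(self.dosages.shape[1])]
        if len(self.loci) != self.dosages.shape[1]:
            raise ValueError("one locus id per column required")
        if self.populations is not None and len(self.populations) != len(self.labels):
            raise ValueError("one population label per individual required")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    @property
    def monomorphic(self) -> np.ndarray:
        p = self.allele_freqs
        return (p <= 0.0) | (p >= 1.0)


@dataclass
class EffectSizeModel:
    """Allele-frequency-dependent effect-size variance: the alpha model.

    ``beta2(p) = scale * (2 p (1 - p)) ** (-alpha)``.  ``alpha = 1`` is the
    canonical GWAS standardization (large effects on rare alleles, as under
    mutation-selection balance with Gaussian stabilizing selection, where
    scale = 2 * mu / V_s); ``alpha = 0`` makes effect variance independent
    of frequency (the centered-only convention used in breeding).
    """

    scale: float = 0.01
    alpha: float = 1.0
    mu: float | None = None
    V_s: float | None = None

    @classmethod
    def from_mutation_selection(cls, mu: float, V_s: float) -> "EffectSizeModel":
        return cls(scale=2.0 * mu / V_s, alpha=1.0, mu=mu, V_s=V_s)

    def variance(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("effect-size variance undefined at p in {0, 1}")
        return self.scale * (2.0 * p * (1.0 - p)) ** (-self.alpha)


def grm(
    geno: GenotypeMatrix, alpha: float = 1.0, normalize_by_L: bool = True
) -> CovarianceMatrix:
    """Genetic relatedness matrix under the alpha-model weighting.

    Entry (i, j) is ``(1/L) * sum_l G~_il G~_jl (2 p_l (1 - p_l))**(-alpha)``
    with per-locus mean-centered dosages ``G~`` and sample frequencies
    ``p_l``; monomorphic loci are dropped first.  ``alpha = 1`` gives the
    canonical GRM, ``alpha = 0`` the centered-only cross-product; the
    ``1/L`` normalization (on by default) keeps diagonals O(1), a flag
    preserves the raw sum.
    """
    keep = ~geno.monomorphic
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("grm: dropped %d monomorphic loci", n_dropped)
    if not keep.any():
        raise ValueError("all loci are monomorphic; GRM undefined")
    G = geno.dosages[:, keep].astype(float)
    p = G.mean(axis=0) / 2.0
    Gc = G - 2.0 * p
    w = (2.0 * p * (1.0 - p)) ** (-alpha)
    K = (Gc * w) @ Gc.T
    if normalize_by_L:
        K /= Gc.shape[1]
    K = (K + K.T) / 2.0  # enforce exact symmetry against rounding
    return CovarianceMatrix(K, geno.labels)


# -- pedigree kinship ------------------------------------------------------


@dataclass
class Pedigree:
    """Pedigree records ``(individual, sire, dam)``; ``None`` marks founders.

    Records are topologically sorted on construction (parents before
    offspring); a cyclic pedigree raises.
    """

    records: list[tuple[str, str | None, str | None]]
    order: list[str] = field(init=False)

    def __post_init__(self):
        parents = {}
        for ind, sire, dam in self.records:
            if ind in parents:
                raise ValueError(f"duplicate pedigree record for {ind!r}")
            parents[ind] = (sire, dam)
        for ind, (sire, dam) in parents.items():
            for par in (sire, dam):
                if par is not None and par not in parents:
                    raise ValueError(f"parent {par!r} of {ind!r} has no record")
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(ind: str, stack: tuple = ()):
            if state.get(ind) == 2:
                return
            if state.get(ind) == 1:
                raise ValueError(f"cyclic pedigree involving {ind!r}")
            state[ind] = 1
            for par in parents[ind]:
                if par is not None:
                    visit(par)
            state[ind] = 2
            order.append(ind)

        for ind in parents:
            visit(ind)
        self.order = order
        self.parents = parents


def pedigree_kinship(ped: Pedigree) -> CovarianceMatrix:
    """Numerator relationship matrix A = 2*theta from a pedigree.

    Standard tabular recursion in topological order: A_ii = 1 + A_fm / 2
    (founders and unknown parents contribute 0), and for j earlier than i,
    A_ij = (A_jf + A_jm) / 2.  Multiply by the additive genetic variance
    externally to obtain trait covariances.
    """
    order = ped.order
    idx = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        sire, dam = ped.parents[ind]
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[i, j] = A[j, i] = a
    return CovarianceMatrix(A, order)


# -- eGRM and phylogenetic vcv ---------------------------------------------


def egrm_from_genetrees(
    trees: Iterable[Tree], convention: str = "ratio-of-means"
) -> CovarianceMatrix:
    """Expected GRM from a collection of gene trees.

    With S_k the shared-path matrix of tree k and T_k its total branch
    length: ``ratio-of-means`` returns ``mean_k(S_k) / mean_k(T_k)`` (the
    ratio-of-expectations form of the coalescent expectation) and
    ``mean-of-ratios`` returns ``mean_k(S_k / T_k)`` (the per-tree Brownian
    form).  Either way the result times ``L * E(beta^2)`` is the genetic
    covariance ``Cov(A_i, A_j)`` contributed by L such loci.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one gene tree")
    if convention not in ("ratio-of-means", "mean-of-ratios"):
        raise ValueError(f"unknown convention {convention!r}")
    ref = set(trees[0].tip_labels)
    for k, tree in enumerate(trees[1:], start=2):
        tips = set(tree.tip_labels)
        if tips != ref:
            diff = sorted(tips.symmetric_difference(ref))
            raise ValueError(f"tree {k} tip set differs from tree 1: {diff}")
    labels = trees[0].tip_labels
    S = [shared_path_matrix(t).values for t in trees]
    T = [t.total_length for t in trees]
    if convention == "ratio-of-means":
        out = np.mean(S, axis=0) / np.mean(T)
    else:
        out = np.mean([s / t for s, t in zip(S, T)], axis=0)
    return CovarianceMatrix(out, labels)


def phylo_vcv(tree: Tree, rate: float = 1.0) -> CovarianceMatrix:
    """Brownian-motion trait covariance on a species tree: rate x shared paths.

    Under the additive model the diffusion rate equals L * E(beta^2) / T —
    total mutational input times mean squared effect per unit tree length.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return shared_path_matrix(tree).scaled(rate)
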