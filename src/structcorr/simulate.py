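"""Synthetic data generators: Brownian traits, coalescent genotypes,
alpha-model phenotypes.

These generators produce the null (no true effect) study conditions used by
the false-positive-rate experiments:

* Brownian-motion traits on a tree, with optional clade-level shifts — a
  single shared random displacement added to every member of a clade, the
  canonical non-Brownian confounder;
* structured-coalescent genotypes at independent loci (msprime; each locus
  is an independent infinite-sites tree sequence — independent loci stand
  in for the high-recombination regime, isolating structure from linkage);
* additive phenotypes built from genotypes with alpha-model effect sizes,
  environmental noise calibrated to a target heritability, and optional
  population-level environmental shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import msprime

from .trees import Tree
from .covariance import EffectSizeModel, GenotypeMatrix

__all__ = [
    "TraitData",
    "Demography",
    "simulate_bm",
    "add_clade_shift",
    "simulate_coalescent_genotypes",
    "simulate_trait_from_genotypes",
    "draw_test_variant",
]


@dataclass
class TraitData:
    """Per-individual phenotype decomposition y = A + E (+ shift)."""

    labels: list[str]
    y: np.ndarray
    A: np.ndarray
    E: np.ndarray
    shift: float = 0.0
    shifted: list[str] = field(default_factory=list)

    def series(self) -> pd.Series:
        return pd.Series(self.y, index=self.labels, name="y")


def simulate_bm(tree: Tree, rate: float, rng: np.random.Generator) -> pd.Series:
    """Tip values of a Brownian motion with variance ``rate`` per unit length.

    The process starts at 0 at the origin; each edge adds an independent
    N(0, rate * length) increment (the stem edge included, if present).
    Returns a Series indexed by tip label in lexicographic order, matching
    the shared-path-matrix convention.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    vals = np.zeros(tree.n_nodes)
    vals[0] = rng.normal(0.0, np.sqrt(rate * tree.root_length)) if tree.root_length else 0.0
    for node in range(1, tree.n_nodes):
        vals[node] = vals[tree.parent[node]] + rng.normal(
            0.0, np.sqrt(rate * tree.length[node])
        )
    out = pd.Series(
        {tree.labels[i]: vals[i] for i in tree.tip_ids}, name="bm"
    ).sort_index()
    return out


def add_clade_shift(
    traits: pd.Series, tips, sd: float, rng: np.random.Generator
) -> pd.Series:
    """Add one shared N(0, sd^2) draw to every listed tip's value.

    The same scalar is applied to all members (so within-clade contrasts are
    unchanged); independent draws across traits/replicates are the caller's
    responsibility via the rng.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    tips = list(tips)
    unknown = [t for t in tips if t not in traits.index]
    if unknown:
        raise KeyError(f"unknown tip labels: {unknown}")
    out = traits.copy()
    if sd > 0:
        out.loc[tips] += rng.normal(0.0, sd)
    return out


# -- coalescent genotypes --------------------------------------------------


@dataclass
class Demography:
    """A population tree (branch lengths in generations) with diploid sizes.

    ``N`` is the diploid population size on every branch (a per-population
    override dict may map tip/ancestor names to sizes).  ``samples`` gives
    the number of diploid individuals sampled per terminal population.
    """

    tree: Tree
    N: float = 10_000.0
    samples: dict[str, int] | int = 1
    N_by_branch: dict[str, float] | None = None

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("population size must be > 0")
        if isinstance(self.samples, int):
            self.samples = {lab: self.samples for lab in self.tree.tip_labels}
        if any(v < 1 for v in self.samples.values()):
            raise ValueError("sample counts must be >= 1")
        if not self.tree.is_ultrametric:
            raise ValueError("population tree must be ultrametric (time units)")

    @classmethod
    def single_population(cls, N: float, n_diploids: int) -> "Demography":
        """Panmictic special case (divergence zero): a one-tip tree."""
        tree = Tree([-1], [0.0], ["pop1"])
        return cls(tree=tree, N=N, samples={"pop1": n_diploids})

    @classmethod
    def two_populations(cls, split_time: float, N: float, n_per_pop: int) -> "Demography":
        """Two populations that diverged ``split_time`` generations ago."""
        if split_time <= 0:
            return cls.single_population(N, 2 * n_per_pop)
        tree = Tree(
            [-1, 0, 0], [0.0, split_time, split_time], [None, "pop1", "pop2"]
        )
        return cls(tree=tree, N=N, samples=n_per_pop)

    def _size(self, name: str) -> float:
        if self.N_by_branch and name in self.N_by_branch:
            return self.N_by_branch[name]
        return self.N

    def to_msprime(self) -> msprime.Demography:
        tree = self.tree
        dem = msprime.Demography()
        depth = tree.depths()
        tip_depth = depth[tree.tip_ids].max()
        names: dict[int, str] = {}
        n_anc = 0
        for node in range(tree.n_nodes):
            if tree.is_tip(node):
                names[node] = tree.labels[node]
            else:
                n_anc += 1
                names[node] = f"anc{n_anc}"
            dem.add_population(name=names[node], initial_size=self._size(names[node]))
        splits = []
        for node in range(tree.n_nodes):
            if not tree.is_tip(node):
                # msprime cannot sample from a population that splits at the
                # sampling time; floor zero-age splits (zero-length terminal
                # branches) at a negligible positive age
                t = max(tip_depth - depth[node], 1e-6)
                splits.append((t, [names[c] for c in tree.children[node]], names[node]))
        for t, derived, anc in sorted(splits, key=lambda s: s[0]):
            dem.add_population_split(time=t, derived=derived, ancestral=anc)
        dem.sort_events()
        return dem


def _ts_to_tree(ts, labels: list[str]) -> Tree:
    """Convert a one-tree tskit tree sequence into a Tree (haploid tips)."""
    t = ts.first()
    root = t.root
    order = [root] + [u for u in t.nodes(order="preorder") if u != root]
    ids = {u: i for i, u in enumerate(order)}
    parent = [-1] + [ids[t.parent(u)] for u in order[1:]]
    length = [0.0] + [t.branch_length(u) for u in order[1:]]
    out_labels: list[str | None] = [
        labels[u] if t.is_leaf(u) else None for u in order
    ]
    return Tree(parent, length, out_labels)


def simulate_coalescent_genotypes(
    dem: Demography,
    n_loci: int,
    per_locus_mutation_rate: float,
    rng: np.random.Generator,
    return_trees: bool = False,
):
    """Independent structured-coalescent loci with infinite-sites mutations.

    Each locus is an independent single-tree coalescent genealogy of the
    sampled lineages under ``dem`` (pairwise within-population coalescence
    rate 1/(2N) per generation; daughter populations merge at splits), with
    mutations dropped as a Poisson process at ``per_locus_mutation_rate``
    per generation of branch.  Every mutation creates a new biallelic
    column; haploid genomes are paired sequentially into diploids within
    populations.

    Returns a :class:`GenotypeMatrix` (and the per-locus gene trees, tips
    labelled ``<individual>.0/.1``, if ``return_trees``).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if per_locus_mutation_rate < 0:
        raise ValueError("mutation rate must be >= 0")
    msdem = dem.to_msprime()
    sample_sets = {pop: cnt for pop, cnt in sorted(dem.samples.items())}
    ind_labels: list[str] = []
    pops: list[str] = []
    for pop, cnt in sample_sets.items():
        for k in range(cnt):
            ind_labels.append(f"{pop}_{k + 1}")
            pops.append(pop)
    hap_labels = [f"{ind}.{a}" for ind in ind_labels for a in (0, 1)]
    seed_anc, seed_mut = rng.integers(1, 2**31 - 1, size=2)
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=msdem,
        ploidy=2,
        sequence_length=1,
        num_replicates=n_loci,
        random_seed=int(seed_anc),
    )
    mut_seeds = np.random.default_rng(seed_mut).integers(1, 2**31 - 1, size=n_loci)
    cols = []
    loci = []
    trees = []
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=per_locus_mutation_rate,
            random_seed=int(mut_seeds[k]),
            discrete_genome=False,
            model=msprime.BinaryMutationModel(),
        )
        if mts.num_sites:
            gm = mts.genotype_matrix()  # sites x haploids, 0/1
            gm = np.minimum(gm, 1)  # collapse any back-mutation to presence
            dose = gm[:, 0::2] + gm[:, 1::2]  # pair haploids into diploids
            cols.append(dose.T)
            loci.extend(f"l{k}_{s}" for s in range(gm.shape[0]))
        if return_trees:
            trees.append(_ts_to_tree(ts, hap_labels))
    if cols:
        dosages = np.concatenate(cols, axis=1).astype(np.int8)
    else:
        dosages = np.zeros((len(ind_labels), 0), dtype=np.int8)
    geno = GenotypeMatrix(dosages, ind_labels, loci, populations=pops)
    return (geno, trees) if return_trees else geno


# -- alpha-model phenotypes ------------------------------------------------


def simulate_trait_from_genotypes(
    geno: GenotypeMatrix,
    esm: EffectSizeModel | None = None,
    h2: float = 0.5,
    env_shift_sd: float = 0.0,
    shifted_population: str | None = None,
    rng: np.random.Generator | None = None,
) -> TraitData:
    """Additive phenotype with alpha-model effects and a target heritability.

    Per polymorphic locus, ``beta_l ~ N(0, scale * (2 p_l (1-p_l))**-alpha)``
    (defaults scale 0.01, alpha 1); the genetic value is ``A_i = sum_l
    beta_l G_il``; environmental noise is iid ``N(0, Var(A) (1-h2)/h2)`` so
    the realized heritability is approximately ``h2``.  If a shifted
    population is named, one shared ``N(0, env_shift_sd^2)`` draw is added
    to the phenotypes of its members (the environmental confounder).
    """
    if esm is None:
        esm = EffectSizeModel()
    if rng is None:
        raise ValueError("an rng is required")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    keep = ~geno.monomorphic
    if not keep.any():
        raise ValueError("no polymorphic loci; trait undefined")
    G = geno.dosages[:, keep].astype(float)
    p = G.mean(axis=0) / 2.0
    beta = rng.normal(0.0, np.sqrt(esm.variance(p)))
    A = G @ beta
    var_a = float(np.var(A))
    if var_a == 0:
        raise ValueError("genetic values have zero variance")
    sigma_e2 = var_a * (1.0 - h2) / h2
    E = rng.normal(0.0, np.sqrt(sigma_e2), size=geno.n) if sigma_e2 > 0 else np.zeros(geno.n)
    y = A + E
    shift = 0.0
    shifted: list[str] = []
    if shifted_population is not None and env_shift_sd > 0:
        if geno.populations is None:
            raise ValueError("genotypes carry no population labels")
        mask = np.array([pop == shifted_population for pop in geno.populations])
        if not mask.any():
            raise KeyError(f"unknown population {shifted_population!r}")
        shift = float(rng.normal(0.0, env_shift_sd))
        y = y + shift * mask
        shifted = [lab for lab, m in zip(geno.labels, mask) if m]
    return TraitData(labels=list(geno.labels), y=y, A=A, E=E, shift=shift, shifted=shifted)


def draw_test_variant(
    geno: GenotypeMatrix, min_freq: float, rng: np.random.Generator
) -> pd.Series:
    """Uniformly choose a locus with ``min_freq < p < 1 - min_freq`` and
    return its mean-centered dosage vector (Series indexed by individual)."""
    p = geno.allele_freqs
    ok = np.flatnonzero((p > min_freq) & (p < 1.0 - min_freq))
    if ok.size == 0:
        raise ValueError(f"no locus with allele frequency in ({min_freq}, {1 - min_freq})")
    j = int(ok[rng.integers(ok.size)])
    col = geno.dosages[:, j].astype(float)
    return pd.Series(col - col.mean(), index=geno.labels, name=geno.loci[j])
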