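"""False-positive-rate simulation studies.

Four replicate drivers measure the empirical false-positive rate (fraction
of null replicates with p < alpha) of the structure-correction strategies:

* ``run_felsenstein_phylo`` — two star clades, Brownian x and y, optional
  non-Brownian clade shifts; methods OLS / OLS+eig1 / PGLS / PGLS+eig1.
* ``run_felsenstein_gwas`` — two diverged populations, coalescent
  genotypes, alpha-model trait, optional environmental shift in one
  population; methods OLS / OLS+eig1 / LMM / LMM+eig1, Sigma = GRM.
* ``run_complex_phylo`` — a fresh pure-birth tree per replicate, J
  eigenvector covariates swept over a grid; OLS+J vs PGLS+J.
* ``run_complex_gwas`` — a fresh pure-birth population tree per replicate,
  coalescent genotypes from its tips; OLS+J vs LMM+J.

Every replicate draws its rng from ``(master seed, cell index, replicate
index)``, so grids are embarrassingly parallel yet bit-reproducible and the
result is independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import build_felsenstein_tree, simulate_pure_birth, shared_path_matrix
from .covariance import CovarianceMatrix, EffectSizeModel, grm
from .simulate import (
    Demography,
    add_clade_shift,
    draw_test_variant,
    simulate_bm,
    simulate_coalescent_genotypes,
    simulate_trait_from_genotypes,
)
from .regression import association_test

__all__ = [
    "ExperimentResult",
    "run_felsenstein_phylo",
    "run_felsenstein_gwas",
    "run_complex_phylo",
    "run_complex_gwas",
]


@dataclass
class ExperimentResult:
    """Tidy FPR table: one row per (grid value, method)."""

    table: pd.DataFrame
    grid_var: str
    alpha: float
    n_reps: int
    seed: int
    pvalues: dict = field(default_factory=dict)  # (grid value, method) -> array

    def fpr(self, grid_value, method: str) -> float:
        t = self.table
        row = t[(t["grid_value"] == grid_value) & (t["method"] == method)]
        if len(row) != 1:
            raise KeyError(f"no unique cell ({grid_value!r}, {method!r})")
        return float(row["fpr"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _parse_method(method: str) -> tuple[str, int]:
    """'pgls+eig3' -> ('gls', 3); 'lmm' -> ('lmm', 0); 'ols+eig1' -> ('ols', 1)."""
    base, _, suffix = method.partition("+")
    J = 0
    if suffix:
        if not suffix.startswith("eig"):
            raise ValueError(f"unknown method suffix in {method!r}")
        J = int(suffix[3:])
    base = {"ols": "ols", "pgls": "gls", "gls": "gls", "lmm": "lmm"}.get(base)
    if base is None:
        raise ValueError(f"unknown method {method!r}")
    return base, J


def _assemble(rows, pvals, grid_var, alpha, n_reps, seed, store_pvalues):
    table = pd.DataFrame(rows)
    table["fpr"] = table["n_sig"] / table["n_reps"]
    return ExperimentResult(
        table=table,
        grid_var=grid_var,
        alpha=alpha,
        n_reps=n_reps,
        seed=seed,
        pvalues=pvals if store_pvalues else {},
    )


def _resolve_grid(divergence_grid, shift_sd_grid, default_fixed):
    """Exactly one of the two grids varies; the other is a fixed scalar."""
    if divergence_grid is not None and shift_sd_grid is not None:
        raise ValueError("vary either the divergence grid or the shift grid, not both")
    if divergence_grid is not None:
        return "divergence", list(divergence_grid), default_fixed["shift_sd"], None
    if shift_sd_grid is not None:
        return "shift_sd", list(shift_sd_grid), None, default_fixed["divergence"]
    raise ValueError("one of divergence_grid / shift_sd_grid is required")


def run_felsenstein_phylo(
    divergence_grid=None,
    shift_sd_grid=None,
    *,
    divergence: float = 1.0,
    shift_sd: float = 0.0,
    n_per_clade: int = 100,
    tip_length: float = 0.5,
    n_reps: int = 1000,
    methods=("ols", "ols+eig1", "pgls", "pgls+eig1"),
    alpha: float = 0.05,
    seed: int = 0,
    store_pvalues: bool = False,
) -> ExperimentResult:
    """Two-clade phylogenetic null: independent rate-1 Brownian x and y.

    When a shift grid is swept, independent clade-1 shifts (one shared draw
    per trait per replicate) are applied to x and y at the fixed divergence.
    """
    grid_var, grid, fixed_shift, fixed_div = _resolve_grid(
        divergence_grid, shift_sd_grid, {"shift_sd": shift_sd, "divergence": divergence}
    )
    rows = []
    pvals: dict = {}
    for ci, gv in enumerate(grid):
        d = gv if grid_var == "divergence" else fixed_div
        s = gv if grid_var == "shift_sd" else fixed_shift
        tree = build_felsenstein_tree(n_per_clade, tip_length, d)
        sigma = shared_path_matrix(tree)
        clade1 = [lab for lab in tree.tip_labels if lab.startswith("c1_")]
        cell_p = {m: np.empty(n_reps) for m in methods}
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, ci, rep])
            x = simulate_bm(tree, 1.0, rng)
            y = simulate_bm(tree, 1.0, rng)
            if s > 0:
                x = add_clade_shift(x, clade1, s, rng)
                y = add_clade_shift(y, clade1, s, rng)
            for m in methods:
                base, J = _parse_method(m)
                fit = association_test(y, x, sigma, J=J, method=base)
                cell_p[m][rep] = fit.pvalues["x"]
        for m in methods:
            rows.append(
                {
                    "grid_var": grid_var,
                    "grid_value": gv,
                    "method": m,
                    "J": _parse_method(m)[1],
                    "n_reps": n_reps,
                    "n_sig": int((cell_p[m] < alpha).sum()),
                }
            )
            pvals[(gv, m)] = cell_p[m]
    return _assemble(rows, pvals, grid_var, alpha, n_reps, seed, store_pvalues)


def _gwas_replicate(
    rng,
    dem: Demography,
    n_loci: int,
    mu: float,
    esm: EffectSizeModel,
    h2: float,
    shift_sd_relative: float,
    shifted_population: str | None,
    test_min_freq: float = 0.1,
    grm_alpha: float = 1.0,
):
    """One GWAS null replicate: genotypes, GRM, trait, independent test variant."""
    geno = simulate_coalescent_genotypes(dem, n_loci, mu, rng)
    sigma = grm(geno, alpha=grm_alpha)
    trait = simulate_trait_from_genotypes(geno, esm, h2=h2, rng=rng)
    y = np.asarray(trait.y, dtype=float)
    if shift_sd_relative > 0 and shifted_population is not None:
        # shift scale set relative to the replicate's pre-shift phenotypic SD
        sd_abs = shift_sd_relative * float(np.std(y))
        mask = np.array([p == shifted_population for p in geno.populations])
        y = y + float(rng.normal(0.0, sd_abs)) * mask
    # the test variant comes from an independently simulated region
    for _ in range(50):
        test_geno = simulate_coalescent_genotypes(dem, 25, mu, rng)
        try:
            x = draw_test_variant(test_geno, test_min_freq, rng)
            break
        except ValueError:
            continue
    else:
        raise RuntimeError("no test variant with the required frequency found")
    return pd.Series(y, index=geno.labels), x, sigma


def run_felsenstein_gwas(
    divergence_grid=None,
    shift_sd_grid=None,
    *,
    divergence: float = 10000.0,
    shift_sd: float = 0.0,
    samples_per_pop: int = 100,
    N: float = 10_000.0,
    n_loci: int = 1000,
    per_locus_mutation_rate: float = 1e-5,
    h2: float = 0.5,
    n_reps: int = 500,
    methods=("ols", "ols+eig1", "lmm", "lmm+eig1"),
    alpha: float = 0.05,
    seed: int = 0,
    store_pvalues: bool = False,
) -> ExperimentResult:
    """Two-population GWAS null: alpha-model trait, independent test variant.

    Divergence is in generations (0 collapses to a single panmictic
    population); shift values are environmental shifts applied to
    population 1, expressed in units of the replicate's phenotypic SD.
    Sigma is the alpha=1 GRM of the causal genotypes; ``eig1`` adds its
    first eigenvector (the population axis) as a covariate.
    """
    grid_var, grid, fixed_shift, fixed_div = _resolve_grid(
        divergence_grid, shift_sd_grid, {"shift_sd": shift_sd, "divergence": divergence}
    )
    esm = EffectSizeModel()
    rows = []
    pvals: dict = {}
    for ci, gv in enumerate(grid):
        d = gv if grid_var == "divergence" else fixed_div
        s = gv if grid_var == "shift_sd" else fixed_shift
        dem = Demography.two_populations(d, N, samples_per_pop)
        cell_p = {m: np.empty(n_reps) for m in methods}
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, ci, rep])
            y, x, sigma = _gwas_replicate(
                rng, dem, n_loci, per_locus_mutation_rate, esm, h2, s, "pop1"
            )
            for m in methods:
                base, J = _parse_method(m)
                fit = association_test(y, x, sigma, J=J, method=base)
                cell_p[m][rep] = fit.pvalues["x"]
        for m in methods:
            rows.append(
                {
                    "grid_var": grid_var,
                    "grid_value": gv,
                    "method": m,
                    "J": _parse_method(m)[1],
                    "n_reps": n_reps,
                    "n_sig": int((cell_p[m] < alpha).sum()),
                }
            )
            pvals[(gv, m)] = cell_p[m]
    return _assemble(rows, pvals, grid_var, alpha, n_reps, seed, store_pvalues)


def run_complex_phylo(
    J_grid=range(0, 11),
    *,
    n_tips: int = 200,
    birth_rate: float = 1.0,
    n_reps: int = 1000,
    methods=("ols", "pgls"),
    alpha: float = 0.05,
    seed: int = 0,
    store_pvalues: bool = False,
) -> ExperimentResult:
    """Fine-structure phylogenetic null: a fresh pure-birth tree per
    replicate, J eigenvector covariates swept over a grid."""
    J_grid = list(J_grid)
    if max(J_grid) >= n_tips - 2:
        raise ValueError("max(J_grid) must be < n_tips - 2")
    counts = {(J, m): 0 for J in J_grid for m in methods}
    pvals = {(J, m): np.empty(n_reps) for J in J_grid for m in methods}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        tree = simulate_pure_birth(n_tips, birth_rate, rng)
        sigma = shared_path_matrix(tree)
        x = simulate_bm(tree, 1.0, rng)
        y = simulate_bm(tree, 1.0, rng)
        for m in methods:
            base, _ = _parse_method(m)
            for J in J_grid:
                fit = association_test(y, x, sigma, J=J, method=base)
                p = fit.pvalues["x"]
                pvals[(J, m)][rep] = p
                if p < alpha:
                    counts[(J, m)] += 1
    rows = [
        {
            "grid_var": "J",
            "grid_value": J,
            "method": m,
            "J": J,
            "n_reps": n_reps,
            "n_sig": counts[(J, m)],
        }
        for J in J_grid
        for m in methods
    ]
    return _assemble(rows, pvals, "J", alpha, n_reps, seed, store_pvalues)


def run_complex_gwas(
    J_grid=range(0, 11),
    *,
    n_pops: int = 20,
    birth_rate: float = 5.0,
    gens_scale: float = 10_000.0,
    diploids_per_pop: int = 10,
    N: float = 10_000.0,
    n_loci: int = 1000,
    per_locus_mutation_rate: float = 1e-5,
    h2: float = 0.5,
    n_reps: int = 500,
    methods=("ols", "lmm"),
    alpha: float = 0.05,
    seed: int = 0,
    store_pvalues: bool = False,
) -> ExperimentResult:
    """Fine-structure GWAS null: a fresh pure-birth population tree per
    replicate (branch lengths scaled to generations), coalescent genotypes
    from its tips, J GRM eigenvectors swept over a grid."""
    J_grid = list(J_grid)
    n_samples = n_pops * diploids_per_pop
    if max(J_grid) >= n_samples - 2:
        raise ValueError("max(J_grid) must be < n_samples - 2")
    esm = EffectSizeModel()
    counts = {(J, m): 0 for J in J_grid for m in methods}
    pvals = {(J, m): np.empty(n_reps) for J in J_grid for m in methods}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        ptree = simulate_pure_birth(n_pops, birth_rate, rng)
        scaled = type(ptree)(
            ptree.parent,
            ptree.length * gens_scale,
            ptree.labels,
            root_length=ptree.root_length * gens_scale,
        )
        dem = Demography(tree=scaled, N=N, samples=diploids_per_pop)
        y, x, sigma = _gwas_replicate(
            rng, dem, n_loci, per_locus_mutation_rate, esm, h2, 0.0, None
        )
        for m in methods:
            base, _ = _parse_method(m)
            for J in J_grid:
                fit = association_test(y, x, sigma, J=J, method=base)
                p = fit.pvalues["x"]
                pvals[(J, m)][rep] = p
                if p < alpha:
                    counts[(J, m)] += 1
    rows = [
        {
            "grid_var": "J",
            "grid_value": J,
            "method": m,
            "J": J,
            "n_reps": n_reps,
            "n_sig": counts[(J, m)],
        }
        for J in J_grid
        for m in methods
    ]
    return _assemble(rows, pvals, "J", alpha, n_reps, seed, store_pvalues)
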