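"""Pairwise coevolution screen with eigenvector-augmented PGLS.

Given a species tree and an expression matrix (species x genes, missing
entries allowed), every unordered gene pair observed jointly in enough
species is tested for correlated evolution: the tree is pruned to the
pair's joint species set, the subtree's Brownian variance-covariance is
eigendecomposed, and a PGLS regression of one gene on the other — plus the
top-J subtree eigenvectors as fixed covariates — yields a slope p-value.
Benjamini-Hochberg FDR is applied separately within each choice of J, and
summaries report how the number of discoveries and their enrichment for an
annotated (e.g., physically interacting) pair set change with J.

``generate_coevo_fixture`` builds a synthetic stand-in for a real
expression data set: truly coevolving pairs follow a correlated bivariate
Brownian motion, a fraction of genes receive a shared clade shift (the
confounder that produces spurious correlations), and entries are knocked
out at random to emulate per-gene missingness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .trees import Tree, prune_to_tips, shared_path_matrix
from .covariance import CovarianceMatrix
from .regression import fit_gls, augment_with_eigenvectors

__all__ = [
    "simulate_species_tree",
    "validate_expression",
    "count_admissible_pairs",
    "pairwise_pgls_screen",
    "bh_fdr",
    "screen_summary",
    "generate_coevo_fixture",
]


def simulate_species_tree(
    n_species: int,
    rng: np.random.Generator,
    min_clade_frac: float = 0.3,
) -> Tree:
    """Pure-birth species tree with a reasonably balanced root split.

    Trees are drawn until the smaller root clade holds at least
    ``min_clade_frac`` of the tips, and the stem is stripped (an inferred
    phylogeny carries no branch above its root).  A balanced deep split is
    the regime where a clade-shift confounder is not simply a global
    constant — the study condition the synthetic screen emulates.
    """
    from .trees import root_clades, simulate_pure_birth

    while True:
        tree = simulate_pure_birth(n_species, 1.0, rng)
        if len(root_clades(tree)[-1]) >= min_clade_frac * n_species:
            return tree.without_stem()


def validate_expression(expr: pd.DataFrame, tree: Tree, min_species: int = 2) -> None:
    """Check species labels against the tree and per-gene observation counts."""
    missing = sorted(set(expr.index) - set(tree.tip_labels))
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    obs = expr.notna().sum(axis=0)
    thin = sorted(obs.index[obs < min_species])
    if thin:
        raise ValueError(f"genes observed in fewer than {min_species} species: {thin}")


def count_admissible_pairs(expr: pd.DataFrame, min_species: int = 15) -> int:
    """Number of unordered gene pairs jointly observed in >= min_species
    species (the counting path; no model fits)."""
    obs = expr.notna().to_numpy(dtype=np.int32)
    joint = obs.T @ obs
    iu = np.triu_indices(joint.shape[0], k=1)
    return int((joint[iu] >= min_species).sum())


def pairwise_pgls_screen(
    expr: pd.DataFrame,
    tree: Tree,
    J: int,
    min_species: int = 15,
) -> pd.DataFrame:
    """Screen all admissible gene pairs with eigenvector-augmented PGLS.

    For each unordered pair, the response is the lexicographically smaller
    gene id (the bivariate Brownian model is symmetric; a regression is
    not, so the orientation is fixed).  Eigenvector loadings are computed
    on the pruned subtree of the pair's joint species set, so pairs with
    different missingness patterns use different loadings.  Returns a frame
    with columns gene1, gene2, n_species, slope, pvalue, and an attrs entry
    ``n_skipped`` counting pairs below the species threshold.
    """
    validate_expression(expr, tree)
    genes = sorted(expr.columns)
    if J >= min_species - 2:
        raise ValueError(f"J={J} too large for subtrees of {min_species} species")
    obs = expr.notna()
    cache: dict[frozenset, tuple[list, CovarianceMatrix]] = {}
    rows = []
    n_skipped = 0
    for g1, g2 in itertools.combinations(genes, 2):
        joint = obs[g1] & obs[g2]
        species = sorted(expr.index[joint])
        if len(species) < min_species:
            n_skipped += 1
            continue
        key = frozenset(species)
        if key not in cache:
            sub = prune_to_tips(tree, species)
            cache[key] = (sub.tip_labels, shared_path_matrix(sub))
        labels, sigma = cache[key]
        y = expr.loc[labels, g1].to_numpy(dtype=float)
        x = expr.loc[labels, g2].to_numpy(dtype=float)
        X = pd.DataFrame({"intercept": np.ones(len(labels)), "x": x})
        if J > 0:
            X = augment_with_eigenvectors(X, sigma, J)
        fit = fit_gls(y, X, sigma, sigma_g2=1.0, sigma_e2=0.0)
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "n_species": len(labels),
                "slope": fit.params["x"],
                "pvalue": fit.pvalues["x"],
            }
        )
    out = pd.DataFrame(rows, columns=["gene1", "gene2", "n_species", "slope", "pvalue"])
    out.attrs["n_skipped"] = n_skipped
    out.attrs["J"] = J
    return out


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def screen_summary(
    results_by_J: dict[int, pd.DataFrame],
    interacting: set | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-J discovery counts, proportion vs the J=0 baseline, and
    enrichment of an annotated pair set among discoveries.

    FDR is controlled at ``q`` separately within each J.  With ``f(J)`` the
    fraction of discoveries that are annotated, enrichment is
    ``e(J) = f(J) / f(0)``; ratios are NaN where the baseline is empty.
    """
    if 0 not in results_by_J:
        raise ValueError("the J=0 baseline must be included")
    interacting = {frozenset(p) for p in interacting} if interacting else set()
    rows = []
    for J in sorted(results_by_J):
        res = results_by_J[J]
        rej = bh_fdr(res["pvalue"].to_numpy(), q=q)
        n_sig = int(rej.sum())
        if interacting:
            hits = sum(
                1
                for flag, g1, g2 in zip(rej, res["gene1"], res["gene2"])
                if flag and frozenset((g1, g2)) in interacting
            )
            frac = hits / n_sig if n_sig else np.nan
        else:
            hits, frac = 0, np.nan
        rows.append(
            {
                "J": J,
                "n_tested": len(res),
                "n_sig": n_sig,
                "n_interacting_sig": hits,
                "interacting_fraction": frac,
            }
        )
    out = pd.DataFrame(rows).set_index("J")
    base = out.loc[0]
    out["proportion_vs_J0"] = np.where(
        base["n_sig"] > 0, out["n_sig"] / base["n_sig"], np.nan
    )
    out["enrichment"] = out["interacting_fraction"] / base["interacting_fraction"]
    return out.reset_index()


def generate_coevo_fixture(
    tree: Tree,
    n_genes: int,
    frac_true_pairs: float,
    true_corr: float,
    confounder_clade,
    confounder_sd: float,
    frac_confounded: float,
    missing_rate: float,
    rng: np.random.Generator,
    min_species: int = 15,
    rate: float = 1.0,
) -> tuple[pd.DataFrame, set]:
    """Synthetic expression matrix with known coevolving pairs (synthetic
    stand-in for a real cross-species expression data set).

    ``frac_true_pairs`` is the fraction of genes assigned to a truly
    coevolving pair (pairs are disjoint): each true pair evolves as a
    bivariate Brownian motion with correlation ``true_corr``; all other
    genes are independent Brownian motions.  A fraction
    ``frac_confounded`` of all genes additionally receives one shared
    N(0, confounder_sd^2) shift on ``confounder_clade`` (independent draws
    per gene) — the non-Brownian confounder that creates spurious
    correlations.  Entries are then dropped at ``missing_rate`` per cell,
    never leaving a gene with fewer than ``min_species`` observations.

    Returns the expression frame (species x genes) and the set of true
    pairs as frozensets of gene ids.
    """
    from .simulate import simulate_bm, add_clade_shift

    if not (0 <= true_corr <= 1):
        raise ValueError("true_corr must be in [0, 1]")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    species = tree.tip_labels
    S = len(species)
    if S < min_species:
        raise ValueError(
            f"tree has {S} tips but every gene must keep >= {min_species} observations"
        )
    confounder_clade = list(confounder_clade)
    unknown = sorted(set(confounder_clade) - set(species))
    if unknown:
        raise ValueError(f"confounder clade tips not in tree: {unknown}")
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    n_true = int(frac_true_pairs * n_genes / 2)
    true_pairs = {
        frozenset((genes[2 * k], genes[2 * k + 1])) for k in range(n_true)
    }
    data = {}
    rho = true_corr
    for k in range(n_true):
        z1 = simulate_bm(tree, rate, rng)
        z2 = simulate_bm(tree, rate, rng)
        data[genes[2 * k]] = z1
        data[genes[2 * k + 1]] = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    for g in genes[2 * n_true:]:
        data[g] = simulate_bm(tree, rate, rng)
    expr = pd.DataFrame(data).loc[species]
    n_conf = int(round(frac_confounded * n_genes))
    conf_genes = rng.choice(genes, size=n_conf, replace=False) if n_conf else []
    for g in conf_genes:
        expr[g] = add_clade_shift(expr[g], confounder_clade, confounder_sd, rng)
    if missing_rate > 0:
        for g in genes:
            k = int(rng.binomial(S, missing_rate))
            k = min(k, S - min_species)
            if k > 0:
                drop = rng.choice(S, size=k, replace=False)
                expr.iloc[drop, expr.columns.get_loc(g)] = np.nan
    return expr, true_pairs
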