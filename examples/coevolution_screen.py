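"""Eigenvector-augmented PGLS screen for coevolving gene expression.

A synthetic expression matrix over a 20-species tree contains a handful of
truly coevolving gene pairs (correlated bivariate Brownian motion) plus a
clade-level shift applied to half the genes — a non-Brownian confounder
that makes unrelated genes look correlated.  Screening all pairs with PGLS
and adding the subtree's leading eigenvectors as covariates shrinks the
discovery list while concentrating it on the truly coevolving pairs.
"""

import numpy as np

from structcorr import generate_coevo_fixture, pairwise_pgls_screen, screen_summary
from structcorr.coevolution import simulate_species_tree
from structcorr.trees import root_clades

rng = np.random.default_rng(5)
tree = simulate_species_tree(20, rng)
expr, true_pairs = generate_coevo_fixture(
    tree,
    n_genes=60,
    frac_true_pairs=0.3,
    true_corr=0.9,
    confounder_clade=root_clades(tree)[0],
    confounder_sd=5.0,
    frac_confounded=0.5,
    missing_rate=0.1,
    rng=rng,
)
results = {J: pairwise_pgls_screen(expr, tree, J=J, min_species=15) for J in range(4)}
summ = screen_summary(results, true_pairs)
print(summ[["J", "n_tested", "n_sig", "n_interacting_sig",
            "proportion_vs_J0", "enrichment"]].round(3).to_string(index=False))
print(
    "\nAs eigenvectors are added the significant-pair count drops "
    "(proportion_vs_J0 < 1) while the share of discoveries that are truly "
    "coevolving rises (enrichment > 1): fewer, better hits."
)
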