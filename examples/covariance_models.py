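"""One covariance, four constructions.

The genetic covariance among individuals can be realized from genotypes
(GRM), from a pedigree (numerator relationship matrix), from gene trees
(expected GRM), or from a species tree (Brownian variance-covariance).
This script builds each from a matching small input and shows the
single-tree identity: the eGRM of one gene tree is the tree's vcv divided
by its total branch length.
"""

import numpy as np

from structcorr import (
    GenotypeMatrix,
    Pedigree,
    egrm_from_genetrees,
    grm,
    parse_newick,
    pedigree_kinship,
    phylo_vcv,
)

rng = np.random.default_rng(3)

geno = GenotypeMatrix(
    rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(4, 40)).astype(np.int8),
    ["i1", "i2", "i3", "i4"],
)
print("GRM (alpha = 1):\n", grm(geno).values.round(2))

ped = Pedigree([("f", None, None), ("m", None, None), ("kid", "f", "m")])
print("\nPedigree 2*theta:\n", pedigree_kinship(ped).values)

tree = parse_newick("((A:1,B:1):1,C:2);")
vcv = phylo_vcv(tree, rate=1.0)
egrm = egrm_from_genetrees([tree])
print("\nBrownian vcv:\n", vcv.values)
print("\neGRM of the same (single) gene tree x total length:\n",
      (egrm.values * tree.total_length))
print(
    "\nThe last two matrices coincide: with one tree, averaging mutations "
    "over branches reproduces the Brownian covariance up to the rate scale."
)
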