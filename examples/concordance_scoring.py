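"""Bipartition concordance between gene trees and a species tree.

Each internal edge of an unrooted tree splits the taxa in two; the fraction
of a gene tree's splits that also occur in the species tree measures their
topological agreement (1.0 = identical unrooted topology).
"""

import geneshop as gs

species = gs.parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);")
genes = {
    "identical": "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);",
    "one_conflict": "(((A:1,C:1):1,(B:1,D:1):1):1,(E:1,F:1):2);",
    "missing_taxon": "(((A:1,B:1):1,C:1):1,(E:1,F:1):2);",
}

for name, newick in genes.items():
    res = gs.concordance_proportion(gs.parse_newick(newick), species)
    print(
        f"{name}: concordance={res.concordance:.3f} "
        f"({res.shared_count}/{res.gene_biparts} splits shared, "
        f"{len(res.shared_taxa)} shared taxa)"
    )

print()
print("Both trees are restricted to their shared taxa before comparison, so")
print("genes with patchy taxon sampling still get a well-defined score.")
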