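"""Market-class structure from a dosage-blind genotype panel.

Simulates a panel of clones in four market-class groups genotyped at 82
biallelic markers (tetraploid heterozygotes collapsed to AB), estimates
per-group allele frequencies, computes the Rogers distance matrix, and
builds a UPGMA tree.
"""

import spudsnp as s
from spudsnp.popgen import (
    distance_matrix,
    group_allele_frequencies,
    upgma,
    write_newick,
)

matrix, group_map, truth = s.generate_panel(
    groups=[("chip_processing", 60), ("frenchfry_processing", 60),
            ("round_white", 60), ("russet", 60)],
    n_markers=82,
    divergence=0.25,
    missing_rate=0.02,
    seed=5,
)
print(f"panel: {len(matrix.clones)} clones x {len(matrix.markers)} markers")

freqs = group_allele_frequencies(matrix, group_map)
mat = distance_matrix(freqs)
print("\nRogers distance matrix (mean |p - q| over markers):")
print(mat.round(3).to_string())

tree = upgma(mat)
print("\nUPGMA tree (ultrametric; branch lengths in distance units):")
print(write_newick(tree))
# Groups generated with evenly spread allele frequencies join in order of
# their frequency offsets; the two extreme groups sit deepest in the tree.
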