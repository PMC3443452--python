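"""Inspect PIN edge evidence on the deterministic toy fixture.

The toy instance (6 pathways, 20 genes, 12 PPIs) is small enough to apply the
edge rules by hand: an edge survives only if a shared gene is differentially
expressed (t-test p < 0.05) or a cross-pathway protein pair is co-expressed
(|Pearson r| > 0.8). See docs/toy_fixture.md for the full derivation.
"""

import pathpin as pp

toy = pp.make_toy_fixture()
expr = pp.standardize(toy.expression)
mapped = pp.map_genes_to_pathways(expr, toy.gene_sets)
pin = pp.build_pin(mapped, toy.ppi, expr, toy.labels)

for (a, b), ev in sorted(pin.edges.items()):
    reasons = []
    if ev.shared_de_genes:
        reasons.append(f"shared DE gene(s) {sorted(ev.shared_de_genes)}")
    if ev.coexpressed_ppi_pairs:
        reasons.append(f"co-expressed PPI {sorted(ev.coexpressed_ppi_pairs)}")
    print(f"{a} -- {b}: kept because {' and '.join(reasons)}")
print(f"total: {len(pin.edges)} edges among {len(pin.nodes)} pathways")
# Expected: P1--P2 (shared gene g04 is DE) and P2--P3 (PPI g05-g07 has r = 1).
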