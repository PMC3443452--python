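# Toy fixture: hand-traceable instance

`pathpin.make_toy_fixture()` returns a deterministic 6-pathway / 20-gene /
12-PPI dataset with 6 disease (S01–S06) and 6 control (S07–S12) samples whose
values are embedded in `pathpin/simulate.py`. Every PIN rule can be applied by
hand, which makes the fixture the exactness oracle for network construction
and the greedy search.

## Design

Genes g01–g04 are shifted by ≈ +5 in disease with small jitter, so each is
strongly differentially expressed (two-sample t-test p ≪ 0.001). All other
genes have identical disease and control halves (t = 0, p = 1) or symmetric
patterns with equal class means. Genes g17–g20 are measured but belong to no
pathway.

Pathways: P1 = {g01..g04}, P2 = {g04, g05, g06}, P3 = {g06, g07, g08},
P4 = {g09, g10, g11}, P5 = {g11, g12, g13}, P6 = {g14, g15, g16}.

## Candidate edges and their fate (α = 0.05, ρ_min = 0.8)

| pair | candidate via | support | kept? |
| --- | --- | --- | --- |
| P1–P2 | shared gene g04; PPI g01–g05 | g04 is DE | **yes** |
| P2–P3 | shared gene g06; PPI g05–g07 | g06 not DE, but g05 ≡ g07 so r = 1 > 0.8 | **yes** |
| P3–P4 | PPI g07–g09 | r(g07, g09) = 4/√(21·8) ≈ 0.31 | no |
| P4–P5 | shared gene g11; PPI g11–g12 | g11 not DE; r(g11, g12) ≈ −0.08 | no |
| P2–P6, P3–P6 | PPI g06–g14 (g06 ∈ P2 ∩ P3) | r(g06, g14) = 12/√280 ≈ 0.72 | no |

The remaining PPIs are within-pathway (g01–g02, g02–g03, g09–g10, g14–g15)
or touch unmapped genes (g03–g17, g17–g18, g19–g20) and create no pathway
pair. Expected PIN edge set: **{P1–P2, P2–P3}**.

## Greedy trace

P1's activity (PC1 of four strongly shifted genes) separates the classes with
a wide margin, so its cross-validated AUC is exactly 1.0 and step 1 selects
P1 (P2, whose member g04 also separates, ties at best and loses the
lexicographic tie-break). The only PIN neighbor, P2, cannot improve on AUC
1.0, so the search stops: final set **{P1}**, final CV-AUC 1.0.

These expectations are exported as `TOY_EXPECTED_PIN_EDGES`,
`TOY_EXPECTED_FIRST_PATHWAY` and `TOY_EXPECTED_FINAL_SET` and asserted by the
test suite; regeneration of the fixture files is byte-identical.
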