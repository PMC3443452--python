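"""Synthetic case/control expression data with planted dysregulated pathways.

A latent-factor model drives within-pathway correlation: every pathway p has a
per-sample factor f_p ~ Normal(0, 1), shifted by ``delta`` in disease samples
when p is planted as dysregulated. A member gene's expression is
sqrt(rho) * factor + sqrt(1-rho) * noise, so each gene has unit marginal
variance and any two genes of the same pathway correlate at rho. Genes shared
between pathways average their pathways' factors (rescaled back to unit
variance), which both creates gene-sharing edges between neighboring pathways
and mirrors how crosstalk genes respond to several processes at once. A PPI
graph is drawn denser within pathways than between them.

Defaults reflect a mid-sized two-class microarray study: 50 samples per class,
30 pathways of 8-12 genes with 25% chained overlap, within-pathway correlation
0.6, and two adjacent planted pathways shifted by 1.5 standard deviations of
their latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CONTROL,
    DISEASE,
    ExpressionMatrix,
    GeneSetCollection,
    InputError,
    PPIGraph,
    SampleLabels,
)


@dataclass
class SimulationDesign:
    n_genes: int = 400
    n_samples_per_class: int = 50
    n_pathways: int = 30
    genes_per_pathway: tuple[int, int] = (8, 12)
    overlap_fraction: float = 0.25
    rho: float = 0.6  # within-pathway gene correlation
    planted_pathways: tuple[str, ...] = ("PW02", "PW03")
    delta: float = 1.5  # latent-factor mean shift in disease, in factor SDs
    ppi_within_density: float = 0.3
    ppi_between_density: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise InputError("overlap_fraction must be in [0, 1)")
        if not (0 <= self.rho < 1):
            raise InputError("rho must be in [0, 1)")
        for d in (self.ppi_within_density, self.ppi_between_density):
            if not (0 <= d <= 1):
                raise InputError("PPI densities must be in [0, 1]")
        lo, hi = self.genes_per_pathway
        if lo < 1 or hi < lo:
            raise InputError("genes_per_pathway must be a (low, high) range with low >= 1")


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    labels: SampleLabels
    gene_sets: GeneSetCollection
    ppi: PPIGraph
    truth: list[str] = field(default_factory=list)


def _pathway_name(k: int, n: int) -> str:
    width = max(2, len(str(n)))
    return f"PW{k + 1:0{width}d}"


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Draw one dataset bundle, bit-reproducible from ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    names = [_pathway_name(k, design.n_pathways) for k in range(design.n_pathways)]
    bad = [p for p in design.planted_pathways if p not in names]
    if bad:
        raise InputError(f"planted pathways not generated: {bad}")

    lo, hi = design.genes_per_pathway
    sizes = rng.integers(lo, hi + 1, size=design.n_pathways)

    # chained membership: each pathway reuses a fraction of the previous one's
    # genes, producing the overlapping gene-set structure of curated collections
    gene_width = max(4, len(str(design.n_genes)))
    all_genes = [f"G{i + 1:0{gene_width}d}" for i in range(design.n_genes)]
    next_new = 0
    membership: dict[str, list[int]] = {}  # gene -> pathway indices
    pathway_genes: list[list[str]] = []
    for k in range(design.n_pathways):
        size = int(sizes[k])
        genes: list[str] = []
        if k > 0:
            n_ov = min(int(round(design.overlap_fraction * size)), size - 1, len(pathway_genes[-1]))
            if n_ov > 0:
                genes.extend(rng.choice(pathway_genes[-1], size=n_ov, replace=False).tolist())
        n_new = size - len(genes)
        if next_new + n_new > design.n_genes:
            raise InputError("n_genes too small for the requested pathway layout")
        genes.extend(all_genes[next_new : next_new + n_new])
        next_new += n_new
        pathway_genes.append(genes)
        for g in genes:
            membership.setdefault(g, []).append(k)

    n_per = design.n_samples_per_class
    sample_ids = [f"D{i + 1:03d}" for i in range(n_per)] + [f"C{i + 1:03d}" for i in range(n_per)]
    labels = SampleLabels(
        assignments={
            **{s: DISEASE for s in sample_ids[:n_per]},
            **{s: CONTROL for s in sample_ids[n_per:]},
        }
    )

    factors = rng.standard_normal((design.n_pathways, 2 * n_per))
    planted_idx = [names.index(p) for p in design.planted_pathways]
    for k in planted_idx:
        factors[k, :n_per] += design.delta

    noise = rng.standard_normal((design.n_genes, 2 * n_per))
    x = noise.copy()
    sq_rho, sq_noise = np.sqrt(design.rho), np.sqrt(1 - design.rho)
    for i, g in enumerate(all_genes):
        ks = membership.get(g)
        if ks:
            f = factors[ks].sum(axis=0) / np.sqrt(len(ks))
            x[i] = sq_rho * f + sq_noise * noise[i]
    expr = ExpressionMatrix(
        values=pd.DataFrame(x, index=all_genes, columns=sample_ids), standardized=False
    )

    sets = GeneSetCollection(
        sets={
            name: (f"simulated pathway {name}", frozenset(genes))
            for name, genes in zip(names, pathway_genes)
        }
    )

    ppi = _draw_ppi(rng, membership, design)

    return SimulatedDataset(
        expression=expr,
        labels=labels,
        gene_sets=sets,
        ppi=ppi,
        truth=list(design.planted_pathways),
    )


def _draw_ppi(
    rng: np.random.Generator,
    membership: dict[str, list[int]],
    design: SimulationDesign,
) -> PPIGraph:
    """Bernoulli edges among pathway-member genes, denser within pathways."""
    members = sorted(membership)
    pw_of = {g: set(ks) for g, ks in membership.items()}
    pairs: list[tuple[str, str]] = []
    probs: list[float] = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            within = bool(pw_of[a] & pw_of[b])
            pairs.append((a, b))
            probs.append(design.ppi_within_density if within else design.ppi_between_density)
    draws = rng.random(len(pairs))
    edges = [pair for pair, u, p in zip(pairs, draws, probs) if u < p]
    return PPIGraph.from_pairs(edges)


# ---------------------------------------------------------------------------
# deterministic toy fixture
#
# 6 pathways over 20 genes and 12 PPIs with values chosen so every PIN rule
# can be applied by hand (see docs/toy_fixture.md):
#   P1-P2 share g04 (strongly shifted, DE)           -> edge kept
#   P2-P3 share g06 (balanced, not DE); PPI g05-g07
#     with identical rows (r = 1 > 0.8)              -> edge kept
#   P3-P4 linked only by PPI g07-g09 (r ~ 0.31)      -> removed
#   P4-P5 share g11 (not DE); PPI g11-g12 (|r| small) -> removed
#   P2-P6 and P3-P6 linked only by PPI g06-g14
#     (r ~ 0.72, below the 0.8 cutoff)               -> removed
# Greedy selection: P1's activity separates the classes perfectly (AUC 1),
# its only PIN neighbor P2 cannot improve on that, so the trace is {P1}.

TOY_EXPECTED_PIN_EDGES = frozenset({("P1", "P2"), ("P2", "P3")})
TOY_EXPECTED_FIRST_PATHWAY = "P1"
TOY_EXPECTED_FINAL_SET = ["P1"]

_TOY_VALUES: dict[str, list[float]] = {
    # g01-g04: shifted ~+5 in disease -> strongly differentially expressed
    "g01": [5.1, 4.9, 5.2, 4.8, 5.0, 5.05, 0.1, -0.1, 0.2, -0.2, 0.0, 0.05],
    "g02": [4.8, 5.2, 4.9, 5.1, 5.0, 4.95, -0.1, 0.1, -0.2, 0.2, 0.0, -0.05],
    "g03": [5.3, 4.7, 5.1, 4.9, 5.2, 4.85, 0.3, -0.3, 0.1, -0.1, 0.2, -0.15],
    "g04": [5.0, 5.1, 4.9, 5.2, 4.8, 5.0, 0.0, 0.1, -0.1, 0.2, -0.2, 0.0],
    # class-balanced genes (identical disease and control halves -> t = 0)
    "g05": [1, -1, 2, -2, 0.5, -0.5, 1, -1, 2, -2, 0.5, -0.5],
    "g06": [0.5, 1.5, -0.5, -1.5, 1.0, -1.0, 0.5, 1.5, -0.5, -1.5, 1.0, -1.0],
    "g07": [1, -1, 2, -2, 0.5, -0.5, 1, -1, 2, -2, 0.5, -0.5],  # == g05, r = 1
    "g08": [2, 0, -2, 1, -1, 0, 2, 0, -2, 1, -1, 0],
    "g09": [0, 1, 0, -1, 1, -1, 0, 1, 0, -1, 1, -1],
    "g10": [1, 1, -1, -1, 0, 0, 1, 1, -1, -1, 0, 0],
    "g11": [0.2, -0.2, 0.4, -0.4, 0.1, -0.1, 0.3, -0.3, 0.1, -0.1, 0.2, -0.2],
    "g12": [1, 0, -1, 1, 0, -1, 1, 0, -1, 1, 0, -1],
    "g13": [-1, 1, 0, 0, 1, -1, -1, 1, 0, 0, 1, -1],
    "g14": [0, 2, -2, 0, 1, -1, 0, 2, -2, 0, 1, -1],
    "g15": [1, -2, 1, 0, -1, 1, 1, -2, 1, 0, -1, 1],
    "g16": [0.5, 0.5, -0.5, -0.5, 1, -1, 0.5, 0.5, -0.5, -0.5, 1, -1],
    # g17-g20: measured but in no pathway
    "g17": [1, 2, 3, 2, 1, 0, 1, 2, 3, 2, 1, 0],
    "g18": [0, 1, -1, 2, -2, 1, 0, 1, -1, 2, -2, 1],
    "g19": [3, 1, 2, 0, 1, 2, 3, 1, 2, 0, 1, 2],
    "g20": [-1, -2, 0, 1, 2, 0, -1, -2, 0, 1, 2, 0],
}

_TOY_SETS: dict[str, list[str]] = {
    "P1": ["g01", "g02", "g03", "g04"],
    "P2": ["g04", "g05", "g06"],
    "P3": ["g06", "g07", "g08"],
    "P4": ["g09", "g10", "g11"],
    "P5": ["g11", "g12", "g13"],
    "P6": ["g14", "g15", "g16"],
}

_TOY_PPI: list[tuple[str, str]] = [
    ("g01", "g05"),  # cross P1-P2, weakly correlated
    ("g05", "g07"),  # cross P2-P3, identical rows (r = 1)
    ("g07", "g09"),  # cross P3-P4, r ~ 0.31
    ("g06", "g14"),  # cross P2/P3-P6, r ~ 0.72
    ("g11", "g12"),  # cross P4-P5, |r| ~ 0.08
    ("g01", "g02"),  # within P1
    ("g02", "g03"),  # within P1
    ("g09", "g10"),  # within P4
    ("g14", "g15"),  # within P6
    ("g03", "g17"),  # to an unmapped gene
    ("g17", "g18"),  # among unmapped genes
    ("g19", "g20"),  # among unmapped genes
]


def make_toy_fixture() -> SimulatedDataset:
    """Deterministic 6-pathway / 20-gene / 12-PPI instance (values in code)."""
    sample_ids = [f"S{i + 1:02d}" for i in range(12)]
    values = pd.DataFrame(
        {s: [vals[j] for vals in _TOY_VALUES.values()] for j, s in enumerate(sample_ids)},
        index=list(_TOY_VALUES),
        dtype=float,
    )
    labels = SampleLabels(
        assignments={
            **{s: DISEASE for s in sample_ids[:6]},
            **{s: CONTROL for s in sample_ids[6:]},
        }
    )
    sets = GeneSetCollection(
        sets={name: (f"toy pathway {name}", frozenset(genes)) for name, genes in _TOY_SETS.items()}
    )
    return SimulatedDataset(
        expression=ExpressionMatrix(values=values, standardized=False),
        labels=labels,
        gene_sets=sets,
        ppi=PPIGraph.from_pairs(_TOY_PPI),
        truth=["P1"],
    )
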