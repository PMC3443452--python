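"""Condition-specific pathway interaction network (PIN) construction.

Candidate edges between pathway pairs come from two sources: sharing at least
one gene, or a protein-protein interaction whose endpoints lie one in each
pathway. A candidate edge is retained only with dataset-specific support:
at least one shared gene differentially expressed between disease and control
(two-sample t-test, p < alpha), or at least one cross-pathway PPI pair whose
expression is strongly co-expressed (|Pearson r| > rho_min). Otherwise the
edge is removed, making the network specific to the condition under study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .io import (
    DISEASE,
    ExpressionMatrix,
    GeneSetCollection,
    InputError,
    PPIGraph,
    SampleLabels,
)

logger = logging.getLogger(__name__)


@dataclass
class EdgeEvidence:
    """Why a pathway pair is (or is not) connected in the PIN."""

    shared_genes: frozenset[str] = field(default_factory=frozenset)
    shared_de_genes: frozenset[str] = field(default_factory=frozenset)
    ppi_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    coexpressed_ppi_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def retained(self) -> bool:
        return bool(self.shared_de_genes) or bool(self.coexpressed_ppi_pairs)


@dataclass
class PathwayNetwork:
    """Undirected network over pathways with per-edge evidence."""

    nodes: list[str]
    edges: dict[tuple[str, str], EdgeEvidence]
    params: dict[str, float]

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def neighbors(self, pathway: str) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            if a == pathway:
                out.add(b)
            elif b == pathway:
                out.add(a)
        return out

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), ev in self.edges.items():
            g.add_edge(
                a,
                b,
                n_shared=len(ev.shared_genes),
                n_shared_de=len(ev.shared_de_genes),
                n_ppi=len(ev.ppi_pairs),
                n_coexp_ppi=len(ev.coexpressed_ppi_pairs),
            )
        return g

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\tpp\t{b}\n")

    def write_evidence(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pathwayA\tpathwayB\tn_shared\tn_shared_de\tn_ppi\tn_coexp_ppi\n")
            for (a, b), ev in sorted(self.edges.items()):
                fh.write(
                    f"{a}\t{b}\t{len(ev.shared_genes)}\t{len(ev.shared_de_genes)}"
                    f"\t{len(ev.ppi_pairs)}\t{len(ev.coexpressed_ppi_pairs)}\n"
                )


def differential_genes(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    *,
    welch: bool = False,
    bh_correct: bool = False,
) -> dict[str, float]:
    """Two-sample t-test p-value per gene (disease vs control).

    Student's pooled-variance test by default; ``welch=True`` drops the
    equal-variance assumption. ``bh_correct=True`` applies Benjamini-Hochberg
    before thresholding (raw p-values by default).
    """
    y = labels.binary(expr.sample_ids)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise InputError("both classes need >=2 samples for a t-test")
    x = expr.values.to_numpy()
    _, p = stats.ttest_ind(x[:, y == 1], x[:, y == 0], axis=1, equal_var=not welch)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance-in-both-groups genes: no evidence
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    return dict(zip(expr.gene_ids, p.tolist()))


def coexpressed_pairs(
    expr: ExpressionMatrix,
    pairs: set[tuple[str, str]],
    rho_min: float,
) -> set[tuple[str, str]]:
    """Subset of gene pairs with |Pearson r| strictly above ``rho_min``.

    Correlation is computed across all samples, both classes pooled.
    """
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for pair in pairs for g in pair if g not in idx]
    if missing:
        raise InputError(f"pair genes not in matrix: {sorted(set(missing))[:5]}")
    x = expr.values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    out: set[tuple[str, str]] = set()
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        denom = norms[ia] * norms[ib]
        if denom == 0:
            continue
        r = float(xc[ia] @ xc[ib]) / denom
        if abs(r) > rho_min:
            out.add((a, b))
    return out


def build_pin(
    sets: GeneSetCollection,
    ppi: PPIGraph,
    expr: ExpressionMatrix,
    labels: SampleLabels,
    alpha: float = 0.05,
    rho_min: float = 0.8,
    *,
    welch: bool = False,
    bh_correct: bool = False,
) -> PathwayNetwork:
    """Assemble candidate pathway edges and keep those with condition support.

    A pathway pair is a candidate if the pathways share a gene or a PPI links a
    gene of one to a gene of the other (membership, not exclusivity: a PPI
    between two genes each lying in both pathways still counts). The edge is
    retained iff a shared gene is differentially expressed at ``alpha`` or a
    candidate PPI pair is co-expressed beyond ``rho_min``.
    """
    names = sorted(sets.names())
    gene2pw: dict[str, list[str]] = {}
    for name in names:
        for g in sets.genes(name):
            gene2pw.setdefault(g, []).append(name)

    # candidate shared-gene evidence
    shared: dict[tuple[str, str], set[str]] = {}
    for g, pws in gene2pw.items():
        if len(pws) < 2:
            continue
        for i in range(len(pws)):
            for j in range(i + 1, len(pws)):
                key = PathwayNetwork.canonical(pws[i], pws[j])
                shared.setdefault(key, set()).add(g)

    # candidate cross-pathway PPI evidence
    ppi_ev: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for a, b in ppi.edges:
        for pa in gene2pw.get(a, ()):  # genes absent from any pathway contribute nothing
            for pb in gene2pw.get(b, ()):
                if pa == pb:
                    continue
                key = PathwayNetwork.canonical(pa, pb)
                ppi_ev.setdefault(key, set()).add((a, b))

    pvals = differential_genes(expr, labels, welch=welch, bh_correct=bh_correct)
    de_genes = {g for g, p in pvals.items() if p < alpha}

    needed_pairs = {pair for pairs in ppi_ev.values() for pair in pairs}
    coexp = coexpressed_pairs(expr, needed_pairs, rho_min) if needed_pairs else set()

    edges: dict[tuple[str, str], EdgeEvidence] = {}
    for key in sorted(set(shared) | set(ppi_ev)):
        sh = frozenset(shared.get(key, set()))
        pp = frozenset(ppi_ev.get(key, set()))
        ev = EdgeEvidence(
            shared_genes=sh,
            shared_de_genes=frozenset(g for g in sh if g in de_genes),
            ppi_pairs=pp,
            coexpressed_ppi_pairs=frozenset(p for p in pp if p in coexp),
        )
        if ev.retained:
            edges[key] = ev

    if not edges:
        logger.warning("pathway interaction network has no edges under the current filters")
    return PathwayNetwork(nodes=names, edges=edges, params={"alpha": alpha, "rho_min": rho_min})
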