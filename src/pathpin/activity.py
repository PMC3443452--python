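"""Pathway activity scores: first principal component of member-gene expression.

Each pathway becomes a "meta-gene": the per-sample projection of its member
genes' standardized expression onto the unit-norm leading eigenvector of the
gene-gene covariance matrix. The principal-component sign is fixed by a
deterministic convention so repeated runs agree bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, InputError

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Pathways x samples activity scores plus per-pathway gene loadings."""

    scores: pd.DataFrame  # index = pathway ids, columns = sample ids
    loadings: dict[str, pd.Series]  # pathway -> unit-norm weights over its genes

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def write(self, scores_path: str | Path, loadings_path: str | Path | None = None) -> None:
        self.scores.to_csv(scores_path, sep="\t", index_label="pathway")
        if loadings_path is not None:
            with open(loadings_path, "w") as fh:
                fh.write("pathway\tgene\tweight\n")
                for pw, w in self.loadings.items():
                    for gene, weight in w.items():
                        fh.write(f"{pw}\t{gene}\t{weight:.10g}\n")


def map_genes_to_pathways(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    min_genes: int = 1,
) -> GeneSetCollection:
    """Restrict every pathway to genes measured in ``expr``.

    Pathways left with fewer than ``min_genes`` measured genes are dropped and
    reported. Raises if nothing survives.
    """
    if not expr.standardized:
        raise InputError("expression must be standardized before pathway mapping")
    measured = set(expr.gene_ids)
    kept: dict[str, tuple[str, frozenset[str]]] = {}
    dropped: list[str] = []
    for name, (desc, genes) in sets.sets.items():
        present = genes & measured
        if len(present) >= min_genes:
            kept[name] = (desc, frozenset(present))
        else:
            dropped.append(name)
    if dropped:
        logger.info(
            "dropped %d/%d pathways with <%d measured genes", len(dropped), len(sets), min_genes
        )
    if not kept:
        raise InputError("no pathway retains enough measured genes")
    return GeneSetCollection(sets=kept)


def _leading_component(z: np.ndarray, genes: list[str]) -> np.ndarray:
    """Unit-norm leading eigenvector of cov(z), sign-fixed.

    ``z`` is member-genes x samples; ``genes`` is the (sorted) gene order,
    used to break an exact-zero loading sum deterministically.
    """
    if z.shape[0] == 1:
        return np.array([1.0])
    cov = np.cov(z, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    w = eigvecs[:, -1]
    w = w / np.linalg.norm(w)
    s = w.sum()
    if s < 0:
        w = -w
    elif s == 0:
        # tie-break: loading of the lexicographically smallest gene positive
        k = int(np.argmin(np.array(genes, dtype=object)))
        if w[k] < 0:
            w = -w
    return w


def compute_activity(expr: ExpressionMatrix, sets: GeneSetCollection) -> ActivityMatrix:
    """First-principal-component activity score for every pathway and sample.

    PCA is fitted on all samples jointly so disease and control scores live on
    the same scale. Single-gene pathways get the gene's standardized row.
    """
    if not expr.standardized:
        raise InputError("expression must be standardized")
    measured = set(expr.gene_ids)
    rows: list[np.ndarray] = []
    names: list[str] = []
    loadings: dict[str, pd.Series] = {}
    for name, (_, genes) in sets.sets.items():
        member = sorted(genes)
        missing = [g for g in member if g not in measured]
        if missing:
            raise InputError(f"pathway {name!r} has unmeasured genes: {missing[:5]}")
        z = expr.values.loc[member].to_numpy()
        w = _leading_component(z, member)
        rows.append(w @ z)
        names.append(name)
        loadings[name] = pd.Series(w, index=member)
    scores = pd.DataFrame(rows, index=names, columns=expr.sample_ids)
    return ActivityMatrix(scores=scores, loadings=loadings)


def activity_from_genes(expr: ExpressionMatrix, genes: list[str]) -> ActivityMatrix:
    """Wrap individual standardized gene rows as single-feature 'activities'.

    Lets gene-level baselines flow through the same evaluation machinery as
    pathway markers, so comparisons differ only in the features used.
    """
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise InputError(f"genes not in matrix: {missing[:5]}")
    scores = expr.values.loc[genes].copy()
    loadings = {g: pd.Series([1.0], index=[g]) for g in genes}
    return ActivityMatrix(scores=scores, loadings=loadings)
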