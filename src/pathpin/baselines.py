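"""Gene-biomarker baseline (t-test ranking) and marker-overlap reporting."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, InputError, SampleLabels


@dataclass
class RankedGeneList:
    """Genes ordered by ascending p-value, ties by descending |t| then gene id."""

    table: pd.DataFrame  # columns: gene, t, p

    def top(self, k: int) -> list[str]:
        return self.table["gene"].head(k).tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def rank_genes_ttest(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    k: int | None = None,
    *,
    welch: bool = False,
) -> RankedGeneList:
    """Rank genes by two-sample t-test between disease and control.

    With ``k`` given, truncate to the top k; the resulting genes' standardized
    expression rows serve directly as classifier features.
    """
    if k is not None and k <= 0:
        raise InputError("k must be positive")
    if k is not None and k > expr.n_genes:
        raise InputError(f"k={k} exceeds the {expr.n_genes} available genes")
    y = labels.binary(expr.sample_ids)
    x = expr.values.to_numpy()
    t, p = stats.ttest_ind(x[:, y == 1], x[:, y == 0], axis=1, equal_var=not welch)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    table = pd.DataFrame({"gene": expr.gene_ids, "t": t, "p": p})
    table["abs_t"] = table["t"].abs()
    table = table.sort_values(
        by=["p", "abs_t", "gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="abs_t")
    table = table.reset_index(drop=True)
    if k is not None:
        table = table.head(k)
    return RankedGeneList(table=table)


def marker_gene_overlap(
    selected_pathways: list[str],
    sets: GeneSetCollection,
    ranked: RankedGeneList,
) -> dict[str, float]:
    """Overlap between selected pathways' genes and same-size top gene list.

    The union of the selected pathways' (measured) genes is intersected with
    an equally sized head of the ranked gene list; the percentage is the
    intersection size over the pathway-gene count, times 100.
    """
    union: set[str] = set()
    for pw in selected_pathways:
        if pw not in sets:
            raise InputError(f"pathway {pw!r} not in collection")
        union |= sets.genes(pw)
    if not union:
        raise InputError("selected pathways contribute no genes")
    n = len(union)
    top = set(ranked.top(n))
    n_overlap = len(union & top)
    return {
        "n_pathway_genes": n,
        "n_overlap": n_overlap,
        "percentage": 100.0 * n_overlap / n,
    }
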