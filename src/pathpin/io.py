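"""Readers, writers and core containers for expression data, labels, gene sets and PPIs.

Expression matrices are stored genes x samples. Standardization rescales every
gene row to mean 0 and unit sample standard deviation (divisor n-1), the usual
first step before summarizing pathways by principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"


class FormatError(ValueError):
    """A file does not conform to its declared text format."""


class IntegrityError(ValueError):
    """Parsed content violates an internal consistency requirement."""


class InputError(ValueError):
    """Input is well-formed but unusable (empty, mislabelled, too small...)."""


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with unique identifiers on both axes."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate gene identifiers: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise IntegrityError(f"duplicate sample identifiers: {dup[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleLabels:
    """Binary disease/control assignment per sample."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.assignments.values()} - {DISEASE, CONTROL}
        if bad:
            raise InputError(f"labels must be '{DISEASE}' or '{CONTROL}', got {sorted(bad)}")
        classes = set(self.assignments.values())
        if classes != {DISEASE, CONTROL}:
            raise InputError("both disease and control classes must be non-empty")

    def binary(self, sample_ids: Iterable[str]) -> np.ndarray:
        """0/1 vector aligned to ``sample_ids`` (1 = disease)."""
        try:
            return np.array(
                [1 if self.assignments[s] == DISEASE else 0 for s in sample_ids], dtype=int
            )
        except KeyError as e:
            raise InputError(f"sample {e.args[0]!r} has no label") from e

    def class_counts(self) -> tuple[int, int]:
        vals = list(self.assignments.values())
        return vals.count(DISEASE), vals.count(CONTROL)


@dataclass
class GeneSetCollection:
    """Named pathways; each maps to a description and a non-empty gene set."""

    sets: dict[str, tuple[str, frozenset[str]]]  # name -> (description, genes)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise IntegrityError(f"gene set {name!r} is empty")

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class PPIGraph:
    """Undirected protein-protein interaction edges as canonical gene pairs."""

    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PPIGraph":
        edges = {cls.canonical(a, b) for a, b in pairs if a != b}
        return cls(edges=frozenset(edges))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# loaders


def load_expression(
    path: str | Path,
    probe_map: str | Path | None = None,
    *,
    missing: str = "error",
    uppercase_genes: bool = False,
) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix (rows = genes/probes, header = samples).

    If ``probe_map`` is given (two-column TSV: probe id, gene symbol), probes
    without a gene are dropped and genes measured by several probes get the
    arithmetic mean of their probes' raw values, per sample.

    ``missing`` controls NA policy: ``"error"`` (default) rejects matrices with
    missing values, ``"mean"`` imputes the gene-row mean.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression matrix {path}: {e}") from e
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputError(f"expression matrix {path} is empty")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sample identifiers in header of {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)

    if probe_map is not None:
        mapping = _read_probe_map(probe_map)
        if uppercase_genes:
            mapping = {p: g.upper() for p, g in mapping.items()}
        keep = [p for p in df.index if mapping.get(p)]
        dropped = df.shape[0] - len(keep)
        if dropped:
            logger.info("dropped %d probes with no gene mapping", dropped)
        if not keep:
            raise InputError("no probes map to a gene")
        df = df.loc[keep]
        df.index = [mapping[p] for p in df.index]
        df = df.groupby(level=0, sort=False).mean()
    elif uppercase_genes:
        df.index = df.index.str.upper()
        if df.index.has_duplicates:
            raise IntegrityError("upper-casing gene symbols created duplicates")

    if df.index.has_duplicates:
        raise IntegrityError("duplicate gene identifiers after probe collapsing")

    if df.isna().any().any():
        if missing == "mean":
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
            if df.isna().any().any():
                raise InputError("genes with all values missing cannot be imputed")
        else:
            n_bad = int(df.isna().any(axis=1).sum())
            raise InputError(
                f"{n_bad} gene rows contain missing values (pass missing='mean' to impute)"
            )
    return ExpressionMatrix(values=df, standardized=False)


def _read_probe_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            # a probe with an empty gene field still needs the delimiter
            raise FormatError(f"probe map line {i}: expected 2 tab-separated fields")
        probe, gene = fields[0].strip(), fields[1].strip()
        mapping[probe] = gene  # empty string = unmapped
    return mapping


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every gene row to mean 0, sample std 1 (divisor n-1).

    Genes with zero variance cannot be standardized and are removed (logged).
    """
    if expr.standardized:
        raise InputError("matrix is already standardized")
    values = expr.values
    means = values.mean(axis=1)
    stds = values.std(axis=1, ddof=1)
    keep = stds > 0
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "removed %d zero-variance genes: %s%s",
            n_removed,
            ", ".join(values.index[~keep][:5]),
            "..." if n_removed > 5 else "",
        )
    if not keep.any():
        raise InputError("all genes have zero variance")
    z = values.loc[keep].sub(means[keep], axis=0).div(stds[keep], axis=0)
    return ExpressionMatrix(values=z, standardized=True)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene1 TAB gene2 ...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {i}: expected >=3 tab-separated fields")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise IntegrityError(f"duplicate gene set name {name!r} (line {i})")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise FormatError(f"GMT line {i}: gene set {name!r} has no genes")
        sets[name] = (desc, genes)
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets=sets)


def load_ppi(path: str | Path) -> PPIGraph:
    """Parse a two-column tab-delimited gene-pair list; extra columns ignored.

    Self-interactions are dropped; duplicate pairs in either order collapse.
    """
    pairs: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"PPI line {i}: expected >=2 tab-separated fields")
        pairs.append((fields[0].strip(), fields[1].strip()))
    graph = PPIGraph.from_pairs(pairs)
    if not graph.edges:
        logger.warning("PPI file %s yields no edges", path)
    return graph


def load_labels(path: str | Path) -> SampleLabels:
    """Two-column TSV: sample id, label in {disease, control}."""
    assignments: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"labels line {i}: expected 2 tab-separated fields")
        sample, label = fields[0].strip(), fields[1].strip().lower()
        if sample in assignments:
            raise IntegrityError(f"duplicate label for sample {sample!r} (line {i})")
        assignments[sample] = label
    return SampleLabels(assignments=assignments)


def check_labels(expr: ExpressionMatrix, labels: SampleLabels) -> None:
    """Every expression sample must carry exactly one label."""
    missing = [s for s in expr.sample_ids if s not in labels.assignments]
    if missing:
        raise InputError(f"samples without labels: {missing[:5]}")


# ---------------------------------------------------------------------------
# writers (the simulate CLI emits exactly what the loaders read)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in labels.assignments.items():
            fh.write(f"{sample}\t{label}\n")


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_ppi(ppi: PPIGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


def restandardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the standardization transform regardless of the flag (internal)."""
    return standardize(replace(expr, standardized=False))
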