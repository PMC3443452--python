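import numpy as np
import pandas as pd
import pytest

import pathpin as pp


@pytest.fixture(scope="session")
def toy():
    return pp.make_toy_fixture()


@pytest.fixture(scope="session")
def toy_pipeline(toy):
    """Toy bundle pushed through standardization, mapping, activity and PIN."""
    expr = pp.standardize(toy.expression)
    mapped = pp.map_genes_to_pathways(expr, toy.gene_sets)
    activity = pp.compute_activity(expr, mapped)
    pin = pp.build_pin(mapped, toy.ppi, expr, toy.labels)
    return {"expr": expr, "mapped": mapped, "activity": activity, "pin": pin, "labels": toy.labels}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_expression(rng, n_genes=10, n_samples=20, standardized=False):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    values = pd.DataFrame(rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples)
    expr = pp.ExpressionMatrix(values=values, standardized=False)
    return pp.standardize(expr) if standardized else expr


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory, toy):
    """Toy bundle serialized to the on-disk formats the loaders read."""
    from pathpin import io as pio

    out = tmp_path_factory.mktemp("toy_files")
    pio.write_expression(toy.expression, out / "expression.tsv")
    pio.write_labels(toy.labels, out / "labels.tsv")
    pio.write_gmt(toy.gene_sets, out / "sets.gmt")
    pio.write_ppi(toy.ppi, out / "ppi.tsv")
    return out
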