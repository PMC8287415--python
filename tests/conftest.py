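import numpy as np
import pytest

from dyspia import (
    BackgroundSet,
    ExpressionMatrix,
    GenePair,
    PathwayPairSet,
    PhenotypeLabels,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expression(n_genes, n_case, n_control, rng, prefix="G"):
    """Random expression matrix with case columns first."""
    genes = [f"{prefix}{i:04d}" for i in range(n_genes)]
    samples = [f"c{i:03d}" for i in range(n_case)] + [
        f"t{i:03d}" for i in range(n_control)
    ]
    values = rng.standard_normal((n_genes, n_case + n_control))
    expr = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
    labels = PhenotypeLabels(
        {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    )
    return expr, labels


@pytest.fixture
def small_dataset(rng):
    """20 genes x (6 case + 6 control), plus a background of all gene pairs."""
    expr, labels = make_expression(20, 6, 6, rng)
    pairs = [
        GenePair(a, b)
        for i, a in enumerate(expr.gene_ids)
        for b in expr.gene_ids[i + 1 :]
    ]
    bg = BackgroundSet(pairs=pairs, provenance=["observed"] * len(pairs))
    return expr, labels, bg


@pytest.fixture
def toy_pathways(small_dataset):
    expr, _, bg = small_dataset
    rng = np.random.default_rng(42)
    pathways = []
    for k in range(3):
        members = rng.choice(len(bg.pairs), size=10, replace=False)
        pathways.append(
            PathwayPairSet(
                pathway_id=f"pw{k}",
                name=f"toy pathway {k}",
                pairs=frozenset(bg.pairs[i] for i in members),
            )
        )
    return pathways
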