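import numpy as np
import pytest

from rulexp import ExpressionDataset, ExpressionSimSpec, generate_expression


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, two balanced classes."""
    rng = np.random.default_rng(0)
    return ExpressionDataset(
        genes=["gA", "gB", "gC"],
        samples=["s1", "s2", "s3", "s4"],
        values=rng.normal(size=(4, 3)),
        labels=["A", "A", "B", "B"],
    )


@pytest.fixture
def separable_dataset() -> ExpressionDataset:
    """Gene 0 separates the classes with a clean margin."""
    ds, _ = generate_expression(
        ExpressionSimSpec(n_per_class=(15, 15), n_genes=10, n_informative=1,
                          separable=True, seed=42)
    )
    return ds


@pytest.fixture
def planted_dataset() -> tuple[ExpressionDataset, set[str]]:
    """Default study conditions: 200 genes, 10 informative at 2 SD, 50+50."""
    return generate_expression(ExpressionSimSpec(seed=7))
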