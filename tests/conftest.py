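import numpy as np
import pytest

from genesieve import (
    ClassifierSpec,
    ExpressionMatrix,
    GeneSet,
    SampleLabels,
    SyntheticSpec,
    simulate_gem,
)


@pytest.fixture
def tiny_gem():
    """3 genes x 4 samples with hand-written values."""
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [0.0, 1.0, 2.5, 3.0],
                [10.0, 0.25, 7.0, 1.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
    )


@pytest.fixture
def tiny_gem_tsv(tiny_gem, tmp_path):
    path = tmp_path / "gem.tsv"
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(tiny_gem.sample_ids) + "\n")
        for g, row in zip(tiny_gem.gene_ids, tiny_gem.values):
            fh.write(g + "\t" + "\t".join(str(v) for v in row) + "\n")
    return path


@pytest.fixture
def two_class_labels():
    mapping = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
    return SampleLabels(mapping=mapping)


@pytest.fixture
def fast_spec():
    """Deterministic fallback classifier, few bootstraps: unit-test scale."""
    return ClassifierSpec(backend="linear_fallback", n_runs=3, rng_seed=11)


@pytest.fixture(scope="session")
def planted_gem():
    """Small synthetic matrix with planted signal shared across tests."""
    spec = SyntheticSpec(
        n_genes=120,
        n_samples=120,
        n_classes=3,
        planted_genes=4,
        effect_size=2.0,
        noise_sd=1.0,
        rng_seed=42,
    )
    return simulate_gem(spec)


@pytest.fixture
def planted_set(planted_gem):
    gem, _, truth = planted_gem
    others = [g for g in gem.gene_ids if g not in truth][:8]
    return GeneSet(name="PLANTED", genes=tuple(truth) + tuple(others))
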