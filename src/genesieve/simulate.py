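"""Synthetic expression matrices with planted class-discriminative genes.

The generator emulates the structure of a log-transformed bulk RNA-seq
matrix: every gene g gets a baseline b_g ~ Normal(mu0, tau^2); a chosen
number of *planted* genes additionally receive a class-specific offset
delta * u_{g,c} with u_{g,c} drawn uniformly from {-1, +1} per (gene,
class) — re-drawn until at least two classes differ — and every value gets
Normal(0, sigma^2) measurement noise.  Sign-pattern offsets (rather than
one-vs-rest shifts) mean that separating all classes generally requires
*combinations* of planted genes, which is exactly the polygenic premise the
decomposition is designed to probe.

Values are produced directly on the log2 scale (``transform_state=log2p1``)
so fixtures skip preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, SampleLabels


@dataclass
class SyntheticSpec:
    """Shape, signal and noise of a simulated expression matrix.

    Defaults are the desk-scale benchmark conditions used throughout the
    test-suite: 500 genes x 200 samples, 4 balanced classes, 5 planted
    genes with effect size delta = 2 (log2 units) against unit noise.
    """

    n_genes: int = 500
    n_samples: int = 200
    n_classes: int = 4
    class_proportions: list[float] | None = None
    planted_genes: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.planted_genes <= self.n_genes:
            raise ValueError("planted_genes must be within [0, n_genes]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_proportions is None:
            self.class_proportions = [1.0 / self.n_classes] * self.n_classes
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if (props <= 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be positive and sum to 1")


def _class_counts(props: np.ndarray, n_samples: int) -> np.ndarray:
    """Largest-remainder apportionment of samples to classes (each >= 1)."""
    quota = props * n_samples
    counts = np.maximum(np.floor(quota).astype(int), 1)
    frac = quota - np.floor(quota)
    while counts.sum() < n_samples:
        c = int(np.lexsort((np.arange(len(props)), -frac))[0])
        counts[c] += 1
        frac[c] -= 1.0
    while counts.sum() > n_samples:
        order = np.lexsort((np.arange(len(props)), frac))
        for c in order:
            if counts[c] > 1:
                counts[c] -= 1
                frac[c] += 1.0
                break
    return counts


def simulate_gem(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleLabels, list[str]]:
    """Generate (matrix, labels, planted gene ids) deterministically.

    Gene ids are ``G000001``..; sample ids ``S0001``..; class labels
    ``C1``.. in block order.  Identical specs (including seed) produce
    bit-identical matrices.
    """
    rng = np.random.default_rng(spec.rng_seed)
    G, N, C = spec.n_genes, spec.n_samples, spec.n_classes
    counts = _class_counts(np.asarray(spec.class_proportions), N)
    y = np.repeat(np.arange(C), counts)

    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    planted_idx = np.sort(rng.choice(G, size=spec.planted_genes, replace=False))

    # per-(gene, class) sign patterns; redraw constant rows so at least two
    # classes actually differ for every planted gene
    patterns = rng.choice([-1.0, 1.0], size=(spec.planted_genes, C))
    for i in range(spec.planted_genes):
        while np.all(patterns[i] == patterns[i, 0]):
            patterns[i] = rng.choice([-1.0, 1.0], size=C)

    offsets = np.zeros((G, C))
    offsets[planted_idx] = spec.effect_size * patterns

    values = (
        baselines[:, None]
        + offsets[:, y]
        + rng.normal(0.0, spec.noise_sd, size=(G, N))
    )

    gene_ids = [f"G{i + 1:06d}" for i in range(G)]
    sample_ids = [f"S{j + 1:04d}" for j in range(N)]
    gem = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        transform_state="log2p1",
    )
    labels = SampleLabels(
        mapping={s: f"C{y[j] + 1}" for j, s in enumerate(sample_ids)},
        class_names=[f"C{c + 1}" for c in range(C)],
    )
    truth = [gene_ids[i] for i in planted_idx]
    return gem, labels, truth
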