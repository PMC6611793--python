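"""Standard synthetic benchmarks for the screen/decompose/select pipeline.

These are the package's reference evaluation conditions, shared by the test
suite and the reproduction script:

* **Recovery**: a 500-gene x 200-sample matrix with 4 balanced classes and
  5 planted genes (effect size delta = 2 log2 units, unit noise); the
  decomposition runs on a 30-gene set holding all 5 planted genes plus 25
  noise genes drawn at random, with M = 30 seed subsets and 3 bootstrap
  splits per subset.  Reported: recall of planted genes among candidates.
* **Validation**: the candidate/non-candidate split from a recovery run is
  contrasted against 50 size-matched random sets with the full 10-run
  protocol; reported: foreground classification potential (FCP = observed
  accuracy minus random-set mean) of each arm.
* **Null calibration**: on a matrix with no planted signal, the screen's
  false-positive rate at alpha = 0.01 over repeated draws of the tested
  set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import CandidateSplit, compare_split, select_candidates
from .decompose import DecompositionConfig, gene_frequencies, run_decomposition
from .matrix import ExpressionMatrix, GeneSet, SampleLabels
from .potential import ClassifierSpec
from .screen import ScreenConfig, sample_random_sets, screen_gene_set
from .simulate import SyntheticSpec, simulate_gem


@dataclass
class RecoveryRun:
    """One seeded recovery benchmark repetition."""

    seed: int
    gem: ExpressionMatrix
    labels: SampleLabels
    truth: list[str]
    gene_set: GeneSet
    split: CandidateSplit

    @property
    def recall(self) -> float:
        """Fraction of planted genes recovered among the candidates."""
        return len(set(self.split.candidate_genes) & set(self.truth)) / len(
            self.truth
        )


def recovery_fixture(seed: int, set_size: int = 30) -> tuple:
    """The benchmark matrix and gene set for one repetition.

    The set holds every planted gene plus randomly drawn noise genes
    (random so that no systematic identifier ordering interacts with the
    deterministic tie-breaks of the seed selection).
    """
    gem, labels, truth = simulate_gem(SyntheticSpec(rng_seed=seed))
    rng = np.random.default_rng(10_000 + seed)
    pool = [g for g in gem.gene_ids if g not in truth]
    fill = [pool[j] for j in rng.choice(len(pool), set_size - len(truth), replace=False)]
    gs = GeneSet(name=f"PLANTED{set_size}", genes=tuple(truth) + tuple(fill))
    return gem, labels, truth, gs


def recovery_run(seed: int, M: int = 30, n_runs: int = 3) -> RecoveryRun:
    """Decompose the benchmark set and select candidates for one seed."""
    gem, labels, truth, gs = recovery_fixture(seed)
    cspec = ClassifierSpec(
        backend="linear_fallback", n_runs=n_runs, rng_seed=seed + 100
    )
    cfg = DecompositionConfig(M=M, rng_seed=seed + 200)
    log = run_decomposition(gem, labels, gs, cspec, cfg)
    split = select_candidates(gene_frequencies(log), set_name=gs.name)
    return RecoveryRun(
        seed=seed, gem=gem, labels=labels, truth=truth, gene_set=gs, split=split
    )


def recovery_benchmark(base_seed: int = 0, n_seeds: int = 5) -> list[RecoveryRun]:
    """The full recovery benchmark: one run per seed."""
    return [recovery_run(base_seed + i) for i in range(n_seeds)]


def validation_fcp(run: RecoveryRun, n_random: int = 50) -> dict[str, float]:
    """FCP of each arm of a recovery run's split (10-run protocol)."""
    cspec = ClassifierSpec(
        backend="linear_fallback", n_runs=10, rng_seed=run.seed + 300
    )
    report = compare_split(
        run.gem, run.labels, run.split, cspec,
        n_random=n_random, rng_seed=run.seed + 400,
    )
    return {a.arm: a.fcp for a in report.arms}


def null_screen_calibration(
    base_seed: int = 0,
    n_reps: int = 100,
    set_size: int = 10,
    alpha: float = 0.01,
) -> float:
    """False-positive rate of the Phase I screen on pure noise.

    One noise-only matrix (no planted genes) is screened ``n_reps`` times,
    each time with a freshly drawn tested set and background; returns the
    fraction of repetitions flagged significant at ``alpha``.
    """
    gem, labels, _ = simulate_gem(
        SyntheticSpec(
            n_genes=300,
            n_samples=120,
            n_classes=3,
            planted_genes=0,
            rng_seed=base_seed + 77,
        )
    )
    hits = 0
    for rep in range(n_reps):
        gs = sample_random_sets(
            gem.gene_ids, set_size, 1, rng_seed=base_seed + 1000 + rep
        )[0]
        cspec = ClassifierSpec(
            backend="linear_fallback", n_runs=10, rng_seed=base_seed + 2000 + rep
        )
        res = screen_gene_set(
            gem,
            labels,
            gs,
            cspec,
            ScreenConfig(n_random_sets=50, alpha=alpha, rng_seed=base_seed + 3000 + rep),
        )
        hits += res.significant
    return hits / n_reps
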