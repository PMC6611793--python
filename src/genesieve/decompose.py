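"""Phase II: combinatorial decomposition of a gene set.

All subsets of size k = 1..3 are enumerated and scored exhaustively
(C(n, k) of them per size).  From then on the search is seeded: the M
highest-scoring subsets of the current size, plus M/2 random ones to keep
the search diverse, are each extended by every absent gene of the set,
duplicates are removed, and the unique children are scored.  This continues
until the only subset left is the full set, producing a log of every subset
ever evaluated with its accuracy — the raw material for candidate-gene
selection.

With M = 60 the seeded stage creates at most (3/2)·M·(n − k) subsets of
size k + 1; a 36-gene set thus yields C(36,3) = 7140 exhaustive triples and
then 90·33 = 2970 children of size 4.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .matrix import ExpressionMatrix, GeneSet, SampleLabels
from .potential import (
    BootstrapPotential,
    ClassifierSpec,
    fallback_accuracies,
    _mlp_accuracies,
    prepare_runs,
)
from .candidates import FrequencyTable, select_candidates

logger = logging.getLogger(__name__)


@dataclass
class DecompositionConfig:
    """Search parameters of the seeded subset expansion."""

    M: int = 60
    random_seed_fraction: float = 0.5
    exhaustive_k_max: int = 3
    rng_seed: int = 0
    exhaustive_budget: int = 500_000

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.exhaustive_k_max < 1:
            raise ValueError("exhaustive_k_max must be >= 1")
        if not 0.0 <= self.random_seed_fraction:
            raise ValueError("random_seed_fraction must be non-negative")


@dataclass(frozen=True)
class SubsetRecord:
    """One evaluated subset: canonically sorted genes and its accuracy."""

    genes: tuple[str, ...]
    accuracy: float

    @property
    def k(self) -> int:
        return len(self.genes)


@dataclass
class DecompositionLog:
    """Every subset evaluated at each iteration k, with accuracies."""

    set_name: str
    n: int
    gene_order: list[str]
    iterations: dict[int, list[SubsetRecord]] = field(default_factory=dict)

    @property
    def m(self) -> dict[int, int]:
        """Number of unique evaluated subsets per iteration."""
        return {k: len(v) for k, v in self.iterations.items()}

    def best(self, k: int) -> SubsetRecord:
        """Highest-accuracy record at size k (ties: smallest tuple)."""
        return min(self.iterations[k], key=lambda r: (-r.accuracy, r.genes))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"iteration": k, "subset": ";".join(r.genes), "accuracy": r.accuracy}
            for k in sorted(self.iterations)
            for r in self.iterations[k]
        ]
        return pd.DataFrame(rows, columns=["iteration", "subset", "accuracy"])

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df["accuracy"] = df["accuracy"].map(lambda a: repr(float(a)))
        df.to_csv(path, sep="\t", index=False)


def read_log(path, set_name: str | None = None) -> DecompositionLog:
    """Load a decomposition log written by :meth:`DecompositionLog.write_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"subset": str})
    iterations: dict[int, list[SubsetRecord]] = {}
    genes: set[str] = set()
    for _, row in df.iterrows():
        subset = tuple(str(row["subset"]).split(";"))
        genes.update(subset)
        iterations.setdefault(int(row["iteration"]), []).append(
            SubsetRecord(genes=subset, accuracy=float(row["accuracy"]))
        )
    n = max(iterations) if iterations else 0
    return DecompositionLog(
        set_name=set_name or "log",
        n=n,
        gene_order=sorted(genes),
        iterations=iterations,
    )


def count_subsets(n: int, k: int) -> int:
    """Number of k-gene subsets of an n-gene set: the binomial coefficient."""
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    return math.comb(n, k)


def total_subsets(n: int) -> int:
    """All non-empty subsets of an n-gene set: sum_k C(n,k) = 2^n - 1.

    Reported as a diagnostic of the full search space the exhaustive stage
    avoids; never enumerated.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    return 2**n - 1


def enumerate_subsets(genes, k: int) -> list[tuple[str, ...]]:
    """All C(n, k) subsets, canonically sorted, in lexicographic order."""
    genes = sorted(genes)
    if k < 1 or k > len(genes):
        raise ValueError(f"need 1 <= k <= {len(genes)}, got k={k}")
    return list(combinations(genes, k))


def extend_seeds(
    seeds: list[tuple[str, ...]], full_set: GeneSet
) -> list[tuple[str, ...]]:
    """Grow each size-k seed by every absent gene of the set; dedupe.

    Each seed yields n - k children; children are canonically sorted and
    globally de-duplicated, so the result has at most len(seeds)·(n - k)
    tuples, returned in sorted order.
    """
    if not seeds:
        raise ValueError("no seeds to extend")
    full = set(full_set.genes)
    k = len(seeds[0])
    children: set[tuple[str, ...]] = set()
    for seed in seeds:
        if len(seed) != k:
            raise ValueError("all seeds must have identical size")
        sset = set(seed)
        if not sset <= full:
            missing = sorted(sset - full)
            raise ValueError(
                f"seed gene(s) {missing} not in set {full_set.name!r}"
            )
        for g in full - sset:
            children.add(tuple(sorted(seed + (g,))))
    return sorted(children)


def select_seed_pool(
    records: list[SubsetRecord],
    cfg: DecompositionConfig,
    rng_seed: int | None = None,
) -> list[tuple[str, ...]]:
    """Top-M subsets by accuracy plus M/2 random ones from the remainder.

    Ties in the top-M cut are broken by lexicographic tuple order so the
    pool is deterministic; the random picks are drawn without replacement
    from the non-top records under the given seed.  When fewer records exist
    than requested, all available are taken.
    """
    if not records:
        raise ValueError("no records to seed from")
    ks = {r.k for r in records}
    if len(ks) != 1:
        raise ValueError(f"records span multiple sizes {sorted(ks)}")
    ordered = sorted(records, key=lambda r: (-r.accuracy, r.genes))
    top = [r.genes for r in ordered[: cfg.M]]
    rest = [r.genes for r in ordered[cfg.M :]]
    n_random = min(int(cfg.M * cfg.random_seed_fraction), len(rest))
    pool = list(top)
    if n_random > 0:
        rng = np.random.default_rng(
            cfg.rng_seed if rng_seed is None else rng_seed
        )
        # draw from the remainder in canonical order so the choice depends
        # only on the seed, not on the incoming record order
        rest_sorted = sorted(rest)
        picks = rng.choice(len(rest_sorted), size=n_random, replace=False)
        pool.extend(rest_sorted[j] for j in sorted(picks))
    return sorted(set(pool))


class GeneSubsetSelector(SelectorMixin, BaseEstimator):
    """Sieve the genes of a set that carry its classification signal.

    scikit-learn feature selector: ``fit(X, y)`` runs the exhaustive-then-
    seeded subset decomposition over the columns listed in ``genes``
    (default: all columns), tallies how often each gene appears in the
    evaluated subsets of every iteration, and selects as candidates the
    genes whose aggregate frequency is at least
    ``mean + sd_multiplier * SD`` of the aggregate-frequency distribution.

    Attributes
    ----------
    log_ : DecompositionLog
    frequency_table_ : FrequencyTable
    candidate_genes_, noncandidate_genes_ : list of str
    threshold_ : float
    support_ : bool mask over input features (True = candidate)
    """

    def __init__(
        self,
        genes=None,
        M: int = 60,
        random_seed_fraction: float = 0.5,
        exhaustive_k_max: int = 3,
        sd_multiplier: float = 0.5,
        random_state: int = 0,
        exhaustive_budget: int = 500_000,
        potential: BootstrapPotential | None = None,
        scorer=None,
    ):
        self.genes = genes
        self.M = M
        self.random_seed_fraction = random_seed_fraction
        self.exhaustive_k_max = exhaustive_k_max
        self.sd_multiplier = sd_multiplier
        self.random_state = random_state
        self.exhaustive_budget = exhaustive_budget
        self.potential = potential
        self.scorer = scorer

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"F{j}" for j in range(X.shape[1])]
        )
        idx = (
            np.arange(X.shape[1], dtype=np.intp)
            if self.genes is None
            else np.asarray(self.genes, dtype=np.intp)
        )
        set_genes = [names[j] for j in idx]
        cfg = DecompositionConfig(
            M=self.M,
            random_seed_fraction=self.random_seed_fraction,
            exhaustive_k_max=self.exhaustive_k_max,
            rng_seed=self.random_state,
            exhaustive_budget=self.exhaustive_budget,
        )
        pot = self.potential if self.potential is not None else BootstrapPotential()
        spec = pot._spec()
        if self.scorer is None and y is None:
            raise ValueError("y is required unless a scorer is injected")
        codes = None
        if y is not None:
            y = np.asarray(y)
            codes = np.searchsorted(np.unique(y), y)
        self.log_ = _decompose(
            X[:, idx],
            codes,
            set_genes,
            set_name="selection",
            cfg=cfg,
            spec=spec,
            scorer=self.scorer,
        )
        self.frequency_table_ = gene_frequencies(self.log_)
        split = select_candidates(self.frequency_table_, self.sd_multiplier)
        self.candidate_genes_ = list(split.candidate_genes)
        self.noncandidate_genes_ = list(split.noncandidate_genes)
        self.threshold_ = split.threshold
        cand = set(self.candidate_genes_)
        self.support_ = np.array([names[j] in cand for j in range(X.shape[1])])
        return self

    def _get_support_mask(self):
        return self.support_


def _decompose(
    X: np.ndarray,
    y: np.ndarray | None,
    set_genes: list[str],
    set_name: str,
    cfg: DecompositionConfig,
    spec: ClassifierSpec,
    scorer=None,
) -> DecompositionLog:
    """Core decomposition loop over X restricted to the set's columns."""
    n = len(set_genes)
    if n < 2:
        raise ValueError("decomposition needs a set of at least 2 genes")
    col = {g: j for j, g in enumerate(set_genes)}
    gs = GeneSet(name=set_name, genes=tuple(set_genes))

    k_max = min(cfg.exhaustive_k_max, n)
    while k_max > 1 and count_subsets(n, k_max) > cfg.exhaustive_budget:
        warnings.warn(
            f"C({n},{k_max}) exceeds the evaluation budget "
            f"({cfg.exhaustive_budget}); reducing exhaustive_k_max to {k_max - 1}",
            stacklevel=2,
        )
        k_max -= 1

    if scorer is None:
        runs = prepare_runs(X, y, spec)

        def evaluate(subsets: list[tuple[str, ...]]) -> np.ndarray:
            cols = np.array([[col[g] for g in s] for s in subsets], dtype=np.intp)
            if spec.backend == "linear_fallback":
                acc = fallback_accuracies(runs, cols)
            else:
                acc = _mlp_accuracies(runs, cols, spec)
            return acc.mean(axis=0)

    else:

        def evaluate(subsets: list[tuple[str, ...]]) -> np.ndarray:
            return np.array([float(scorer(s)) for s in subsets])

    log = DecompositionLog(set_name=set_name, n=n, gene_order=sorted(set_genes))

    def record(k: int, subsets: list[tuple[str, ...]]) -> None:
        accs = evaluate(subsets)
        log.iterations[k] = [
            SubsetRecord(genes=s, accuracy=float(a)) for s, a in zip(subsets, accs)
        ]
        logger.debug("%s: iteration %d evaluated %d subsets", set_name, k, len(subsets))

    for k in range(1, k_max + 1):
        record(k, enumerate_subsets(set_genes, k))
    k = k_max
    while k < n:
        pool = select_seed_pool(log.iterations[k], cfg, rng_seed=cfg.rng_seed + k)
        record(k + 1, extend_seeds(pool, gs))
        k += 1
    return log


def run_decomposition(
    gem: ExpressionMatrix,
    labels: SampleLabels,
    gs: GeneSet,
    cspec: ClassifierSpec,
    cfg: DecompositionConfig | None = None,
    scorer=None,
) -> DecompositionLog:
    """Decompose a (resolved) gene set against an expression matrix.

    ``scorer`` may inject a deterministic subset-scoring callable
    ``tuple -> accuracy`` in place of classifier training (used for
    search-behaviour verification); with a scorer, ``gem``/``labels`` may
    be ``None``.
    """
    cfg = cfg or DecompositionConfig()
    if scorer is None:
        X = gem.submatrix(list(gs.genes)).T
        y = labels.encode(gem.sample_ids)
    else:
        X = np.zeros((0, gs.n))
        y = None
    return _decompose(
        X,
        y,
        list(gs.genes),
        set_name=gs.name,
        cfg=cfg,
        spec=cspec,
        scorer=scorer,
    )


def gene_frequencies(log: DecompositionLog) -> FrequencyTable:
    """Per-iteration gene occurrence counts over all evaluated subsets.

    At an exhaustive iteration k every gene appears in exactly C(n-1, k-1)
    subsets, so those rows are constant; the contrast between genes builds
    up in the seeded iterations.
    """
    genes = list(log.gene_order)
    col = {g: j for j, g in enumerate(genes)}
    ks = sorted(log.iterations)
    counts = np.zeros((len(ks), len(genes)), dtype=np.int64)
    for i, k in enumerate(ks):
        for rec in log.iterations[k]:
            for g in rec.genes:
                counts[i, col[g]] += 1
    return FrequencyTable(genes=genes, iterations=ks, counts=counts)
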