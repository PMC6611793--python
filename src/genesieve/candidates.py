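"""Candidate-gene selection from a decomposition log, and its validation.

A gene's aggregate frequency is the number of evaluated subsets containing
it, summed over all iterations of the decomposition.  Genes at least
``sd_multiplier`` (default one-half) sample standard deviations above the
mean of that distribution are the candidates; the rest are non-candidates.
``compare_split`` then contrasts the classification potential of the full
set, the candidates and the non-candidates, each against size-matched
random gene sets (the foreground classification potential, FCP = observed
minus background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleLabels
from .potential import ClassifierSpec, accuracies_for_subsets


@dataclass
class FrequencyTable:
    """Gene occurrence counts per decomposition iteration (the heatmap)."""

    genes: list[str]
    iterations: list[int]
    counts: np.ndarray  # (len(iterations), len(genes)) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.iterations), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.iterations)} iterations x {len(self.genes)} genes"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def aggregate(self) -> np.ndarray:
        """Per-gene sum of counts across all iterations."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.iterations, columns=self.genes)


@dataclass
class CandidateSplit:
    """Partition of a gene set into candidates and non-candidates."""

    set_name: str
    candidate_genes: list[str]
    noncandidate_genes: list[str]
    threshold: float
    mean_aggregate: float
    sd_aggregate: float
    degenerate: bool = False

    def to_json_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "candidate_genes": list(self.candidate_genes),
            "noncandidate_genes": list(self.noncandidate_genes),
            "threshold": self.threshold,
            "mean_aggregate": self.mean_aggregate,
            "sd_aggregate": self.sd_aggregate,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CandidateSplit":
        return cls(
            set_name=d["set_name"],
            candidate_genes=list(d["candidate_genes"]),
            noncandidate_genes=list(d["noncandidate_genes"]),
            threshold=float(d["threshold"]),
            mean_aggregate=float(d["mean_aggregate"]),
            sd_aggregate=float(d["sd_aggregate"]),
            degenerate=bool(d["degenerate"]),
        )


def select_candidates(
    ft: FrequencyTable, sd_multiplier: float = 0.5, set_name: str = "set"
) -> CandidateSplit:
    """Split genes at ``mean + sd_multiplier * SD`` of aggregate frequency.

    The SD is the sample standard deviation (divisor n - 1); inclusion is
    ``>=`` so exact-threshold ties count as candidates.  An all-equal
    distribution (SD = 0) is flagged degenerate and every gene is returned
    as a candidate.
    """
    if len(ft.genes) < 2:
        raise ValueError("need at least 2 genes to form a split")
    agg = ft.aggregate.astype(float)
    mean = float(agg.mean())
    sd = float(agg.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "all aggregate frequencies equal; degenerate split returns every "
            "gene as a candidate",
            stacklevel=2,
        )
        return CandidateSplit(
            set_name=set_name,
            candidate_genes=list(ft.genes),
            noncandidate_genes=[],
            threshold=mean,
            mean_aggregate=mean,
            sd_aggregate=sd,
            degenerate=True,
        )
    threshold = mean + sd_multiplier * sd
    is_cand = agg >= threshold
    return CandidateSplit(
        set_name=set_name,
        candidate_genes=[g for g, c in zip(ft.genes, is_cand) if c],
        noncandidate_genes=[g for g, c in zip(ft.genes, is_cand) if not c],
        threshold=threshold,
        mean_aggregate=mean,
        sd_aggregate=sd,
    )


@dataclass
class ArmReport:
    """One arm of the validation comparison."""

    arm: str
    genes: list[str]
    mean_accuracy: float
    sd_accuracy: float
    random_mean: float | None = None  # BCP over size-matched random sets

    @property
    def fcp(self) -> float | None:
        if self.random_mean is None:
            return None
        return self.mean_accuracy - self.random_mean


@dataclass
class ComparisonReport:
    """Full-set vs candidate vs non-candidate validation."""

    set_name: str
    arms: list[ArmReport] = field(default_factory=list)

    def arm(self, name: str) -> ArmReport:
        for a in self.arms:
            if a.arm == name:
                return a
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set": self.set_name,
                    "arm": a.arm,
                    "size": len(a.genes),
                    "accuracy": a.mean_accuracy,
                    "sd": a.sd_accuracy,
                    "random_mean": np.nan if a.random_mean is None else a.random_mean,
                    "fcp": np.nan if a.fcp is None else a.fcp,
                }
                for a in self.arms
            ]
        )


def compare_split(
    gem: ExpressionMatrix,
    labels: SampleLabels,
    split: CandidateSplit,
    cspec: ClassifierSpec,
    n_random: int = 50,
    rng_seed: int = 0,
) -> ComparisonReport:
    """Contrast full set, candidates and non-candidates against random sets.

    Each arm is evaluated for classification potential; its background
    (BCP) is the mean potential of ``n_random`` random gene sets of the
    same size drawn from all genes in the matrix, and FCP = accuracy - BCP.
    With ``n_random=0`` only the observed accuracies are reported.  An
    empty arm is skipped with a warning.
    """
    y = labels.encode(gem.sample_ids)
    codes = np.searchsorted(np.unique(y), y)
    X = gem.values.T
    rng = np.random.default_rng(rng_seed)
    report = ComparisonReport(set_name=split.set_name)
    arms = [
        ("full", list(split.candidate_genes) + list(split.noncandidate_genes)),
        ("candidates", list(split.candidate_genes)),
        ("noncandidates", list(split.noncandidate_genes)),
    ]
    for arm_name, genes in arms:
        if not genes:
            warnings.warn(f"{arm_name} arm is empty; skipped", stacklevel=2)
            continue
        idx = np.sort(gem.rows(genes))
        subsets = [idx]
        if n_random > 0:
            subsets += [
                np.sort(rng.choice(gem.n_genes, size=len(idx), replace=False))
                for _ in range(n_random)
            ]
        acc = accuracies_for_subsets(X, codes, np.stack(subsets), cspec)
        per_run = acc[:, 0]
        report.arms.append(
            ArmReport(
                arm=arm_name,
                genes=genes,
                mean_accuracy=float(per_run.mean()),
                sd_accuracy=float(per_run.std(ddof=1)) if len(per_run) > 1 else 0.0,
                random_mean=(
                    float(acc[:, 1:].mean()) if n_random > 0 else None
                ),
            )
        )
    return report
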