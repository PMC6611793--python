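"""Phase I screen: gene-set potential versus size-matched random gene sets.

A curated gene set earns a pass into the combinatorial decomposition only if
its classification potential significantly exceeds the background potential
of random gene sets of the same size drawn from all genes in the matrix: a
one-sided Student t-test of the observed set potential against the empirical
distribution of the random sets' mean accuracies (default 50 random sets at
alpha 0.01).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone

from .matrix import ExpressionMatrix, GeneSet, SampleLabels, resolve_gene_set
from .potential import (
    BootstrapPotential,
    ClassificationPotential,
    accuracies_for_subsets,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Phase I configuration: background size and significance gate."""

    n_random_sets: int = 50
    alpha: float = 0.01
    rng_seed: int = 0
    exclude_tested: bool = False

    def __post_init__(self) -> None:
        if self.n_random_sets < 2:
            raise ValueError("n_random_sets must be >= 2 (a t-test needs variance)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class ScreenResult:
    """One gene set's observed vs background classification potential."""

    set_name: str
    set_potential: ClassificationPotential
    random_mean_accuracies: list[float]
    t_statistic: float
    p_value: float
    significant: bool = field(init=False)
    alpha: float = 0.01
    error: str | None = None

    def __post_init__(self) -> None:
        self.significant = bool(
            self.p_value < self.alpha
            and self.set_potential.mean_accuracy
            > float(np.mean(self.random_mean_accuracies))
        )

    @property
    def background_potential(self) -> float:
        """Mean accuracy of the size-matched random sets (the BCP)."""
        return float(np.mean(self.random_mean_accuracies))

    @property
    def foreground_potential(self) -> float:
        """Observed minus background potential (the FCP)."""
        return self.set_potential.mean_accuracy - self.background_potential


def sample_random_sets(
    universe: list[str],
    size: int,
    count: int,
    exclude: list[str] | None = None,
    rng_seed: int = 0,
) -> list[GeneSet]:
    """Draw ``count`` random gene sets of ``size`` unique genes each.

    Sets are drawn uniformly without replacement from ``universe`` (minus
    ``exclude``); distinct sets may overlap one another.
    """
    pool = list(universe)
    if exclude:
        drop = set(exclude)
        pool = [g for g in pool if g not in drop]
    if size > len(pool):
        raise ValueError(
            f"cannot draw sets of size {size} from a universe of {len(pool)}"
        )
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(count):
        picks = rng.choice(len(pool), size=size, replace=False)
        out.append(
            GeneSet(name=f"RANDOM_{i:04d}", genes=tuple(pool[j] for j in picks))
        )
    return out


class RandomSetScreen(BaseEstimator):
    """Test whether a feature subset out-classifies size-matched random subsets.

    scikit-learn estimator: ``fit(X, y)`` evaluates the classification
    potential of the columns in ``genes`` and of ``n_random_sets`` random
    column subsets of the same size (all on shared bootstrap partitions, a
    paired design that cancels common split noise), then applies a
    one-sided Student t-test of the observed potential against the
    random-set mean distribution.

    Attributes
    ----------
    set_potential_ : ClassificationPotential
    random_mean_accuracies_ : ndarray of shape (n_random_sets,)
    t_statistic_, p_value_ : float
    significant_ : bool
        ``p_value_ < alpha`` and the subset's mean accuracy exceeds the mean
        of the random means.
    """

    def __init__(
        self,
        genes=None,
        n_random_sets: int = 50,
        alpha: float = 0.01,
        random_state: int = 0,
        exclude_tested: bool = False,
        potential: BootstrapPotential | None = None,
    ):
        self.genes = genes
        self.n_random_sets = n_random_sets
        self.alpha = alpha
        self.random_state = random_state
        self.exclude_tested = exclude_tested
        self.potential = potential

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        cfg = ScreenConfig(
            n_random_sets=self.n_random_sets,
            alpha=self.alpha,
            rng_seed=self.random_state,
            exclude_tested=self.exclude_tested,
        )
        pot = self.potential if self.potential is not None else BootstrapPotential()
        spec = clone(pot)._spec()
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
        size = len(idx)
        universe = np.arange(X.shape[1], dtype=np.intp)
        if cfg.exclude_tested:
            universe = np.setdiff1d(universe, idx)
        if size > len(universe):
            raise ValueError("random sets cannot be size-matched: universe too small")
        rng = np.random.default_rng(cfg.rng_seed)
        randoms = np.stack(
            [
                np.sort(rng.choice(universe, size=size, replace=False))
                for _ in range(cfg.n_random_sets)
            ]
        )
        codes = np.searchsorted(np.unique(y), y)
        all_subsets = np.vstack([np.sort(idx)[None, :], randoms])
        acc = accuracies_for_subsets(X, codes, all_subsets, spec)
        set_runs = acc[:, 0]
        random_means = acc[:, 1:].mean(axis=0)
        t, p = _t_test_greater(set_runs, random_means)
        self.set_potential_ = ClassificationPotential(
            gene_list=[names[j] for j in idx],
            per_run_accuracy=[float(a) for a in set_runs],
        )
        self.random_mean_accuracies_ = random_means
        self.t_statistic_ = t
        self.p_value_ = p
        self.significant_ = bool(
            p < cfg.alpha
            and set_runs.mean() > random_means.mean()
        )
        return self


def _t_test_greater(set_runs: np.ndarray, random_means: np.ndarray) -> tuple[float, float]:
    """One-sided Student t-test of the set's potential against its null.

    The set's observed potential (mean of its bootstrap runs) is treated as
    a single draw from the null distribution whose sample is the
    size-matched random-set means:

        t = (OCP - mean(BCP_j)) / (s_B * sqrt(1 + 1/m)),  df = m - 1.

    The set's per-run accuracies are *not* used as the dispersion estimate:
    bootstrap runs share training samples, so their spread reflects split
    noise only and omits the between-set variance that dominates under the
    null, which would make a two-sample construction anti-conservative.
    Degenerate (zero-variance) backgrounds fall back to a direct mean
    comparison.
    """
    m = len(random_means)
    ocp = float(np.mean(set_runs))
    mu = float(np.mean(random_means))
    s = float(np.std(random_means, ddof=1))
    if s == 0.0 or not np.isfinite(s):
        return (np.inf if ocp > mu else -np.inf if ocp < mu else 0.0), (
            0.0 if ocp > mu else 1.0
        )
    t = (ocp - mu) / (s * np.sqrt(1.0 + 1.0 / m))
    p = float(stats.t.sf(t, df=m - 1))
    return float(t), p


def screen_gene_set(
    gem: ExpressionMatrix,
    labels: SampleLabels,
    gs: GeneSet,
    cspec,
    scfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Screen one (resolved) gene set against its random-set background."""
    scfg = scfg or ScreenConfig()
    est = RandomSetScreen(
        genes=gem.rows(list(gs.genes)),
        n_random_sets=scfg.n_random_sets,
        alpha=scfg.alpha,
        random_state=scfg.rng_seed,
        exclude_tested=scfg.exclude_tested,
        potential=BootstrapPotential(
            backend=cspec.backend,
            hidden_sizes=cspec.hidden_sizes,
            learning_rate=cspec.learning_rate,
            train_fraction=cspec.train_fraction,
            n_runs=cspec.n_runs,
            epochs=cspec.epochs,
            batch_size=cspec.batch_size,
            random_state=cspec.rng_seed,
            stratify=cspec.stratify,
        ),
    )
    est.fit(gem.values.T, labels.encode(gem.sample_ids), feature_names=gem.gene_ids)
    return ScreenResult(
        set_name=gs.name,
        set_potential=ClassificationPotential(
            gene_list=list(gs.genes),
            per_run_accuracy=est.set_potential_.per_run_accuracy,
        ),
        random_mean_accuracies=[float(a) for a in est.random_mean_accuracies_],
        t_statistic=est.t_statistic_,
        p_value=est.p_value_,
        alpha=scfg.alpha,
    )


def screen_collection(
    gem: ExpressionMatrix,
    labels: SampleLabels,
    sets: list[GeneSet],
    cspec,
    scfg: ScreenConfig | None = None,
) -> tuple[list[ScreenResult], pd.DataFrame]:
    """Screen a whole collection; failing sets are recorded, not fatal.

    Returns the per-set results plus a rank-ordered summary table with a
    Benjamini-Hochberg column reported for reference (the significance gate
    itself uses the raw per-set p-value, matching the screening protocol).
    """
    scfg = scfg or ScreenConfig()
    seen: dict[str, int] = {}
    results: list[ScreenResult] = []
    for i, gs in enumerate(sets):
        name = gs.name
        if name in seen:
            seen[name] += 1
            name = f"{gs.name}#{seen[gs.name]}"
            warnings.warn(
                f"duplicate gene set name {gs.name!r}; renamed to {name!r}",
                stacklevel=2,
            )
        else:
            seen[name] = 1
        try:
            resolved = resolve_gene_set(gs, gem)
            per_set = ScreenConfig(
                n_random_sets=scfg.n_random_sets,
                alpha=scfg.alpha,
                rng_seed=scfg.rng_seed + i,
                exclude_tested=scfg.exclude_tested,
            )
            res = screen_gene_set(gem, labels, resolved, cspec, per_set)
            res.set_name = name
        except Exception as exc:  # failing set is recorded and skipped
            logger.warning("screen failed for set %r: %s", name, exc)
            res = ScreenResult(
                set_name=name,
                set_potential=ClassificationPotential(gene_list=[], per_run_accuracy=[0.0]),
                random_mean_accuracies=[0.0, 0.0],
                t_statistic=float("nan"),
                p_value=1.0,
                alpha=scfg.alpha,
                error=str(exc),
            )
        results.append(res)
    return results, screen_summary(results)


def screen_summary(results: list[ScreenResult]) -> pd.DataFrame:
    """Rank-ordered summary table (best observed accuracy first)."""
    rows = []
    for r in results:
        rows.append(
            {
                "set": r.set_name,
                "n": len(r.set_potential.gene_list),
                "accuracy": r.set_potential.mean_accuracy,
                "random_mean": r.background_potential,
                "fcp": r.foreground_potential,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "error": r.error or "",
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        ok = df["error"] == ""
        df["p_bh"] = np.nan
        if ok.any():
            df.loc[ok, "p_bh"] = stats.false_discovery_control(
                df.loc[ok, "p_value"].to_numpy()
            )
        df = df.sort_values("accuracy", ascending=False, kind="mergesort")
        df = df.reset_index(drop=True)
    return df
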