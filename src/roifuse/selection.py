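"""Feature selection: embedded (EBM), filter (FBM), and correlation pruning.

Two alternative ranking procedures reduce a modality's ROI features to a
small working set:

* **EBM** (embedded-based): over ``n_runs`` Monte-Carlo iterations, draw a
  balanced subject split, draw a uniform random subset of ``subset_size``
  features, fit a random forest on the training portion, and record each
  subset feature's impurity importance.  A feature's score is its mean
  recorded importance; features scoring below ``importance_ratio`` times
  the best feature are dropped.
* **FBM** (filter-based): a two-sample Student t-test per feature; features
  with p above ``p_threshold`` are dropped and survivors are ranked by |t|.

Both feed a two-stage Pearson pruning of redundant features: first every
feature correlating with the top-ranked feature beyond ``r_top`` is
removed, then a greedy rank-ordered pass removes any lower-ranked survivor
correlating beyond ``r_pairwise`` with an anchor.  The surviving ranking
is finally truncated to ``max_features``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from ._forest import random_forest_importances
from .errors import ConfigError, DataError, EmptySelectionError
from .tables import AD, CN, FeatureTable

__all__ = [
    "SelectionConfig",
    "ImportanceProfile",
    "Removal",
    "SelectionResult",
    "ebm_importance",
    "importance_filter",
    "fbm_univariate",
    "correlation_prune",
    "select_features",
]

STAGES = ("importance_filter", "p_filter", "r_top", "r_pairwise", "truncation")


@dataclass(frozen=True)
class SelectionConfig:
    """All knobs of the selection pipeline; defaults are the study settings."""

    method: str = "ebm"                # "ebm" | "fbm"
    subset_size: int = 8               # features per EBM iteration
    n_runs: int = 2000                 # EBM Monte-Carlo iterations
    importance_ratio: float = 0.55     # EBM filter: keep >= ratio * max importance
    p_threshold: float = 0.05          # FBM filter: drop p > threshold
    r_top: float = 0.55                # prune |r| > r_top vs the top feature
    r_pairwise: float = 0.70           # prune |r| > r_pairwise vs higher-ranked anchors
    max_features: int = 8              # final truncation
    seed: int = 0
    train_fraction: float = 0.8        # per-iteration EBM split
    n_trees: int = 500                 # forest size per EBM iteration
    welch: bool = False                # Welch instead of Student t for FBM

    def __post_init__(self):
        if self.method not in ("ebm", "fbm"):
            raise ConfigError("SelectionConfig.method must be 'ebm' or 'fbm'")
        if self.n_runs < 1:
            raise ConfigError("SelectionConfig.n_runs must be >= 1")
        if self.subset_size < 1:
            raise ConfigError("SelectionConfig.subset_size must be >= 1")
        if not 0.0 < self.importance_ratio <= 1.0:
            raise ConfigError("SelectionConfig.importance_ratio must lie in (0, 1]")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigError("SelectionConfig.p_threshold must lie in (0, 1]")
        if not 0.0 < self.r_top <= 1.0:
            raise ConfigError("SelectionConfig.r_top must lie in (0, 1]")
        if not 0.0 < self.r_pairwise <= 1.0:
            raise ConfigError("SelectionConfig.r_pairwise must lie in (0, 1]")
        if self.max_features < 1:
            raise ConfigError("SelectionConfig.max_features must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("SelectionConfig.train_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ConfigError("SelectionConfig.n_trees must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ImportanceProfile:
    """Per-feature ranking statistics.

    For EBM, ``mean_importance`` (NaN for a feature never drawn) and
    ``appearance_count``; for FBM, ``t_value`` and ``p_value``.
    """

    feature_names: tuple[str, ...]
    mean_importance: np.ndarray | None = None
    appearance_count: np.ndarray | None = None
    t_value: np.ndarray | None = None
    p_value: np.ndarray | None = None


@dataclass(frozen=True)
class Removal:
    feature: str
    stage: str       # one of STAGES
    reason: str


@dataclass(frozen=True)
class SelectionResult:
    """Surviving ranked features plus a full audit of every removal."""

    selected: tuple[str, ...]
    removed: tuple[Removal, ...]
    correlation_matrix: np.ndarray | None = None
    correlation_features: tuple[str, ...] = ()

    def __post_init__(self):
        if set(self.selected) & {r.feature for r in self.removed}:
            raise ValueError("a feature cannot be both selected and removed")

    def to_dict(self) -> dict:
        d = {
            "selected": list(self.selected),
            "removed": [asdict(r) for r in self.removed],
        }
        if self.correlation_matrix is not None:
            d["correlation_matrix"] = {
                "features": list(self.correlation_features),
                "r": self.correlation_matrix.tolist(),
            }
        return d


def _rank_order(stat: np.ndarray, names: tuple[str, ...]) -> list[int]:
    """Descending by statistic, lexicographic on name for ties."""
    return sorted(range(len(names)), key=lambda j: (-stat[j], names[j]))


def _stratified_train_indices(labels: np.ndarray, train_fraction: float,
                              rng: np.random.Generator) -> np.ndarray:
    parts = []
    for cls in (CN, AD):
        idx = np.flatnonzero(labels == cls)
        n_test = max(1, int(round(len(idx) * (1.0 - train_fraction))))
        if n_test >= len(idx):
            raise DataError(f"class {cls} too small for a balanced split")
        perm = rng.permutation(idx)
        parts.append(perm[n_test:])
    return np.sort(np.concatenate(parts))


def ebm_importance(table: FeatureTable, config: SelectionConfig) -> ImportanceProfile:
    """Monte-Carlo random-subset forest importances.

    Each of ``config.n_runs`` iterations draws a class-balanced random
    subject split, a uniform random subset of ``subset_size`` features,
    fits a random forest on the training portion restricted to the subset
    and records the subset features' impurity importances.  A feature's
    ``mean_importance`` averages its recorded importances over the
    iterations in which it appeared.  Deterministic for a fixed seed.
    """
    p = table.n_features
    if config.subset_size > p:
        raise ConfigError("SelectionConfig.subset_size exceeds the feature count")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sums = np.zeros(p)
    counts = np.zeros(p, dtype=np.int64)
    values = np.ascontiguousarray(table.values)
    for _ in range(config.n_runs):
        train_idx = _stratified_train_indices(table.labels, config.train_fraction, rng)
        feats = np.sort(rng.choice(p, size=config.subset_size, replace=False))
        forest_seed = int(rng.integers(0, 2**31))
        X = np.ascontiguousarray(values[np.ix_(train_idx, feats)])
        y = table.labels[train_idx]
        imp = random_forest_importances(
            X, y, n_trees=config.n_trees, seed=forest_seed)
        sums[feats] += imp
        counts[feats] += 1
    with np.errstate(invalid="ignore"):
        mean_imp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ImportanceProfile(table.feature_names, mean_importance=mean_imp,
                             appearance_count=counts)


def importance_filter(profile: ImportanceProfile, importance_ratio: float) -> list[str]:
    """Drop features scoring strictly below ``ratio * max importance``.

    The boundary value survives (removal is strictly "lesser than").
    Output is ranked from the biggest to the smallest importance.
    """
    if profile.mean_importance is None or len(profile.feature_names) == 0:
        raise DataError("importance profile is empty")
    imp = np.asarray(profile.mean_importance, dtype=float)
    defined = ~np.isnan(imp)
    if not defined.any():
        raise DataError("no feature has a defined importance")
    cutoff = importance_ratio * np.nanmax(imp)
    keep = [j for j in range(len(imp)) if defined[j] and imp[j] >= cutoff]
    keep.sort(key=lambda j: (-imp[j], profile.feature_names[j]))
    return [profile.feature_names[j] for j in keep]


def _univariate_stats(table: FeatureTable, welch: bool = False):
    cn = table.values[table.labels == CN]
    ad = table.values[table.labels == AD]
    if len(cn) < 2 or len(ad) < 2:
        raise DataError("each diagnostic group needs >= 2 subjects for the t-test")
    t, p = stats.ttest_ind(ad, cn, axis=0, equal_var=not welch)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)


def fbm_univariate(table: FeatureTable, p_threshold: float = 0.05,
                   welch: bool = False) -> ImportanceProfile:
    """Per-feature two-sample t-test; survivors ranked by descending |t|.

    Features with p strictly above ``p_threshold`` are removed; the
    returned profile is restricted to survivors.  The classical
    equal-variance Student form is the default; ``welch=True`` switches to
    the unequal-variance form.
    """
    t, p = _univariate_stats(table, welch=welch)
    keep = [j for j in range(table.n_features) if p[j] <= p_threshold]
    keep.sort(key=lambda j: (-abs(t[j]), table.feature_names[j]))
    return ImportanceProfile(
        tuple(table.feature_names[j] for j in keep),
        t_value=t[keep], p_value=p[keep])


def correlation_prune(table: FeatureTable, ranked_features, r_top: float = 0.55,
                      r_pairwise: float = 0.70) -> SelectionResult:
    """Two-stage Pearson redundancy pruning of a ranked feature list.

    Stage 1 removes every feature whose absolute correlation with the
    top-ranked feature strictly exceeds ``r_top`` (the top feature always
    survives).  Stage 2 walks the survivors in rank order from the second
    onward; each anchor removes any lower-ranked survivor whose absolute
    correlation with it strictly exceeds ``r_pairwise``.  Correlations are
    computed on raw (pre-standardization) values over all subjects pooled.
    """
    ranked = list(ranked_features)
    if not ranked:
        raise DataError("ranked_features must be non-empty")
    sub = table.select_features(ranked)
    sd = sub.values.std(axis=0)
    for j, name in enumerate(ranked):
        if sd[j] == 0:
            raise DataError(f"feature {name!r} is constant; correlation undefined")
    corr = np.corrcoef(sub.values, rowvar=False)
    corr = np.atleast_2d(corr)
    removed: list[Removal] = []
    # stage 1: against the top-ranked feature
    top = ranked[0]
    survivors = [0]
    for j in range(1, len(ranked)):
        r = corr[0, j]
        if abs(r) > r_top:
            removed.append(Removal(ranked[j], "r_top",
                                   f"|r|={abs(r):.3f} with top feature {top!r} > {r_top:g}"))
        else:
            survivors.append(j)
    # stage 2: greedy rank-ordered pairwise pass from the second survivor on
    a = 1
    while a < len(survivors):
        anchor = survivors[a]
        kept = survivors[: a + 1]
        for j in survivors[a + 1:]:
            r = corr[anchor, j]
            if abs(r) > r_pairwise:
                removed.append(Removal(
                    ranked[j], "r_pairwise",
                    f"|r|={abs(r):.3f} with anchor {ranked[anchor]!r} > {r_pairwise:g}"))
            else:
                kept.append(j)
        survivors = kept
        a += 1
    return SelectionResult(
        selected=tuple(ranked[j] for j in survivors),
        removed=tuple(removed),
        correlation_matrix=corr,
        correlation_features=tuple(ranked),
    )


def select_features(table: FeatureTable, config: SelectionConfig) -> SelectionResult:
    """Full selection pipeline: ranking filter -> r_top -> r_pairwise -> truncation."""
    removed: list[Removal] = []
    if config.method == "ebm":
        profile = ebm_importance(table, config)
        ranked = importance_filter(profile, config.importance_ratio)
        imp = dict(zip(profile.feature_names, profile.mean_importance))
        cutoff = config.importance_ratio * np.nanmax(profile.mean_importance)
        for name in table.feature_names:
            if name not in ranked:
                removed.append(Removal(
                    name, "importance_filter",
                    f"mean importance {imp[name]:.4g} < {cutoff:.4g} "
                    f"({config.importance_ratio:g} x max)"))
    else:
        t, p = _univariate_stats(table, welch=config.welch)
        order = _rank_order(np.abs(t), table.feature_names)
        ranked = []
        for j in order:
            name = table.feature_names[j]
            if p[j] > config.p_threshold:
                removed.append(Removal(
                    name, "p_filter", f"p={p[j]:.4g} > {config.p_threshold:g}"))
            else:
                ranked.append(name)
    if not ranked:
        raise EmptySelectionError(
            f"no feature survived the {config.method.upper()} ranking filter")
    pruned = correlation_prune(table, ranked, config.r_top, config.r_pairwise)
    removed.extend(pruned.removed)
    selected = list(pruned.selected)
    for name in selected[config.max_features:]:
        removed.append(Removal(
            name, "truncation", f"rank beyond max_features={config.max_features}"))
    selected = selected[: config.max_features]
    if not selected:
        raise EmptySelectionError("feature selection eliminated every feature")
    return SelectionResult(
        selected=tuple(selected),
        removed=tuple(removed),
        correlation_matrix=pruned.correlation_matrix,
        correlation_features=pruned.correlation_features,
    )
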