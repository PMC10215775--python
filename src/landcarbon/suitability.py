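"""Development-probability ("suitability") learning from land expansion.

For every land class, cells that newly became that class between two dates
are positive examples; an equal number of random other cells are negatives.
A random-forest classifier per class maps driving-factor rasters (terrain,
climate, accessibility, socio-economics) to a probability surface used by
the cellular automaton, and its impurity-based feature importances give the
per-class driving-factor contribution table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grid_core import LandUseGrid


@dataclass
class DriverStack:
    """Named continuous (or categorical) rasters on the land-use grid."""

    layers: dict[str, np.ndarray]
    categorical: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"driver layers do not share one shape: {sorted(shapes)}")
        for name, arr in self.layers.items():
            if np.nanstd(np.asarray(arr, dtype=float)) == 0:
                warnings.warn(f"driver layer {name!r} is constant", stacklevel=2)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def design_matrix(self) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
        """Flattened feature matrix with one-hot encoded categorical layers.

        Returns (X, feature_names, groups) where ``groups`` maps each driver
        name to its feature column indices (several for one-hot layers).
        """
        cols, names, groups = [], [], {}
        for name, arr in self.layers.items():
            flat = np.asarray(arr).ravel()
            if name in self.categorical:
                levels = np.unique(flat)
                idxs = []
                for lv in levels:
                    idxs.append(len(names))
                    cols.append((flat == lv).astype(float))
                    names.append(f"{name}={lv:g}")
                groups[name] = idxs
            else:
                groups[name] = [len(names)]
                cols.append(flat.astype(float))
                names.append(name)
        return np.column_stack(cols), names, groups


@dataclass
class SampleSet:
    """Per-class balanced expansion/non-expansion samples (flat cell indices)."""

    positives: dict[str, np.ndarray]
    negatives: dict[str, np.ndarray]
    no_expansion: tuple[str, ...]
    class_priors: dict[str, float]


def extract_expansion_samples(
    grid_t1: LandUseGrid,
    grid_t2: LandUseGrid,
    per_class_n: int = 2000,
    seed: int = 0,
) -> SampleSet:
    """Sample expansion cells (newly class k at t2) and random non-k cells.

    Classes with zero expansion cells are flagged; their suitability later
    falls back to the class's persistence frequency.  Deterministic under
    ``seed``.
    """
    if grid_t1.shape != grid_t2.shape:
        raise ValueError("grids must share one shape")
    rng = np.random.default_rng(seed)
    both = (grid_t1.valid_mask & grid_t2.valid_mask).ravel()
    c1, c2 = grid_t1.codes.ravel(), grid_t2.codes.ravel()
    positives, negatives, flagged, priors = {}, {}, [], {}
    n_valid = int(both.sum())
    for code, name in sorted(grid_t1.class_table.items()):
        new_k = both & (c2 == code) & (c1 != code)
        pos = np.flatnonzero(new_k)
        priors[name] = float(np.count_nonzero(both & (c2 == code))) / max(n_valid, 1)
        if pos.size == 0:
            flagged.append(name)
            positives[name] = pos
            negatives[name] = pos
            continue
        if pos.size > per_class_n:
            pos = np.sort(rng.choice(pos, size=per_class_n, replace=False))
        pool = np.flatnonzero(both & (c2 != code))
        n_neg = min(pos.size, pool.size)
        negatives[name] = np.sort(rng.choice(pool, size=n_neg, replace=False))
        positives[name] = pos
    return SampleSet(positives, negatives, tuple(flagged), priors)


@dataclass
class ModelSpec:
    """Ensemble-of-randomized-trees contract for the suitability learner."""

    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0


@dataclass
class SuitabilityResult:
    """Per-class probability surfaces plus the fitted per-class models."""

    surfaces: dict[str, np.ndarray]
    models: dict[str, RandomForestClassifier]
    feature_names: list[str]
    feature_groups: dict[str, list[int]]
    fallback: tuple[str, ...]


def fit_predict_suitability(
    samples: SampleSet, drivers: DriverStack, spec: ModelSpec = ModelSpec()
) -> SuitabilityResult:
    """Fit one expansion-vs-not forest per class and predict everywhere.

    Surfaces are probabilities in [0, 1] over the full grid; no-expansion
    classes get a constant surface at their persistence frequency.
    """
    X, feat_names, groups = drivers.design_matrix()
    trained = [c for c in samples.positives if c not in samples.no_expansion]
    if len(trained) < 1:
        warnings.warn(
            "no class has expansion samples; all suitability surfaces fall back "
            "to persistence frequencies",
            stacklevel=2,
        )
    surfaces, models = {}, {}
    for name in samples.positives:
        if name in samples.no_expansion:
            surfaces[name] = np.full(drivers.shape, samples.class_priors[name])
            continue
        pos, neg = samples.positives[name], samples.negatives[name]
        Xs = np.vstack([X[pos], X[neg]])
        ys = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
        if np.unique(ys).size < 2:
            raise ValueError(f"degenerate single-class sample for {name!r}")
        rf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            random_state=spec.seed,
            n_jobs=1,
        )
        rf.fit(Xs, ys)
        proba = rf.predict_proba(X)[:, list(rf.classes_).index(1.0)]
        surfaces[name] = proba.reshape(drivers.shape)
        models[name] = rf
    return SuitabilityResult(surfaces, models, feat_names, groups, samples.no_expansion)


def factor_contributions(result: SuitabilityResult) -> pd.DataFrame:
    """Normalised impurity importances per class × driver.

    One-hot feature columns are summed back to their source driver; each
    class row sums to one.  Only classes with a fitted model appear.
    """
    if not result.models:
        raise ValueError("no fitted models; cannot compute contributions")
    drivers = list(result.feature_groups)
    rows = {}
    for name, rf in result.models.items():
        imp = rf.feature_importances_
        agg = np.array([imp[result.feature_groups[d]].sum() for d in drivers])
        total = agg.sum()
        rows[name] = agg / total if total > 0 else np.full(len(drivers), 1 / len(drivers))
    return pd.DataFrame(rows, index=drivers).T
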