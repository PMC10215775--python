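"""Development scenarios as machine-checkable constraint sets.

Three presets mirror the study design:

* ``s1-trend`` — trend continuation: water frozen as a restricted
  conversion area, construction never converts away.
* ``s2-eco`` — ecological protection: conversions into forest/grassland
  up-weighted, eco-land (forest, grassland, water) → unused and
  construction expansion down-weighted.
* ``s3-comprehensive`` — comprehensive development: non-construction →
  construction down-weighted, unused → forest/grassland up-weighted,
  cultivated land conversions away down-weighted.

The published settings are qualitative; the up/down probability
multipliers default to 1.5 / 0.5 and are configurable.  Per-class
neighborhood weights come from the published scenario table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .grid_core import CLASSES
from .transitions import TransitionProbabilities

ECO_CLASSES = ("forest", "grassland", "water")

#: default qualitative-rule multipliers
UP_WEIGHT = 1.5
DOWN_WEIGHT = 0.5

PRESET_NAMES = ("s1-trend", "s2-eco", "s3-comprehensive")
_ALIASES = {"s1": "s1-trend", "s2": "s2-eco", "s3": "s3-comprehensive"}


@dataclass
class ScenarioConfig:
    """Constraint set for one development scenario.

    ``allowed`` is a boolean class×class matrix (diagonal always true);
    ``multipliers`` scales transition probabilities before renormalisation;
    ``restricted_mask`` freezes cells to their current class; ``demand`` is
    the per-class area target (km²) the CA must allocate.
    """

    name: str
    allowed: pd.DataFrame
    neighborhood_weights: pd.Series
    multipliers: pd.DataFrame
    restricted_mask: np.ndarray | None = None
    demand: pd.Series | None = None
    demand_tolerance_km2: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diag(self.allowed.values)):
            raise ValueError("self-transitions must always be allowed")
        w = self.neighborhood_weights.values
        if (w < 0).any() or (w > 1).any():
            raise ValueError("neighborhood weights must lie in [0, 1]")
        if (self.multipliers.values <= 0).any():
            raise ValueError("probability multipliers must be positive")

    @property
    def classes(self) -> list[str]:
        return list(self.allowed.index)

    def to_yaml(self, path: str) -> None:
        payload = {
            "name": self.name,
            "classes": self.classes,
            "neighborhood_weights": [float(v) for v in self.neighborhood_weights],
            "allowed": self.allowed.values.astype(bool).tolist(),
            "multipliers": self.multipliers.values.astype(float).tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str, restricted_mask=None) -> "ScenarioConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        classes = payload["classes"]
        return cls(
            name=payload["name"],
            allowed=pd.DataFrame(payload["allowed"], index=classes, columns=classes),
            neighborhood_weights=pd.Series(payload["neighborhood_weights"], index=classes),
            multipliers=pd.DataFrame(payload["multipliers"], index=classes, columns=classes),
            restricted_mask=restricted_mask,
        )


def _ones(classes) -> pd.DataFrame:
    return pd.DataFrame(1.0, index=classes, columns=classes)


def _all_true(classes) -> pd.DataFrame:
    return pd.DataFrame(True, index=classes, columns=classes)


def preset(
    name: str,
    masks: dict[str, np.ndarray] | None = None,
    classes=CLASSES,
    up_weight: float = UP_WEIGHT,
    down_weight: float = DOWN_WEIGHT,
) -> ScenarioConfig:
    """Build one of the three scenario presets.

    ``masks`` may supply per-class boolean rasters (e.g. ``{"water": ...}``)
    used to assemble the restricted area where the scenario calls for one.
    """
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in PRESET_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {PRESET_NAMES}")
    classes = list(classes)
    weights_table = datasets.neighborhood_weights()
    weights = weights_table.loc[key, classes].astype(float)
    allowed = _all_true(classes)
    mult = _ones(classes)
    restricted = None
    masks = masks or {}

    if key == "s1-trend":
        # construction is terminal; water is a restricted conversion area
        for other in classes:
            if other != "construction":
                allowed.loc["construction", other] = False
        if "water" in masks:
            restricted = np.asarray(masks["water"], dtype=bool)
    elif key == "s2-eco":
        for src in classes:
            for eco in ("forest", "grassland"):
                if src != eco:
                    mult.loc[src, eco] *= up_weight
        for eco in ECO_CLASSES:
            mult.loc[eco, "unused"] *= down_weight
        for src in classes:
            if src != "construction":
                mult.loc[src, "construction"] *= down_weight
    else:  # s3-comprehensive
        for src in classes:
            if src != "construction":
                mult.loc[src, "construction"] *= down_weight
        for eco in ("forest", "grassland"):
            mult.loc["unused", eco] *= up_weight
        for dst in classes:
            if dst != "cultivated":
                mult.loc["cultivated", dst] *= down_weight

    return ScenarioConfig(
        name=key,
        allowed=allowed,
        neighborhood_weights=weights,
        multipliers=mult,
        restricted_mask=restricted,
    )


def apply_constraints(
    tp: TransitionProbabilities, config: ScenarioConfig
) -> TransitionProbabilities:
    """Apply a scenario's transition constraints to base probabilities.

    Disallowed entries are zeroed, multipliers applied, rows renormalised to
    sum one.  A row whose every transition (diagonal included) is disallowed
    is an error.
    """
    P = tp.P.loc[config.classes, config.classes].astype(float)
    out = P.values * config.allowed.values * config.multipliers.values
    sums = out.sum(axis=1)
    dead = sums <= 0
    if dead.any():
        bad = [config.classes[i] for i in np.flatnonzero(dead)]
        raise ValueError(f"scenario {config.name!r} leaves no allowed transition for {bad}")
    out = out / sums[:, np.newaxis]
    return TransitionProbabilities(
        pd.DataFrame(out, index=config.classes, columns=config.classes), tp.period_years
    )
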