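"""Spectral indices and impervious-surface extraction.

Two normalised-difference indices drive the workflow: MNDWI
((green − swir1)/(green + swir1)) masks water and snow, and ENDISI
([(2·blue + swir2)/2 − (nir + red + swir1)] / [(2·blue + swir2)/2 +
(nir + red + swir1)]) highlights built surfaces while suppressing terrain
shadow.  Extraction thresholds default to 0 and can be set automatically by
Otsu's method; accuracy is assessed on randomly sampled verification points
against a reference mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transitions import ConfusionMatrix

BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")


@dataclass
class SpectralStack:
    """Aligned surface-reflectance bands (values nominally in [0, 1])."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir1: np.ndarray
    swir2: np.ndarray

    def __post_init__(self) -> None:
        shapes = {getattr(self, b).shape for b in BANDS}
        if len(shapes) > 1:
            raise ValueError("bands are not aligned on one grid")
        for b in BANDS:
            arr = np.asarray(getattr(self, b), dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -0.1 or finite.max() > 1.1):
                raise ValueError(f"band {b!r} outside plausible reflectance [-0.1, 1.1]")
            setattr(self, b, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / den, np.nan)
    return out


def mndwi(stack: SpectralStack) -> np.ndarray:
    """(green − swir1) / (green + swir1); NaN where the denominator is 0."""
    return _safe_ratio(stack.green - stack.swir1, stack.green + stack.swir1)


def endisi(stack: SpectralStack) -> np.ndarray:
    """Enhanced normalised difference impervious surface index.

    [(2·blue + swir2)/2 − (nir + red + swir1)] over the matching sum; NaN
    where the denominator is 0.
    """
    bright = (2.0 * stack.blue + stack.swir2) / 2.0
    veg = stack.nir + stack.red + stack.swir1
    return _safe_ratio(bright - veg, bright + veg)


def ndvi(stack: SpectralStack) -> np.ndarray:
    """(nir − red)/(nir + red): utility for when no external NDVI layer exists."""
    return _safe_ratio(stack.nir - stack.red, stack.nir + stack.red)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Bimodal (between-class variance maximising) threshold."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0 or v.min() == v.max():
        raise ValueError("cannot threshold a constant or empty surface")
    hist, edges = np.histogram(v, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1 - omega))
    k = int(np.nanargmax(sigma_b))
    return float(centers[k])


def extract_impervious(
    stack: SpectralStack,
    water_thresh: float | str = 0.0,
    isa_thresh: float | str = 0.0,
) -> np.ndarray:
    """Binary impervious mask: water/snow masked by MNDWI, then ENDISI cut.

    Either threshold may be the string ``"otsu"`` for an automatic bimodal
    split.  Returns a float array: 1 impervious, 0 pervious, NaN masked.
    """
    wi = mndwi(stack)
    ei = endisi(stack)
    if water_thresh == "otsu":
        water_thresh = otsu_threshold(wi)
    if isa_thresh == "otsu":
        isa_thresh = otsu_threshold(ei[~(wi > water_thresh)])
    mask = np.where(ei > isa_thresh, 1.0, 0.0)
    mask[wi > water_thresh] = np.nan  # water/snow removed from the domain
    mask[~np.isfinite(ei)] = np.nan
    return mask


def point_accuracy(
    mask: np.ndarray, reference: np.ndarray, n_points: int = 700, seed: int = 0
) -> ConfusionMatrix:
    """Random-point accuracy check of a binary mask against a reference.

    Samples ``n_points`` jointly valid cells without replacement (seeded)
    and cross-tabulates them; OA and Kappa come from the confusion matrix.
    """
    mask = np.asarray(mask, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mask.shape != reference.shape:
        raise ValueError("masks are not aligned")
    valid = np.flatnonzero(np.isfinite(mask.ravel()) & np.isfinite(reference.ravel()))
    if n_points > valid.size:
        raise ValueError(f"n_points={n_points} exceeds {valid.size} valid cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(valid, size=n_points, replace=False)
    ref = reference.ravel()[pick].astype(int)
    sim = mask.ravel()[pick].astype(int)
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (ref, sim), 1)
    labels = ["pervious", "impervious"]
    return ConfusionMatrix(pd.DataFrame(counts, index=labels, columns=labels))
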