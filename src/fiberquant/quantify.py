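"""Per-fiber, per-nucleus and cytoplasmic MFI extraction and normalization.

The fiber table passes through three normalization stages, in a fixed
order, mirroring the quantitative MyHC immunohistology convention:

1. background correction: subtract a per-channel scalar background
   (default: median intensity of the non-fiber pixels), clamped at 0;
2. fluorophore normalization: divide each channel by its section-wide
   mean over fibers, so conjugate brightness differences between the four
   MyHC antibodies cancel and isotypes become comparable;
3. per-fiber sum normalization: divide each fiber's four scaled MyHC
   values by their sum, yielding a compositional fraction per isotype.

Stage columns in the table: ``raw_<ch>``, ``corrected_<ch>``,
``scaled_<ch>``, ``frac_<ch>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigurationError
from .section import FiberLabelMap, GFP, MultiChannelSection, MYHC_CHANNELS

__all__ = [
    "BackgroundEstimate",
    "fiber_mfi",
    "estimate_background",
    "correct_background",
    "normalize_fluorophores",
    "normalize_fiber_sum",
    "flag_gfp_positive",
    "nuclear_mfi",
    "cytoplasmic_mfi",
    "fiber_table_pipeline",
]


@dataclass
class BackgroundEstimate:
    """Scalar background per channel plus the method that produced it."""

    values: Mapping[str, float]
    method: str = "median_of_background_pixels"

    def __post_init__(self) -> None:
        for ch, v in self.values.items():
            if v < 0:
                raise ValueError(f"background for {ch!r} must be >= 0")

    def __getitem__(self, channel: str) -> float:
        return float(self.values[channel])


def fiber_mfi(
    section: MultiChannelSection,
    label_map: FiberLabelMap,
    channels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Raw per-fiber mean fluorescence intensities.

    Returns one row per fiber with ``fiber_id``, ``csa_um2`` and a
    ``raw_<channel>`` column per requested channel (default: all channels
    of the section).
    """
    if label_map.labels.shape != section.shape:
        raise ValueError("label map and section rasters differ in shape")
    channels = list(channels) if channels is not None else sorted(section.channels)
    missing = [c for c in channels if c not in section]
    if missing:
        raise ConfigurationError(f"section has no channel(s) {missing}")
    ids = label_map.fiber_ids
    table = pd.DataFrame({"fiber_id": ids.astype(np.int64)})
    counts = np.bincount(label_map.labels.ravel())
    table["csa_um2"] = counts[ids] * label_map.pixel_size_um**2
    for ch in channels:
        if ids.size:
            table[f"raw_{ch}"] = ndimage.mean(section[ch], label_map.labels, index=ids)
        else:
            table[f"raw_{ch}"] = np.array([], dtype=float)
    return table


def estimate_background(
    section: MultiChannelSection,
    label_map: FiberLabelMap,
    channels: Iterable[str] | None = None,
    fixed: Mapping[str, float] | None = None,
) -> BackgroundEstimate:
    """Per-channel background: median intensity of non-fiber (label 0) pixels.

    ``fixed`` overrides the estimate for the listed channels with given
    values (the fixed-threshold convention used for collagen carries over
    to backgrounds when a calibrated value is preferred).
    """
    channels = list(channels) if channels is not None else sorted(section.channels)
    bg_mask = label_map.labels == 0
    if not bg_mask.any():
        raise ValueError("label map has no background pixels to estimate from")
    values = {}
    for ch in channels:
        if fixed is not None and ch in fixed:
            values[ch] = float(fixed[ch])
        else:
            values[ch] = float(np.median(section[ch][bg_mask]))
    method = "median_of_background_pixels" if not fixed else "median_with_fixed_overrides"
    return BackgroundEstimate(values=values, method=method)


def correct_background(table: pd.DataFrame, background: BackgroundEstimate) -> pd.DataFrame:
    """``corrected_<ch> = max(raw_<ch> - background[ch], 0)``.

    Negative differences are clamped at zero: MFIs are physical
    intensities and a fiber cannot be darker than empty slide.
    """
    out = table.copy()
    for col in table.columns:
        if not col.startswith("raw_"):
            continue
        ch = col[len("raw_"):]
        if ch in background.values:
            out[f"corrected_{ch}"] = np.clip(table[col] - background[ch], 0.0, None)
    return out


def normalize_fluorophores(
    table: pd.DataFrame, channels: Iterable[str] = MYHC_CHANNELS
) -> pd.DataFrame:
    """Divide each channel by its mean over the section's fibers.

    After this stage every channel's fiber mean equals 1, so a global
    rescaling of any one raster (different fluorophore brightness,
    exposure, detector gain) has no effect downstream.
    """
    out = table.copy()
    if len(table) == 0:
        raise ValueError("fluorophore normalization needs at least one fiber")
    for ch in channels:
        col = f"corrected_{ch}"
        if col not in table.columns:
            raise ConfigurationError(f"missing corrected-stage column {col!r}")
        mean = float(table[col].mean())
        if mean <= 0:
            raise ValueError(
                f"channel {ch!r} has zero section mean; cannot normalize fluorophores"
            )
        out[f"scaled_{ch}"] = table[col] / mean
    return out


def normalize_fiber_sum(
    table: pd.DataFrame, channels: Iterable[str] = MYHC_CHANNELS
) -> pd.DataFrame:
    """Per-fiber compositional fractions of the scaled MyHC channels.

    Fibers whose scaled values sum to zero cannot be typed; they are
    flagged (``zero_sum = True``) and their fractions left as NaN rather
    than fabricating a composition.
    """
    out = table.copy()
    cols = [f"scaled_{ch}" for ch in channels]
    for col in cols:
        if col not in table.columns:
            raise ConfigurationError(f"missing scaled-stage column {col!r}")
    scaled = table[cols].to_numpy(dtype=float)
    sums = scaled.sum(axis=1)
    zero = sums == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = scaled / sums[:, None]
    fracs[zero] = np.nan
    for i, ch in enumerate(channels):
        out[f"frac_{ch}"] = fracs[:, i]
    out["zero_sum"] = zero
    return out


def flag_gfp_positive(
    table: pd.DataFrame,
    background: BackgroundEstimate,
    gfp_channel: str = GFP,
    k: float = 2.0,
) -> pd.DataFrame:
    """Mark fibers whose raw GFP MFI exceeds k x GFP background (default k=2)."""
    col = f"raw_{gfp_channel}"
    if col not in table.columns:
        raise ConfigurationError(f"table lacks {col!r}; run fiber_mfi with the GFP channel")
    out = table.copy()
    out["gfp_positive"] = table[col] > k * background[gfp_channel]
    return out


def nuclear_mfi(channel: np.ndarray, nucleus_map: FiberLabelMap) -> pd.DataFrame:
    """Mean probe intensity per segmented nucleus."""
    img = np.asarray(channel, dtype=float)
    if img.shape != nucleus_map.labels.shape:
        raise ValueError("channel and nucleus map differ in shape")
    ids = nucleus_map.fiber_ids
    if ids.size == 0:
        return pd.DataFrame({"nucleus_id": [], "mfi": []}).astype(
            {"nucleus_id": np.int64, "mfi": float}
        )
    return pd.DataFrame(
        {
            "nucleus_id": ids.astype(np.int64),
            "mfi": ndimage.mean(img, nucleus_map.labels, index=ids),
        }
    )


def cytoplasmic_mfi(channel: np.ndarray, nucleus_map: FiberLabelMap) -> float:
    """Mean intensity over all pixels outside segmented nuclei."""
    img = np.asarray(channel, dtype=float)
    if img.shape != nucleus_map.labels.shape:
        raise ValueError("channel and nucleus map differ in shape")
    outside = nucleus_map.labels == 0
    if not outside.any():
        raise ValueError("nuclei cover the entire field; no cytoplasmic compartment")
    return float(img[outside].mean())


def fiber_table_pipeline(
    section: MultiChannelSection,
    label_map: FiberLabelMap,
    channels: Iterable[str] | None = None,
    myhc_channels: Iterable[str] = MYHC_CHANNELS,
    background_fixed: Mapping[str, float] | None = None,
    gfp_channel: str | None = None,
    gfp_k: float = 2.0,
) -> pd.DataFrame:
    """Full raw -> corrected -> scaled -> fraction fiber table in one call."""
    table = fiber_mfi(section, label_map, channels)
    background = estimate_background(section, label_map, channels, fixed=background_fixed)
    table = correct_background(table, background)
    table = normalize_fluorophores(table, myhc_channels)
    table = normalize_fiber_sum(table, myhc_channels)
    if gfp_channel is not None and f"raw_{gfp_channel}" in table.columns:
        table = flag_gfp_positive(table, background, gfp_channel, k=gfp_k)
    return table
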