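"""Regional ventilation metrics from reconstructed EIT pixel time series.

Coordinates: row 0 is the most ventral row, column 0 the subject's right
side; pixel coordinates are normalised to [0, 100] over the lung-mask
bounding box, so a center of ventilation (CoV) of 0% along the
ventral-dorsal axis is the most ventral extreme and 100% the most dorsal
(respectively right -> left for the RL axis). CoV is the amplitude-weighted
centroid of the tidal image; values below the uniform-ventilation reference
indicate preferential ventilation of the ventral (non-gravity-dependent)
lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import EITFrameSeries

__all__ = [
    "TidalImage", "tidal_image", "center_of_ventilation", "uniform_cov",
    "relative_aeration", "weighted_mean_relative_aeration",
    "unventilated_fraction", "standard_regions", "regional_summary",
]


@dataclass
class TidalImage:
    """Per-pixel tidal amplitude image with its lung mask."""

    amplitude: np.ndarray  # 2D, >= 0 after rectification
    lung_mask: np.ndarray  # 2D boolean
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if self.amplitude.shape != self.lung_mask.shape:
            raise ValueError("amplitude and lung_mask shapes must match")
        if np.any(self.amplitude < 0):
            raise ValueError("tidal amplitudes must be >= 0 (rectified)")


def tidal_image(frames: EITFrameSeries, breath_window: tuple[float, float] | None = None,
                prominence_fraction: float = 0.25) -> TidalImage:
    """Average end-inspiratory minus end-expiratory pixel image.

    Breaths are located on the global (lung-sum) signal: end-inspiration at
    its peaks, end-expiration at the preceding troughs (peak prominence
    ``prominence_fraction`` of the global signal range). The per-pixel
    amplitude is averaged over all complete breaths in ``breath_window``
    (whole series by default); negative pixels are clipped to zero with the
    clip count reported in ``meta['n_clipped']``.
    """
    sel = np.ones(frames.times.size, dtype=bool)
    if breath_window is not None:
        sel = (frames.times >= breath_window[0]) & (frames.times <= breath_window[1])
    g = frames.global_signal()[sel]
    f = frames.frames[sel]
    if g.size < 3:
        raise ValueError("window too short to contain a breath")
    rng_g = float(g.max() - g.min())
    if rng_g <= 0:
        raise ValueError("global signal is flat: no breath in window")
    peaks, _ = find_peaks(g, prominence=prominence_fraction * rng_g)
    troughs, _ = find_peaks(-g, prominence=prominence_fraction * rng_g)
    troughs = np.concatenate([[0], troughs])  # series starts at end-expiration
    pairs = []
    for pk in peaks:
        prior = troughs[troughs < pk]
        if prior.size:
            pairs.append((int(prior[-1]), int(pk)))
    if not pairs:
        raise ValueError("no complete breath found in window")
    amp = np.mean([f[pk] - f[tr] for tr, pk in pairs], axis=0)
    n_clipped = int(np.sum(amp < 0))
    amp = np.clip(amp, 0.0, None)
    amp[~frames.lung_mask] = 0.0
    return TidalImage(amplitude=amp, lung_mask=frames.lung_mask,
                      meta={"n_breaths": len(pairs), "n_clipped": n_clipped})


def _axis_coords(mask: np.ndarray, axis: str) -> np.ndarray:
    """Normalised [0, 100] pixel-centre coordinates over the mask bounding box."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if axis.upper() == "VD":
        idx = np.flatnonzero(rows)
        coord = np.full(mask.shape[0], np.nan)
        coord[idx[0]:idx[-1] + 1] = (
            (np.arange(idx[0], idx[-1] + 1) - idx[0] + 0.5)
            / (idx[-1] - idx[0] + 1) * 100.0)
        return np.broadcast_to(coord[:, None], mask.shape)
    if axis.upper() == "RL":
        idx = np.flatnonzero(cols)
        coord = np.full(mask.shape[1], np.nan)
        coord[idx[0]:idx[-1] + 1] = (
            (np.arange(idx[0], idx[-1] + 1) - idx[0] + 0.5)
            / (idx[-1] - idx[0] + 1) * 100.0)
        return np.broadcast_to(coord[None, :], mask.shape)
    raise ValueError("axis must be 'VD' or 'RL'")


def center_of_ventilation(image: TidalImage, axis: str = "VD",
                          method: str = "centroid") -> float:
    """Center of ventilation (%) along the gravity (VD) or right-left axis.

    ``centroid`` (default) is the amplitude-weighted mean coordinate — the
    standard EIT CoV. ``log`` gives the literal log-scale geometric mean of
    the coordinates (weights unchanged), provided for comparison.
    Invariant to global amplitude scaling; an all-zero image raises.
    """
    w = image.amplitude[image.lung_mask]
    x = _axis_coords(image.lung_mask, axis)[image.lung_mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero tidal image: CoV undefined")
    if method == "centroid":
        return float((w * x).sum() / total)
    if method == "log":
        return float(np.exp((w * np.log(x)).sum() / total))
    raise ValueError(f"unknown CoV method {method!r}")


def uniform_cov(lung_mask: np.ndarray, axis: str = "VD") -> float:
    """CoV (%) of a uniformly ventilated lung mask (the reference line)."""
    mask = np.asarray(lung_mask, dtype=bool)
    x = _axis_coords(mask, axis)[mask]
    return float(x.mean())


def relative_aeration(image: TidalImage, regions: dict[str, np.ndarray]) -> dict[str, float]:
    """Region signal share divided by region pixel share (1.0 = uniform).

    ``regions`` must partition the lung mask; empty regions raise.
    """
    union = np.zeros_like(image.lung_mask)
    for name, m in regions.items():
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError(f"region {name!r} is empty")
        if np.any(union & m):
            raise ValueError("regions overlap: not a partition")
        union |= m
    if not np.array_equal(union, image.lung_mask):
        raise ValueError("regions must partition the lung mask exactly")
    total_sig = image.amplitude[image.lung_mask].sum()
    total_pix = int(image.lung_mask.sum())
    if total_sig <= 0:
        raise ValueError("all-zero tidal image")
    out = {}
    for name, m in regions.items():
        m = np.asarray(m, dtype=bool)
        share_sig = image.amplitude[m].sum() / total_sig
        share_pix = m.sum() / total_pix
        out[name] = float(share_sig / share_pix)
    return out


def weighted_mean_relative_aeration(image: TidalImage,
                                    regions: dict[str, np.ndarray]) -> float:
    """Pixel-share-weighted mean of relative aeration; identically 1 for any
    partition (sum rule used as a pipeline self-check)."""
    ratios = relative_aeration(image, regions)
    total_pix = int(image.lung_mask.sum())
    return float(sum(
        ratios[name] * np.asarray(m, dtype=bool).sum() / total_pix
        for name, m in regions.items()))


def unventilated_fraction(image: TidalImage,
                          threshold_fraction: float = 0.10) -> float:
    """Percentage of lung pixels with tidal amplitude below threshold.

    The threshold is ``threshold_fraction`` x the mean *nonzero* lung-pixel
    amplitude (silent-space convention); comparison is strict, so a
    threshold fraction of 0 returns 0%. The definition is recorded in the
    returned image metadata by :func:`regional_summary`.
    """
    amps = image.amplitude[image.lung_mask]
    if amps.size == 0 or amps.max() <= 0:
        raise ValueError("all-zero tidal image")
    nonzero = amps[amps > 0]
    thr = threshold_fraction * nonzero.mean()
    return float(100.0 * np.mean(amps < thr))


def standard_regions(lung_mask: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """Default partitions: ventral/central/dorsal thirds (bounding-box rows)
    and right/left halves (bounding-box columns)."""
    mask = np.asarray(lung_mask, dtype=bool)
    rows = np.flatnonzero(np.any(mask, axis=1))
    r0, r1 = rows[0], rows[-1] + 1
    cuts = np.linspace(r0, r1, 4).round().astype(int)
    names = ("ventral", "central", "dorsal")
    vd = {}
    for k, name in enumerate(names):
        m = np.zeros_like(mask)
        m[cuts[k]:cuts[k + 1], :] = True
        vd[name] = mask & m
    cols = np.flatnonzero(np.any(mask, axis=0))
    mid = int(round((cols[0] + cols[-1] + 1) / 2))
    right = np.zeros_like(mask)
    right[:, :mid] = True
    rl = {"right": mask & right, "left": mask & ~right}
    return {"VD": vd, "RL": rl}


def regional_summary(image: TidalImage,
                     unventilated_threshold: float = 0.10) -> dict:
    """Figure-style regional summary: CoV (VD, RL) with uniform references,
    relative aeration per standard region, and unventilated fraction."""
    regions = standard_regions(image.lung_mask)
    out = {
        "CoV_VD": center_of_ventilation(image, "VD"),
        "CoV_RL": center_of_ventilation(image, "RL"),
        "uniform_CoV_VD": uniform_cov(image.lung_mask, "VD"),
        "uniform_CoV_RL": uniform_cov(image.lung_mask, "RL"),
        "unventilated_pct": unventilated_fraction(image, unventilated_threshold),
        "unventilated_threshold_definition":
            f"amplitude < {unventilated_threshold} x mean nonzero lung amplitude",
    }
    for name, ratio in relative_aeration(image, regions["VD"]).items():
        out[f"rel_aeration_{name}"] = ratio
    for name, ratio in relative_aeration(image, regions["RL"]).items():
        out[f"rel_aeration_{name}"] = ratio
    return out
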