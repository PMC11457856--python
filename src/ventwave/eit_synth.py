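"""Synthetic regional ventilation maps and EIT-style frame series.

The generator stands in for the reconstructed pixel tidal-ventilation images
produced by an EIT system (48 frames/s): each lung pixel carries a fixed
share of the global volume signal, so the frame series is exactly volume-
conservative before noise. Reconstruction from electrode voltages is out of
scope; the pipeline starts at reconstructed images.
"""

from __future__ import annotations

import numpy as np

from .core import EITFrameSeries, RegionalMap, WaveformRecording

__all__ = ["make_regional_map", "synthesize_eit"]


def _elliptical_lungs(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of two elliptical lung fields (row 0 = ventral,
    col 0 = subject's right)."""
    nr, nc = shape
    r = (np.arange(nr) + 0.5) / nr  # 0 ventral -> 1 dorsal
    c = (np.arange(nc) + 0.5) / nc  # 0 right -> 1 left
    rr, cc = np.meshgrid(r, c, indexing="ij")
    right = ((rr - 0.5) / 0.38) ** 2 + ((cc - 0.27) / 0.20) ** 2 <= 1.0
    left = ((rr - 0.5) / 0.38) ** 2 + ((cc - 0.73) / 0.20) ** 2 <= 1.0
    return right | left


def make_regional_map(shape: tuple[int, int] = (32, 32),
                      right_share: float = 0.55,
                      ventral_dorsal_bias: float = 0.3,
                      heterogeneity_cv: float = 0.0,
                      silent_fraction: float = 0.0,
                      seed: int | None = None) -> RegionalMap:
    """Build a lamb-like regional ventilation map.

    Defaults emulate the heterogeneous pattern reported for preterm lungs:
    ventilation favouring the right lung (``right_share`` of the signal) and
    the non-gravity-dependent (ventral) regions (linear gradient of relative
    strength ``ventral_dorsal_bias``). Optional multiplicative log-normal
    pixel heterogeneity and a fraction of unventilated (silent) lung pixels,
    both seeded.

    Parameters
    ----------
    right_share
        Fraction of total ventilation assigned to the right lung.
    ventral_dorsal_bias
        0 = uniform along the gravity axis; 0.3 means the most ventral row
        is weighted ~1.3x and the most dorsal ~0.7x before normalisation.
    silent_fraction
        Fraction of lung pixels zeroed (chosen at random, seeded) to emulate
        unventilated regions.
    """
    if not 0 < right_share < 1:
        raise ValueError("right_share must be in (0, 1)")
    mask = _elliptical_lungs(shape)
    nr, nc = shape
    rowfrac = ((np.arange(nr) + 0.5) / nr)[:, None] * np.ones((1, nc))
    w = 1.0 + ventral_dorsal_bias * (0.5 - rowfrac) * 2.0
    w = np.where(mask, np.maximum(w, 0.0), 0.0)

    rng = np.random.default_rng(seed)
    if heterogeneity_cv > 0:
        if seed is None:
            raise ValueError("seed required for heterogeneous maps")
        sigma = np.sqrt(np.log1p(heterogeneity_cv ** 2))
        w = w * np.where(mask, rng.lognormal(0.0, sigma, shape), 0.0)
    if silent_fraction > 0:
        if seed is None:
            raise ValueError("seed required for silent-region maps")
        lung_idx = np.flatnonzero(mask)
        n_silent = int(round(silent_fraction * lung_idx.size))
        chosen = rng.choice(lung_idx, size=n_silent, replace=False)
        w.flat[chosen] = 0.0

    cols = (np.arange(nc) + 0.5) / nc
    right_mask = mask & (cols[None, :] < 0.5)
    left_mask = mask & ~(cols[None, :] < 0.5)
    sr, sl = w[right_mask].sum(), w[left_mask].sum()
    if sr > 0 and sl > 0:
        w[right_mask] *= right_share / sr
        w[left_mask] *= (1.0 - right_share) / sl
    else:  # degenerate single-lung map: just normalise
        w /= w.sum()
    w /= w.sum()
    return RegionalMap(regional_share=w, lung_mask=mask)


def synthesize_eit(recording: WaveformRecording, rmap: RegionalMap,
                   frame_rate: float = 48.0, seed: int | None = None,
                   noise_sd: float = 0.0) -> EITFrameSeries:
    """Project a global volume signal onto a regional map at EIT frame rate.

    Each frame's pixel value is ``regional_share * volume(t) * pixel_gain``
    plus optional seeded Gaussian noise; the recording's volume channel is
    resampled to ``frame_rate`` by linear interpolation. Noise-free, the sum
    over lung pixels reproduces the global volume signal exactly when gains
    are 1 (conservation property used by the calibration tests).
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("seed is mandatory when noise is enabled")
    n_frames = int(np.floor(recording.duration * frame_rate)) + 1
    times = recording.time[0] + np.arange(n_frames) / frame_rate
    vol = np.interp(times, recording.time, recording.volume)
    gain = rmap.pixel_gain if rmap.pixel_gain is not None else 1.0
    frames = vol[:, None, None] * (rmap.regional_share * gain)[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return EITFrameSeries(
        frames=frames, times=times, frame_rate=frame_rate,
        lung_mask=rmap.lung_mask,
        meta={"source_subject": recording.subject_id, "noise_sd": noise_sd,
              "seed": seed},
    )
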