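"""Tissue masks, Gaussian smoothing, SUVR normalization and the bandpass utility.

SUVR (standardized uptake value ratio) divides a summed PET uptake volume by
the mean of a white-matter reference region, then keeps gray-matter voxels
with SUVR strictly above 1.  The reference region requires WM probability
> 0.9 together with 8 mm-smoothed GM and CSF probabilities < 0.05; all three
criteria are strict inequalities.  Boundary handling for smoothing is plain
zero-padding, which keeps the operation linear; quantitative checks should
therefore stay on interior voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_volumes import BoldSeries, Mask, Volume3D, check_grid_compatibility

#: FWHM = sigma * 2*sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SuvrMap:
    """Unitless uptake ratio per voxel; NaN outside the analysis mask."""

    grid: "VolumeGrid"
    values: np.ndarray
    reference_mean: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("value array shape must equal grid shape")
        if self.reference_mean <= 0:
            raise ValueError("reference mean must be positive")

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _sigma_voxels(grid, fwhm_mm: float) -> tuple[float, float, float]:
    return tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in grid.voxel_size_mm)


def gaussian_smooth(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable Gaussian smoothing with zero-padded boundaries.

    ``fwhm_mm`` is converted per axis to sigma = FWHM / (voxel * 2*sqrt(2 ln 2)),
    so anisotropic voxels are handled; FWHM 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return Volume3D(vol.grid, vol.values.copy())
    out = ndimage.gaussian_filter(
        vol.values, sigma=_sigma_voxels(vol.grid, fwhm_mm), mode="constant", cval=0.0
    )
    return Volume3D(vol.grid, out)


def masked_gaussian_smooth(values: np.ndarray, present: np.ndarray, grid, fwhm_mm: float) -> np.ndarray:
    """Gaussian smoothing restricted to present voxels.

    Kernel weights are renormalized over the present set (smooth(v*m)/smooth(m)),
    so a constant map stays constant and missing voxels neither contribute nor
    receive values.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    out = np.full(values.shape, np.nan)
    if fwhm_mm == 0:
        out[present] = values[present]
        return out
    sigma = _sigma_voxels(grid, fwhm_mm)
    filled = np.where(present, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(present.astype(np.float64), sigma=sigma, mode="constant", cval=0.0)
    ok = present & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def _check_probability(vol: Volume3D, name: str) -> None:
    v = vol.values
    if np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9:
        raise ValueError(f"{name} probabilities must lie in [0, 1]")


def white_matter_reference_mask(
    wm_prob: Volume3D, gm_prob: Volume3D, csf_prob: Volume3D, fwhm_mm: float = 8.0
) -> Mask:
    """Reference region: WM > 0.9 with 8 mm-smoothed GM < 0.05 and CSF < 0.05."""
    check_grid_compatibility([wm_prob, gm_prob, csf_prob])
    for vol, name in ((wm_prob, "WM"), (gm_prob, "GM"), (csf_prob, "CSF")):
        _check_probability(vol, name)
    gm_s = gaussian_smooth(gm_prob, fwhm_mm).values
    csf_s = gaussian_smooth(csf_prob, fwhm_mm).values
    member = (wm_prob.values > 0.9) & (gm_s < 0.05) & (csf_s < 0.05)
    return Mask(wm_prob.grid, member).require_nonempty("white-matter reference region")


def gray_matter_mask(gm_prob: Volume3D, threshold: float = 0.10) -> Mask:
    """Gray-matter analysis mask: probability strictly above ``threshold`` (default 10%)."""
    _check_probability(gm_prob, "GM")
    return Mask(gm_prob.grid, gm_prob.values > threshold).require_nonempty("gray-matter mask")


def compute_suvr(pet_summed: Volume3D, reference: Mask) -> SuvrMap:
    """Divide every voxel by the mean uptake inside the reference region."""
    check_grid_compatibility([pet_summed, reference])
    reference.require_nonempty("reference region")
    ref_mean = float(np.nanmean(pet_summed.values[reference.membership]))
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(f"reference-region mean must be positive, got {ref_mean}")
    return SuvrMap(pet_summed.grid, pet_summed.values / ref_mean, reference_mean=ref_mean)


def threshold_suvr(suvr: SuvrMap, gm: Mask, min_value: float = 1.0) -> SuvrMap:
    """Keep values only inside GM and strictly above ``min_value``; elsewhere missing."""
    check_grid_compatibility([suvr, gm])
    gm.require_nonempty("gray-matter mask")
    keep = gm.membership & (suvr.values > min_value) & ~np.isnan(suvr.values)
    if not keep.any():
        raise ValueError("no voxel survives the SUVR threshold inside gray matter")
    out = np.full(suvr.values.shape, np.nan)
    out[keep] = suvr.values[keep]
    return SuvrMap(suvr.grid, out, reference_mean=suvr.reference_mean)


def bandpass_filter(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldSeries:
    """Frequency-domain bandpass with a cosine roll-off over one frequency bin.

    The mean (0 Hz) is always removed.  Components outside [low, high] are
    suppressed, components well inside the band pass essentially unchanged.
    """
    nyquist = 0.5 / bold.sampling_interval_s
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"need 0 <= low < high < Nyquist ({nyquist:.4f} Hz); got [{low_hz}, {high_hz}]"
        )
    n = bold.n_timepoints
    if n < 16:
        raise ValueError("bandpass needs at least 16 timepoints")
    out = np.empty_like(bold.data)
    _bandpass_inplace(bold.data.reshape(-1, n), out.reshape(-1, n),
                      bold.sampling_interval_s, low_hz, high_hz)
    return BoldSeries(bold.grid, out, sampling_interval_s=bold.sampling_interval_s)


def bandpass_weights(n: int, dt: float, low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """Per-rfft-bin gain of the bandpass: 1 in-band, cosine roll-off over one bin, 0 at DC."""
    freqs = np.fft.rfftfreq(n, d=dt)
    df = freqs[1] - freqs[0]
    w = np.zeros_like(freqs)
    core = (freqs >= low_hz) & (freqs <= high_hz)
    w[core] = 1.0
    lo_edge = (freqs >= low_hz - df) & (freqs < low_hz)
    w[lo_edge] = 0.5 * (1 + np.cos(np.pi * (low_hz - freqs[lo_edge]) / df))
    hi_edge = (freqs > high_hz) & (freqs <= high_hz + df)
    w[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - high_hz) / df))
    w[0] = 0.0
    return w


def _bandpass_inplace(flat_in: np.ndarray, flat_out: np.ndarray, dt, low_hz, high_hz) -> None:
    n = flat_in.shape[1]
    w = bandpass_weights(n, dt, low_hz, high_hz)
    spec = np.fft.rfft(flat_in, axis=1)
    spec *= w[None, :]
    flat_out[:] = np.fft.irfft(spec, n=n, axis=1)
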