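"""Per-cube preprocessing: saturation masking, 2x spatial downsampling,
linear baseline correction and vector normalization.

The sequence runs along the spatial dimensions first (mask, downsample)
and then along the spectral dimension per pixel (baseline, normalization),
yielding one unit-norm spectrum per retained downsampled pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis import SpectralAxis
from .cube_io import HyperCube

__all__ = [
    "PixelSpectraMatrix",
    "DegeneratePixelError",
    "mask_saturated",
    "downsample2",
    "baseline_correct",
    "vector_normalize",
    "preprocess",
]

NORM_EPS = 1e-12


class DegeneratePixelError(ValueError):
    """A pixel spectrum has (near-)zero Euclidean norm and cannot be normalized."""


@dataclass
class PixelSpectraMatrix:
    """Preprocessed pixel spectra of one image.

    ``spectra`` is (n_pixels, n_channels) with unit-L2-norm rows;
    ``pixel_index`` holds the (row, col) of each spectrum in the
    downsampled grid; ``shape`` is that grid's shape; ``meta`` carries
    image/mouse/genotype provenance.
    """

    spectra: np.ndarray
    pixel_index: np.ndarray
    shape: tuple[int, int]
    axis: SpectralAxis
    meta: dict

    def __len__(self) -> int:
        return self.spectra.shape[0]


def mask_saturated(cube: HyperCube, sat_value: float | None = None) -> HyperCube:
    """Mask every pixel reaching ``sat_value`` in at least one channel.

    Existing mask entries are preserved (logical OR). ``sat_value`` defaults
    to the cube's metadata value.
    """
    if sat_value is None:
        sat_value = cube.meta.get("sat_value")
        if sat_value is None:
            raise ValueError("sat_value missing from arguments and cube metadata")
    sat_value = float(sat_value)
    if sat_value <= 0:
        raise ValueError(f"sat_value must be positive, got {sat_value}")
    hot = np.any(cube.values >= sat_value, axis=2)
    return HyperCube(
        values=cube.values,
        axis=cube.axis,
        sat_mask=cube.sat_mask | hot,
        meta=dict(cube.meta),
    )


def downsample2(cube: HyperCube) -> HyperCube:
    """Halve the spatial dimensions by averaging 2x2 blocks per channel.

    Block means are taken over unmasked input pixels only; an output pixel
    is masked iff all four inputs are masked.  Odd trailing rows/columns
    are trimmed first.
    """
    h, w, c = cube.values.shape
    h2, w2 = h - h % 2, w - w % 2
    values = cube.values[:h2, :w2]
    mask = cube.sat_mask[:h2, :w2]

    blocks = values.reshape(h2 // 2, 2, w2 // 2, 2, c)
    keep = (~mask).reshape(h2 // 2, 2, w2 // 2, 2).astype(np.float64)
    counts = keep.sum(axis=(1, 3))
    sums = (blocks * keep[..., None]).sum(axis=(1, 3))
    out_mask = counts == 0
    safe = np.where(out_mask, 1.0, counts)
    means = sums / safe[..., None]
    means[out_mask] = 0.0
    return HyperCube(
        values=means,
        axis=cube.axis,
        sat_mask=out_mask,
        meta=dict(cube.meta),
    )


def baseline_correct(
    spectrum: np.ndarray, axis: SpectralAxis, anchor_m: int = 3
) -> np.ndarray:
    """Subtract a two-anchor linear baseline in wavenumber.

    The line passes through (mean wavenumber, mean intensity) of the first
    ``anchor_m`` and last ``anchor_m`` channels — the signal-poor edges of
    the CH-stretch window.  Accepts a single spectrum or an (n, C) matrix;
    negative results are kept.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    wn = axis.wavenumbers_cm1
    c = wn.size
    if anchor_m < 1 or c < 2 * anchor_m:
        raise ValueError(
            f"need at least {2 * anchor_m} channels for anchor_m={anchor_m}, got {c}"
        )
    if spectrum.shape[-1] != c:
        raise ValueError(f"spectrum has {spectrum.shape[-1]} channels, axis has {c}")
    x_lo, x_hi = wn[:anchor_m].mean(), wn[-anchor_m:].mean()
    y_lo = spectrum[..., :anchor_m].mean(axis=-1)
    y_hi = spectrum[..., -anchor_m:].mean(axis=-1)
    slope = (y_hi - y_lo) / (x_hi - x_lo)
    line = y_lo[..., None] + slope[..., None] * (wn - x_lo)
    return spectrum - line


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Divide by the Euclidean norm (sqrt of the summed squared intensities)."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    norm = np.sqrt(np.sum(spectrum**2, axis=-1))
    if np.any(norm < NORM_EPS):
        raise DegeneratePixelError("spectrum has (near-)zero Euclidean norm")
    return spectrum / norm[..., None]


def preprocess(
    cube: HyperCube, sat_value: float | None = None, anchor_m: int = 3
) -> PixelSpectraMatrix:
    """Full sequence: mask_saturated -> downsample2 -> baseline_correct ->
    vector_normalize; masked and degenerate pixels are dropped."""
    cube = mask_saturated(cube, sat_value)
    cube = downsample2(cube)
    h, w, c = cube.values.shape
    keep = ~cube.sat_mask.ravel()
    flat = cube.values.reshape(h * w, c)[keep]
    rows, cols = np.divmod(np.flatnonzero(keep), w)

    corrected = baseline_correct(flat, cube.axis, anchor_m)
    norms = np.sqrt(np.sum(corrected**2, axis=1))
    ok = norms >= NORM_EPS
    if not np.any(ok):
        raise ValueError("preprocessing dropped every pixel of the image")
    spectra = corrected[ok] / norms[ok, None]
    index = np.column_stack([rows[ok], cols[ok]])
    return PixelSpectraMatrix(
        spectra=spectra,
        pixel_index=index,
        shape=(h, w),
        axis=cube.axis,
        meta=dict(cube.meta),
    )
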