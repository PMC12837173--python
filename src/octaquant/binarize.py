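"""Local adaptive thresholding of en-face angiograms.

En-face OCT angiograms show bright flow signal over a dark speckle
background whose local statistics drift across the field, so a single global
threshold under- or over-segments parts of the image.  The local methods
here compute, for every pixel, the mean ``m`` and standard deviation ``s``
of the intensities in a centered square window and threshold:

* Niblack:     ``T = m + k * s``
* Phansalkar:  ``T = m * (1 + p * exp(-q * m) + k * (s / r - 1))``
* local Otsu:  Otsu's between-class-variance maximizer on the window histogram

A pixel is vessel iff its intensity is *strictly greater* than its local
threshold (so a zero-variance constant image is deterministically all
background under Niblack).  Borders are handled by reflective padding,
avoiding the artificial low-mean rim that zero padding would create.

The Phansalkar rule is designed for faint, low-contrast objects: the
``p * exp(-q * m)`` term raises the threshold where the local mean is small,
which suppresses the dark background, while ``k * (s / r - 1)`` lowers it in
busy, high-variance neighbourhoods.  Intensities are normalized to [0, 1]
before thresholding so these terms behave as published.  By convention a
macula scan is thresholded with Phansalkar and an ONH scan with Niblack
(see :func:`default_params`).

Sign convention (Niblack): this module uses the bright-object form with
``k = +0.2`` by default — vessels must exceed the local mean by ``k * s``.
For dark objects on a bright field pass ``polarity="dark_vessels"``: the
image is inverted to ``1 - img`` and the same bright rule applied, which is
equivalent to the classic dark-object Niblack with the sign of ``k`` flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu

from .core import ImageSpec, as_float01

Method = Literal["phansalkar", "niblack", "otsu_global", "otsu_local"]
Polarity = Literal["bright_vessels", "dark_vessels"]


@dataclass(frozen=True)
class ThresholdParams:
    """Binarization method and its coefficients.

    Defaults follow the established local-threshold literature: Niblack
    ``k = 0.2`` (bright-object convention), Phansalkar ``k = 0.25``,
    ``r = 0.5``, ``p_coef = 2``, ``q_coef = 10``, window 15 px.
    """

    method: Method
    window_px: int = 15
    k: float | None = None
    r: float = 0.5
    p_coef: float = 2.0
    q_coef: float = 10.0
    polarity: Polarity = "bright_vessels"

    def __post_init__(self) -> None:
        if self.method not in ("phansalkar", "niblack", "otsu_global", "otsu_local"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "otsu_global":
            if self.window_px < 3 or self.window_px % 2 == 0:
                raise ValueError("window_px must be odd and >= 3")
        if self.method == "phansalkar" and not self.r > 0:
            raise ValueError("r must be positive for the phansalkar method")

    @property
    def k_effective(self) -> float:
        if self.k is not None:
            return self.k
        return {"niblack": 0.2, "phansalkar": 0.25}.get(self.method, 0.0)


def default_params(center_type: str) -> ThresholdParams:
    """Site-to-method routing: macula scans -> Phansalkar, ONH scans -> Niblack."""
    if center_type == "macula":
        return ThresholdParams(method="phansalkar")
    if center_type == "onh":
        return ThresholdParams(method="niblack")
    raise ValueError(f"unknown center_type {center_type!r}")


@dataclass(frozen=True)
class BinaryVesselMap:
    mask: np.ndarray
    source_spec: ImageSpec | None = None
    params: ThresholdParams | None = None


def _local_mean_std(img: np.ndarray, window_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean and standard deviation with reflective border padding."""
    m = uniform_filter(img, size=window_px, mode="reflect")
    m2 = uniform_filter(img * img, size=window_px, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    return m, np.sqrt(var)


def _local_otsu_thresholds(img: np.ndarray, window_px: int) -> np.ndarray:
    """Per-pixel Otsu threshold over the centered window (reflect-padded)."""
    half = window_px // 2
    # np.pad "symmetric" matches scipy.ndimage's "reflect" border convention
    padded = np.pad(img, half, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window_px, window_px))
    thresholds = np.empty(img.shape, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = windows[i, j]
            if w.max() == w.min():
                # no contrast: put the threshold at the constant value so the
                # strict ">" rule yields background
                thresholds[i, j] = w.flat[0]
            else:
                thresholds[i, j] = threshold_otsu(w)
    return thresholds


def compute_thresholds(img01: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Threshold surface for a [0, 1]-scaled image (bright-object convention)."""
    k = params.k_effective
    if params.method == "otsu_global":
        if img01.max() == img01.min():
            warnings.warn("constant image: no valid Otsu threshold, returning all-background",
                          stacklevel=3)
            return np.full(img01.shape, img01.flat[0])
        return np.full(img01.shape, threshold_otsu(img01))
    if params.method == "otsu_local":
        return _local_otsu_thresholds(img01, params.window_px)
    m, s = _local_mean_std(img01, params.window_px)
    if params.method == "niblack":
        return m + k * s
    # phansalkar
    return m * (1.0 + params.p_coef * np.exp(-params.q_coef * m) + k * (s / params.r - 1.0))


def binarize(
    img: np.ndarray,
    params: ThresholdParams,
    spec: ImageSpec | None = None,
) -> BinaryVesselMap:
    """Threshold a grayscale angiogram into a boolean vessel map.

    8-bit input is scaled to [0, 1]; float input is assumed to already be on
    that scale.  With ``polarity="dark_vessels"`` the inverted image
    ``1 - img`` is thresholded with the identical bright-object rule.
    """
    img01 = as_float01(np.asarray(img))
    if img01.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if params.polarity == "dark_vessels":
        img01 = 1.0 - img01
    t = compute_thresholds(img01, params)
    # 1e-9 guard keeps floating-point dust in the windowed moments from
    # flipping zero-variance ties; far below the 1/255 quantum of 8-bit input
    return BinaryVesselMap(mask=img01 > t + 1e-9, source_spec=spec, params=params)
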