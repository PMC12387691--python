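"""Feature extractors that turn a 2D slice into a multi-channel activation map.

The informativeness score downstream is the mean Shannon entropy over the
channels of the extractor's output, so any deterministic callable mapping an
``H×W×3`` slice to an ``H'×W'×C`` array can serve. The built-in
:class:`FilterBankExtractor` is a fixed multi-scale bank of derivative and
blob filters (Sobel pairs, Gaussian derivatives, Laplacians of Gaussian,
Gaussian smoothing, C = 8): fully deterministic, no learned weights, no
downloads. Pretrained CNN feature extractors can be plugged in through the
same protocol.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = ["FeatureExtractor", "FilterBankExtractor", "IdentityExtractor"]


class FeatureExtractor(Protocol):
    """Contract for activation-map extractors.

    Implementations must be deterministic (same slice in, bit-identical
    map out) and return a finite ``H'×W'×C`` array with ``C >= 1``.
    """

    name: str
    input_size: tuple[int, int]
    channel_count: int

    def __call__(self, slice_chw: np.ndarray) -> np.ndarray: ...


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        return arr.mean(axis=2)
    return arr


class FilterBankExtractor:
    """Deterministic multi-scale filter bank (C = 8 channels).

    Channels: Sobel x/y, Gaussian first derivatives x/y at ``sigma``,
    Laplacian of Gaussian at ``sigma`` and ``2*sigma``, Gaussian
    smoothing at ``sigma``, and the resized input itself.
    """

    def __init__(self, input_size: tuple[int, int] = (64, 64),
                 sigma: float = 1.5) -> None:
        self.name = f"filterbank-c8-s{sigma:g}"
        self.input_size = tuple(int(s) for s in input_size)
        self.sigma = float(sigma)
        self.channel_count = 8

    def __call__(self, slice_arr: np.ndarray) -> np.ndarray:
        img = _to_gray(np.asarray(slice_arr, dtype=np.float64))
        if img.shape != self.input_size:
            img = resize(img, self.input_size, order=1, mode="reflect",
                         anti_aliasing=False, preserve_range=True)
        s = self.sigma
        chans = [
            ndimage.sobel(img, axis=0, mode="reflect"),
            ndimage.sobel(img, axis=1, mode="reflect"),
            ndimage.gaussian_filter(img, s, order=(1, 0), mode="reflect"),
            ndimage.gaussian_filter(img, s, order=(0, 1), mode="reflect"),
            ndimage.gaussian_laplace(img, s, mode="reflect"),
            ndimage.gaussian_laplace(img, 2 * s, mode="reflect"),
            ndimage.gaussian_filter(img, s, mode="reflect"),
            img,
        ]
        out = np.stack(chans, axis=2)
        return out


class IdentityExtractor:
    """Pass the (grayscale) slice through as a single-channel map.

    Scoring with this extractor reduces the informativeness measure to
    the plain pixel-histogram entropy of the slice.
    """

    def __init__(self, input_size: tuple[int, int] | None = None) -> None:
        self.name = "identity"
        self.input_size = input_size
        self.channel_count = 1

    def __call__(self, slice_arr: np.ndarray) -> np.ndarray:
        img = _to_gray(np.asarray(slice_arr, dtype=np.float64))
        if self.input_size is not None and img.shape != tuple(self.input_size):
            img = resize(img, self.input_size, order=1, mode="reflect",
                         anti_aliasing=False, preserve_range=True)
        return img[:, :, None]
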