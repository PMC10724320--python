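"""Focus stacking: collapse a multi-focal-plane stack into one all-in-focus image.

Chromogen granules sit at different depths within a 4 µm section, so a single
focal plane misses part of them.  The stack is collapsed by per-pixel
*selection* (not blending): for every pixel the plane with the highest local
sharpness — variance of the Laplacian response in a small window — wins.
Selection preserves granule contrast and guarantees that every fused pixel
value exists in some input plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = ["FocalStack", "FusedImage", "fuse_stack", "read_stack", "write_fused"]


@dataclass
class FocalStack:
    """Calibrated multi-plane image of one epithelial field.

    ``planes`` has shape (n_planes, H, W) or (n_planes, H, W, 3) with RGB
    channel order; all planes share shape and dtype.
    """

    planes: np.ndarray
    um_per_pixel: float

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim not in (3, 4):
            raise ValueError("planes must be (n, H, W) or (n, H, W, 3)")
        if self.planes.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")

    @property
    def n_planes(self) -> int:
        return int(self.planes.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self.planes.shape[1:3])  # type: ignore[return-value]


@dataclass
class FusedImage:
    """All-in-focus image plus the per-pixel plane-selection index map."""

    image: np.ndarray
    um_per_pixel: float
    index_map: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index_map is not None and self.index_map.shape != self.image.shape[:2]:
            raise ValueError("index map must match image frame shape")


def _luminance(plane: np.ndarray) -> np.ndarray:
    if plane.ndim == 3:
        return plane.astype(np.float64).mean(axis=-1)
    return plane.astype(np.float64)


def _sharpness(plane: np.ndarray, window: int) -> np.ndarray:
    """Local variance of the Laplacian response (the focus measure)."""
    lap = ndi.laplace(_luminance(plane))
    mean = ndi.uniform_filter(lap, size=window)
    mean_sq = ndi.uniform_filter(lap * lap, size=window)
    return np.maximum(mean_sq - mean * mean, 0.0)


def fuse_stack(stack: FocalStack, window: int = 9) -> FusedImage:
    """Fuse a focal stack by per-pixel argmax of local sharpness.

    Parameters
    ----------
    stack:
        Aligned focal stack.
    window:
        Odd side length (pixels) of the local-variance window, >= 3.

    Ties break toward the lowest plane index, so a stack of identical
    planes returns plane 0 unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    planes = stack.planes
    if planes.shape[0] == 1:
        return FusedImage(
            image=planes[0].copy(),
            um_per_pixel=stack.um_per_pixel,
            index_map=np.zeros(stack.frame_shape, dtype=np.intp),
        )
    scores = np.stack([_sharpness(p, window) for p in planes])
    index_map = np.argmax(scores, axis=0)
    if planes.ndim == 4:
        sel = index_map[None, :, :, None]
        fused = np.take_along_axis(planes, np.broadcast_to(sel, (1,) + planes.shape[1:]), axis=0)[0]
    else:
        fused = np.take_along_axis(planes, index_map[None], axis=0)[0]
    return FusedImage(image=fused, um_per_pixel=stack.um_per_pixel, index_map=index_map)


def read_stack(path, um_per_pixel: float) -> FocalStack:
    """Read a multi-page TIFF as a focal stack."""
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    elif planes.ndim == 3 and planes.shape[-1] in (3, 4):
        # single RGB page
        planes = planes[None, ..., :3]
    return FocalStack(planes=planes, um_per_pixel=um_per_pixel)


def write_fused(fused: FusedImage, image_path, index_map_path=None) -> None:
    tifffile.imwrite(str(image_path), fused.image)
    if index_map_path is not None:
        import imageio.v3 as iio

        iio.imwrite(str(index_map_path), fused.index_map.astype(np.uint8))
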