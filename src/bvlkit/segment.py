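"""Brain parenchyma / TIV segmentation contract and a simple fallback.

Real-data use expects externally computed masks (any tool producing binary
NIfTI masks).  The bundled fallback is intensity thresholding (multi-Otsu)
plus morphological cleanup -- adequate for the geometric phantoms in this
package, not for clinical scans.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
from scipy.ndimage import binary_closing, binary_fill_holes, label
from skimage.filters import threshold_multiotsu

from .volume import Volume3D


class Segmenter(Protocol):
    """Behavioral contract: crop -> (parenchyma_mask, tiv_mask), both uint8."""

    def __call__(self, vol: Volume3D) -> tuple[Volume3D, Volume3D]: ...


class SegmentationError(RuntimeError):
    pass


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = label(mask)
    if n == 0:
        raise SegmentationError("no component found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(sizes.argmax())


def otsu_segmenter(vol: Volume3D) -> tuple[Volume3D, Volume3D]:
    """Fallback segmenter: multi-Otsu threshold + closing + largest component.

    Parenchyma: the brightest intensity class, morphologically closed,
    largest connected component.  TIV: the filled region enclosing parenchyma
    and interior CSF (parenchyma plus everything it surrounds).
    """
    data = vol.data.astype(np.float32)
    if np.ptp(data) == 0:
        raise SegmentationError("constant image")
    try:
        ths = threshold_multiotsu(data, classes=4)
    except ValueError as exc:
        raise SegmentationError(f"multi-Otsu failed: {exc}") from exc
    par = data >= ths[-1]
    par = binary_closing(par, iterations=2)
    par = _largest_component(par)
    tiv = binary_fill_holes(par)
    return (
        Volume3D(par.astype(np.uint8), vol.affine),
        Volume3D(tiv.astype(np.uint8), vol.affine),
    )


def external_masks_segmenter(parenchyma: Volume3D, tiv: Volume3D) -> Segmenter:
    """Wrap precomputed masks behind the segmenter contract."""

    def _seg(vol: Volume3D) -> tuple[Volume3D, Volume3D]:
        if parenchyma.shape != vol.shape or tiv.shape != vol.shape:
            raise SegmentationError("external masks do not match the crop grid")
        return parenchyma, tiv

    return _seg
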