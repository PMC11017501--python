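"""Infarct volume from serial coronal section masks.

Infarcted tissue is delineated on evenly spaced (typically 2 mm) coronal
sections, and the infarct volume is expressed as percent of the
ipsilateral hemisphere:

    V_%stroke = (Σ infarct area / Σ ipsilateral hemisphere area) × 100.

With uniform section thickness the thickness cancels; it is recorded for
provenance only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SectionMaskSet", "infarct_percent"]


@dataclass
class SectionMaskSet:
    """Per-section binary masks of infarct and ipsilateral hemisphere."""

    infarct_masks: list[np.ndarray]
    hemisphere_masks: list[np.ndarray]
    pixel_size_mm: float = 1.0
    section_thickness_mm: float = 2.0

    def __post_init__(self) -> None:
        if len(self.infarct_masks) == 0:
            raise ValueError("need at least one section")
        if len(self.infarct_masks) != len(self.hemisphere_masks):
            raise ValueError("infarct and hemisphere mask counts differ")
        if self.pixel_size_mm <= 0 or self.section_thickness_mm <= 0:
            raise ValueError("pixel size and section thickness must be positive")
        self.infarct_masks = [np.asarray(m, dtype=bool) for m in self.infarct_masks]
        self.hemisphere_masks = [np.asarray(m, dtype=bool) for m in self.hemisphere_masks]
        for k, (inf, hemi) in enumerate(zip(self.infarct_masks, self.hemisphere_masks)):
            if inf.shape != hemi.shape:
                raise ValueError(f"section {k}: mask shapes differ")
            if np.any(inf & ~hemi):
                raise ValueError(f"section {k}: infarct extends outside the hemisphere")


def infarct_percent(masks: SectionMaskSet) -> float:
    """Infarct volume as percent of the ipsilateral hemisphere.

    Pixel areas are summed over sections; the uniform pixel size and
    section thickness cancel in the ratio.
    """
    infarct_px = sum(int(m.sum()) for m in masks.infarct_masks)
    hemisphere_px = sum(int(m.sum()) for m in masks.hemisphere_masks)
    if hemisphere_px == 0:
        raise ValueError("zero hemisphere area")
    return 100.0 * infarct_px / hemisphere_px
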