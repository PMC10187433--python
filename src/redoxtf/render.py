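"""Synthetic microscopy renderer: disc cells with ground-truth label masks.

Each snapshot cell is drawn as a disc nucleus centred inside a disc
cytoplasm on a regular grid.  Channel intensities are constructed so the
programmed measurements are exactly recoverable in the noise-free case:

* FOXO1 channel: nucleus at ``total * foxo1_nf``, cytoplasm at
  ``total * (1 - foxo1_nf)``, so nuclear/(nuclear + ring) mean recovers
  ``foxo1_nf`` whenever the 3-px ring lies inside the cytoplasm disc.
* p53 and gamma-H2AX channels: nucleus at the programmed nuclear level.

The label mask assigns every nucleus pixel its cell's integer label
(row order of the input, starting at 1).  Optional photon (Poisson) noise
emulates shot-limited acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError, InputError
from .simulate import SnapshotCell

__all__ = ["FieldGeometry", "render_field", "CHANNEL_NAMES"]

#: Channel order of the rendered image.
CHANNEL_NAMES = ("foxo1", "p53", "gh2ax")

#: Total FOXO1 intensity (nucleus + cytoplasm levels sum), a.u.
FOXO_TOTAL = 1000.0
#: Cytoplasmic background of the nuclear-only channels, a.u.
NUCLEAR_CHANNEL_CYTO = 0.0


@dataclass(frozen=True)
class FieldGeometry:
    """Layout of the rendered field (pixels)."""

    nucleus_radius: int = 6
    cell_radius: int = 12
    spacing: int = 28     # centre-to-centre grid spacing
    margin: int = 16

    def __post_init__(self) -> None:
        if self.nucleus_radius < 1 or self.cell_radius <= self.nucleus_radius:
            raise GeometryError(
                "need cell_radius > nucleus_radius >= 1, got "
                f"nucleus={self.nucleus_radius}, cell={self.cell_radius}")
        if self.spacing < 2 * self.cell_radius:
            raise GeometryError(
                f"spacing {self.spacing} < cell diameter {2 * self.cell_radius}: "
                "cells would overlap at the requested density")


def render_field(cells: Sequence[SnapshotCell],
                 geometry: FieldGeometry = FieldGeometry(),
                 rng: np.random.Generator | None = None,
                 poisson_noise: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render a snapshot population into a multi-channel image + label mask.

    Returns
    -------
    image : float ndarray, shape (3, H, W)
        Channels in :data:`CHANNEL_NAMES` order.  Intensities stay within
        16-bit range; writing to disk quantizes to uint16.
    labels : uint16 ndarray, shape (H, W)
        Nucleus label mask; label ``i+1`` marks the nucleus of ``cells[i]``.
    """
    if len(cells) == 0:
        raise InputError("cells must be non-empty")
    if len(cells) > 65535:
        raise GeometryError("at most 65535 cells fit a 16-bit label mask")
    if poisson_noise and rng is None:
        raise InputError("poisson_noise requires an rng")

    n = len(cells)
    per_row = int(np.ceil(np.sqrt(n)))
    side = 2 * geometry.margin + (per_row - 1) * geometry.spacing \
        + 2 * geometry.cell_radius + 1
    image = np.zeros((3, side, side))
    labels = np.zeros((side, side), dtype=np.uint16)

    yy, xx = np.mgrid[0:side, 0:side]
    for i, cell in enumerate(cells):
        cy = geometry.margin + geometry.cell_radius \
            + (i // per_row) * geometry.spacing
        cx = geometry.margin + geometry.cell_radius \
            + (i % per_row) * geometry.spacing
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuc = r2 <= geometry.nucleus_radius ** 2
        cyto = (r2 <= geometry.cell_radius ** 2) & ~nuc
        if labels[nuc].any():
            raise GeometryError(f"nucleus of cell {cell.cell_id} overlaps another")
        labels[nuc] = i + 1
        image[0][nuc] = FOXO_TOTAL * cell.foxo1_nf
        image[0][cyto] = FOXO_TOTAL * (1.0 - cell.foxo1_nf)
        image[1][nuc] = cell.p53_nuc
        image[1][cyto] = NUCLEAR_CHANNEL_CYTO
        image[2][nuc] = cell.gh2ax
        image[2][cyto] = NUCLEAR_CHANNEL_CYTO

    if poisson_noise:
        image = rng.poisson(image).astype(float)
    return image, labels
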