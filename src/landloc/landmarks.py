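"""Per-image landmark coordinate containers.

Coordinates follow the package-wide convention: 0-based pixels,
``(u, v) = (column, row)``, pixel centres at integer positions. Landmark
indices are 1-based in file formats (matching the l-numbering used in the
hand-radiograph literature) and 0-based in arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_LANDMARKS = 37


@dataclass
class LandmarkSet:
    """2-D landmark annotations for a single image.

    Parameters
    ----------
    coords : (L, 2) float array of (u, v) pixel positions.
    visible : (L,) bool array; False marks landmarks that are missing or
        were transformed out of the image frame.
    image_id : identifier of the source image.
    """

    coords: np.ndarray
    visible: np.ndarray = None  # type: ignore[assignment]
    image_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (L, 2), got {self.coords.shape}")
        if self.visible is None:
            self.visible = np.ones(len(self.coords), dtype=bool)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.visible.shape != (len(self.coords),):
            raise ValueError("visible must have one flag per landmark")
        if not np.all(np.isfinite(self.coords[self.visible])):
            raise ValueError("visible landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    def get(self, index1: int) -> np.ndarray:
        """Coordinate of the landmark with 1-based index ``index1``."""
        return self.coords[index1 - 1]

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.coords.copy(), self.visible.copy(), self.image_id)
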