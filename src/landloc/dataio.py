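"""Dataset readers/writers and run provenance.

Annotation files are CSV rows ``index,u,v`` with 1-based landmark indices
and pixel coordinates in the units of the stored image; missing indices
become invisible landmarks. Images are grayscale PNG/TIFF (Pillow) or MHA
(SimpleITK when available).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .landmarks import DEFAULT_N_LANDMARKS, LandmarkSet

log = logging.getLogger("landloc")

COORD_DECIMALS = 4


def read_annotations(path: str | Path, n_landmarks: int = DEFAULT_N_LANDMARKS) -> LandmarkSet:
    """Parse one annotation CSV into a dense LandmarkSet."""
    path = Path(path)
    coords = np.zeros((n_landmarks, 2), dtype=float)
    visible = np.zeros(n_landmarks, dtype=bool)
    seen: set[int] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.lower().startswith("index"):
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'index,u,v', got {raw!r}")
        idx = int(parts[0])
        if idx in seen:
            raise ValueError(f"{path}:{lineno}: duplicate landmark index {idx}")
        if not (1 <= idx <= n_landmarks):
            raise ValueError(f"{path}:{lineno}: index {idx} out of range")
        seen.add(idx)
        coords[idx - 1] = (float(parts[1]), float(parts[2]))
        visible[idx - 1] = True
    if len(seen) < n_landmarks:
        log.warning("%s: %d of %d landmarks annotated; the rest are invisible",
                    path.name, len(seen), n_landmarks)
    return LandmarkSet(coords, visible, image_id=path.stem)


def write_annotations(lms: LandmarkSet, path: str | Path) -> None:
    """Inverse of :func:`read_annotations`; coordinates at 4 decimals,
    invisible landmarks omitted."""
    lines = ["index,u,v"]
    for i, (xy, vis) in enumerate(zip(lms.coords, lms.visible), start=1):
        if vis:
            lines.append(f"{i},{xy[0]:.{COORD_DECIMALS}f},{xy[1]:.{COORD_DECIMALS}f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_image(path: str | Path) -> np.ndarray:
    """Grayscale float image in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(sitk.ReadImage(str(path))).squeeze()
    else:
        from PIL import Image

        img = Image.open(path)
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
    mx = arr.max()
    return arr / mx if mx > 0 else arr.astype(float)


@dataclass
class DatasetManifest:
    """Standard layout: images/, annotations/, splits/fold{k}_{train,test}.txt."""

    root: Path
    image_paths: dict[str, Path]
    annotation_paths: dict[str, Path]
    splits: dict[str, list[str]]
    n_landmarks: int = DEFAULT_N_LANDMARKS

    @classmethod
    def discover(cls, root: str | Path, n_landmarks: int = DEFAULT_N_LANDMARKS) -> "DatasetManifest":
        root = Path(root)
        images = {p.stem: p for p in sorted((root / "images").glob("*"))}
        annos = {p.stem: p for p in sorted((root / "annotations").glob("*.csv"))}
        missing = set(images) ^ set(annos)
        if missing:
            raise FileNotFoundError(
                f"images and annotations do not match for ids: {sorted(missing)[:5]}"
            )
        splits = {}
        for p in sorted((root / "splits").glob("*.txt")):
            splits[p.stem] = [ln for ln in p.read_text().split() if ln]
        return cls(root, images, annos, splits, n_landmarks)

    def load(self, ids: list[str] | None = None):
        ids = ids if ids is not None else sorted(self.image_paths)
        images = [read_image(self.image_paths[i]) for i in ids]
        lms = [read_annotations(self.annotation_paths[i], self.n_landmarks)
               for i in ids]
        return images, lms


def write_provenance(path: str | Path, config: dict, seed: int | None) -> None:
    """JSON record of a run: config hash, seed, library versions."""
    import scipy
    import sklearn

    blob = json.dumps(config, sort_keys=True, default=str)
    rec = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(rec, indent=2, default=str))
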