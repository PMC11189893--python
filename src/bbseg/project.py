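"""No-code project workflow: a folder layout driven by a parameter file.

``create_project`` lays out the directory tree and writes a default
parameter file; users then drop training images and masks (and optional
area-of-interest masks) into the folders and run train / predict / eval.
Every train image must have a same-named mask; AOI masks are optional
per image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    IMAGE_SUFFIXES,
    ImageRecord,
    read_aoi_raster,
    read_label_raster,
    read_raster,
)
from .params import ParamSet, load_params, save_params

SUBDIRS = ("train_images", "train_masks", "test_images", "aoi", "outputs", "models")
PARAM_FILE = "params.txt"


class ProjectError(RuntimeError):
    pass


@dataclass
class ProjectLayout:
    """Paths of a project on disk."""

    root: Path

    @property
    def param_file(self) -> Path:
        return self.root / PARAM_FILE

    def dir(self, name: str) -> Path:
        return self.root / name

    def params(self) -> ParamSet:
        return load_params(self.param_file)

    def _images_in(self, sub: str) -> list[Path]:
        d = self.dir(sub)
        return sorted(
            p for p in d.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
        ) if d.is_dir() else []

    def mask_for(self, image_path: Path) -> Path:
        """The same-named mask of a training image (any raster suffix)."""
        for suffix in IMAGE_SUFFIXES:
            cand = self.dir("train_masks") / (image_path.stem + suffix)
            if cand.exists():
                return cand
        raise ProjectError(f"no mask found for training image {image_path.name!r}")

    def aoi_for(self, image_path: Path) -> Path | None:
        for suffix in IMAGE_SUFFIXES:
            cand = self.dir("aoi") / (image_path.stem + suffix)
            if cand.exists():
                return cand
        return None

    def load_training_set(
        self,
    ) -> tuple[list[ImageRecord], list[np.ndarray], list[np.ndarray | None]]:
        """All training images with their label maps and optional AOIs."""
        images, masks, aois = [], [], []
        for path in self._images_in("train_images"):
            images.append(read_raster(path))
            masks.append(read_label_raster(self.mask_for(path)))
            aoi_path = self.aoi_for(path)
            aois.append(read_aoi_raster(aoi_path) if aoi_path else None)
        if not images:
            raise ProjectError("no training images found in train_images/")
        return images, masks, aois

    def test_images(self) -> list[Path]:
        return self._images_in("test_images")

    @property
    def model_path(self) -> Path:
        return self.dir("models") / "network.npz"


def create_project(root: str | Path) -> ProjectLayout:
    """Create the folder layout and default parameter file under ``root``.

    Refuses (leaving the disk unchanged) if ``root`` already contains a
    project, i.e. a parameter file.
    """
    root = Path(root)
    layout = ProjectLayout(root=root)
    if layout.param_file.exists():
        raise ProjectError(f"{root} already contains a project ({PARAM_FILE} exists)")
    root.mkdir(parents=True, exist_ok=True)
    for sub in SUBDIRS:
        (root / sub).mkdir(exist_ok=True)
    save_params(ParamSet(), layout.param_file)
    return layout


def open_project(root: str | Path) -> ProjectLayout:
    root = Path(root)
    layout = ProjectLayout(root=root)
    if not layout.param_file.exists():
        raise ProjectError(f"{root} is not a project ({PARAM_FILE} missing)")
    return layout
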