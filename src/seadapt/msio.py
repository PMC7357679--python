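"""Multi-band raster I/O and center-labeled patch extraction.

Scenes are H×W×B reflectance rasters stored as multi-band TIFF; label masks
are single-band integer rasters where 0 means unlabeled and 1..N_c index the
habitat classes (default order: seagrass, sea, sand, land, intertidal).
Patches are odd-sized square windows whose class is the class of the center
pixel; border pixels without a full window are skipped, as is any window that
touches nodata.

Coordinates are 0-based and row-major throughout: the patch centered at
(r, c) with size P covers the closed window
[r - P//2, r + P//2] × [c - P//2, c + P//2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .errors import FormatError, ValidationError

#: Canonical habitat classes, in fixed internal order (0-based).
DEFAULT_CLASS_NAMES: tuple[str, ...] = ("seagrass", "sea", "sand", "land", "intertidal")

#: RGB rendering colors for label maps (seagrass green, sea blue, sand cyan,
#: land yellow, intertidal magenta); index 0 (unlabeled) renders black.
CLASS_COLORS: dict[str, tuple[int, int, int]] = {
    "seagrass": (0, 170, 0),
    "sea": (0, 0, 255),
    "sand": (0, 255, 255),
    "land": (255, 255, 0),
    "intertidal": (255, 0, 255),
}

_DESCRIPTION_KEY = "seadapt"


@dataclass
class MultispectralScene:
    """An H×W×B reflectance raster with a nodata mask.

    Non-finite pixels are always treated as nodata; ``geo`` carries opaque
    georeferencing metadata through read/write untouched.
    """

    pixels: np.ndarray
    band_names: tuple[str, ...] = ()
    nodata_mask: np.ndarray | None = None
    geo: dict | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3 or min(self.pixels.shape) < 1:
            raise ValidationError(f"scene must be H×W×B with all dims >= 1, got shape {self.pixels.shape}")
        h, w, b = self.pixels.shape
        if not self.band_names:
            self.band_names = tuple(f"band_{i + 1}" for i in range(b))
        if len(self.band_names) != b:
            raise ValidationError(f"{len(self.band_names)} band names for {b} bands")
        nonfinite = ~np.isfinite(self.pixels).all(axis=2)
        if self.nodata_mask is None:
            self.nodata_mask = nonfinite
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != (h, w):
                raise ValidationError("nodata_mask shape must match scene H×W")
            self.nodata_mask = self.nodata_mask | nonfinite

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]


@dataclass
class LabelMask:
    """An H×W integer mask; 0 = unlabeled, 1..N_c = class index + 1."""

    labels: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if np.issubdtype(labels.dtype, np.floating) and not np.all(labels == np.round(labels)):
                raise FormatError("label mask must be integer-valued")
            labels = labels.astype(np.int64)
        if labels.ndim != 2:
            raise ValidationError(f"label mask must be 2-D, got shape {labels.shape}")
        n_c = len(self.class_names)
        if labels.size and (labels.min() < 0 or labels.max() > n_c):
            raise ValidationError(
                f"labels must lie in 0..{n_c}, found range [{labels.min()}, {labels.max()}]"
            )
        self.labels = labels.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        """Pixel count per class (length N_c, excludes unlabeled)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_classes + 1)[1:]


@dataclass
class PatchSet:
    """N center-labeled P×P×B patches with provenance coordinates.

    ``labels`` are 0-based class indices and are ``None`` for unlabeled sets.
    """

    patches: np.ndarray
    labels: np.ndarray | None
    centers: np.ndarray
    patch_size: int = 5
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    band_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.int64).reshape(-1, 2)
        if self.patches.ndim != 4:
            raise ValidationError("patches must be N×P×P×B")
        n, p1, p2, _ = self.patches.shape
        if (p1, p2) != (self.patch_size, self.patch_size):
            raise ValidationError("patch array spatial dims disagree with patch_size")
        if len(self.centers) != n:
            raise ValidationError("centers length must equal patch count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != n:
                raise ValidationError("labels length must equal patch count")
        if not np.isfinite(self.patches).all():
            raise ValidationError("patches must be finite")

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, idx: np.ndarray | Sequence[int]) -> "PatchSet":
        idx = np.asarray(idx, dtype=np.int64)
        return PatchSet(
            self.patches[idx],
            None if self.labels is None else self.labels[idx],
            self.centers[idx],
            self.patch_size,
            self.class_names,
            self.band_names,
        )


# ---------------------------------------------------------------------------
# Raster read/write
# ---------------------------------------------------------------------------

def _encode_description(band_names: Sequence[str], nodata: float | None, geo: dict | None) -> str:
    payload = {"band_names": list(band_names), "nodata": nodata, "geo": geo}
    return json.dumps({_DESCRIPTION_KEY: payload})


def _decode_description(desc: str | None) -> dict:
    if not desc:
        return {}
    try:
        parsed = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        return {}
    return parsed.get(_DESCRIPTION_KEY, {}) if isinstance(parsed, dict) else {}


def write_scene(scene: MultispectralScene, path: str | Path, nodata: float | None = None) -> None:
    """Write a scene as a band-last multi-band float32 TIFF.

    Nodata pixels are stored as ``nodata`` when given, otherwise as NaN; either
    way :func:`read_scene` restores the mask.
    """
    data = scene.pixels.astype(np.float32)
    if scene.nodata_mask.any():
        data = data.copy()
        data[scene.nodata_mask] = np.nan if nodata is None else nodata
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=_encode_description(scene.band_names, nodata, scene.geo),
    )


def read_scene(path: str | Path, nodata: float | None = None) -> MultispectralScene:
    """Read a multi-band TIFF as a :class:`MultispectralScene`.

    Band order is preserved as stored. Pixels equal to the declared nodata
    value (from the file header or the ``nodata`` argument) and non-finite
    pixels are flagged in ``nodata_mask``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = _decode_description(tif.pages[0].description)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3 or data.shape[2] < 1:
        raise FormatError(f"{path}: expected an H×W or H×W×B raster, got shape {data.shape}")
    data = data.astype(np.float64)
    declared = meta.get("nodata") if nodata is None else nodata
    mask = ~np.isfinite(data).all(axis=2)
    if declared is not None:
        mask |= (data == declared).any(axis=2)
        data = data.copy()
        data[mask] = np.nan
    band_names = tuple(meta.get("band_names") or ())
    return MultispectralScene(data, band_names, mask, meta.get("geo"))


def read_label_mask(path: str | Path, class_names: Sequence[str] = DEFAULT_CLASS_NAMES) -> LabelMask:
    """Read a single-band integer raster as a :class:`LabelMask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(str(path))
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-band, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.floating):
        if not np.isfinite(data).all() or not np.all(data == np.round(data)):
            raise FormatError(f"{path}: label mask is float-valued")
        data = data.astype(np.int64)
    return LabelMask(data, tuple(class_names))


def write_label_map(mask: LabelMask, path: str | Path, png_path: str | Path | None = None) -> None:
    """Write a label mask as a single-band uint8/uint16 TIFF.

    ``read_label_mask`` inverts the write bit-exactly. When ``png_path`` is
    given, also renders a color map using the habitat colormap
    (:data:`CLASS_COLORS`; unlabeled pixels are black).
    """
    dtype = np.uint8 if mask.n_classes < 256 else np.uint16
    tifffile.imwrite(str(path), mask.labels.astype(dtype), photometric="minisblack")
    if png_path is not None:
        render_label_map(mask).save(str(png_path))


def render_label_map(mask: LabelMask) -> Image.Image:
    """Render a label mask to an RGB image via the habitat colormap."""
    lut = np.zeros((mask.n_classes + 1, 3), dtype=np.uint8)
    fallback = [(128, 128, 128)] * mask.n_classes
    for i, name in enumerate(mask.class_names):
        lut[i + 1] = CLASS_COLORS.get(name, fallback[i])
    return Image.fromarray(lut[mask.labels], mode="RGB")


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

def eligible_centers(
    scene: MultispectralScene,
    mask: LabelMask | None = None,
    patch_size: int = 5,
    labeled_only: bool = False,
) -> np.ndarray:
    """Boolean H×W map of pixels with a full, nodata-free P×P window.

    With ``labeled_only``, additionally requires a nonzero center label.
    """
    if patch_size % 2 == 0 or patch_size < 1:
        raise ValidationError(f"patch_size must be odd and positive, got {patch_size}")
    h, w, _ = scene.shape
    half = patch_size // 2
    ok = np.zeros((h, w), dtype=bool)
    if h < patch_size or w < patch_size:
        return ok
    good = ~scene.nodata_mask
    # a center is eligible iff every pixel of its window is good
    windows = sliding_window_view(good, (patch_size, patch_size))
    ok[half : h - half, half : w - half] = windows.all(axis=(2, 3))
    if labeled_only:
        if mask is None:
            raise ValidationError("labeled_only requires a label mask")
        ok &= mask.labels > 0
    return ok


def extract_patches(
    scene: MultispectralScene,
    mask: LabelMask | None = None,
    patch_size: int = 5,
    labeled_only: bool = True,
) -> PatchSet:
    """Extract all eligible center-labeled patches in row-major center order.

    A center is eligible when its full P×P window lies inside the raster and
    contains no nodata; with ``labeled_only`` the center pixel must also carry
    a nonzero label. Labels in the returned set are 0-based (mask value − 1).
    """
    if mask is not None and mask.shape != scene.shape[:2]:
        raise ValidationError(f"scene {scene.shape[:2]} and mask {mask.shape} differ in H×W")
    ok = eligible_centers(scene, mask, patch_size, labeled_only)
    rows, cols = np.nonzero(ok)  # np.nonzero is row-major, hence deterministic order
    half = patch_size // 2
    h, w, b = scene.shape
    if len(rows) == 0:
        patches = np.empty((0, patch_size, patch_size, b))
        labels = np.empty(0, dtype=np.int64) if labeled_only else None
        return PatchSet(patches, labels, np.empty((0, 2), dtype=np.int64), patch_size,
                        mask.class_names if mask is not None else DEFAULT_CLASS_NAMES,
                        scene.band_names)
    windows = sliding_window_view(scene.pixels, (patch_size, patch_size), axis=(0, 1))
    patches = windows[rows - half, cols - half]  # (N, B, P, P)
    patches = np.ascontiguousarray(np.moveaxis(patches, 1, -1))
    labels = mask.labels[rows, cols] - 1 if labeled_only else None
    return PatchSet(
        patches,
        labels,
        np.stack([rows, cols], axis=1),
        patch_size,
        mask.class_names if mask is not None else DEFAULT_CLASS_NAMES,
        scene.band_names,
    )
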