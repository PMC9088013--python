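"""Volume I/O and the simplified structural-MRI preprocessing chain.

A :class:`Volume` is a 3D scalar grid indexed ``(sagittal, coronal, axial)``
— in scanner terms the RAS axes x (left-right), y (posterior-anterior),
z (inferior-superior) — with per-axis voxel spacing in millimetres.

The preprocessing offered here is a deliberately lightweight stand-in for
a full neuroimaging pipeline: crop away blank background, z-score the
intensities, and resample to a fixed model grid (default 91 x 101 x 91 at
2 mm).  Registration, skull stripping and bias-field correction are
expected to have been done offline with dedicated tools; ``preprocess``
accepts an optional ``hook`` callable so such steps can be spliced in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume", "SliceBank", "VolumeFormatError", "EmptyForegroundError",
    "read_volume", "write_volume", "crop_background", "normalize_intensity",
    "resize_volume", "extract_slices", "stack_slices", "preprocess",
    "DEFAULT_GRID",
]

#: Model input grid (voxels) at 2 mm isotropic spacing.
DEFAULT_GRID: tuple[int, int, int] = (91, 101, 91)


class VolumeFormatError(ValueError):
    """File exists but is not readable as NIfTI."""


class EmptyForegroundError(ValueError):
    """No voxel exceeds the background threshold."""


@dataclass
class Volume:
    """3D image with axis semantics (sagittal, coronal, axial).

    ``data`` is indexed ``[sagittal, coronal, axial]``; ``spacing`` is the
    voxel size per axis in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.data).all())


@dataclass
class SliceBank:
    """The three ordered stacks of 2D slices cut from one volume."""

    sagittal: list[np.ndarray] = field(default_factory=list)
    coronal: list[np.ndarray] = field(default_factory=list)
    axial: list[np.ndarray] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(M_x, M_y, M_z): number of slices per view."""
        return len(self.sagittal), len(self.coronal), len(self.axial)

    def view(self, k: str) -> list[np.ndarray]:
        try:
            return {"x": self.sagittal, "y": self.coronal,
                    "z": self.axial}[k] if len(k) == 1 else getattr(self, k)
        except (KeyError, AttributeError):
            raise ValueError(f"unknown view {k!r}; use x/y/z or "
                             "sagittal/coronal/axial") from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Load a NIfTI-1/2 file as a Volume in (sagittal, coronal, axial) order.

    The image is reoriented to closest-canonical RAS so that array axes
    0/1/2 correspond to the sagittal/coronal/axial slice directions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:
        raise VolumeFormatError(
            f"{path} is not a readable NIfTI file: {exc}") from exc
    return Volume(data, tuple(float(z) for z in zooms))


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI with an RAS diagonal affine from its spacing."""
    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def crop_background(v: Volume, threshold: float = 0.0) -> Volume:
    """Crop to the minimal bounding box of voxels brighter than ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = v.data > threshold
    if not mask.any():
        raise EmptyForegroundError(
            f"no voxel exceeds threshold {threshold}; cannot crop")
    slices = []
    for ax in range(3):
        profile = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(profile)
        slices.append(slice(idx[0], idx[-1] + 1))
    return Volume(v.data[tuple(slices)].copy(), v.spacing)


def normalize_intensity(v: Volume) -> Volume:
    """Z-score the volume: zero mean, unit standard deviation.

    A constant volume maps to all zeros (zero-variance guard).  Real
    pipelines would normalise over a brain mask after bias correction;
    that refinement belongs in a preprocessing ``hook``.
    """
    data = np.asarray(v.data, dtype=np.float64)
    mu = data.mean()
    sd = data.std()
    if sd == 0.0 or not np.isfinite(sd):
        return Volume(np.zeros_like(data), v.spacing)
    return Volume((data - mu) / sd, v.spacing)


def resize_volume(v: Volume, target: tuple[int, int, int]) -> Volume:
    """Trilinear resample onto ``target`` voxels (align-corners convention).

    Output sample i along an axis sits at input coordinate
    ``i * (n_in - 1) / (n_out - 1)``, so the corner voxels map exactly and
    a linear ramp stays a linear ramp.  Spacing is rescaled to preserve the
    physical corner-to-corner extent.
    """
    target = tuple(int(t) for t in target)
    if len(target) != 3 or any(t < 1 for t in target):
        raise ValueError(f"target dimensions must be three positive ints, got {target}")
    if target == v.shape:
        return Volume(v.data.copy(), v.spacing)
    coords = [
        np.linspace(0.0, n_in - 1.0, n_out) if n_out > 1 else np.array([(n_in - 1) / 2.0])
        for n_in, n_out in zip(v.shape, target)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(v.data, dtype=np.float64),
                                  np.stack([g.ravel() for g in grid]),
                                  order=1, mode="nearest").reshape(target)
    spacing = tuple(
        sp * (n_in - 1) / (n_out - 1) if n_out > 1 else sp * n_in
        for sp, n_in, n_out in zip(v.spacing, v.shape, target))
    return Volume(out, spacing)


def preprocess(v: Volume, *, crop: bool = True, normalize: bool = True,
               target_grid: tuple[int, int, int] | None = DEFAULT_GRID,
               crop_threshold: float = 0.0, hook=None) -> Volume:
    """Apply the simplified preprocessing chain: crop -> z-score -> resize.

    ``hook``, if given, is called first with the raw Volume and must return
    a Volume — the splice point for externally registered / bias-corrected
    data.  Configuration mirrors the YAML schema in :func:`preprocess_config`.
    """
    if hook is not None:
        v = hook(v)
    if crop:
        v = crop_background(v, crop_threshold)
    if normalize:
        v = normalize_intensity(v)
    if target_grid is not None:
        v = resize_volume(v, target_grid)
    if not v.is_finite():
        raise ValueError("preprocessing produced non-finite intensities")
    return v


def preprocess_config(config: dict | str | Path):
    """Build a ``Volume -> Volume`` preprocessor from a dict or YAML/JSON file.

    Recognised keys: ``crop`` (bool), ``normalize`` (bool), ``target_grid``
    (3 ints or null), ``crop_threshold`` (float).
    """
    if not isinstance(config, dict):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)
    crop = bool(config.get("crop", True))
    normalize = bool(config.get("normalize", True))
    grid = config.get("target_grid", DEFAULT_GRID)
    grid = tuple(grid) if grid is not None else None
    thr = float(config.get("crop_threshold", 0.0))
    return lambda v: preprocess(v, crop=crop, normalize=normalize,
                                target_grid=grid, crop_threshold=thr)


# ---------------------------------------------------------------------------
# slice decomposition
# ---------------------------------------------------------------------------

def extract_slices(v: Volume) -> SliceBank:
    """Cut a volume into its sagittal, coronal and axial slice stacks."""
    data = v.data
    return SliceBank(
        sagittal=[data[i, :, :] for i in range(data.shape[0])],
        coronal=[data[:, j, :] for j in range(data.shape[1])],
        axial=[data[:, :, k] for k in range(data.shape[2])],
    )


def stack_slices(slices: list[np.ndarray], view: str,
                 spacing=(1.0, 1.0, 1.0)) -> Volume:
    """Inverse of :func:`extract_slices` for one view."""
    arr = np.stack(slices, axis={"sagittal": 0, "coronal": 1, "axial": 2,
                                 "x": 0, "y": 1, "z": 2}[view])
    return Volume(arr, spacing)
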