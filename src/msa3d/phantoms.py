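"""Synthetic brain phantoms with a localized "atrophy" lesion.

The phantom world is deliberately simple so that ground truth is exact:

* the "brain" is an axis-aligned ellipsoid inscribed in the volume box,
  intensity ~ 1 with i.i.d. Gaussian texture, background exactly 0;
* the class signal is a multiplicative intensity reduction (factor
  ``1 - effect_size``) inside a smaller lesion ellipsoid whose centre and
  radii are known, so the set of informative slices per view is known
  exactly — the ground truth needed to test slice-attention recovery and
  saliency localization.

This emulates atrophy-driven signal loss in a known subregion; it does not
emulate cortical anatomy, spatially correlated noise, or scanner effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import Volume, write_volume

__all__ = ["PhantomSpec", "SyntheticDataset", "make_phantom", "generate_dataset",
           "save_dataset", "DESK_SHAPE"]

#: Desk-scale grid: the 91x101x91 model grid's anisotropy at roughly 1/4 scale.
DESK_SHAPE: tuple[int, int, int] = (24, 28, 24)

VIEWS = ("sagittal", "coronal", "axial")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model of one phantom family.

    effect_size is the fractional intensity reduction in [0, 1] inside the
    lesion; noise_sd the i.i.d. Gaussian texture scale added to brain voxels.
    """

    shape: tuple[int, int, int] = DESK_SHAPE
    lesion_center: tuple[int, int, int] | None = None
    lesion_radii: tuple[int, int, int] = (3, 3, 3)
    effect_size: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.lesion_center is None:
            # off-centre by one brain-radius/2 along y: inside but asymmetric
            c = tuple(s // 2 + (s // 8 if ax == 1 else 0)
                      for ax, s in enumerate(self.shape))
            object.__setattr__(self, "lesion_center", c)
        _check_lesion_inside(self.shape, self.lesion_center, self.lesion_radii)


def _brain_geometry(shape):
    center = [(s - 1) / 2.0 for s in shape]
    radii = [s / 2.0 for s in shape]
    return center, radii


def _check_lesion_inside(shape, center, radii):
    """Conservative containment: ||c_norm|| + max(r_k/R_k) <= 1."""
    bc, br = _brain_geometry(shape)
    off = np.sqrt(sum(((c - b) / r) ** 2 for c, b, r in zip(center, bc, br)))
    rmax = max(r / R for r, R in zip(radii, br))
    if off + rmax > 1.0:
        raise ValueError(
            f"lesion (center {center}, radii {radii}) does not fit inside the "
            f"brain ellipsoid of shape {shape}")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec, with_lesion: bool = False) -> Volume:
    """Render one phantom volume; bitwise deterministic given ``spec.seed``.

    The lesion multiplies the (noisy) brain intensities by
    ``1 - effect_size``, so ``effect_size=0`` gives a volume identical to
    the lesion-free one at the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    bc, br = _brain_geometry(spec.shape)
    brain = _ellipsoid_mask(spec.shape, bc, br)
    data = np.zeros(spec.shape, dtype=np.float64)
    intensity = 1.0 + (rng.standard_normal(spec.shape) * spec.noise_sd
                       if spec.noise_sd > 0 else 0.0)
    data[brain] = np.broadcast_to(intensity, spec.shape)[brain]
    if with_lesion:
        lesion = _ellipsoid_mask(spec.shape, spec.lesion_center, spec.lesion_radii)
        data[lesion & brain] *= (1.0 - spec.effect_size)
    return Volume(data)


def lesion_mask(spec: PhantomSpec,
                center: tuple[int, int, int] | None = None) -> np.ndarray:
    """Boolean mask of the lesion ellipsoid (intersected with the brain)."""
    bc, br = _brain_geometry(spec.shape)
    brain = _ellipsoid_mask(spec.shape, bc, br)
    return _ellipsoid_mask(spec.shape, center or spec.lesion_center,
                           spec.lesion_radii) & brain


@dataclass
class SyntheticDataset:
    """Labelled phantoms plus exact per-view informative-slice ground truth."""

    volumes: list[Volume]
    labels: list[int]
    informative_slices: dict[str, set[int]]
    spec: PhantomSpec
    lesion_centers: list[tuple[int, int, int] | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.volumes)

    def as_arrays(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        x = np.stack([v.data for v in self.volumes]).astype(dtype)
        return x, np.asarray(self.labels, dtype=np.int64)


def _slice_range(center: int, radius: int, limit: int) -> set[int]:
    return set(range(max(center - radius, 0), min(center + radius, limit - 1) + 1))


def generate_dataset(n_per_class: int, spec: PhantomSpec,
                     jitter: tuple[int, int, int] = (2, 2, 2),
                     seed: int | None = None) -> SyntheticDataset:
    """Simulate ``n_per_class`` controls (label 0) and lesioned subjects (1).

    Each lesioned subject's centre is jittered uniformly within
    ``+/- jitter`` per axis; ``informative_slices`` records, per view, the
    union of lesion extents over the class-1 samples.  Per-sample render
    seeds are spawned from ``seed`` so different datasets never share noise.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)

    volumes, labels, centers = [], [], []
    informative: dict[str, set[int]] = {v: set() for v in VIEWS}
    for i in range(n_per_class):
        s = PhantomSpec(spec.shape, spec.lesion_center, spec.lesion_radii,
                        spec.effect_size, spec.noise_sd, int(sample_seeds[i]))
        volumes.append(make_phantom(s, with_lesion=False))
        labels.append(0)
        centers.append(None)
    for i in range(n_per_class):
        offset = [int(rng.integers(-j, j + 1)) if j > 0 else 0 for j in jitter]
        center = tuple(c + o for c, o in zip(spec.lesion_center, offset))
        _check_lesion_inside(spec.shape, center, spec.lesion_radii)
        s = PhantomSpec(spec.shape, center, spec.lesion_radii,
                        spec.effect_size, spec.noise_sd,
                        int(sample_seeds[n_per_class + i]))
        volumes.append(make_phantom(s, with_lesion=True))
        labels.append(1)
        centers.append(center)
        for ax, view in enumerate(VIEWS):
            informative[view] |= _slice_range(center[ax], spec.lesion_radii[ax],
                                              spec.shape[ax])
    return SyntheticDataset(volumes, labels, informative, spec, centers)


def save_dataset(ds: SyntheticDataset, directory: str | Path) -> Path:
    """Write phantoms as NIfTI files plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (v, y) in enumerate(zip(ds.volumes, ds.labels)):
        fname = f"phantom_{i:04d}.nii.gz"
        write_volume(v, directory / fname)
        rows.append({"filename": fname, "label": y})
    manifest = pd.DataFrame(rows)
    for view in VIEWS:
        idx = sorted(ds.informative_slices[view])
        manifest[f"informative_{view}"] = ";".join(map(str, idx))
    path = directory / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
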