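"""Voxel-grid geometry, feature containers, smoothing/resampling, parcellation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class GridGeometry:
    """Regular 3-d voxel grid with a brain mask."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.dims, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.dims:
                raise ValueError("brain_mask shape does not match dims")
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class FeatureGrid:
    """Per-scan voxel feature maps on a shared grid.

    ``data`` is (n_scans, *dims); ``index`` carries one row per scan
    with at least subject_id, scan_time and age columns.
    """

    data: np.ndarray
    geometry: GridGeometry
    index: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1:] != self.geometry.dims:
            raise ValueError("data must be (n_scans, *dims) matching geometry")
        if len(self.index) and len(self.index) != self.data.shape[0]:
            raise ValueError("index length does not match number of scans")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    def take(self, indices) -> "FeatureGrid":
        """Row subset of scans (shares geometry)."""
        indices = np.asarray(indices)
        index = self.index.iloc[indices].reset_index(drop=True) if len(self.index) else self.index
        return FeatureGrid(data=self.data[indices], geometry=self.geometry, index=index)

    def masked_matrix(self) -> np.ndarray:
        """(n_scans, n_mask_voxels) matrix restricted to the brain mask."""
        return self.data.reshape(self.n_scans, -1)[:, self.geometry.brain_mask.ravel()]

    def write(self, directory, basename: str = "features") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{basename}.npy", self.data)
        np.save(directory / f"{basename}_mask.npy", self.geometry.brain_mask)
        meta = {"dims": list(self.geometry.dims), "spacing": list(self.geometry.spacing)}
        (directory / f"{basename}_geometry.json").write_text(json.dumps(meta))
        self.index.to_csv(directory / f"{basename}_index.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory, basename: str = "features") -> "FeatureGrid":
        directory = Path(directory)
        data = np.load(directory / f"{basename}.npy")
        mask = np.load(directory / f"{basename}_mask.npy")
        meta = json.loads((directory / f"{basename}_geometry.json").read_text())
        index = pd.read_csv(directory / f"{basename}_index.tsv", sep="\t")
        geom = GridGeometry(tuple(meta["dims"]), tuple(meta["spacing"]), mask)
        return cls(data=data, geometry=geom, index=index)

    def to_nifti(self, scan: int):
        """Optional NIfTI export of one scan (requires nibabel)."""
        import nibabel as nib

        affine = np.diag(list(self.geometry.spacing) + [1.0])
        return nib.Nifti1Image(self.data[scan], affine)


def smooth_and_resample(grid: FeatureGrid, fwhm: float, factor: int) -> FeatureGrid:
    """Gaussian smoothing (stated FWHM in mm) then linear-interpolation downsampling.

    sigma per axis = fwhm / (spacing * 2 sqrt(2 ln 2)); ``factor`` is the
    integer downsampling factor per axis, applied via order-1 spline
    (linear) interpolation. fwhm = 0 and factor = 1 is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)

    geom = grid.geometry
    data = grid.data
    if fwhm > 0:
        sigma_vox = [fwhm / (s * FWHM_TO_SIGMA) for s in geom.spacing]
        data = np.stack(
            [ndimage.gaussian_filter(scan, sigma=sigma_vox, mode="nearest") for scan in data]
        )
    if factor > 1:
        zoom = 1.0 / factor
        data = np.stack(
            [ndimage.zoom(scan, zoom=zoom, order=1, mode="nearest", grid_mode=True)
             for scan in data]
        )
        new_mask = (
            ndimage.zoom(
                geom.brain_mask.astype(float), zoom=zoom, order=1, mode="nearest",
                grid_mode=True,
            )
            > 0.5
        )
        if not new_mask.any():  # tiny masks can vanish under coarse resampling
            new_mask = (
                ndimage.zoom(
                    geom.brain_mask.astype(float), zoom=zoom, order=1, mode="nearest",
                    grid_mode=True,
                )
                > 0.0
            )
        geom = GridGeometry(
            dims=data.shape[1:],
            spacing=tuple(s * factor for s in geom.spacing),
            brain_mask=new_mask,
        )
    return FeatureGrid(data=data, geometry=geom, index=grid.index.copy())


@dataclass
class ParcelAtlas:
    """Integer parcel labels per voxel; 0 is background."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"parcels without names: {sorted(unnamed)}")

    @property
    def parcel_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


def shell_core_mask(dims, shell_fraction: float = 0.55):
    """Analytic spherical brain: returns (brain_mask, shell_mask, core_mask).

    The brain is a centered ball; the core is the inner ball with radius
    ``shell_fraction`` of the brain radius, and the shell is the rest.
    Stands in for a cortical-ribbon vs subcortical partition.
    """
    dims = tuple(int(d) for d in dims)
    coords = np.meshgrid(*[np.arange(d) - (d - 1) / 2.0 for d in dims], indexing="ij")
    radius = min(dims) / 2.0 - 0.5
    r = np.sqrt(sum(c**2 for c in coords)) / radius
    brain = r <= 1.0
    core = r <= shell_fraction
    shell = brain & ~core
    return brain, shell, core


def shell_core_atlas(geometry: GridGeometry, shell_fraction: float = 0.55) -> ParcelAtlas:
    """Nine-parcel analytic atlas: one core parcel plus eight shell octants."""
    dims = geometry.dims
    brain, shell, core = shell_core_mask(dims, shell_fraction)
    brain &= geometry.brain_mask
    shell &= geometry.brain_mask
    core &= geometry.brain_mask
    labels = np.zeros(dims, dtype=int)
    labels[core] = 1
    names = {1: "core"}
    centers = [(d - 1) / 2.0 for d in dims]
    octant = np.zeros(dims, dtype=int)
    for axis, c in enumerate(centers):
        idx = np.arange(dims[axis]) >= c
        shape = [1, 1, 1]
        shape[axis] = dims[axis]
        octant += (idx.reshape(shape) * (2**axis)).astype(int) * np.ones(dims, dtype=int)
    for o in range(8):
        sel = shell & (octant == o)
        if sel.any():
            label = 2 + o
            labels[sel] = label
            names[label] = f"shell_octant_{o}"
    return ParcelAtlas(labels=labels, names=names)


def parcel_means(grid: FeatureGrid, atlas: ParcelAtlas) -> pd.DataFrame:
    """Mean feature value over member voxels, per scan x parcel."""
    if atlas.labels.shape != grid.geometry.dims:
        raise ValueError("atlas not aligned to grid")
    flat_labels = atlas.labels.ravel()
    mat = grid.data.reshape(grid.n_scans, -1)
    out = {}
    for pid in atlas.parcel_ids:
        members = flat_labels == pid
        if not members.any():
            raise ValueError(f"parcel {pid} ({atlas.names[pid]}) is empty")
        out[atlas.names[pid]] = mat[:, members].mean(axis=1)
    table = pd.DataFrame(out)
    if len(grid.index):
        table = pd.concat([grid.index.reset_index(drop=True), table], axis=1)
    return table
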