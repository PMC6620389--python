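"""ALM soma segmentation by seeded confidence-connected region growing.

The soma appears as a bright blob in the confocal stack.  Starting from the
traced soma node, a small seed neighborhood defines initial intensity
statistics; voxels whose intensity lies within ``multiplier`` standard
deviations of the region mean are flood-filled from the seed, the statistics
are recomputed from the grown region, and the process repeats for a fixed
number of iterations.  A morphological opening then strips thin attachments
(the dendrite stub), and the volume is the voxel count times the physical
voxel volume.

Stacks are stored ``(z, y, x)`` (the multi-page TIFF axis order) with
physical voxel dimensions ``(dx, dy, dz)`` in µm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import ball

from .classification import ClassifiedTree, NodeLabel
from .swc_io import SeedMarker

__all__ = [
    "ImageStack",
    "SegmentConfig",
    "SomaSegmentation",
    "SegmentationOverflowError",
    "gaussian_smooth",
    "confidence_connected",
    "segment_soma",
    "find_boundary_seed",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class SegmentationOverflowError(RuntimeError):
    """Region growing flooded most of the stack: bad seed or multiplier."""


@dataclass
class ImageStack:
    """3D grayscale stack, voxels indexed (z, y, x), voxel_dims (dx, dy, dz) µm."""

    voxels: np.ndarray
    voxel_dims: tuple[float, float, float] = (0.223, 0.223, 0.300)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("stack must be a non-empty 3D array")
        if min(self.voxel_dims) <= 0:
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def um_to_voxel(self, xyz_um) -> tuple[int, int, int]:
        """Map a physical (x, y, z) µm point to the nearest (z, y, x) index."""
        dx, dy, dz = self.voxel_dims
        x, y, z = xyz_um
        idx = (int(round(z / dz)), int(round(y / dy)), int(round(x / dx)))
        if not all(0 <= idx[k] < self.voxels.shape[k] for k in range(3)):
            raise ValueError(f"point {tuple(xyz_um)} µm falls outside the stack")
        return idx

    @classmethod
    def from_tiff(
        cls, path: str | Path, voxel_dims=(0.223, 0.223, 0.300)
    ) -> "ImageStack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return cls(voxels=arr, voxel_dims=tuple(voxel_dims))

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.voxels)


@dataclass(frozen=True)
class SegmentConfig:
    """Region-growing hyperparameters (the standard defaults of the family)."""

    multiplier: float = 2.5
    iterations: int = 4
    init_radius: int = 1
    opening_radius: int = 1
    blur_sigma: tuple[float, float, float] = (0.7, 0.7, 0.52)

    def __post_init__(self) -> None:
        if self.multiplier <= 0 or self.iterations <= 0 or self.init_radius <= 0:
            raise ValueError("segmentation parameters must be positive")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be non-negative")


@dataclass
class SomaSegmentation:
    mask: np.ndarray
    seed: tuple[int, int, int]
    volume: float       # µm³
    voxel_count: int


def gaussian_smooth(stack: ImageStack, sigma=(0.7, 0.7, 0.52)) -> ImageStack:
    """Separable Gaussian blur with reflective borders; sigma per (x, y, z) axis
    in voxels.  Mean intensity is preserved (reflection loses no mass)."""
    sx, sy, sz = sigma
    if min(sx, sy, sz) < 0:
        raise ValueError("sigma must be non-negative")
    out = ndimage.gaussian_filter(
        stack.voxels.astype(float), sigma=(sz, sy, sx), mode="reflect"
    )
    return ImageStack(voxels=out, voxel_dims=stack.voxel_dims)


def _flood_within(
    img: np.ndarray, seed: tuple[int, int, int], lo: float, hi: float
) -> np.ndarray:
    """26-connected component of {lo <= img <= hi} containing the seed."""
    within = (img >= lo) & (img <= hi)
    if not within[seed]:
        within = within.copy()
        within[seed] = True  # seed always belongs to its own region
    labels, _ = ndimage.label(within, structure=_STRUCTURE_26)
    return labels == labels[seed]


def confidence_connected(
    stack: ImageStack,
    seed: tuple[int, int, int],
    cfg: SegmentConfig | None = None,
    init_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Seeded confidence-connected region growing (26-connectivity).

    Initialize with the seed's cubic neighborhood of radius ``init_radius``
    (or an explicit ``init_mask``); for ``iterations`` rounds, compute the
    region's intensity mean and SD and flood-fill from the seed accepting
    voxels within ``mean ± multiplier*SD``.  Raises
    ``SegmentationOverflowError`` if the region exceeds half the stack.
    """
    cfg = cfg or SegmentConfig()
    img = stack.voxels.astype(float)
    shape = img.shape
    if not all(0 <= seed[k] < shape[k] for k in range(3)):
        raise ValueError(f"seed {seed} outside the stack")

    if init_mask is not None:
        region = init_mask.astype(bool)
        if not region[seed]:
            raise ValueError("init_mask must contain the seed")
    else:
        r = cfg.init_radius
        sl = tuple(
            slice(max(0, seed[k] - r), min(shape[k], seed[k] + r + 1))
            for k in range(3)
        )
        region = np.zeros(shape, dtype=bool)
        region[sl] = True
    for _ in range(cfg.iterations):
        vals = img[region]
        mu, sd = float(vals.mean()), float(vals.std())
        region = _flood_within(
            img, seed, mu - cfg.multiplier * sd, mu + cfg.multiplier * sd
        )
        if region.sum() > 0.5 * img.size:
            raise SegmentationOverflowError(
                "segmentation flooded more than half the stack; "
                "check the seed location and the multiplier"
            )
    return region


def segment_soma(
    stack: ImageStack,
    tree: ClassifiedTree,
    cfg: SegmentConfig | None = None,
) -> SomaSegmentation:
    """Segment the ALM soma seeded at the soma node nearest the tree root.

    The confidence-connected mask is cleaned with a morphological opening
    (ball of ``opening_radius`` voxels in index space), keeping the seed's
    connected component; the volume is the voxel count times the voxel
    volume.
    """
    cfg = cfg or SegmentConfig()
    soma_ids = [i for i, lab in tree.labels.items() if lab == NodeLabel.SOMA]
    if not soma_ids:
        raise ValueError("classified tree has no soma nodes")
    root_pos = tree.tree.nodes[tree.tree.root_id].position
    nearest = min(
        soma_ids,
        key=lambda i: (
            float(np.linalg.norm(tree.tree.nodes[i].position - root_pos)),
            i,
        ),
    )
    seed_node = tree.tree.nodes[nearest]
    seed = stack.um_to_voxel(seed_node.position)

    # Segmentation runs on the stack as given.  The pipeline's Gaussian
    # pre-smoothing exists to help tracing; smoothing before region growing
    # collapses the noise statistics the confidence band is built from and
    # biases the soma boundary toward the bright interior.
    mask = confidence_connected(stack, seed, cfg)
    if cfg.opening_radius > 0:
        # closing + hole filling consolidates the noisy mask crust before
        # the opening strips thin attachments; opening a rough crust would
        # erode a full voxel shell off the soma
        r = cfg.opening_radius
        mask = ndimage.binary_fill_holes(
            ndimage.binary_closing(mask, structure=ball(r))
        )
        mask = ndimage.binary_opening(mask, structure=ball(r))
        if mask[seed]:
            labels, _ = ndimage.label(mask, structure=_STRUCTURE_26)
            mask = labels == labels[seed]
        elif mask.any():
            # opening may erode the exact seed voxel; keep the component
            # nearest the seed
            labels, n = ndimage.label(mask, structure=_STRUCTURE_26)
            centers = ndimage.center_of_mass(mask, labels, range(1, n + 1))
            best = int(
                np.argmin(
                    [np.linalg.norm(np.array(c) - np.array(seed)) for c in centers]
                )
            )
            mask = labels == best + 1
    count = int(mask.sum())
    return SomaSegmentation(
        mask=mask,
        seed=seed,
        volume=count * stack.voxel_volume,
        voxel_count=count,
    )


def find_boundary_seed(stack: ImageStack) -> SeedMarker:
    """Brightest voxel on the six faces of the volume — where a PLM process
    crosses the field-of-view boundary.  Ties break by lexicographic
    (z, y, x) index order."""
    img = stack.voxels
    boundary = np.zeros(img.shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    masked = np.where(boundary, img, -np.inf)
    z, y, x = np.unravel_index(int(np.argmax(masked)), img.shape)
    return SeedMarker(x=float(x), y=float(y), z=float(z), comment="boundary seed")
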