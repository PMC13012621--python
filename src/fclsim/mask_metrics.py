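"""Statistics on 2-D integer label masks of flat clathrin lattices.

Experimental FCL masks (e.g. derived from platinum-replica EM images)
arrive as integer-labeled grids: 0 is background, each positive label one
FCL.  Labels are authoritative; no re-segmentation is performed, and a
label split over disconnected pixels is still one FCL.  The two metrics
are per-FCL area (pixel count x pixel area) and the number of *other* FCLs
whose centroid falls in the closed 1 um x 1 um axis-aligned square centred
on each FCL centroid.  A synthetic generator produces masks of
non-overlapping ellipses with log-normal areas and exact ground truth for
round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse


class MaskFormatError(ValueError):
    """The mask is not a non-negative integer label grid."""


@dataclass(frozen=True)
class LabelMask:
    """2-D non-negative integer label grid with physical pixel size (um)."""

    grid: np.ndarray
    pixel_size: float  # um per pixel

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise MaskFormatError("mask grid must be 2-D")
        if not np.issubdtype(grid.dtype, np.integer):
            if np.any(grid != np.round(grid)):
                raise MaskFormatError("mask labels must be integers")
            grid = grid.astype(np.int64)
        if np.any(grid < 0):
            raise MaskFormatError("mask labels must be non-negative")
        if self.pixel_size <= 0:
            raise MaskFormatError("pixel_size must be > 0 um")
        object.__setattr__(self, "grid", grid.astype(np.int64))


@dataclass(frozen=True)
class FCLRecord:
    """One labeled FCL: label id, centroid (um), area (um^2)."""

    label: int
    centroid: tuple
    area: float


def fcl_records(mask: LabelMask) -> list[FCLRecord]:
    """One record per distinct nonzero label.

    Area = pixel count x pixel_size^2; centroid = mean of pixel centers,
    where pixel (row, col) has its center at ((col + 0.5), (row + 0.5)) x
    pixel_size in (x, y).
    """
    grid = mask.grid
    labels = np.unique(grid)
    labels = labels[labels > 0]
    records = []
    for lab in labels:
        rows, cols = np.nonzero(grid == lab)
        area = len(rows) * mask.pixel_size**2
        cx = (cols.mean() + 0.5) * mask.pixel_size
        cy = (rows.mean() + 0.5) * mask.pixel_size
        records.append(FCLRecord(label=int(lab), centroid=(cx, cy), area=area))
    return records


def neighbor_counts(
    records: list[FCLRecord], window: float = 1.0, include_self: bool = False
) -> np.ndarray:
    """FCLs per neighboring ``window`` x ``window`` um square.

    For each record, counts records whose centroid lies in the closed
    axis-aligned square of side ``window`` centred on its centroid.  The
    focal FCL itself is excluded unless ``include_self``.
    """
    if window <= 0:
        raise MaskFormatError("window must be > 0 um")
    if not records:
        return np.zeros(0, dtype=int)
    cent = np.array([r.centroid for r in records])
    half = window / 2.0
    inside = (np.abs(cent[:, None, :] - cent[None, :, :]) <= half).all(axis=-1)
    counts = inside.sum(axis=1)
    if not include_self:
        counts = counts - 1
    return counts.astype(int)


def synthetic_mask(
    n_fcl: int,
    field_size: float = 6.0,
    pixel_size: float = 0.01,
    mean_area: float = 0.05,
    sigma_log: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_attempts_per_fcl: int = 200,
):
    """Generate a synthetic FCL label mask with exact ground truth.

    Non-overlapping ellipses with log-normal areas (``mean_area`` um^2 is
    the distribution mean; ``sigma_log`` the log-space sd) at uniform random
    centers and orientations within a ``field_size`` x ``field_size`` um
    field.  Returns ``(LabelMask, records)`` where the records carry the
    rasterised ground truth (pixel-count areas and pixel centroids).  If a
    region cannot be placed without overlap within the attempt budget the
    mask is returned with fewer regions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_fcl < 0 or field_size <= 0 or pixel_size <= 0 or mean_area <= 0:
        raise MaskFormatError("generator parameters must be positive")
    npix = int(round(field_size / pixel_size))
    grid = np.zeros((npix, npix), dtype=np.int64)
    # log-normal with mean = exp(mu + sigma^2/2)
    mu = np.log(mean_area) - sigma_log**2 / 2.0

    label = 0
    for _ in range(n_fcl):
        placed = False
        for _attempt in range(max_attempts_per_fcl):
            area = float(rng.lognormal(mu, sigma_log))
            aspect = rng.uniform(1.0, 2.0)
            # area = pi a b with a = aspect * b (semi-axes, um)
            b = np.sqrt(area / (np.pi * aspect))
            a = aspect * b
            theta = rng.uniform(0.0, np.pi)
            cx = rng.uniform(a, field_size - a)
            cy = rng.uniform(a, field_size - a)
            rr, cc = draw_ellipse(
                cy / pixel_size,
                cx / pixel_size,
                a / pixel_size,
                b / pixel_size,
                shape=grid.shape,
                rotation=theta,
            )
            if len(rr) == 0 or np.any(grid[rr, cc] != 0):
                continue
            label += 1
            grid[rr, cc] = label
            placed = True
            break
        if not placed:
            break

    mask = LabelMask(grid=grid, pixel_size=pixel_size)
    return mask, fcl_records(mask)


# --------------------------------------------------------------------------
# mask I/O: integer TIFF or headerless CSV integer grid
# --------------------------------------------------------------------------


def load_mask(path: str | Path, pixel_size: float) -> LabelMask:
    """Read a label mask from an integer TIFF or a headerless CSV grid.

    ``pixel_size`` (um/pixel) is always supplied explicitly, never inferred.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = tifffile.imread(path)
    else:
        grid = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    return LabelMask(grid=np.asarray(grid), pixel_size=pixel_size)


def save_mask(mask: LabelMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, mask.grid.astype(np.int32))
    else:
        np.savetxt(path, mask.grid, fmt="%d", delimiter=",")
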