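"""Object-preserving cropping, patch extraction and augmentation.

Arbitrary-size images are turned into fixed-extent training patches in two
steps: a crop window whose extent tiles exactly by the patch size is placed
so the foreground object stays inside the patches (centred on the mask
centroid, clamped to the image), then patches are cut on a regular grid.
When an axis is already divisible by the patch extent no cropping happens on
that axis; when the foreground bounding box is larger than a patch on some
axis, cropping cannot keep the object whole, so the full image extent is kept
on that axis and an overlapping tiling covers it instead.

Coordinates are 0-based, half-open, row-major: (y, x) in 2D, (z, y, x) in 3D.
Channels, if any, occupy a trailing axis and are never tiled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["PatchPlan", "AugmentSpec", "plan_patches", "extract_patches", "augment"]


@dataclass(frozen=True)
class PatchPlan:
    """Crop window plus tiling layout mapping an image to fixed-size patches."""

    image_extent: tuple[int, ...]
    crop_offset: tuple[int, ...]
    crop_extent: tuple[int, ...]
    patch_extent: tuple[int, ...]
    patch_origins: tuple[tuple[int, ...], ...]  # offsets within the crop window
    overlap_flag: bool

    def __post_init__(self) -> None:
        for origin in self.patch_origins:
            for o, p, c in zip(origin, self.patch_extent, self.crop_extent):
                if o < 0 or o + p > c:
                    raise ValueError("patch exceeds the crop window")
        if not self.overlap_flag:
            for c, p in zip(self.crop_extent, self.patch_extent):
                if c % p:
                    raise ValueError(
                        "non-overlapping plan requires crop extent to be a "
                        "multiple of the patch extent"
                    )

    @property
    def num_patches(self) -> int:
        return len(self.patch_origins)


def _foreground_stats(mask: np.ndarray | None):
    """(centroid, bbox_min, bbox_max) of the foreground, or None if empty."""
    if mask is None:
        return None
    fg = np.argwhere(np.asarray(mask) > 0)
    if fg.size == 0:
        return None
    return fg.mean(axis=0), fg.min(axis=0), fg.max(axis=0) + 1


def _cover_origins(window: int, patch: int) -> list[int]:
    """Origins of the minimal patch count covering ``window``, spread evenly."""
    n = math.ceil(window / patch)
    if n == 1:
        return [0]
    span = window - patch
    return [round(i * span / (n - 1)) for i in range(n)]


def plan_patches(
    image_extent: tuple[int, ...] | list[int],
    patch_extent: tuple[int, ...] | list[int],
    mask: np.ndarray | None = None,
) -> PatchPlan:
    """Plan the crop window and patch tiling for one image.

    Per axis: if the image extent is divisible by the patch extent the full
    extent is kept and tiled without overlap.  Otherwise a crop window of
    size ``floor(extent / patch) * patch`` is centred on the foreground-mask
    centroid (image centre when the mask is empty) and clamped to the image
    bounds, ties broken toward the lower coordinate.  If the foreground
    bounding box exceeds the patch extent on the axis, cropping cannot keep
    the object inside one patch: the full image extent is kept and covered by
    the minimal number of overlapping patches with evenly spread origins.

    Foreground pixels that fall outside the chosen crop window are reported
    via a warning carrying the clipped-pixel count.
    """
    image_extent = tuple(int(e) for e in image_extent)
    patch_extent = tuple(int(p) for p in patch_extent)
    if len(image_extent) != len(patch_extent):
        raise ValueError("image and patch extents must have the same rank")
    for axis, (e, p) in enumerate(zip(image_extent, patch_extent)):
        if p <= 0:
            raise ValueError(f"patch extent must be positive (axis {axis})")
        if p > e:
            raise ValueError(
                f"patch extent {p} exceeds image extent {e} on axis {axis}"
            )
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape[: len(image_extent)] != image_extent:
            raise ValueError("mask is not aligned with the image extent")
    stats = _foreground_stats(mask)

    offsets: list[int] = []
    extents: list[int] = []
    per_axis_origins: list[list[int]] = []
    overlap = False
    for axis, (e, p) in enumerate(zip(image_extent, patch_extent)):
        if e % p == 0:
            offsets.append(0)
            extents.append(e)
            per_axis_origins.append(list(range(0, e, p)))
            continue
        bbox_fits = True
        if stats is not None:
            _, lo, hi = stats
            bbox_fits = (hi[axis] - lo[axis]) <= p
        if not bbox_fits:
            # No crop can contain the object in a single patch on this axis.
            offsets.append(0)
            extents.append(e)
            per_axis_origins.append(_cover_origins(e, p))
            overlap = True
            continue
        crop = (e // p) * p
        if stats is not None:
            center = stats[0][axis]
        else:
            center = (e - 1) / 2.0
        off = int(math.floor(center - crop / 2.0 + 0.5))  # ties toward lower
        off = max(0, min(off, e - crop))
        offsets.append(off)
        extents.append(crop)
        per_axis_origins.append(list(range(0, crop, p)))

    origins = tuple(tuple(o) for o in product(*per_axis_origins))
    plan = PatchPlan(
        image_extent=image_extent,
        crop_offset=tuple(offsets),
        crop_extent=tuple(extents),
        patch_extent=patch_extent,
        patch_origins=origins,
        overlap_flag=overlap,
    )

    if stats is not None:
        window = tuple(
            slice(o, o + c) for o, c in zip(plan.crop_offset, plan.crop_extent)
        )
        total_fg = int(np.count_nonzero(mask > 0))
        kept_fg = int(np.count_nonzero(np.asarray(mask)[window] > 0))
        clipped = total_fg - kept_fg
        if clipped:
            warnings.warn(
                f"cropping clips {clipped} foreground pixel(s) outside the "
                "crop window",
                stacklevel=2,
            )
    return plan


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray | None,
    plan: PatchPlan,
) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Cut (patch, mask_patch) pairs per the plan, in row-major origin order.

    Pixel values are untouched; a trailing channel axis on the image is kept
    intact.  ``mask`` may be ``None`` (inference), in which case the second
    element of each pair is ``None``.
    """
    image = np.asarray(image)
    rank = len(plan.image_extent)
    if image.shape[:rank] != plan.image_extent:
        raise ValueError(
            f"plan was made for extent {plan.image_extent} but image has "
            f"{image.shape[:rank]}"
        )
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape[:rank] != plan.image_extent:
            raise ValueError("mask extent does not match the plan")
    out = []
    for origin in plan.patch_origins:
        sl = tuple(
            slice(co + o, co + o + p)
            for co, o, p in zip(plan.crop_offset, origin, plan.patch_extent)
        )
        out.append((image[sl], None if mask is None else mask[sl]))
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """Geometric augmentation settings.

    ``rotations`` holds quarter-turn multiples (0..3); ``reflections`` flags
    one entry per spatial axis; ``max_translation_fraction`` bounds a random
    integer-pixel translation (reflection-padded) drawn per pair from
    ``rng_seed``.  Each enabled transform beyond the identity multiplies the
    output count.
    """

    rotations: frozenset[int] = frozenset({0})
    reflections: tuple[bool, ...] = ()
    max_translation_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rot = frozenset(int(r) % 4 for r in self.rotations) or frozenset({0})
        object.__setattr__(self, "rotations", rot)
        if not 0.0 <= self.max_translation_fraction <= 0.2:
            raise ValueError("max_translation_fraction must lie in [0, 0.2]")


def _spatial_rank(image: np.ndarray, mask: np.ndarray) -> int:
    # The mask carries spatial axes only; the image may add a channel axis.
    return mask.ndim


def _rotate(a: np.ndarray, k: int, rank: int) -> np.ndarray:
    # Quarter turns act in the trailing spatial plane: (y, x) in both 2D and
    # 3D, leaving a 3D stack's z axis (and any channel axis) untouched.
    return np.rot90(a, k=k, axes=(rank - 2, rank - 1))


def _reflect(a: np.ndarray, axis: int) -> np.ndarray:
    return np.flip(a, axis=axis)


def _translate(a: np.ndarray, shift: tuple[int, ...], rank: int) -> np.ndarray:
    pad = [(abs(s), abs(s)) for s in shift] + [(0, 0)] * (a.ndim - rank)
    padded = np.pad(a, pad, mode="reflect")
    sl = tuple(
        slice(abs(s) - s, abs(s) - s + n) for s, n in zip(shift, a.shape[:rank])
    ) + (slice(None),) * (a.ndim - rank)
    return padded[sl]


def augment(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    spec: AugmentSpec,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Apply the enabled geometric transforms to every (image, mask) pair.

    The identical transform is applied to image and mask (nearest-neighbour
    semantics hold trivially: quarter-turn rotations, axis reflections and
    integer-pixel translations never interpolate).  Output order: for each
    input pair, its transforms in a fixed order (rotations ascending,
    reflections by axis, then the translation); deterministic under
    ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for image, mask in pairs:
        image = np.asarray(image)
        mask = np.asarray(mask)
        rank = _spatial_rank(image, mask)
        for k in sorted(spec.rotations):
            out.append((_rotate(image, k, rank), _rotate(mask, k, rank)))
        for axis, enabled in enumerate(spec.reflections[:rank]):
            if enabled:
                out.append((_reflect(image, axis), _reflect(mask, axis)))
        if spec.max_translation_fraction > 0:
            shift = tuple(
                int(rng.integers(-int(spec.max_translation_fraction * n),
                                 int(spec.max_translation_fraction * n) + 1))
                for n in mask.shape[:rank]
            )
            out.append(
                (_translate(image, shift, rank), _translate(mask, shift, rank))
            )
    return out
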