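"""Multi-view, multi-scale patch extraction, voxel sampling and mirroring.

For a query voxel, each requested view contributes one 32x32 patch per
pyramid scale ``lambda``: the scale-0 patch is the unaltered in-plane crop
centred on the voxel (which sits at patch index (16, 16)); the scale-l patch
covers a ``(32 * 2**l)**2`` in-plane field of view reduced to 32x32 by
non-overlapping ``2**l x 2**l`` average pooling. The pooling lattice is
anchored to the volume grid (block edges at multiples of ``2**l``), so a
context patch is exactly a 32x32 crop of the once-pooled image and the
voxel lies inside patch pixel (16, 16); a volume that is constant within
each ``2**l``-block yields the scale-0 patch of the block-mean image
exactly. Regions outside the grid are zero-filled — consistent with
intensities normalized to zero mean inside the eye mask — so every voxel
is a valid query point. Channels follow the canonical sequence order
(FIESTA-like, T2-like, T1c-like).

Two code paths produce identical (bit-for-bit) patches:

* :func:`extract_patch_set` — the readable reference: aligned crop of the
  volume, then block-mean pooling;
* :class:`PatchExtractor` — the batch path used by training and inference,
  which pools each view's plane stack once per subject and then only
  gathers 32x32 crops per query voxel.

Block means are accumulated in float64 (summing the fast in-plane axis
first) and rounded to float32, in the same order on both paths. Because
the lattice is grid-anchored, all voxels sharing a ``2**l`` block (and the
slice, for planar views) share the scale-l patch bit-for-bit — inference
exploits this to evaluate each context branch once per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VIEW_AXES, VIEWS_2D, LabelMap, SequenceStack, SphereROI

PATCH = 32  # in-plane patch size fixed by the architecture
HALF = PATCH // 2  # query voxel sits inside patch pixel (16, 16)


@dataclass(frozen=True)
class PatchRequest:
    """What to extract around one query voxel."""

    voxel: tuple[int, int, int]
    scales: tuple[int, ...] = (0, 1, 2)
    views: tuple[str, ...] = VIEWS_2D
    patch_size: int = PATCH

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or tuple(sorted(self.scales)) != tuple(self.scales):
            raise ValueError("scales must be non-empty and sorted")
        bad = set(self.views) - (set(VIEWS_2D) | {"3d"})
        if bad:
            raise ValueError(f"unknown views {bad}")
        if "3d" in self.views and len(self.views) != 1:
            raise ValueError("the 3d view cannot be mixed with planar views")
        if self.patch_size != PATCH:
            raise ValueError("patch size is fixed at 32 by the architecture")


@dataclass
class PatchSet:
    """Patches keyed by ``(view, scale)``: ``(32, 32, ch)`` planar arrays or
    ``(32, 32, 32, ch)`` for the 3d view; optional training label."""

    patches: dict[tuple[str, int], np.ndarray]
    label: int | None = None


def _block_mean(crop: np.ndarray, m: int) -> np.ndarray:
    """Average-pool a (..., A*m, B*m) crop to (..., A, B); float32 result."""
    if m == 1:
        return crop.astype(np.float32, copy=True)
    sh = crop.shape
    a, b = sh[-2] // m, sh[-1] // m
    r = crop.reshape(sh[:-2] + (a, m, b, m))
    s = r.sum(axis=-1, dtype=np.float64).sum(axis=-2)
    return (s / (m * m)).astype(np.float32)


def _block_mean_3d(crop: np.ndarray, m: int) -> np.ndarray:
    if m == 1:
        return crop.astype(np.float32, copy=True)
    sh = crop.shape
    a, b, c = (sh[-3] // m, sh[-2] // m, sh[-1] // m)
    r = crop.reshape(sh[:-3] + (a, m, b, m, c, m))
    s = r.sum(axis=-1, dtype=np.float64).sum(axis=-2).sum(axis=-3)
    return (s / m**3).astype(np.float32)


def _aligned_crop(arr: np.ndarray, starts, size: int) -> np.ndarray:
    """Zero-padded crop ``[start, start+size)`` per trailing axis of a
    channel-first array."""
    ch = arr.shape[0]
    nd = len(starts)
    out = np.zeros((ch,) + (size,) * nd, dtype=arr.dtype)
    src, dst = [slice(None)], [slice(None)]
    for ax, s0 in enumerate(starts):
        n = arr.shape[1 + ax]
        lo, hi = max(s0, 0), min(s0 + size, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - s0, hi - s0))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def extract_patch_set(
    stack: SequenceStack, request: PatchRequest, label: int | None = None
) -> PatchSet:
    """Reference (single-voxel) patch extraction; see module docstring."""
    arr = stack.as_array()  # (ch, X, Y, Z)
    v = tuple(int(c) for c in request.voxel)
    if any(not 0 <= v[i] < arr.shape[1 + i] for i in range(3)):
        raise IndexError(f"query voxel {v} outside grid {arr.shape[1:]}")
    patches: dict[tuple[str, int], np.ndarray] = {}
    for view in request.views:
        for lam in request.scales:
            m = 2**lam
            if view == "3d":
                starts = [(v[i] // m - HALF) * m for i in range(3)]
                crop = _aligned_crop(arr, starts, PATCH * m)
                patch = _block_mean_3d(crop, m)  # (ch, 32, 32, 32)
            else:
                (a_ax, b_ax), s_ax = VIEW_AXES[view]
                plane = np.take(arr, v[s_ax], axis=1 + s_ax)  # (ch, A, B)
                starts = [(v[a_ax] // m - HALF) * m, (v[b_ax] // m - HALF) * m]
                crop = _aligned_crop(plane, starts, PATCH * m)
                patch = _block_mean(crop, m)  # (ch, 32, 32)
            patches[(view, lam)] = np.ascontiguousarray(np.moveaxis(patch, 0, -1))
    return PatchSet(patches, label=label)


class PatchExtractor:
    """Fast batched patch extraction from once-pooled pyramid volumes.

    With the grid-anchored pooling lattice, the scale-l patch is a plain
    32x32 crop (at index ``coordinate // 2**l``) of the pooled plane stack,
    so per-voxel extraction is a single flat gather.
    """

    def __init__(
        self,
        stack: SequenceStack | np.ndarray,
        scales: tuple[int, ...] = (0, 1, 2),
        views: tuple[str, ...] = VIEWS_2D,
    ) -> None:
        arr = stack.as_array() if isinstance(stack, SequenceStack) else stack
        self.arr = np.asarray(arr, dtype=np.float32)
        self.scales = tuple(scales)
        self.views = tuple(views)
        self.ch = self.arr.shape[0]
        self.grid_shape = self.arr.shape[1:]
        # pooled[(view, lam)] -> channels-last pooled array with Z-margins
        self._pooled: dict[tuple[str, int], np.ndarray] = {}
        for view in self.views:
            for lam in self.scales:
                self._precompute(view, lam)

    # Pooled-array layout: pooled block q covers original coordinates
    # [q*m, (q+1)*m); with a zero margin of Z = 16 blocks per side, patch
    # row k of the voxel at coordinate i is pooled index i//m + k (the
    # crop start i//m - 16 plus the margin 16).
    _Z = HALF

    def _pool_axis_padded(self, sub: np.ndarray, m: int, axes) -> np.ndarray:
        """Block-mean ``sub`` over the given trailing axes (length multiple
        of m), float64 accumulation, float32 result."""
        if m == 1:
            return np.ascontiguousarray(sub)
        sh = list(sub.shape)
        rsh = []
        for ax in range(sub.ndim):
            if ax in axes:
                rsh.extend([sh[ax] // m, m])
            else:
                rsh.append(sh[ax])
        r = sub.reshape(rsh)
        # sum the m-sub-axes from last to first to fix accumulation order
        m_axes = []
        pos = 0
        for ax in range(sub.ndim):
            if ax in axes:
                m_axes.append(pos + 1)
                pos += 2
            else:
                pos += 1
        s = r
        first = True
        for a in reversed(m_axes):
            if first:
                s = s.sum(axis=a, dtype=np.float64)
                first = False
            else:
                s = s.sum(axis=a)
        return (s / float(m ** len(axes))).astype(np.float32)

    def _precompute(self, view: str, lam: int) -> None:
        m = 2**lam
        Z = self._Z
        if view == "3d":
            dims = self.arr.shape[1:]
            pads = [(0, (-d) % m) for d in dims]
            padded = np.pad(self.arr, [(0, 0)] + pads)
            core = self._pool_axis_padded(padded, m, axes=(1, 2, 3))
            stacked = np.moveaxis(core, 0, -1)  # (A',B',C',ch)
            stacked = np.pad(stacked, [(Z, Z)] * 3 + [(0, 0)])
            self._pooled[(view, lam)] = np.ascontiguousarray(stacked)
            return
        (a_ax, b_ax), s_ax = VIEW_AXES[view]
        reordered = np.transpose(self.arr, (0, 1 + s_ax, 1 + a_ax, 1 + b_ax))
        A, B = reordered.shape[2], reordered.shape[3]
        padded = np.pad(reordered, [(0, 0), (0, 0), (0, (-A) % m), (0, (-B) % m)])
        core = self._pool_axis_padded(padded, m, axes=(2, 3))  # (ch,S,A',B')
        stacked = np.moveaxis(core, 0, -1)  # (S, A', B', ch)
        stacked = np.pad(stacked, [(0, 0), (Z, Z), (Z, Z), (0, 0)])
        self._pooled[(view, lam)] = np.ascontiguousarray(stacked)

    def extract_batch(
        self, voxels: np.ndarray, keys=None
    ) -> dict[tuple[str, int], np.ndarray]:
        """Patches for a batch of query voxels.

        Parameters
        ----------
        voxels
            Integer array of shape ``(B, 3)``.
        keys
            Optional subset of this extractor's ``(view, scale)`` pairs.

        Returns
        -------
        dict mapping ``(view, scale)`` to ``(B, 32, 32, ch)`` float32 arrays
        (``(B, 32, 32, 32, ch)`` for the 3d view).
        """
        voxels = np.asarray(voxels, dtype=np.int32)
        out: dict[tuple[str, int], np.ndarray] = {}
        rng32 = np.arange(PATCH, dtype=np.int32)
        wanted = (
            [(v, s) for v in self.views for s in self.scales]
            if keys is None
            else list(keys)
        )
        for view, lam in wanted:
            m = 2**lam
            stacked = self._pooled[(view, lam)]
            if view == "3d":
                Aq, Bq, Cq, ch = stacked.shape
                q0 = voxels // m  # margin Z cancels the -16 crop offset
                fa = (q0[:, 0][:, None] + rng32)
                fb = (fa * Bq)[:, :, None] + (q0[:, 1][:, None] + rng32)[:, None, :]
                fc = (fb * Cq)[:, :, :, None] + (
                    q0[:, 2][:, None] + rng32
                )[:, None, None, :]
                out[(view, lam)] = np.take(
                    stacked.reshape(-1, ch), fc, axis=0, mode="clip"
                )
                continue
            (a_ax, b_ax), s_ax = VIEW_AXES[view]
            S, Aq, Bq, ch = stacked.shape
            sc = voxels[:, s_ax]
            qa0 = voxels[:, a_ax] // m
            qb0 = voxels[:, b_ax] // m
            fa = (sc * Aq + qa0)[:, None] + rng32
            fb = (fa * Bq)[:, :, None] + (qb0[:, None] + rng32)[:, None, :]
            out[(view, lam)] = np.take(
                stacked.reshape(-1, ch), fb, axis=0, mode="clip"
            )
        return out

    def patch_owner_keys(self, voxels: np.ndarray, view: str, lam: int) -> np.ndarray:
        """Integer key identifying which voxels share the (view, scale)
        patch: same pooled block (and slice, for planar views)."""
        voxels = np.asarray(voxels, dtype=np.int64)
        m = 2**lam
        if view == "3d":
            q = voxels // m
            return (q[:, 0] * self.grid_shape[1] + q[:, 1]) * self.grid_shape[2] + q[:, 2]
        (a_ax, b_ax), s_ax = VIEW_AXES[view]
        return (
            voxels[:, s_ax] * self.grid_shape[a_ax] + voxels[:, a_ax] // m
        ) * self.grid_shape[b_ax] + voxels[:, b_ax] // m


def sample_training_voxels(
    labels: LabelMap,
    roi: SphereROI,
    fraction: float = 0.05,
    seed: int = 0,
    pool: str = "roi",
    inference_dilation_mm: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random voxel sample (without replacement) for training.

    The eligible pool is the 25 mm registration mask (``pool="roi"``, the
    default), the 5 mm normalization mask (``pool="roi5"`` — exactly the
    region classified at inference, which keeps the background class near
    the globe and the class balance workable on small grids), or the whole
    volume (``pool="volume"``); ``pool="inference"`` uses the sphere
    dilated by ``inference_dilation_mm`` — exactly the region classified at
    test time.
    Returns ``floor(fraction * pool_size)`` voxels as an ``(n, 3)`` integer
    array plus their ``(n,)`` class labels; reproducible given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if pool == "roi":
        eligible = roi.registration_mask
    elif pool == "roi5":
        eligible = roi.normalization_mask
    elif pool == "inference":
        eligible = roi.mask(inference_dilation_mm)
    elif pool == "volume":
        eligible = np.ones(labels.shape, dtype=bool)
    else:
        raise ValueError("pool must be 'roi', 'roi5', 'inference' or 'volume'")
    coords = np.argwhere(eligible)
    n_pool = coords.shape[0]
    if n_pool == 0:
        raise ValueError("eligible training-voxel pool is empty")
    n = int(np.floor(fraction * n_pool))
    if n == 0:
        raise ValueError("fraction too small: zero voxels sampled")
    rng = np.random.default_rng(seed)
    take = rng.choice(n_pool, size=n, replace=False)
    voxels = coords[take]
    classes = labels.data[tuple(voxels.T)]
    return voxels, classes


#: axis (within a patch array, after the leading batch axis if any) to flip
#: under a left-right mirror; None = patch content unchanged (a left-right
#: flip relocates the sagittal plane itself, so the in-plane content of the
#: sagittal patch at the mirrored voxel is the original patch unchanged).
_MIRROR_AXIS = {"axial": 0, "coronal": 0, "sagittal": None, "3d": 0}


def mirror_augment(patch_set: PatchSet, apply: bool) -> PatchSet:
    """Left-right mirroring augmentation; involutive, label unchanged."""
    if not apply:
        return PatchSet(dict(patch_set.patches), label=patch_set.label)
    flipped = {}
    for (view, lam), patch in patch_set.patches.items():
        ax = _MIRROR_AXIS[view]
        flipped[(view, lam)] = (
            patch.copy() if ax is None else np.ascontiguousarray(np.flip(patch, axis=ax))
        )
    return PatchSet(flipped, label=patch_set.label)


def mirror_batch(
    batch: dict[tuple[str, int], np.ndarray], flip_mask: np.ndarray
) -> dict[tuple[str, int], np.ndarray]:
    """Mirror the selected samples of a batched patch dict in place."""
    idx = np.nonzero(flip_mask)[0]
    if idx.size == 0:
        return batch
    for (view, lam), arr in batch.items():
        ax = _MIRROR_AXIS[view]
        if ax is not None:
            arr[idx] = np.flip(arr[idx], axis=1 + ax)
    return batch
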