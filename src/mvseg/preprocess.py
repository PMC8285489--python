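"""Eye localization and intensity normalization.

The eye is localized with a 3D Hough sphere transform: high-gradient voxels
vote along their (signed) gradient direction for sphere centres at each
candidate radius; per-radius accumulators are surface-normalized, smoothed,
and peak-picked with non-maximum suppression between detections. From each
detected sphere two Euclidean-dilation masks are derived: a 25 mm mask (the
registration / training region of interest) and a 5 mm mask (the intensity
normalization support). Intensities of each sequence are rescaled to zero
mean, unit variance within the union of the detected 5 mm masks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import SequenceStack, SphereROI


def hough_detect_eyes(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    radius_range: tuple[float, float] = (8.0, 14.0),
    max_spheres: int = 1,
    radius_step_mm: float = 0.5,
    edge_percentile: float = 98.0,
    smooth_sigma_mm: float = 1.0,
    vote_threshold: float = 0.08,
) -> list[SphereROI]:
    """Detect up to ``max_spheres`` spherical eyes, ranked by vote strength.

    Parameters
    ----------
    volume
        3D scalar grid (any contrast in which the globe has a strong edge).
    spacing
        Voxel spacing in mm.
    radius_range
        (min, max) sphere radius in mm searched in ``radius_step_mm`` steps;
        the reported radius is refined by parabolic interpolation.
    vote_threshold
        Minimum support for a detection: the fraction of edge voxels lying
        on the candidate sphere's surface shell with radially aligned
        gradients. Coherent spheres score high; incoherent edges from pure
        noise stay far below the default.

    Returns
    -------
    list of :class:`SphereROI`, strongest first; empty when nothing exceeds
    the vote threshold (e.g. a constant volume has no edges, hence no votes).
    """
    volume = np.asarray(volume, dtype=np.float32)
    spacing = np.asarray(spacing, dtype=np.float64)
    shape = volume.shape
    if not 0 < radius_range[0] <= radius_range[1]:
        raise ValueError("radius_range must be positive and ordered")
    if radius_range[1] >= min(n * s for n, s in zip(shape, spacing)) / 2:
        raise ValueError("radius_range exceeds half the grid extent")

    g = np.gradient(volume, *spacing)
    mag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    thresh = np.percentile(mag, edge_percentile)
    if thresh <= 0:
        return []
    edges = mag > thresh
    n_edges = int(edges.sum())
    if n_edges == 0:
        return []

    pos = np.argwhere(edges).astype(np.float64)  # voxel coords
    dirs = np.stack([gi[edges] for gi in g], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    radii = np.arange(radius_range[0], radius_range[1] + 1e-9, radius_step_mm)
    mean_sp = float(np.mean(spacing))
    acc = np.zeros((len(radii),) + shape, dtype=np.float32)
    sigma_vox = smooth_sigma_mm / spacing
    for ir, r in enumerate(radii):
        step_vox = (r * dirs) / spacing  # offset in voxels
        # a bright interior pulls the gradient toward the centre; vote both
        # ways so dark-interior spheres are found too
        for sgn in (+1.0, -1.0):
            cand = np.rint(pos + sgn * step_vox).astype(np.int64)
            ok = np.all((cand >= 0) & (cand < np.asarray(shape)), axis=1)
            if not ok.any():
                continue
            flat = np.ravel_multi_index(tuple(cand[ok].T), shape)
            acc[ir] += np.bincount(flat, minlength=int(np.prod(shape))).reshape(
                shape
            ).astype(np.float32)
        # surface normalization: an ideal sphere contributes ~4*pi*(r/s)^2 votes
        acc[ir] /= 4.0 * np.pi * (r / mean_sp) ** 2
        acc[ir] = ndimage.gaussian_filter(acc[ir], sigma=sigma_vox)

    def support(center: tuple[int, ...], radius: float) -> float:
        """Fraction of edge voxels on the sphere's shell with radially
        aligned gradients (the detection's geometric support)."""
        rel = (pos - np.asarray(center)) * spacing
        dist = np.linalg.norm(rel, axis=1)
        tol = max(1.0, 1.5 * mean_sp)
        on_shell = np.abs(dist - radius) <= tol
        with np.errstate(invalid="ignore"):
            cosang = np.abs(
                (rel * dirs).sum(axis=1) / np.where(dist > 0, dist, np.inf)
            )
        aligned = cosang >= np.cos(np.deg2rad(30.0))
        return float((on_shell & aligned).sum()) / n_edges

    detections: list[SphereROI] = []
    for _ in range(max_spheres):
        peak = np.unravel_index(np.argmax(acc), acc.shape)
        if acc[peak] <= 0:
            break
        ir, center = peak[0], tuple(int(c) for c in peak[1:])
        radius = radii[ir]
        if 0 < ir < len(radii) - 1:  # parabolic refinement over radius
            y0, y1, y2 = (float(acc[(j,) + center]) for j in (ir - 1, ir, ir + 1))
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                radius += 0.5 * radius_step_mm * (y0 - y2) / denom
        votes = support(center, float(radius))
        if votes < vote_threshold:
            break
        detections.append(
            SphereROI(
                center=center,
                radius_mm=float(radius),
                grid_shape=shape,
                voxel_spacing=tuple(float(s) for s in spacing),
                votes=votes,
            )
        )
        # non-maximum suppression: no second eye within 1.5x the radius
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        d2 = sum(((gi - c) * s) ** 2 for gi, c, s in zip(grids, center, spacing))
        acc[:, d2 <= (1.5 * radius) ** 2] = 0.0
    return detections


def normalize_intensities(
    stack: SequenceStack, rois: list[SphereROI]
) -> SequenceStack:
    """Standardize each sequence to mean 0, variance 1 within the eye masks.

    The statistics are computed over the union of the detected spheres'
    5 mm masks (both eyes when two are present); the affine transform
    ``(v - mu) / sigma`` is then applied to the whole volume.
    """
    if not rois:
        raise ValueError("no eye ROI provided for normalization")
    union = np.zeros(stack.shape, dtype=bool)
    for roi in rois:
        union |= roi.normalization_mask
    if not union.any():
        raise ValueError("union of 5 mm normalization masks is empty")

    volumes = {}
    for name in stack.sequences:
        v = stack.volumes[name].astype(np.float32)
        mu = float(v[union].mean(dtype=np.float64))
        sd = float(v[union].std(dtype=np.float64))
        if sd <= 0:
            raise ValueError(
                f"sequence {name!r} has zero intensity variance within the "
                "5 mm eye mask; cannot normalize"
            )
        volumes[name] = ((v - mu) / sd).astype(np.float32)
    return SequenceStack(volumes, stack.voxel_spacing)


def detect_and_normalize(
    stack: SequenceStack,
    reference_sequence: str = "fiesta",
    radius_range: tuple[float, float] = (8.0, 14.0),
    max_spheres: int = 1,
    **hough_kwargs,
) -> tuple[SequenceStack, list[SphereROI]]:
    """Run Hough detection on the reference sequence, then normalize."""
    rois = hough_detect_eyes(
        stack.volumes[reference_sequence],
        stack.voxel_spacing,
        radius_range=radius_range,
        max_spheres=max_spheres,
        **hough_kwargs,
    )
    if not rois:
        raise RuntimeError("eye detection failed: no Hough accumulator peak")
    return normalize_intensities(stack, rois), rois
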