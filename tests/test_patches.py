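"""Patch-pyramid extraction, voxel sampling and mirroring contracts."""

import numpy as np
import pytest

from mvseg.core import VIEW_AXES, SequenceStack
from mvseg.patches import (
    HALF,
    PATCH,
    PatchExtractor,
    PatchRequest,
    extract_patch_set,
    mirror_augment,
    sample_training_voxels,
)
from mvseg.preprocess import hough_detect_eyes


def pool_then_crop_oracle(volume, voxel, view, lam):
    """Independent oracle: average-pool the whole (zero-padded) plane on the
    grid-anchored lattice, then crop 32x32 at ``coordinate // 2**lam - 16``."""
    m = 2**lam
    (a_ax, b_ax), s_ax = VIEW_AXES[view]
    plane = np.take(volume, voxel[s_ax], axis=s_ax)  # (A, B)
    A, B = plane.shape
    padded = np.pad(plane, ((0, (-A) % m), (0, (-B) % m)))
    pooled = (
        padded.reshape(padded.shape[0] // m, m, padded.shape[1] // m, m)
        .sum(axis=-1, dtype=np.float64)
        .sum(axis=-2)
        / (m * m)
    ).astype(np.float32)
    out = np.zeros((PATCH, PATCH), np.float32)
    qa0 = voxel[a_ax] // m - HALF
    qb0 = voxel[b_ax] // m - HALF
    for u in range(PATCH):
        for v in range(PATCH):
            qa, qb = qa0 + u, qb0 + v
            if 0 <= qa < pooled.shape[0] and 0 <= qb < pooled.shape[1]:
                out[u, v] = pooled[qa, qb]
    return out


@pytest.mark.parametrize("view", ["axial", "coronal", "sagittal"])
@pytest.mark.parametrize("lam", [0, 1, 2])
def test_patches_match_pool_then_crop_oracle(random_stack, rng, view, lam):
    shape = random_stack.shape
    voxels = [tuple(rng.integers(0, s) for s in shape) for _ in range(6)]
    voxels += [(0, 0, 0), tuple(s - 1 for s in shape)]
    for vox in voxels:
        ps = extract_patch_set(random_stack, PatchRequest(voxel=vox))
        got = ps.patches[(view, lam)]
        for ci, seq in enumerate(random_stack.sequences):
            oracle = pool_then_crop_oracle(random_stack.volumes[seq], vox, view, lam)
            assert np.array_equal(got[:, :, ci], oracle)


def test_fast_extractor_bit_identical_to_reference(random_stack, rng):
    ext = PatchExtractor(random_stack)
    shape = random_stack.shape
    voxels = np.stack(
        [rng.integers(0, s, size=30) for s in shape], axis=1
    )
    voxels[0] = (0, 0, 0)
    voxels[1] = tuple(s - 1 for s in shape)
    batch = ext.extract_batch(voxels)
    for i in range(len(voxels)):
        ref = extract_patch_set(random_stack, PatchRequest(voxel=tuple(voxels[i])))
        for key, arr in ref.patches.items():
            assert np.array_equal(batch[key][i], arr)


def test_fast_extractor_bit_identical_for_3d_view(random_stack, rng):
    ext = PatchExtractor(random_stack, views=("3d",))
    shape = random_stack.shape
    voxels = np.stack([rng.integers(0, s, size=5) for s in shape], axis=1)
    batch = ext.extract_batch(voxels)
    for i in range(len(voxels)):
        ref = extract_patch_set(
            random_stack, PatchRequest(voxel=tuple(voxels[i]), views=("3d",))
        )
        for key, arr in ref.patches.items():
            assert np.array_equal(batch[key][i], arr)


def test_field_of_view_is_32_times_scale(rng):
    """An impulse just inside the aligned window appears in the patch; one
    just outside does not."""
    shape = (160, 160, 9)
    vox = (80, 80, 4)
    for lam in (0, 1, 2):
        m = 2**lam
        lo = (vox[0] // m - HALF) * m  # window start along x
        for impulse_x, expected in [(lo, True), (lo - 1, False)]:
            vol = np.zeros(shape, np.float32)
            vol[impulse_x, 80, 4] = 1.0
            stack = SequenceStack({"fiesta": vol}, (1, 1, 1))
            ps = extract_patch_set(
                stack, PatchRequest(voxel=vox, scales=(lam,), views=("axial",))
            )
            assert (ps.patches[("axial", lam)] != 0).any() == expected


def test_constant_volume_patch_values():
    vol = np.full((64, 64, 64), 3.25, np.float32)
    stack = SequenceStack({"fiesta": vol}, (1, 1, 1))
    ps = extract_patch_set(stack, PatchRequest(voxel=(32, 32, 32)))
    for (view, lam), patch in ps.patches.items():
        if lam < 2:  # windows (<= 64 voxels wide) lie fully inside the grid
            assert np.allclose(patch, 3.25)
        else:  # the 128-wide window clips; its in-grid core is constant
            assert np.allclose(patch[8:24, 8:24, :], 3.25)
        assert patch[HALF, HALF, 0] == np.float32(3.25)


def test_blockwise_constant_volume_equals_blockmean_patch(rng):
    """Constant 2x2 in-plane blocks: the scale-1 patch equals the scale-0
    patch of the block-mean image."""
    small = rng.normal(size=(20, 20, 8)).astype(np.float32)
    big = np.repeat(np.repeat(small, 2, axis=0), 2, axis=1)  # (40, 40, 8)
    stack = SequenceStack({"fiesta": big}, (1, 1, 1))
    block_stack = SequenceStack({"fiesta": small}, (1, 1, 1))
    for vox in [(13, 21, 3), (20, 20, 4), (0, 39, 7)]:
        lam1 = extract_patch_set(
            stack, PatchRequest(voxel=vox, scales=(1,), views=("axial",))
        ).patches[("axial", 1)]
        lam0 = extract_patch_set(
            block_stack,
            PatchRequest(voxel=(vox[0] // 2, vox[1] // 2, vox[2]),
                         scales=(0,), views=("axial",)),
        ).patches[("axial", 0)]
        assert np.allclose(lam1, lam0, atol=1e-6)


def test_corner_voxel_padding_contract(random_stack):
    ps = extract_patch_set(random_stack, PatchRequest(voxel=(0, 0, 0)))
    patch = ps.patches[("axial", 0)]
    assert (patch[:HALF, :, :] == 0).all()  # out-of-grid rows zero-filled
    assert (patch[:, :HALF, :] == 0).all()
    assert (patch[HALF:, HALF:, :] != 0).any()


def test_pyramid_energy_conserved(random_stack, rng):
    """Mean of the scale-l patch equals the mean of its aligned wide crop."""
    vol = random_stack.volumes["fiesta"]
    for lam in (1, 2):
        m = 2**lam
        vox = tuple(int(rng.integers(0, s)) for s in vol.shape)
        ps = extract_patch_set(
            random_stack, PatchRequest(voxel=vox, scales=(lam,), views=("axial",))
        )
        patch = ps.patches[("axial", lam)][:, :, 0]
        plane = vol[:, :, vox[2]]
        a0 = (vox[0] // m - HALF) * m
        b0 = (vox[1] // m - HALF) * m
        wide = np.zeros((PATCH * m, PATCH * m), np.float64)
        for u in range(PATCH * m):
            for v in range(PATCH * m):
                if 0 <= a0 + u < plane.shape[0] and 0 <= b0 + v < plane.shape[1]:
                    wide[u, v] = plane[a0 + u, b0 + v]
        assert patch.mean(dtype=np.float64) == pytest.approx(wide.mean(), rel=1e-5)


def test_three_views_share_query_voxel_value_at_center(random_stack, rng):
    vox = tuple(int(rng.integers(4, s - 4)) for s in random_stack.shape)
    ps = extract_patch_set(random_stack, PatchRequest(voxel=vox, scales=(0,)))
    expected = random_stack.volumes["fiesta"][vox]
    for view in ("axial", "coronal", "sagittal"):
        assert ps.patches[(view, 0)][HALF, HALF, 0] == expected


def test_extraction_repeatable_bitwise(random_stack):
    req = PatchRequest(voxel=(8, 9, 10))
    a = extract_patch_set(random_stack, req)
    b = extract_patch_set(random_stack, req)
    for key in a.patches:
        assert np.array_equal(a.patches[key], b.patches[key])


def test_request_validation():
    with pytest.raises(ValueError):
        PatchRequest(voxel=(0, 0, 0), scales=())
    with pytest.raises(ValueError):
        PatchRequest(voxel=(0, 0, 0), scales=(1, 0))
    with pytest.raises(ValueError):
        PatchRequest(voxel=(0, 0, 0), views=("axial", "3d"))
    with pytest.raises(IndexError):
        stack = SequenceStack({"fiesta": np.zeros((4, 4, 4), np.float32)}, (1, 1, 1))
        extract_patch_set(stack, PatchRequest(voxel=(9, 0, 0)))


@pytest.fixture(scope="module")
def roi(desk_subject):
    return hough_detect_eyes(
        desk_subject.stack.volumes["fiesta"],
        desk_subject.spec.voxel_spacing,
        radius_range=(6.5, 13.0),
    )[0]


class TestSampler:
    def test_full_fraction_enumerates_pool_once(self, desk_subject, roi):
        voxels, classes = sample_training_voxels(
            desk_subject.labels, roi, fraction=1.0, seed=0
        )
        pool = int(roi.registration_mask.sum())
        assert len(voxels) == pool
        assert len(np.unique(np.ravel_multi_index(tuple(voxels.T),
                                                  desk_subject.labels.shape))) == pool

    def test_sample_count_is_floor_of_fraction(self, desk_subject, roi):
        pool = int(roi.registration_mask.sum())
        voxels, _ = sample_training_voxels(
            desk_subject.labels, roi, fraction=0.05, seed=0
        )
        assert len(voxels) == int(np.floor(0.05 * pool))

    def test_two_seeds_overlap_near_hypergeometric(self, desk_subject, roi):
        frac = 0.2
        pool = int(roi.registration_mask.sum())
        n = int(np.floor(frac * pool))
        sets = []
        for seed in (1, 2):
            v, _ = sample_training_voxels(desk_subject.labels, roi,
                                          fraction=frac, seed=seed)
            sets.append(set(map(tuple, v)))
        overlap = len(sets[0] & sets[1])
        expected = n * n / pool  # E[|A ∩ B|] for independent draws
        sd = np.sqrt(n * frac * (1 - frac))
        assert abs(overlap - expected) < 6 * sd

    def test_labels_match_voxels(self, desk_subject, roi):
        voxels, classes = sample_training_voxels(
            desk_subject.labels, roi, fraction=0.1, seed=3
        )
        assert np.array_equal(classes, desk_subject.labels.data[tuple(voxels.T)])

    def test_degenerate_fraction_rejected(self, desk_subject, roi):
        with pytest.raises(ValueError):
            sample_training_voxels(desk_subject.labels, roi, fraction=1e-9, seed=0)
        with pytest.raises(ValueError):
            sample_training_voxels(desk_subject.labels, roi, fraction=0.0, seed=0)


class TestMirroring:
    def _patch_set(self, stack, vox=(8, 9, 10)):
        return extract_patch_set(stack, PatchRequest(voxel=vox), label=2)

    def test_disabled_is_identity(self, random_stack):
        ps = self._patch_set(random_stack)
        out = mirror_augment(ps, apply=False)
        for key in ps.patches:
            assert np.array_equal(out.patches[key], ps.patches[key])
        assert out.label == 2

    def test_involutive_bit_exact(self, random_stack):
        ps = self._patch_set(random_stack)
        twice = mirror_augment(mirror_augment(ps, True), True)
        for key in ps.patches:
            assert np.array_equal(twice.patches[key], ps.patches[key])
        assert twice.label == 2

    def test_symmetric_input_invariant(self, rng):
        # volume with left-right symmetry vol[x] == vol[19 - x]; for the
        # voxel at x = 10 the 32-row window spans coordinates symmetric
        # about x = 9.5, so the flipped patch reproduces the original
        half = rng.normal(size=(10, 21, 19)).astype(np.float32)
        vol = np.concatenate([half, half[::-1]], axis=0)  # x-size 20
        stack = SequenceStack({"fiesta": vol}, (1, 1, 1))
        vox = (10, 9, 9)
        ps = extract_patch_set(
            stack, PatchRequest(voxel=vox, scales=(0,)), label=2
        )
        mirrored = mirror_augment(ps, True)
        for view in ("axial", "coronal"):
            assert np.array_equal(mirrored.patches[(view, 0)],
                                  ps.patches[(view, 0)])
        # sagittal content is unchanged under mirroring by construction
        assert np.array_equal(mirrored.patches[("sagittal", 0)],
                              ps.patches[("sagittal", 0)])
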