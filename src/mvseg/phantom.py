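"""Synthetic multi-sequence eye-MRI phantoms with 6-class ground truth.

The phantom emulates the geometry the segmentation method assumes: a thin
scleral shell enclosing the vitreous humour, an ellipsoidal lens apposed to
the inner wall at the anterior pole (+y), and optional tumor blobs and a
retinal-detachment wedge inside the globe. Per-sequence tissue contrast is a
configurable (class, sequence) -> mean-intensity table plus i.i.d. Gaussian
noise; class boundaries are assigned by a voxel-centre-in-solid test so the
ground truth is unambiguous for metric oracles (no partial-volume modelling).

Overlaps are resolved with fixed priority lens > retinal detachment > tumor >
vitreous; the sclera shell is never overwritten, so it stays closed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CLASS_INDEX,
    N_CLASSES,
    SEQUENCE_ORDER,
    LabelMap,
    SequenceStack,
)

#: default per-sequence class mean intensities (background, sclera, vitreous,
#: lens, retinal detachment, tumor). Vitreous is bright on the steady-state
#: (FIESTA-like) and T2-like sequences; tumor enhances on the contrast
#: T1-like sequence and is darker than vitreous on T2 — the qualitative
#: contrast structure of the clinical sequences. Values are configurable.
DEFAULT_CLASS_INTENSITY: dict[str, tuple[float, ...]] = {
    "fiesta": (0.05, 0.75, 1.00, 0.45, 0.80, 0.60),
    "t2": (0.05, 0.25, 0.95, 0.40, 0.85, 0.35),
    "t1c": (0.05, 0.35, 0.20, 0.45, 0.55, 0.90),
}


@dataclass(frozen=True)
class RdWedge:
    """Retinal detachment: a sub-retinal wedge apposed to the inner wall.

    Voxels within ``half_angle_deg`` of ``direction`` (from the globe centre)
    whose radius lies within ``thickness_mm`` of the inner scleral surface.
    """

    direction: tuple[float, float, float] = (-1.0, -0.6, 0.0)
    half_angle_deg: float = 35.0
    thickness_mm: float = 2.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic eye.

    Defaults approximate the acquisition geometry of the high-resolution
    steady-state sequence (0.27 x 0.27 x 0.30 mm voxels) and an ~11 mm
    radius globe; volumes then land near the 5.5-6 mL of a child's eye.
    ``tumor_blobs`` are (centre offset from globe centre in mm, radius mm).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 118)
    voxel_spacing: tuple[float, float, float] = (0.27, 0.27, 0.30)
    globe_center: tuple[float, float, float] | None = None  # voxels; None = grid centre
    globe_radius: float = 11.0  # mm
    sclera_thickness: float = 1.0  # mm
    lens_semi_axes: tuple[float, float, float] = (3.6, 2.7, 3.6)  # mm (x, y, z)
    tumor_blobs: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((2.5, -3.0, -2.0), 5.2),
    )
    rd_wedge: RdWedge | None = RdWedge()
    class_intensity: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_INTENSITY)
    )
    noise_sd: float = 0.08
    seed: int = 0

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(s for s in SEQUENCE_ORDER if s in self.class_intensity) + tuple(
            s for s in self.class_intensity if s not in SEQUENCE_ORDER
        )

    @property
    def center_voxels(self) -> tuple[float, float, float]:
        if self.globe_center is not None:
            return tuple(float(c) for c in self.globe_center)
        return tuple((n - 1) / 2.0 for n in self.grid_shape)

    @property
    def cavity_radius(self) -> float:
        """Inner scleral surface radius (mm)."""
        return self.globe_radius - self.sclera_thickness

    def validate(self) -> None:
        if not (0 < self.sclera_thickness < self.globe_radius):
            raise ValueError("sclera_thickness must lie in (0, globe_radius)")
        # globe (plus 5 mm margin) must fit inside the grid
        for c, n, s in zip(self.center_voxels, self.grid_shape, self.voxel_spacing):
            lo, hi = c * s, (n - 1 - c) * s
            if min(lo, hi) < self.globe_radius + 5.0:
                raise ValueError(
                    "globe does not fit inside the grid with a 5 mm margin"
                )
        for offset, radius in self.tumor_blobs:
            if radius <= 0:
                raise ValueError("tumor radius must be positive")
            if np.linalg.norm(offset) + radius > self.cavity_radius:
                raise ValueError(
                    f"tumor blob at {offset} (r={radius} mm) exits the globe cavity"
                )
        for seq, means in self.class_intensity.items():
            if len(means) != N_CLASSES:
                raise ValueError(
                    f"class_intensity[{seq!r}] must give all {N_CLASSES} class means"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.rd_wedge is not None:
            d["rd_wedge"] = dataclasses.asdict(self.rd_wedge)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("rd_wedge") is not None:
            rw = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["rd_wedge"].items()
            }
            d["rd_wedge"] = RdWedge(**rw)
        for key in ("grid_shape", "voxel_spacing", "globe_center", "lens_semi_axes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if "tumor_blobs" in d:
            d["tumor_blobs"] = tuple(
                (tuple(off), float(r)) for off, r in d["tumor_blobs"]
            )
        if "class_intensity" in d:
            d["class_intensity"] = {
                k: tuple(v) for k, v in d["class_intensity"].items()
            }
        return cls(**d)


@dataclass
class PhantomSubject:
    """One synthetic subject: sequences, ground-truth labels and the spec."""

    stack: SequenceStack
    labels: LabelMap
    spec: PhantomSpec
    subject_id: str = "subject"

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.stack.save(directory)
        self.labels.save(directory / "labels.nii.gz")
        (directory / "spec.json").write_text(json.dumps(self.spec.to_dict(), indent=2))


def _coordinate_grids_mm(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    """Open coordinate grids in mm relative to the globe centre."""
    c = spec.center_voxels
    return tuple(
        (np.arange(n, dtype=np.float64)[_expand(i)] - c[i]) * spec.voxel_spacing[i]
        for i, n in enumerate(spec.grid_shape)
    )


def _expand(axis: int):
    sl = [None, None, None]
    sl[axis] = slice(None)
    return tuple(sl)


def generate_phantom(spec: PhantomSpec, subject_id: str = "subject") -> PhantomSubject:
    """Generate one synthetic eye; deterministic given ``spec.seed``.

    The label map is a partition: every voxel gets exactly one class, with
    overlap priority lens > retinal detachment > tumor > vitreous, and the
    scleral shell never overwritten.
    """
    spec.validate()
    x, y, z = _coordinate_grids_mm(spec)
    r = np.sqrt(x**2 + y**2 + z**2)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    cavity = r < spec.cavity_radius
    labels[(r <= spec.globe_radius) & ~cavity] = CLASS_INDEX["sclera"]
    labels[cavity] = CLASS_INDEX["vitreous"]

    # tumor blobs (lowest interior priority: only replace vitreous)
    for offset, radius in spec.tumor_blobs:
        blob = ((x - offset[0]) ** 2 + (y - offset[1]) ** 2 + (z - offset[2]) ** 2) < radius**2
        labels[blob & (labels == CLASS_INDEX["vitreous"])] = CLASS_INDEX["tumor"]

    # retinal detachment wedge against the inner wall (beats tumor)
    if spec.rd_wedge is not None:
        w = spec.rd_wedge
        d = np.asarray(w.direction, dtype=np.float64)
        d = d / np.linalg.norm(d)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (x * d[0] + y * d[1] + z * d[2]) / np.where(r > 0, r, np.inf)
        wedge = (
            (cosang >= np.cos(np.deg2rad(w.half_angle_deg)))
            & (r < spec.cavity_radius)
            & (r >= spec.cavity_radius - w.thickness_mm)
        )
        interior = (labels == CLASS_INDEX["vitreous"]) | (labels == CLASS_INDEX["tumor"])
        labels[wedge & interior] = CLASS_INDEX["retinal_detachment"]

    # lens at the anterior pole (+y), replacing any interior class
    a, b, c = spec.lens_semi_axes
    ly = spec.cavity_radius - spec.lens_semi_axes[1]  # centre depth: touches wall
    lens = (x / a) ** 2 + ((y - ly) / b) ** 2 + (z / c) ** 2 < 1.0
    labels[lens & (labels != CLASS_INDEX["background"]) & (labels != CLASS_INDEX["sclera"])] = (
        CLASS_INDEX["lens"]
    )

    rng = np.random.default_rng(spec.seed)
    volumes = {}
    for seq in spec.sequences:
        means = np.asarray(spec.class_intensity[seq], dtype=np.float32)
        vol = means[labels]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)
        volumes[seq] = vol.astype(np.float32)

    return PhantomSubject(
        stack=SequenceStack(volumes, spec.voxel_spacing),
        labels=LabelMap(labels, spec.voxel_spacing),
        spec=spec,
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class Variability:
    """Relative (fraction) and absolute (mm) jitter ranges for a cohort.

    Each subject draws uniform jitters in ``+-range``; zero ranges reproduce
    the base spec exactly.
    """

    globe_radius_frac: float = 0.10
    center_jitter_mm: float = 1.5
    sclera_frac: float = 0.10
    lens_frac: float = 0.10
    tumor_radius_frac: float = 0.15
    tumor_center_mm: float = 1.0
    intensity_frac: float = 0.05

    @classmethod
    def zero(cls) -> "Variability":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def jitter_spec(base: PhantomSpec, var: Variability, rng: np.random.Generator,
                seed: int) -> PhantomSpec:
    """One independently jittered copy of ``base`` with the given seed."""
    u = lambda frac: 1.0 + rng.uniform(-frac, frac)
    spacing = np.asarray(base.voxel_spacing)
    center = np.asarray(base.center_voxels) + (
        rng.uniform(-var.center_jitter_mm, var.center_jitter_mm, size=3) / spacing
    )
    new_radius = base.globe_radius * u(var.globe_radius_frac)
    new_sclera = base.sclera_thickness * u(var.sclera_frac)
    cavity = new_radius - new_sclera
    blobs = []
    for off, radius in base.tumor_blobs:
        off = np.asarray(off) + rng.uniform(
            -var.tumor_center_mm, var.tumor_center_mm, size=3
        )
        r = radius * u(var.tumor_radius_frac)
        # clamp so the jittered blob stays strictly inside the cavity
        r = min(r, cavity - 0.6)
        reach = np.linalg.norm(off) + r
        if reach > cavity - 0.1:
            off = off * (cavity - 0.1 - r) / np.linalg.norm(off)
        blobs.append((tuple(off), float(r)))
    blobs = tuple(blobs)
    intensity = {
        seq: tuple(m * u(var.intensity_frac) for m in means)
        for seq, means in base.class_intensity.items()
    }
    return dataclasses.replace(
        base,
        globe_center=tuple(center),
        globe_radius=new_radius,
        sclera_thickness=new_sclera,
        lens_semi_axes=tuple(s * u(var.lens_frac) for s in base.lens_semi_axes),
        tumor_blobs=blobs,
        class_intensity=intensity,
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    variability: Variability | None = None,
    seed: int = 0,
) -> list[PhantomSubject]:
    """A cohort of independently jittered phantoms (one eye per subject).

    Subject ``i`` uses phantom seed ``base_spec.seed + i`` (so a 1-subject,
    zero-jitter cohort equals ``generate_phantom(base_spec)`` exactly); the
    ``seed`` argument drives only the geometry/contrast jitter.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_spec = base_spec if base_spec is not None else PhantomSpec()
    variability = variability if variability is not None else Variability()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        spec_i = jitter_spec(base_spec, variability, rng, seed=base_spec.seed + i)
        subjects.append(generate_phantom(spec_i, subject_id=f"subject{i:02d}"))
    return subjects


def load_subject(directory: str | Path) -> PhantomSubject:
    """Load a phantom subject previously written by :meth:`PhantomSubject.save`."""
    directory = Path(directory)
    spec = PhantomSpec.from_dict(json.loads((directory / "spec.json").read_text()))
    stack = SequenceStack.load(
        {seq: directory / f"{seq}.nii.gz" for seq in spec.sequences}
    )
    labels = LabelMap.load(directory / "labels.nii.gz")
    return PhantomSubject(
        stack=stack, labels=labels, spec=spec, subject_id=directory.name
    )


def desk_spec(seed: int = 0) -> PhantomSpec:
    """A reduced-resolution phantom for desk-scale (single-CPU) experiments.

    Same anatomy at ~3x coarser voxels (0.9 mm isotropic, 48^3 grid,
    9.5 mm globe): the tumor occupies a realistic share of the globe
    (~12%) and the vitreous keeps an interior-to-surface ratio large
    enough that overlap metrics are not dominated by single-voxel
    boundary effects, while voxel counts shrink ~25x from clinical
    resolution.
    """
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        voxel_spacing=(0.9, 0.9, 0.9),
        globe_radius=9.5,
        sclera_thickness=1.2,
        lens_semi_axes=(3.1, 2.3, 3.1),
        tumor_blobs=(((0.6, -2.8, -1.2), 4.1),),
        rd_wedge=RdWedge(direction=(-1.0, -0.6, 0.0), half_angle_deg=35.0,
                         thickness_mm=2.4),
        noise_sd=0.08,
        seed=seed,
    )
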