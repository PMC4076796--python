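"""Synthetic fMRI-like data: phantoms, time series, and multi-subject cohorts.

Every demonstration in this package runs on generated data with known ground
truth.  The generator family emulates the structure of a high-resolution
block-design activation study: a brain-like ellipsoidal volume with
white/gray/CSF tissue shells, compact spherical activation blobs confined to
gray matter, 4-D series built as HRF-convolved responses plus Gaussian noise
(optionally with intrinsic spatial smoothness), and cohorts of virtual
subjects that mix responders and non-responders with spatially jittered
activation sites.

All generators are pure functions of their spec and seed; per-subject seeds
are derived from the cohort seed with ``numpy``'s SeedSequence spawn-key
mechanism, so cohorts are reproducible subject by subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .glm import DesignSpec, build_design
from .grids import TissueMasks, VoxelGrid
from .smoothing import SmoothingKernel, gaussian_smooth, smoothing_variance_factor
from .group_inference import SubjectMap

__all__ = [
    "Blob",
    "PhantomSpec",
    "CohortSpec",
    "DesignSpec",
    "make_tissue_masks",
    "make_phantom",
    "make_timeseries",
    "make_cohort",
    "subject_seed",
    "save_cohort",
    "load_cohort",
    "spec_to_yaml",
    "phantom_spec_from_yaml",
    "cohort_spec_from_yaml",
]


@dataclass(frozen=True)
class Blob:
    """A spherical activation site: center (voxel indices), radius (voxels),
    dimensionless effect amplitude."""

    center: tuple[int, int, int]
    radius: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"blob radius must be > 0, got {self.radius}")
        if not np.isfinite(self.amplitude):
            raise ValueError("blob amplitude must be finite")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a ground-truth activation phantom with tissue shells.

    The brain is an ellipsoid with semi-axes ``brain_frac * shape / 2``;
    within it, normalized radius below ``white_frac`` is white matter, up to
    ``gray_frac`` is gray matter, and the remaining outer shell is CSF.
    Activation blobs must be centered in gray matter.
    """

    shape: tuple[int, int, int]
    blobs: tuple[Blob, ...] = ()
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_frac: float = 0.92
    white_frac: float = 0.55
    gray_frac: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.white_frac <= self.gray_frac <= 1.0:
            raise ValueError("need 0 <= white_frac <= gray_frac <= 1")
        if not 0.0 < self.brain_frac <= 1.0:
            raise ValueError("brain_frac must be in (0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a heterogeneous virtual cohort.

    ``round(responder_fraction * n_subjects)`` subjects (ties rounded toward
    responders) carry the template activation displaced by Gaussian spatial
    jitter with effect amplitude ``effect_offset``; the rest are pure noise.
    """

    n_subjects: int = 20
    responder_fraction: float = 1.0
    effect_offset: float = 1.0
    spatial_jitter: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.spatial_jitter < 0:
            raise ValueError("spatial_jitter must be >= 0")

    @property
    def n_responders(self) -> int:
        # round half toward responders
        return int(np.floor(self.responder_fraction * self.n_subjects + 0.5))


def make_tissue_masks(spec: PhantomSpec) -> TissueMasks:
    """Concentric ellipsoidal white / gray / CSF shells inside the grid."""
    shape = np.asarray(spec.shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = np.maximum(spec.brain_frac * shape / 2.0, 1e-9)
    idx = np.indices(spec.shape).astype(float)
    rho = np.sqrt(sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)))
    brain = rho <= 1.0
    white = brain & (rho < spec.white_frac)
    gray = brain & ~white & (rho <= spec.gray_frac)
    csf = brain & ~white & ~gray
    return TissueMasks(gray=gray, white=white, csf=csf)


def _ball_mask(shape, center, radius: float) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


def make_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, TissueMasks]:
    """Build the noise-free true effect map and its tissue masks.

    The returned grid holds each blob's amplitude inside the blob and zero
    elsewhere (overlaps take the maximum amplitude); tissue masks come from
    :func:`make_tissue_masks`.  Deterministic given the spec.
    """
    masks = make_tissue_masks(spec)
    truth = np.zeros(spec.shape)
    for i, blob in enumerate(spec.blobs):
        c = tuple(int(v) for v in blob.center)
        if any(not 0 <= c[a] < spec.shape[a] for a in range(3)):
            raise ValueError(f"blob {i} at {c} lies outside the grid {spec.shape}")
        if not masks.gray[c]:
            raise ValueError(f"blob {i} at {c} is not centered in gray matter")
        ball = _ball_mask(spec.shape, c, blob.radius)
        truth[ball] = np.maximum(truth[ball], blob.amplitude)
    return VoxelGrid(truth, spec.voxel_size), masks


def make_timeseries(
    truth: VoxelGrid,
    design: DesignSpec,
    noise_sd: float,
    intrinsic_fwhm: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a 4-D BOLD series: truth x task regressor + Gaussian noise.

    ``series[v, t] = truth[v] * regressor[t] + eps[v, t]`` with i.i.d.
    N(0, noise_sd^2) noise, optionally given intrinsic spatial smoothness by
    Gaussian-smoothing each frame to ``intrinsic_fwhm`` voxels.  Smoothed
    noise is generated on a padded grid, cropped, and rescaled by the
    analytic interior standard deviation, so the marginal voxel variance
    stays ``noise_sd^2`` (else smoothness and amplitude would confound).

    Returns an array of shape ``truth.shape + (design.n_scans,)``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if intrinsic_fwhm < 0:
        raise ValueError("intrinsic_fwhm must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    regressor = build_design(design)
    shape = truth.shape
    n = design.n_scans

    if intrinsic_fwhm > 0:
        pad = SmoothingKernel.from_fwhm(intrinsic_fwhm).truncation_radius
        sd_factor = np.sqrt(smoothing_variance_factor(intrinsic_fwhm))
        crop = tuple(slice(pad, pad + s) for s in shape)
        noise = np.empty(shape + (n,))
        for t in range(n):
            frame = rng.standard_normal(tuple(s + 2 * pad for s in shape))
            noise[..., t] = gaussian_smooth(frame, intrinsic_fwhm)[crop] / sd_factor
        noise *= noise_sd
    else:
        noise = noise_sd * rng.standard_normal(shape + (n,))
    return truth.values[..., None] * regressor[None, None, None, :] + noise


def subject_seed(cohort_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Stable per-subject seed: SeedSequence(cohort_seed, spawn_key=(i,))."""
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(subject_index,))


def make_cohort(spec: CohortSpec, template_blobs, shape, voxel_size=(3.0, 3.0, 3.0)) -> list[SubjectMap]:
    """Generate per-subject effect maps for a responder/non-responder cohort.

    The first ``spec.n_responders`` subjects carry the template blobs, each
    blob center displaced by a per-subject Gaussian jitter (sd
    ``spec.spatial_jitter`` voxels, rounded to the lattice, clipped to the
    grid) and filled with amplitude ``spec.effect_offset``; remaining
    subjects are pure noise.  Every map then receives i.i.d. N(0, noise_sd^2)
    noise.  The activation mask records the subject's true (displaced) blob
    support, empty for non-responders.
    """
    template_blobs = tuple(template_blobs)
    shape = tuple(int(s) for s in shape)
    maps: list[SubjectMap] = []
    for i in range(spec.n_subjects):
        ss = subject_seed(spec.seed, i)
        rng = np.random.default_rng(ss)
        truth = np.zeros(shape)
        is_responder = i < spec.n_responders
        if is_responder:
            for blob in template_blobs:
                shift = np.round(rng.normal(0.0, spec.spatial_jitter, size=3)).astype(int)
                center = np.clip(np.asarray(blob.center) + shift, 0, np.asarray(shape) - 1)
                truth[_ball_mask(shape, center, blob.radius)] = spec.effect_offset
        effect = truth + spec.noise_sd * rng.standard_normal(shape)
        maps.append(
            SubjectMap(
                subject_id=f"sub-{i:03d}",
                effect=VoxelGrid(effect, voxel_size),
                activation_mask=truth > 0,
                is_responder=is_responder,
                seed=int(ss.entropy),
            )
        )
    return maps


# ---------------------------------------------------------------------------
# on-disk exchange: NIfTI volumes, CSV manifests, YAML specs


def save_cohort(maps: list[SubjectMap], out_dir) -> pd.DataFrame:
    """Write each subject map as NIfTI plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, m in enumerate(maps):
        path = out_dir / f"{m.subject_id}_effect.nii.gz"
        m.effect.to_nifti(path)
        rows.append(
            {"subject_id": m.subject_id, "responder": bool(m.is_responder), "seed": m.seed, "path": str(path)}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "cohort_manifest.csv", index=False)
    return manifest


def load_cohort(manifest_csv) -> list[SubjectMap]:
    """Rehydrate subject maps from a :func:`save_cohort` manifest."""
    manifest = pd.read_csv(manifest_csv)
    maps = []
    for row in manifest.itertuples():
        effect = VoxelGrid.from_nifti(row.path)
        maps.append(
            SubjectMap(
                subject_id=str(row.subject_id),
                effect=effect,
                activation_mask=np.zeros(effect.shape, dtype=bool),
                is_responder=bool(row.responder),
                seed=int(row.seed),
            )
        )
    return maps


def spec_to_yaml(spec, path) -> None:
    """Serialize a PhantomSpec / CohortSpec / DesignSpec to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump({"kind": type(spec).__name__, **_plain(asdict(spec))}, fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def phantom_spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data.pop("kind", None)
    blobs = tuple(
        Blob(center=tuple(b["center"]), radius=b["radius"], amplitude=b.get("amplitude", 1.0))
        for b in data.pop("blobs", [])
    )
    data["shape"] = tuple(data["shape"])
    if "voxel_size" in data:
        data["voxel_size"] = tuple(data["voxel_size"])
    return PhantomSpec(blobs=blobs, **data)


def cohort_spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data.pop("kind", None)
    return CohortSpec(**data)
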