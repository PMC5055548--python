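"""Synthetic longitudinal FA phantom cohorts.

Real cohorts of pseudoprogression (PsP) and true-progression (TTP) glioma
patients are small and not shareable, so the pipeline ships with a phantom
generator that emulates the one property the classifier exploits: FA in the
lesion area of PsP is lower than in TTP, while everything else (background
anatomy, noise, scanner drift) is drawn from the same distribution in both
classes.

Each phantom subject is a 2D+t stack: a smooth low-frequency background
texture shared in law across classes, a disk-shaped lesion whose mean FA is
set by the class label, a global per-timepoint intensity drift, and i.i.d.
Gaussian noise, clipped to the physical FA range [0, 1] last.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

PSP = "PsP"
TTP = "TTP"
LABELS = (PSP, TTP)

# coarse-grid cell size (pixels) of the low-frequency background texture
_TEXTURE_CELL = 8


@dataclass
class PhantomConfig:
    """Generative parameters of the synthetic FA cohort.

    All FA-valued fields are in FA units (dimensionless, in [0, 1]).
    Defaults encode the study conditions used throughout: a 91x91 crop with
    three timepoints, a 15/25 PsP/TTP class split, and a 16-pixel lesion
    whose FA is depressed strongly in PsP (0.25) and mildly in TTP (0.40)
    against a 0.50 white-matter background — the classical FA picture in
    which treatment effect disrupts tissue microstructure more than
    recurrent tumor does.  Background texture (0.02), per-timepoint drift
    (0.01) and voxel noise (0.03) are shared in law across classes.
    """

    image_height: int = 91
    image_width: int = 91
    n_timepoints: int = 3
    n_psp: int = 15
    n_ttp: int = 25
    background_fa_mean: float = 0.50
    background_texture_sd: float = 0.02
    lesion_center_jitter: int = 2
    lesion_radius: int = 16
    psp_lesion_fa: float = 0.25
    ttp_lesion_fa: float = 0.40
    temporal_drift_sd: float = 0.01
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_fa_mean", "psp_lesion_fa", "ttp_lesion_fa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside the FA range [0, 1]")
        if self.psp_lesion_fa > self.ttp_lesion_fa:
            raise ValueError(
                "psp_lesion_fa must not exceed ttp_lesion_fa: the class contrast "
                "direction (PsP lesion FA lower than TTP) is fixed"
            )
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if min(self.image_height, self.image_width) < 1:
            raise ValueError("image dimensions must be positive")
        for name in ("background_texture_sd", "temporal_drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        margin_h = self.image_height / 2 - self.lesion_radius - self.lesion_center_jitter
        margin_w = self.image_width / 2 - self.lesion_radius - self.lesion_center_jitter
        if margin_h < 0 or margin_w < 0:
            raise ValueError(
                "lesion disk not fully inside image: radius + center jitter "
                f"({self.lesion_radius} + {self.lesion_center_jitter}) exceeds the "
                f"half-image margin (height margin {margin_h:.1f}, width margin {margin_w:.1f})"
            )

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SpatioTemporalVolume:
    """One subject's 2D+t FA stack: an H x W x T grid of FA values."""

    values: np.ndarray
    subject_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be an H x W x T array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FA values must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("FA values must lie in [0, 1]")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]


@dataclass
class LabeledCohort:
    """A list of subject volumes with class labels and (for phantoms) the
    ground-truth binary lesion masks."""

    volumes: list[SpatioTemporalVolume]
    lesion_masks: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.lesion_masks is not None and len(self.lesion_masks) != len(self.volumes):
            raise ValueError("lesion_masks length must equal volumes length")

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.volumes]

    @property
    def subject_ids(self) -> list[str]:
        return [v.subject_id for v in self.volumes]

    def __len__(self) -> int:
        return len(self.volumes)


def _background_texture(shape: tuple[int, int], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency zero-mean random field: white noise on a coarse grid,
    spline-upsampled to image resolution and rescaled to the target sd."""
    h, w = shape
    if sd == 0:
        # keep the rng stream aligned with the sd > 0 branch
        rng.standard_normal((max(2, -(-h // _TEXTURE_CELL) + 1), max(2, -(-w // _TEXTURE_CELL) + 1)))
        return np.zeros(shape)
    ch = max(2, -(-h // _TEXTURE_CELL) + 1)
    cw = max(2, -(-w // _TEXTURE_CELL) + 1)
    coarse = rng.standard_normal((ch, cw))
    field_ = ndimage.zoom(coarse, (h / ch, w / cw), order=3, mode="nearest", grid_mode=True)
    field_ = field_ - field_.mean()
    s = field_.std()
    if s > 0:
        field_ = field_ * (sd / s)
    return field_


def lesion_disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_subject(
    label: str,
    config: PhantomConfig,
    rng: np.random.Generator,
    subject_id: str = "subj",
) -> tuple[SpatioTemporalVolume, np.ndarray]:
    """Generate one phantom subject.

    Returns the volume and its ground-truth lesion mask. The lesion is a
    disk at the (jittered) image center whose mean FA is ``psp_lesion_fa``
    or ``ttp_lesion_fa`` by label; the background texture rides on both the
    background and the lesion so that the shared dictionary has genuine
    common structure to absorb. Per timepoint, a global drift offset is
    added, then i.i.d. noise; clipping to [0, 1] is applied last.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    h, w, T = config.image_height, config.image_width, config.n_timepoints

    texture = _background_texture((h, w), config.background_texture_sd, rng)
    jitter = rng.integers(-config.lesion_center_jitter, config.lesion_center_jitter + 1, size=2)
    center = ((h - 1) / 2 + jitter[0], (w - 1) / 2 + jitter[1])
    mask = lesion_disk_mask((h, w), center, config.lesion_radius)

    lesion_fa = config.psp_lesion_fa if label == PSP else config.ttp_lesion_fa
    base = config.background_fa_mean + texture
    base[mask] = lesion_fa + texture[mask]

    stack = np.empty((h, w, T))
    for t in range(T):
        drift = rng.normal(0.0, config.temporal_drift_sd) if config.temporal_drift_sd > 0 else 0.0
        noise = rng.normal(0.0, config.noise_sd, size=(h, w)) if config.noise_sd > 0 else 0.0
        stack[:, :, t] = base + drift + noise
    np.clip(stack, 0.0, 1.0, out=stack)

    vol = SpatioTemporalVolume(values=stack, subject_id=subject_id, label=label)
    return vol, mask


def generate_cohort(config: PhantomConfig) -> LabeledCohort:
    """Generate a labeled phantom cohort, PsP subjects first then TTP.

    Deterministic given ``config.seed``: per-subject rng streams are spawned
    from a single seed sequence, so the cohort is reproducible subject by
    subject.
    """
    n = config.n_psp + config.n_ttp
    if n < 2:
        raise ValueError("need at least two subjects (n_psp + n_ttp >= 2)")
    streams = np.random.SeedSequence(config.seed).spawn(n)
    volumes, masks = [], []
    labels = [PSP] * config.n_psp + [TTP] * config.n_ttp
    for i, (label, ss) in enumerate(zip(labels, streams)):
        vol, mask = generate_subject(
            label, config, np.random.default_rng(ss), subject_id=f"{label.lower()}_{i:03d}"
        )
        volumes.append(vol)
        masks.append(mask)
    return LabeledCohort(volumes=volumes, lesion_masks=masks)


def save_cohort(cohort: LabeledCohort, outdir: str | Path) -> Path:
    """Persist a cohort as one ``.npz`` archive per subject plus a
    tab-delimited manifest (subject_id, label, path, slice provenance)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id\tlabel\tpath\tslice_provenance"]
    for i, vol in enumerate(cohort.volumes):
        path = outdir / f"{vol.subject_id}.npz"
        payload = {"values": vol.values}
        if cohort.lesion_masks is not None:
            payload["lesion_mask"] = cohort.lesion_masks[i]
        np.savez(path, **payload)
        rows.append(f"{vol.subject_id}\t{vol.label}\t{path.name}\tsynthetic")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def load_phantom_cohort(manifest_path: str | Path) -> LabeledCohort:
    """Load a cohort previously written by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    volumes, masks = [], []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            with np.load(base / rec["path"]) as npz:
                vol = SpatioTemporalVolume(npz["values"], rec["subject_id"], rec["label"])
                masks.append(npz["lesion_mask"] if "lesion_mask" in npz else None)
            volumes.append(vol)
    if any(m is None for m in masks):
        masks = None
    return LabeledCohort(volumes=volumes, lesion_masks=masks)
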