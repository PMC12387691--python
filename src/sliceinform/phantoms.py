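"""Seeded brain-phantom cohorts with a localized class-discriminative effect.

Each phantom is a smooth ellipsoidal "brain" (intensity ≈ 0.7 with a mild
radial falloff, Gaussian-blurred edges) on a near-zero background, mimicking
a skull-stripped, intensity-normalized T1 volume. The positive class
receives — only inside the intersection of the brain mask with one chosen
orientation+segment slab — an intensity offset of ``-effect_amplitude`` and
additive texture noise, emulating localized atrophy-like signal. Both
classes receive a per-subject global intensity gain (nuisance) and
voxelwise Gaussian noise. Everything derives from explicit seeds.

The effect slab is computed with the same fifteen-segment partition
arithmetic the selection pipeline uses, so generator and analysis share one
source of truth for segment coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .slice_selection import partition_segments
from .volume_io import Orientation, Volume3D, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort",
           "write_cohort", "POSITIVE", "NEGATIVE"]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort-level generative parameters.

    ``effect_amplitude`` is the mean intensity decrease (normalized
    units) inside the effect region for the positive class;
    ``effect_texture_sd`` adds i.i.d. texture there; ``noise_sd`` is
    voxelwise noise for everyone; ``nuisance_sd`` scales a per-subject
    global intensity gain.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    brain_semi_axes: tuple[float, float, float] = (0.40, 0.42, 0.38)
    effect_orientation: str = "axial"
    effect_segment: int = 9
    effect_amplitude: float = 0.3
    effect_texture_sd: float = 0.1
    noise_sd: float = 0.02
    nuisance_sd: float = 0.05
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 15:
            raise ValueError("every dim must be >= 15 (fifteen segments)")
        if any(a <= 0 or a > 0.5 for a in self.brain_semi_axes):
            raise ValueError("semi-axes are fractions in (0, 0.5]")
        if not 1 <= self.effect_segment <= 15:
            raise ValueError("effect_segment must be in 1..15")
        for name in ("effect_amplitude", "effect_texture_sd", "noise_sd",
                     "nuisance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        Orientation.from_name(self.effect_orientation)


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    coords = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    r2 = sum(((c - (s - 1) / 2.0) / (a * s)) ** 2
             for c, s, a in zip(coords, spec.shape, spec.brain_semi_axes))
    return r2 <= 1.0


def effect_region(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask: brain ∩ the effect segment's slab along its axis."""
    orientation = Orientation.from_name(spec.effect_orientation)
    parts = partition_segments(spec.shape[orientation.axis_index], orientation)
    seg = next(p for p in parts if p.segment_index == spec.effect_segment)
    slab = np.zeros(spec.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[orientation.axis_index] = slice(seg.start, seg.stop)
    slab[tuple(sl)] = True
    return _brain_mask(spec) & slab


def generate_phantom(spec: PhantomSpec, class_label: str,
                     subject_seed: int, subject_id: str | None = None,
                     ) -> Volume3D:
    """One seeded phantom volume for the given class."""
    if class_label not in (POSITIVE, NEGATIVE):
        raise ValueError(f"class_label must be {POSITIVE!r} or {NEGATIVE!r}")
    rng = np.random.default_rng(subject_seed)
    mask = _brain_mask(spec)
    coords = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    r2 = sum(((c - (s - 1) / 2.0) / (a * s)) ** 2
             for c, s, a in zip(coords, spec.shape, spec.brain_semi_axes))
    base = np.where(mask, 0.7 * (1.0 - 0.15 * np.minimum(r2, 1.0)), 0.0)
    base = ndimage.gaussian_filter(base, spec.blur_sigma)
    vol = base.copy()
    region = effect_region(spec)
    # draw effect noise for both classes to keep the RNG stream aligned,
    # so the null (zero-amplitude) cohorts are identical in law
    texture = rng.normal(0.0, 1.0, size=int(region.sum()))
    if class_label == POSITIVE:
        vol[region] += (-spec.effect_amplitude
                        + spec.effect_texture_sd * texture)
    gain = 1.0 + rng.normal(0.0, spec.nuisance_sd)
    vol = vol * gain + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    sid = subject_id or f"sub-{subject_seed:010d}"
    return Volume3D(vol, subject_id=sid, class_label=class_label)


def generate_cohort(spec: PhantomSpec, n_per_class: int,
                    seed: int | None = None,
                    ) -> tuple[list[tuple[Volume3D, str]], pd.DataFrame]:
    """``2·n_per_class`` phantoms with distinct per-subject seeds.

    Returns the volumes with labels plus a manifest recording every
    generative parameter. The master seed defaults to ``spec.seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    subject_seeds = [int(s) for s in
                     np.random.default_rng(ss).integers(
                         0, 2 ** 31 - 1, size=2 * n_per_class)]
    cohort: list[tuple[Volume3D, str]] = []
    rows = []
    for i, sseed in enumerate(subject_seeds):
        label = NEGATIVE if i < n_per_class else POSITIVE
        sid = f"sub-{i:03d}-{label}"
        vol = generate_phantom(spec, label, sseed, subject_id=sid)
        cohort.append((vol, label))
        rows.append({"subject_id": sid, "label": label,
                     "subject_seed": sseed, "master_seed": master,
                     **{k: (str(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(spec).items()}})
    return cohort, pd.DataFrame(rows)


def write_cohort(cohort: list[tuple[Volume3D, str]], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write each phantom as NIfTI plus the CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for vol, _label in cohort:
        write_volume(vol, out / f"{vol.subject_id}.nii.gz")
    manifest.to_csv(out / "manifest.csv", index=False)
    return out
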