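"""End-to-end runs: config parsing, selection, training, grid, artifacts.

A :class:`RunConfig` fully determines a run: the cohort (simulated or read
from a directory of NIfTI volumes + manifest), the extractor and histogram
bins for slice selection, the model architecture, the CV/training
protocol, and one master seed. Rerunning an identical config reproduces
every numeric output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import logging
import time

import numpy as np
import pandas as pd
import yaml

from .classifier import ModelConfig
from .evaluation import (ExperimentGrid, TrainHyper, accuracy_grid,
                         stack_cell_inputs)
from .extractors import FilterBankExtractor, IdentityExtractor
from .phantoms import PhantomSpec, generate_cohort, POSITIVE
from .slice_selection import CENTRAL_RANGE, SelectionResult, select_all
from .volume_io import Orientation, Volume3D, normalize_intensities, read_volume

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "select_cohort",
           "load_cohort", "export_selection"]

log = logging.getLogger("sliceinform")


class ConfigError(ValueError):
    """Configuration validation failure, naming the offending fields."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    task: str = "positive_vs_negative"
    positive_label: str = POSITIVE
    input_dir: str | None = None       # read volumes here, or ...
    simulate: dict = field(default_factory=dict)   # ... PhantomSpec overrides
    n_per_class: int = 20
    extractor: str = "filterbank"
    extractor_input: tuple[int, int] = (64, 64)
    bins: int = 256
    orientations: tuple[str, ...] = ("axial", "coronal", "sagittal")
    segments: tuple[int, ...] = tuple(CENTRAL_RANGE)
    model: dict = field(default_factory=dict)      # ModelConfig overrides
    hyper: dict = field(default_factory=dict)      # TrainHyper overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        problems = [f"unknown field {k!r}" for k in raw if k not in known]
        if problems:
            raise ConfigError(problems)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            problems.append(f"input_dir: directory {self.input_dir!r} "
                            "does not exist")
        if self.extractor not in ("filterbank", "identity"):
            problems.append(f"extractor: unknown choice {self.extractor!r}")
        for o in self.orientations:
            try:
                Orientation.from_name(o)
            except ValueError as exc:
                problems.append(f"orientations: {exc}")
        if any(not 1 <= s <= 15 for s in self.segments):
            problems.append("segments: indices must lie in 1..15")
        if self.bins < 2:
            problems.append("bins: need at least 2 histogram bins")
        if self.input_dir is None and self.n_per_class < 1:
            problems.append("n_per_class: must be >= 1 when simulating")
        try:
            self.model_config()
        except (TypeError, ValueError) as exc:
            problems.append(f"model: {exc}")
        try:
            self.train_hyper()
        except TypeError as exc:
            problems.append(f"hyper: {exc}")
        if problems:
            raise ConfigError(problems)

    def model_config(self) -> ModelConfig:
        overrides = dict(self.model)
        for key in ("input_size", "block_filters"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return ModelConfig(**overrides)

    def train_hyper(self) -> TrainHyper:
        return TrainHyper(**self.hyper)

    def phantom_spec(self) -> PhantomSpec:
        overrides = dict(self.simulate)
        for key in ("shape", "brain_semi_axes"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        overrides.setdefault("seed", self.seed)
        return PhantomSpec(**overrides)

    def build_extractor(self):
        if self.extractor == "filterbank":
            return FilterBankExtractor(input_size=self.extractor_input)
        return IdentityExtractor(input_size=self.extractor_input)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_cohort(input_dir: str | Path) -> list[tuple[Volume3D, str]]:
    """Read a cohort directory: NIfTI volumes plus ``manifest.csv``.

    The manifest needs ``subject_id`` and ``label`` columns; volumes are
    matched as ``<subject_id>.nii(.gz)``.
    """
    input_dir = Path(input_dir)
    manifest = input_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {input_dir}")
    df = pd.read_csv(manifest)
    cohort = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        path = input_dir / f"{sid}.nii.gz"
        if not path.exists():
            path = input_dir / f"{sid}.nii"
        vol = read_volume(path, subject_id=sid, class_label=str(row["label"]))
        cohort.append((vol, str(row["label"])))
    return cohort


def select_cohort(cohort: list[tuple[Volume3D, str]], cfg: RunConfig,
                  ) -> list[dict[tuple[str, int], SelectionResult]]:
    """Per-volume informative-slice selection over the configured grid."""
    extractor = cfg.build_extractor()
    orientations = tuple(Orientation.from_name(o) for o in cfg.orientations)
    out = []
    for vol, _label in cohort:
        vol = normalize_intensities(vol)
        out.append(select_all(vol, extractor, n_bins=cfg.bins,
                              orientations=orientations,
                              segment_indices=tuple(cfg.segments)))
    return out


def selection_manifest(
        selections: list[dict[tuple[str, int], SelectionResult]],
) -> pd.DataFrame:
    rows = []
    for sel in selections:
        for (orientation, seg), res in sorted(sel.items()):
            rows.append({"subject_id": res.winner.subject_id,
                         "orientation": orientation, "segment": seg,
                         "winner_index": res.winner_index,
                         "mean_entropy": res.scores[res.winner_index].mean})
    return pd.DataFrame(rows)


def export_selection(selections, out_dir: str | Path,
                     png: bool = False) -> Path:
    """Write the selection manifest (CSV + JSON) and optionally PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = selection_manifest(selections)
    df.to_csv(out / "selection.csv", index=False)
    df.to_json(out / "selection.json", orient="records", indent=2)
    if png:
        import imageio.v3 as iio
        png_dir = out / "slices"
        png_dir.mkdir(exist_ok=True)
        for sel in selections:
            for (orientation, seg), res in sorted(sel.items()):
                img = (np.clip(res.winner.pixels, 0, 1) * 255).astype(np.uint8)
                name = (f"{res.winner.subject_id}_{orientation}"
                        f"_seg{seg:02d}_slice{res.winner_index:03d}.png")
                iio.imwrite(png_dir / name, img)
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> ExperimentGrid:
    """simulate/load → select → train/evaluate grid → artifacts on disk."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    t0 = time.time()
    if cfg.input_dir is not None:
        cohort = load_cohort(cfg.input_dir)
        log.info("stage=load seed=%d n=%d t=%.1fs", cfg.seed, len(cohort),
                 time.time() - t0)
    else:
        spec = cfg.phantom_spec()
        cohort, manifest = generate_cohort(spec, cfg.n_per_class,
                                           seed=cfg.seed)
        manifest.to_csv(out / "cohort_manifest.csv", index=False)
        log.info("stage=simulate seed=%d n=%d t=%.1fs", cfg.seed,
                 len(cohort), time.time() - t0)

    t1 = time.time()
    selections = select_cohort(cohort, cfg)
    selection_manifest(selections).to_csv(out / "selection.csv", index=False)
    log.info("stage=select seed=%d cells=%d t=%.1fs", cfg.seed,
             len(selections[0]), time.time() - t1)

    t2 = time.time()
    labels = np.array([1 if lab == cfg.positive_label else 0
                       for _v, lab in cohort])
    cell_inputs = stack_cell_inputs(selections,
                                    cfg.model_config().input_size)
    grid = accuracy_grid(cell_inputs, labels, cfg.model_config(),
                         hyper=cfg.train_hyper(), seed=cfg.seed,
                         task=cfg.task, positive_class=1)
    grid.to_frame().to_csv(out / f"grid_{cfg.task}.csv", index=False)
    grid.orientation_averages().to_csv(
        out / f"grid_{cfg.task}_orientation_averages.csv", index=False)
    log.info("stage=evaluate seed=%d cells=%d t=%.1fs", cfg.seed,
             len(grid.cells), time.time() - t2)
    return grid
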