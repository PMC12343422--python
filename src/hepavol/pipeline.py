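"""End-to-end orchestration: simulate -> train -> segment -> metrics -> stats.

Each stage writes into its own subdirectory of the run directory with
stable file names, records its outputs in a JSON manifest (config hash,
per-stage seeds, output checksums), and is skipped on rerun when its
outputs already exist, so partial runs resume and completed runs are
idempotent. The single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawn keys, so any stage can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ImageVolume, load_nifti, save_nifti, save_yaml
from .stats import CohortVVRAnalysis
from .synthetic.cohort import simulate_cohort
from .synthetic.phantom import PhantomSpec, make_liver_phantom
from .unet.augment import AugmentationParams
from .unet.network import UNetConfig
from .unet.train import VesselSegmentationModel, predict
from .volumetry import (
    LABEL_HEPATIC,
    LABEL_PORTAL,
    dice_by_bin,
    vessel_to_volume_ratios,
)

STAGES = ("simulate", "train", "segment", "metrics", "stats")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is required but absent."""

    def __init__(self, path: Path, stage: str):
        super().__init__(
            f"missing artifact {path}; rerun the '{stage}' stage to produce it"
        )
        self.stage = stage


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    outdir: str = "runs/demo"
    seed: int = 0
    n_control: int = 6
    n_non_acld: int = 6
    n_acld: int = 6
    n_annotated: int = 6  # cases with 'manual' labels used for training
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        grid_shape=(48, 48, 48), spacing_mm=(3.0, 3.0, 3.5)
    ))
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(
        n_classes=5, patch_size=(32, 32, 32), stride=(16, 16, 16), epochs=60
    ))
    augment: bool = False
    stages: tuple[str, ...] = STAGES

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence((seed, STAGES.index(stage)))
    return int(ss.generate_state(1)[0] % 2**31)


class PipelineRun:
    """One reproducible run rooted at ``config.outdir``."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.root = Path(config.outdir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.root / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {
                "config_hash": config.config_hash(),
                "config": config.to_dict(),
                "seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
                "outputs": {},
            }
        save_yaml(config.to_dict(), self.root / "config.yaml")

    # -- plumbing --------------------------------------------------------
    def _record(self, stage: str, paths: list[Path]) -> None:
        self.manifest["outputs"][stage] = {
            str(p.relative_to(self.root)): _checksum(p) for p in sorted(paths)
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _done(self, stage: str) -> bool:
        recorded = self.manifest["outputs"].get(stage)
        if not recorded:
            return False
        return all((self.root / rel).exists() for rel in recorded)

    def _require(self, path: Path, producing_stage: str) -> Path:
        if not path.exists():
            raise MissingArtifactError(path, producing_stage)
        return path

    # -- stages ----------------------------------------------------------
    def simulate(self) -> None:
        stage_dir = self.root / "simulate"
        stage_dir.mkdir(exist_ok=True)
        cfg = self.config
        cohort, specs = simulate_cohort(
            cfg.n_control, cfg.n_non_acld, cfg.n_acld,
            seed=self.manifest["seeds"]["simulate"], phantom_spec=cfg.phantom,
        )
        cohort_path = stage_dir / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        paths = [cohort_path]
        for row, spec in zip(cohort.itertuples(), specs):
            image, labels, _ = make_liver_phantom(spec)
            img_path = stage_dir / f"{row.subject_id}_image.nii.gz"
            lab_path = stage_dir / f"{row.subject_id}_labels.nii.gz"
            save_nifti(image, img_path)
            save_nifti(ImageVolume(labels, spec.spacing_mm), lab_path)
            paths += [img_path, lab_path]
        self._record("simulate", paths)

    def _annotated_ids(self, cohort: pd.DataFrame) -> list[str]:
        # the 'manually annotated' subset: first cases of each group in turn
        ids = []
        per_group = {g: list(cohort[cohort.group == g].subject_id) for g in cohort.group.unique()}
        while len(ids) < min(self.config.n_annotated, len(cohort)):
            for g, members in per_group.items():
                if members and len(ids) < self.config.n_annotated:
                    ids.append(members.pop(0))
        return ids

    def train(self) -> None:
        stage_dir = self.root / "train"
        stage_dir.mkdir(exist_ok=True)
        cohort = pd.read_csv(self._require(self.root / "simulate" / "cohort.csv", "simulate"))
        train_ids = self._annotated_ids(cohort)
        cases = {}
        for sid in train_ids:
            img = load_nifti(self._require(self.root / "simulate" / f"{sid}_image.nii.gz", "simulate"))
            lab = load_nifti(self._require(self.root / "simulate" / f"{sid}_labels.nii.gz", "simulate"))
            cases[sid] = (img, lab.data.astype(np.uint8))
        unet_cfg = UNetConfig(**{**asdict(self.config.unet),
                                 "seed": self.manifest["seeds"]["train"]})
        aug = AugmentationParams() if self.config.augment else None
        model = VesselSegmentationModel(cases, unet_cfg, augmentation=aug)
        results = model.fit()
        weights = stage_dir / "model.npz"
        results.save(weights)
        manifest_csv = stage_dir / "training_manifest.csv"
        pd.DataFrame(
            {"subject_id": list(cohort.subject_id),
             "role": ["train" if s in train_ids else "apply" for s in cohort.subject_id]}
        ).to_csv(manifest_csv, index=False)
        trace_path = stage_dir / "loss_trace.csv"
        pd.DataFrame({"epoch": range(len(results.loss_trace)),
                      "loss": results.loss_trace}).to_csv(trace_path, index=False)
        self._record("train", [weights, weights.with_suffix(".json"), manifest_csv, trace_path])

    def segment(self) -> None:
        from .unet.network import UNet3D

        stage_dir = self.root / "segment"
        stage_dir.mkdir(exist_ok=True)
        network = UNet3D.load(self._require(self.root / "train" / "model.npz", "train"))
        cohort = pd.read_csv(self._require(self.root / "simulate" / "cohort.csv", "simulate"))
        paths = []
        for sid in cohort.subject_id:
            img = load_nifti(self._require(self.root / "simulate" / f"{sid}_image.nii.gz", "simulate"))
            pred = predict(network, img)
            out = stage_dir / f"{sid}_pred.nii.gz"
            save_nifti(ImageVolume(pred, img.spacing_mm), out)
            paths.append(out)
        self._record("segment", paths)

    def metrics(self) -> None:
        stage_dir = self.root / "metrics"
        stage_dir.mkdir(exist_ok=True)
        cohort = pd.read_csv(self._require(self.root / "simulate" / "cohort.csv", "simulate"))
        rows, paths = [], []
        for sid in cohort.subject_id:
            lab = load_nifti(self._require(self.root / "simulate" / f"{sid}_labels.nii.gz", "simulate"))
            labels = lab.data.astype(np.uint8)
            vvr = vessel_to_volume_ratios(labels, lab.spacing_mm)
            entry = {"subject_id": sid, **vvr.as_dict()}
            pred_path = self.root / "segment" / f"{sid}_pred.nii.gz"
            if pred_path.exists():
                pred = load_nifti(pred_path).data.astype(np.uint8)
                rep = dice_by_bin(
                    np.isin(pred, (LABEL_PORTAL, LABEL_HEPATIC)),
                    np.isin(labels, (LABEL_PORTAL, LABEL_HEPATIC)),
                    lab.spacing_mm,
                )
                entry["vessel_dice"] = rep.overall_dice
                for name, val in rep.bin_dice.items():
                    entry[f"dice_{name}"] = val
                pred_vvr = vessel_to_volume_ratios(pred, lab.spacing_mm)
                entry.update({f"pred_{k}": v for k, v in pred_vvr.as_dict().items()})
            subject_json = stage_dir / f"{sid}_metrics.json"
            subject_json.write_text(json.dumps(entry, indent=2, default=float))
            paths.append(subject_json)
            rows.append(entry)
        table = stage_dir / "vvr.csv"
        pd.DataFrame(rows).to_csv(table, index=False)
        self._record("metrics", paths + [table])

    def stats(self) -> None:
        stage_dir = self.root / "stats"
        stage_dir.mkdir(exist_ok=True)
        cohort = pd.read_csv(self._require(self.root / "simulate" / "cohort.csv", "simulate"))
        vvr = pd.read_csv(self._require(self.root / "metrics" / "vvr.csv", "metrics"))
        results = CohortVVRAnalysis(cohort, vvr).fit()
        comp_path = stage_dir / "group_comparisons.csv"
        results.comparison_frame().to_csv(comp_path, index=False)
        dec_rows = []
        for c in results.comparisons:
            for (a, b), d in c.percent_decreases.items():
                dec_rows.append({"vvr": c.vvr, "from": a, "to": b,
                                 "percent_decrease": d,
                                 "corrected_p": c.pairwise_p[(a, b)]})
        dec_path = stage_dir / "percent_decreases.csv"
        pd.DataFrame(dec_rows).to_csv(dec_path, index=False)
        corr_path = stage_dir / "correlations.csv"
        results.spearman["cld"].to_csv(corr_path, index=False)
        summary_path = stage_dir / "summary.txt"
        summary_path.write_text(results.summary() + "\n")
        self._record("stats", [comp_path, dec_path, corr_path, summary_path])

    # -- driver ----------------------------------------------------------
    def run(self, force: bool = False) -> dict:
        for stage in self.config.stages:
            if not force and self._done(stage):
                continue
            getattr(self, stage)()
        return self.manifest


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    return PipelineRun(config).run(force=force)


def make_report(run_dir: str | Path) -> str:
    """Human-readable summary of a (possibly partial) run."""
    root = Path(run_dir)
    lines = [f"# Run report: {root}", ""]
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"config hash: {manifest['config_hash']}")
    comp = root / "stats" / "group_comparisons.csv"
    if comp.exists():
        lines += ["", "## Vessel-to-volume ratios by group", pd.read_csv(comp).to_string(index=False)]
    else:
        lines += ["", "## Vessel-to-volume ratios by group", "(stats stage not run)"]
    dec = root / "stats" / "percent_decreases.csv"
    if dec.exists():
        lines += ["", "## Percent decreases between group medians", pd.read_csv(dec).to_string(index=False)]
    corr = root / "stats" / "correlations.csv"
    if corr.exists():
        lines += ["", "## Spearman correlation map (CLD cohort)", pd.read_csv(corr).to_string(index=False)]
    vvr = root / "metrics" / "vvr.csv"
    if vvr.exists() and "vessel_dice" in pd.read_csv(vvr).columns:
        df = pd.read_csv(vvr)
        lines += ["", "## Segmentation accuracy",
                  f"mean vessel Dice: {df['vessel_dice'].mean():.3f}"]
    else:
        lines += ["", "## Segmentation accuracy", "(segmentation stage not run; Dice absent)"]
    report = "\n".join(lines) + "\n"
    (root / "report.md").write_text(report)
    return report
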