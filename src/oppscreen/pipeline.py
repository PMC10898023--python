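"""End-to-end reproducible pipeline.

Stages: simulate -> split -> train-seg -> segment -> train-clf (model 1
and model 2) -> evaluate -> compare.  Every stage persists its outputs
under the run directory together with a marker file carrying the config
hash and the stage seed, so a rerun with the same config skips completed
stages (delete a stage directory to recompute it) and a config change
invalidates everything downstream.  A single global seed fans out to
per-stage seeds through named ``SeedSequence`` children.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import segnet
from .errors import ConfigurationError, OppscreenError
from .evalstats import SplitSpec, delong_test, evaluate_model, split_indices
from .phantom import (CohortSpec, PhantomSpec, generate_cohort, load_mask,
                      load_slice, write_cohort)
from .qct import LABELS

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

PARTS = ("training", "validation", "test")


@dataclass(frozen=True)
class RunConfig:
    profile: str = "desk"
    seed: int = 0
    n_subjects: int = 120
    image_size: int = 96
    image_format: str = "png"
    phantom: PhantomSpec | None = None
    cohort: CohortSpec | None = None
    split: SplitSpec | None = None
    seg_model: segnet.SegModelConfig | None = None
    seg_train: segnet.SegTrainConfig | None = None
    clf_model: clf.ClfModelConfig | None = None    # in_channels fixed per model
    clf_train: clf.ClfTrainConfig | None = None

    def __post_init__(self):
        if self.profile not in ("desk", "clinical"):
            raise ConfigurationError(f"unknown profile {self.profile!r}")

    def resolved(self) -> "RunConfig":
        """Fill unset sub-configs from the profile defaults."""
        desk = self.profile == "desk"
        size = self.image_size
        ph = self.phantom or (PhantomSpec.desk(size) if desk
                              else PhantomSpec(image_size=size))
        co = self.cohort or CohortSpec.scaled(self.n_subjects, seed=stage_seed(
            self.seed, "simulate"))
        sp = self.split or SplitSpec(ratios=(5, 1, 4), stratify=True,
                                     seed=stage_seed(self.seed, "split"))
        sm = self.seg_model or (segnet.SegModelConfig.desk() if desk
                                else segnet.SegModelConfig())
        st = self.seg_train or (
            segnet.SegTrainConfig.desk(seed=stage_seed(self.seed, "train-seg"))
            if desk else
            segnet.SegTrainConfig(seed=stage_seed(self.seed, "train-seg")))
        cm = self.clf_model or (clf.ClfModelConfig.desk(input_size=size) if desk
                                else clf.ClfModelConfig(input_size=size))
        ct = self.clf_train or (
            clf.ClfTrainConfig.desk(seed=stage_seed(self.seed, "train-clf"))
            if desk else
            clf.ClfTrainConfig(seed=stage_seed(self.seed, "train-clf")))
        sm.validate_input_size(size)   # fail early, not mid-training
        return dataclasses.replace(self, phantom=ph, cohort=co, split=sp,
                                   seg_model=sm, seg_train=st, clf_model=cm,
                                   clf_train=ct)

    def to_dict(self) -> dict:
        r = self.resolved()
        return {
            "profile": r.profile, "seed": r.seed, "n_subjects": r.n_subjects,
            "image_size": r.image_size, "image_format": r.image_format,
            "phantom": r.phantom.to_dict(), "cohort": r.cohort.to_dict(),
            "split": r.split.to_dict(), "seg_model": r.seg_model.to_dict(),
            "seg_train": r.seg_train.to_dict(), "clf_model": r.clf_model.to_dict(),
            "clf_train": r.clf_train.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key, conv in (("phantom", PhantomSpec.from_dict),
                          ("cohort", CohortSpec.from_dict),
                          ("seg_model", segnet.SegModelConfig.from_dict),
                          ("clf_model", clf.ClfModelConfig.from_dict)):
            if key in kw and kw[key] is not None:
                kw[key] = conv(kw[key])
        if kw.get("split") is not None:
            s = dict(kw["split"])
            s["ratios"] = tuple(s["ratios"])
            kw["split"] = SplitSpec(**s)
        if kw.get("seg_train") is not None:
            kw["seg_train"] = segnet.SegTrainConfig(**kw["seg_train"])
        if kw.get("clf_train") is not None:
            kw["clf_train"] = clf.ClfTrainConfig(**kw["clf_train"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# stage plumbing
# ---------------------------------------------------------------------------

def _marker(run_dir: Path, stage: str) -> Path:
    return run_dir / f"stage_{stage}.json"


def _stage_done(run_dir: Path, stage: str, cfg_hash: str) -> bool:
    mk = _marker(run_dir, stage)
    if not mk.exists():
        return False
    try:
        return json.loads(mk.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _finish(run_dir: Path, stage: str, cfg_hash: str, seed: int, **extra):
    _marker(run_dir, stage).write_text(json.dumps(
        dict(stage=stage, config_hash=cfg_hash, seed=seed, **extra), indent=1))


def _load_cohort_arrays(run_dir: Path):
    meta = pd.read_csv(run_dir / "data" / "cohort.csv")
    data = {}
    for _, row in meta.iterrows():
        base = run_dir / "data"
        data[row.subject_id] = dict(
            l1=load_slice(base / row.l1_path), l2=load_slice(base / row.l2_path),
            l1_mask=load_mask(base / row.l1_mask_path),
            l2_mask=load_mask(base / row.l2_mask_path))
    return meta, data


def _load_split(run_dir: Path) -> dict[str, list[str]]:
    return json.loads((run_dir / "split.json").read_text())


def _load_pred_masks(run_dir: Path, meta: pd.DataFrame):
    seg_dir = run_dir / "segmented"
    pred = {}
    for sid in meta.subject_id:
        pred[sid] = dict(l1=load_mask(seg_dir / f"{sid}_l1_pred.png"),
                         l2=load_mask(seg_dir / f"{sid}_l2_pred.png"))
    return pred


def run_pipeline(config: RunConfig, run_dir: Path, log=print) -> Path:
    """Execute all stages into ``run_dir``; returns the run directory."""
    cfg = config.resolved()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    (run_dir / "run_config.yaml").write_text(yaml.safe_dump(cfg.to_dict(),
                                                            sort_keys=False))
    manifest = dict(config_hash=cfg_hash, seed=cfg.seed, profile=cfg.profile)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def stage(name):
        def deco(fn):
            if _stage_done(run_dir, name, cfg_hash):
                log(f"[{name}] up to date, skipping")
                return
            log(f"[{name}] running")
            try:
                extra = fn() or {}
            except Exception as e:
                raise OppscreenError(f"stage {name!r} failed: {e}") from e
            _finish(run_dir, name, cfg_hash, stage_seed(cfg.seed, name), **extra)
        return deco

    @stage("simulate")
    def _simulate():
        subjects, meta = generate_cohort(cfg.cohort, cfg.phantom)
        write_cohort(subjects, meta, run_dir / "data", fmt=cfg.image_format)
        return dict(n_subjects=len(subjects))

    @stage("split")
    def _split():
        meta = pd.read_csv(run_dir / "data" / "cohort.csv")
        parts = split_indices(meta.label.to_numpy(), cfg.split)
        doc = {part: meta.subject_id.iloc[idx].tolist()
               for part, idx in zip(PARTS, parts)}
        (run_dir / "split.json").write_text(json.dumps(doc, indent=1))
        return {f"n_{p}": len(v) for p, v in doc.items()}

    @stage("train-seg")
    def _train_seg():
        meta, data = _load_cohort_arrays(run_dir)
        split = _load_split(run_dir)
        tr = [data[s] for s in split["training"]]
        tu = [data[s] for s in split["validation"]]
        imgs = [d[v] for d in tr for v in ("l1", "l2")]
        msks = [d[v + "_mask"] for d in tr for v in ("l1", "l2")]
        timgs = [d[v] for d in tu for v in ("l1", "l2")]
        tmsks = [d[v + "_mask"] for d in tu for v in ("l1", "l2")]
        model, hist = segnet.train_segmentation(
            imgs, msks, timgs, tmsks, cfg.seg_model, cfg.seg_train)
        segnet.save_checkpoint(model, hist, run_dir / "checkpoints" / "segnet")
        return dict(best_tune_dsc=hist["best_tune_dsc"])

    @stage("segment")
    def _segment():
        from .phantom import _save_mask
        meta, data = _load_cohort_arrays(run_dir)
        split = _load_split(run_dir)
        model, _ = segnet.load_checkpoint(run_dir / "checkpoints" / "segnet")
        seg_dir = run_dir / "segmented"
        seg_dir.mkdir(exist_ok=True)
        sids = meta.subject_id.tolist()
        images = [data[s][v] for s in sids for v in ("l1", "l2")]
        preds = segnet.predict_masks(model, images)
        dscs: dict[str, list[float]] = {p: [] for p in PARTS}
        part_of = {s: p for p in PARTS for s in split[p]}
        for i, sid in enumerate(sids):
            for j, v in enumerate(("l1", "l2")):
                pm = preds[2 * i + j]
                _save_mask(pm, seg_dir / f"{sid}_{v}_pred", "png")
                dscs[part_of[sid]].append(segnet.dsc(pm, data[sid][f"{v}_mask"]))
        metrics = {p: dict(dsc_mean=float(np.mean(v)), dsc_sd=float(np.std(v)),
                           n_images=len(v)) for p, v in dscs.items() if v}
        (run_dir / "seg_metrics.json").write_text(json.dumps(metrics, indent=1))
        return dict(test_dsc=metrics.get("test", {}).get("dsc_mean"))

    def _clf_io(variant):
        meta, data = _load_cohort_arrays(run_dir)
        split = _load_split(run_dir)
        pred = _load_pred_masks(run_dir, meta)
        label_of = dict(zip(meta.subject_id, meta.label))
        size = cfg.clf_model.input_size
        sets = {}
        for part in PARTS:
            xs, ys = [], []
            for sid in split[part]:
                l1 = clf.prepare_input(data[sid]["l1"], pred[sid]["l1"], size)
                if variant == "model1":
                    l2 = clf.prepare_input(data[sid]["l2"], pred[sid]["l2"], size)
                    xs.append(clf.fuse_features(l1, l2))
                else:
                    xs.append(l1[None])
                ys.append(label_of[sid])
            sets[part] = (xs, ys)
        return sets

    for variant in ("model1", "model2"):
        @stage(f"train-clf-{variant}")
        def _train_clf(variant=variant):
            sets = _clf_io(variant)
            in_ch = 2 if variant == "model1" else 1
            mc = dataclasses.replace(cfg.clf_model, in_channels=in_ch)
            ct = dataclasses.replace(
                cfg.clf_train, seed=stage_seed(cfg.seed, f"train-clf-{variant}"))
            model, hist = clf.train_classifier(*sets["training"],
                                               *sets["validation"], mc, ct)
            clf.save_checkpoint(model, hist,
                                run_dir / "checkpoints" / f"clf_{variant}")
            return dict(best_val_macro_auc=hist["best_val_macro_auc"])

    @stage("evaluate")
    def _evaluate():
        frames = []
        scores = {}
        for variant in ("model1", "model2"):
            model, _ = clf.load_checkpoint(run_dir / "checkpoints" / f"clf_{variant}")
            sets = _clf_io(variant)
            for part in PARTS:
                xs, ys = sets[part]
                probs = clf.predict_proba_batch(model, xs)
                rep = evaluate_model(probs, np.array(ys), LABELS, dataset=part)
                df = rep.to_frame()
                df.insert(0, "model", variant)
                frames.append(df)
                if part == "test":
                    scores[variant] = (probs, np.array(ys))
        report = pd.concat(frames, ignore_index=True)
        report.to_csv(run_dir / "classification_report.csv", index=False)
        (run_dir / "classification_report.json").write_text(
            report.to_json(orient="records", indent=1))
        np.savez(run_dir / "test_scores.npz",
                 probs1=scores["model1"][0], probs2=scores["model2"][0],
                 labels=np.array([LABELS.index(l) if isinstance(l, str) else l
                                  for l in scores["model1"][1]]))

    @stage("compare")
    def _compare():
        with np.load(run_dir / "test_scores.npz") as z:
            p1, p2, y = z["probs1"], z["probs2"], z["labels"]
        rows = []
        for k, lab in enumerate(LABELS):
            binary = (y == k).astype(int)
            r = delong_test(p1[:, k], p2[:, k], binary)
            rows.append(dict(cls=lab, auc_1=r.auc_1, auc_2=r.auc_2,
                             z=r.z, p=r.p, degenerate=r.degenerate))
        pd.DataFrame(rows).to_csv(run_dir / "delong.csv", index=False)
        (run_dir / "delong.json").write_text(json.dumps(rows, indent=1))

    return run_dir
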