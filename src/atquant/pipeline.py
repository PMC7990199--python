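"""End-to-end orchestration: phantom -> QAT -> train -> predict -> simulate -> evaluate.

A run is described by a flat configuration tree (usually loaded from YAML),
validated before any compute.  A single global seed fans out to per-stage
seeds through a stable hash of the stage name, so each stage is individually
reproducible.  Every produced file is recorded in a manifest with its SHA-256
content hash; deterministic stages reproduce identical hashes on rerun.
"""

from __future__ import annotations

import hashlib
import logging
import os
import zlib
import numpy as np
import pandas as pd

from .deflation import deflation_curve
from .dn import DNConfig, make_slice_samples, predict, save_checkpoint, train_dn
from .errors import ConfigError
from .evaluation import dice_coefficient, longitudinal_table, sensitivity_summary
from .phantom import phantom_suite
from .qat import at_map, qat_ptm, qat_static856
from .volume import median_filter_3, write_volume

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "out_dir": "atquant_run",
    "seed": 0,
    "stages": ["phantom", "qat", "train", "predict", "curve", "evaluate"],
    "phantom": {"n_subjects": 4, "timepoints": 2},
    "ptm": {"d_convention": "exp_minus_insp"},
    "dn": {"preset": "desk", "epochs": 8, "train_slices": 128, "train_fraction": 0.5},
    "deflation": {
        "betas": [1.0, 0.9, 0.8, 0.7, 0.6, 0.5],
        "methods": ["static856", "ptm"],
        "n_pairs": 2,
    },
    "io_format": "metaimage",
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31 - 1)


def _validate(config: dict, defaults: dict, path: str = "") -> dict:
    merged = {}
    for key, default in defaults.items():
        if key in config and isinstance(default, dict):
            sub = config[key]
            if not isinstance(sub, dict):
                raise ConfigError(f"config key {path}{key} must be a mapping")
            merged[key] = _validate(sub, default, f"{path}{key}.")
        else:
            merged[key] = config.get(key, default)
    unknown = set(config) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key: {path}{sorted(unknown)[0]}")
    return merged


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, out_dir: str):
        self.out_dir = out_dir
        self.rows: list[dict] = []

    def add(self, path: str):
        self.rows.append(
            {
                "path": os.path.relpath(path, self.out_dir),
                "sha256": _sha256(path),
                "bytes": os.path.getsize(path),
            }
        )

    def write(self) -> str:
        out = os.path.join(self.out_dir, "manifest.csv")
        pd.DataFrame(self.rows, columns=["path", "sha256", "bytes"]).to_csv(
            out, index=False
        )
        return out


def run_pipeline(config: dict | None = None) -> tuple[int, Manifest]:
    """Execute the requested stages in dependency order.

    Returns (exit status, manifest).  A stage failure raises; the partial
    manifest written so far is preserved on disk.
    """
    cfg = _validate(config or {}, DEFAULT_CONFIG)
    stages = cfg["stages"]
    known = {"phantom", "qat", "train", "predict", "curve", "evaluate"}
    bad = set(stages) - known
    if bad:
        raise ConfigError(f"unknown stage: {sorted(bad)[0]}")
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    manifest = Manifest(out_dir)
    ext = ".mha" if cfg["io_format"] == "metaimage" else ".nii.gz"
    seed = int(cfg["seed"])

    try:
        pairs = phantom_suite(
            n_subjects=int(cfg["phantom"]["n_subjects"]),
            seed=derive_seed(seed, "phantom"),
            timepoints=int(cfg["phantom"]["timepoints"]),
        )
        prepared = {}  # (subject, timepoint) -> dict with filtered vols + labels
        for p in pairs:
            prepared[(p.subject, p.timepoint)] = {
                "pair": p,
                "insp_f": median_filter_3(p.insp),
                "exp_f": median_filter_3(p.exp),
            }
        if "phantom" in stages:
            pdir = os.path.join(out_dir, "phantoms")
            os.makedirs(pdir, exist_ok=True)
            for p in pairs:
                stem = os.path.join(pdir, f"{p.subject}_t{p.timepoint}")
                for name, vol in (
                    ("insp", p.insp),
                    ("exp", p.exp),
                    ("lung", p.exp_mask),
                    ("at_truth", p.at_truth),
                ):
                    path = f"{stem}_{name}{ext}"
                    write_volume(vol, path)
                    manifest.add(path)

        rows = []
        if {"qat", "train", "predict", "curve", "evaluate"} & set(stages):
            for (subj, tp), d in prepared.items():
                p = d["pair"]
                res_p, ptm = qat_ptm(
                    d["insp_f"], d["exp_f"], p.insp_mask, p.exp_mask,
                    cfg["ptm"]["d_convention"],
                )
                d["ptm"] = ptm
                d["label"] = at_map(d["exp_f"], p.exp_mask, ptm.T)
                res_s = qat_static856(d["exp_f"], p.exp_mask)
                for res, extra in ((res_p, {"X": ptm.X, "Y": ptm.Y, "D": ptm.D}),
                                   (res_s, {})):
                    rows.append(
                        {
                            "subject": subj,
                            "timepoint": tp,
                            "method": res.method,
                            "threshold": res.threshold_used,
                            "lung_voxels": res.lung_voxels,
                            "at_voxels": res.at_voxels,
                            "qat_percent": res.qat_percent,
                            "at_fraction_truth": p.at_fraction_truth,
                            **extra,
                        }
                    )
        if "qat" in stages:
            path = os.path.join(out_dir, "qat_report.csv")
            pd.DataFrame(rows).to_csv(path, index=False)
            manifest.add(path)

        model = None
        dn_cfg = None
        if {"train", "predict", "curve"} & set(stages):
            dncfg_in = dict(cfg["dn"])
            preset = dncfg_in.pop("preset", "desk")
            n_slices = int(dncfg_in.pop("train_slices"))
            train_frac = float(dncfg_in.pop("train_fraction"))
            maker = DNConfig.desk if preset == "desk" else DNConfig
            dn_cfg = maker(seed=derive_seed(seed, "train"), **dncfg_in)
            subjects = sorted({p.subject for p in pairs})
            n_train = max(1, int(round(train_frac * len(subjects))))
            train_subj = set(subjects[:n_train])
            samples = []
            for (subj, tp), d in prepared.items():
                if subj in train_subj:
                    samples += make_slice_samples(
                        d["exp_f"], d["pair"].exp_mask, d["label"], dn_cfg, subj, tp
                    )
            rng = np.random.default_rng(derive_seed(seed, "train-subset"))
            if len(samples) > n_slices:
                keep = rng.choice(len(samples), n_slices, replace=False)
                samples = [samples[i] for i in sorted(keep)]
            model, record = train_dn(samples, dn_cfg)
            if "train" in stages:
                path = os.path.join(out_dir, "model.ckpt.npz")
                save_checkpoint(model, path)
                manifest.add(path)
                tpath = os.path.join(out_dir, "training_record.csv")
                pd.DataFrame({"epoch": range(len(record.train_loss)),
                              "train_loss": record.train_loss}).to_csv(tpath, index=False)
                manifest.add(tpath)

        if "predict" in stages and model is not None:
            for (subj, tp), d in prepared.items():
                _, at_dn, res = predict(model, d["exp_f"], d["pair"].exp_mask, dn_cfg)
                rows.append(
                    {
                        "subject": subj,
                        "timepoint": tp,
                        "method": "dn",
                        "threshold": None,
                        "lung_voxels": res.lung_voxels,
                        "at_voxels": res.at_voxels,
                        "qat_percent": res.qat_percent,
                        "at_fraction_truth": d["pair"].at_fraction_truth,
                        "dice_vs_ptm": dice_coefficient(at_dn, d["label"]),
                        "dice_vs_truth": dice_coefficient(at_dn, d["pair"].at_truth),
                    }
                )
            path = os.path.join(out_dir, "qat_report_all.csv")
            pd.DataFrame(rows).to_csv(path, index=False)
            manifest.add(path)

        curves = []
        if "curve" in stages:
            methods = list(cfg["deflation"]["methods"])
            if "dn" in methods and model is None:
                raise ConfigError("deflation method 'dn' needs the train stage")
            for d in list(prepared.values())[: int(cfg["deflation"]["n_pairs"])]:
                p = d["pair"]
                curves.append(
                    deflation_curve(
                        p.warped_insp, d["insp_f"], p.insp_mask, p.exp_mask,
                        p.jacobian, cfg["deflation"]["betas"], methods,
                        model=model, d_convention=cfg["ptm"]["d_convention"],
                    )
                )
            rows_c = []
            for i, c in enumerate(curves):
                for m, qs in c.qat.items():
                    for beta, q in zip(c.betas, qs):
                        rows_c.append({"curve": i, "method": m, "beta": beta,
                                       "qat_percent": q})
            path = os.path.join(out_dir, "deflation_curves.csv")
            pd.DataFrame(rows_c).to_csv(path, index=False)
            manifest.add(path)

        if "evaluate" in stages:
            table, summary = longitudinal_table(
                [
                    {k: r[k] for k in ("subject", "timepoint", "method", "qat_percent")}
                    for r in rows
                ]
            )
            path = os.path.join(out_dir, "longitudinal_summary.csv")
            summary.to_csv(path, index=False)
            manifest.add(path)
            if curves:
                path = os.path.join(out_dir, "sensitivity_summary.csv")
                sensitivity_summary(curves).to_csv(path, index=False)
                manifest.add(path)
    finally:
        manifest.write()
    return 0, manifest
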