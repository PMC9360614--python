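"""Orchestration of the end-to-end study as seeded, file-backed stages.

Stages (in dependency order): ``enumerate`` -> ``simulate`` -> ``score`` ->
``build`` -> ``train`` -> ``evaluate`` -> ``explain``.  Every stage reads its
inputs from, and writes its artifacts to, one output directory; a
``manifest.json`` accumulates, append-only, one entry per run with the config
digest, seed and artifact checksums.  Re-running with an identical config and
seed reproduces identical artifacts byte for byte.

All randomness is derived from the single master ``seed``: the selection uses
``seed``, the derivative panel ``seed + 1``, the split sampling ``seed + 2``
and model training ``seed + 3``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem_enum, dataset_builder, del_scoring, eval_sar, modeling, synthetic_del
from .chem_enum import FingerprintConfig, InputError

#: Quick-demo defaults: a 1,000-member library that runs in seconds.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "delscreen_out",
    "library": {"n_per_cycle": 10, "blocks_csv": None, "templates_csv": None},
    "selection": {
        "depth_per_condition": 100_000,
        "enrichment_multiplier": 1000.0,
        "binder_ids": [synthetic_del.DEFAULT_BINDER_ID],
        "sticky_fraction": 0.02,
        "sticky_multiplier": 20.0,
    },
    "panel": {"n": 34, "active_fraction": 7 / 34},
    "scoring": {"a": 0.8, "b": 0.2, "method": "minmax"},
    "fingerprint": {"n_bits": 1024, "radius": 2},
    "sampling": {
        "undersample_interval_n": 4,
        "oversample_multiple": 50,
        "oversample_top_k": 50,
        "modify_bit": 2,
        "modify_type": 1,
        "jitter_halfwidth": 0.1,
        "augment": False,
    },
    "splits": {"valid1_size": 150, "test1_size": 150},
    "model": {"kind": "gbm"},
    "threshold": None,
    "sar": {"top_n": 3, "sigma": 0.3},
}

STAGES = ("enumerate", "simulate", "score", "build", "train", "evaluate", "explain")


class PipelineError(RuntimeError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, deep-merged with an optional YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _fp_config(cfg: dict) -> FingerprintConfig:
    return FingerprintConfig(**cfg["fingerprint"])


def _require(out: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise PipelineError(
                f"stage {stage!r} needs missing artifact {name!r}; "
                f"run its producing stage first"
            )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stages


def stage_enumerate(cfg: dict, out: Path) -> list[str]:
    lib = cfg["library"]
    if lib.get("blocks_csv"):
        blocks = chem_enum.read_building_blocks(lib["blocks_csv"])
    else:
        blocks = synthetic_del.generate_building_blocks(lib["n_per_cycle"])
    if lib.get("templates_csv"):
        templates = chem_enum.read_templates(lib["templates_csv"])
    else:
        templates = chem_enum.default_templates()
    result = chem_enum.enumerate_trisynthons(blocks, templates)
    _write_csv(
        pd.DataFrame(
            {
                "block_id": [b.block_id for b in blocks],
                "cycle": [b.cycle for b in blocks],
                "smiles": [b.smiles for b in blocks],
            }
        ),
        out / "blocks.csv",
    )
    _write_csv(
        pd.DataFrame(
            {
                "template_id": [t.template_id for t in templates],
                "step": [t.step for t in templates],
                "smarts": [t.smarts for t in templates],
            }
        ),
        out / "templates.csv",
    )
    _write_csv(result.to_frame(), out / "products.csv")
    if result.failures:
        _write_csv(
            pd.DataFrame(
                {
                    "block1": [f.block_ids[0] for f in result.failures],
                    "block2": [f.block_ids[1] for f in result.failures],
                    "block3": [f.block_ids[2] for f in result.failures],
                    "step": [f.step for f in result.failures],
                    "reason": [f.reason for f in result.failures],
                }
            ),
            out / "enumeration_failures.csv",
        )
    return ["blocks.csv", "templates.csv", "products.csv"]


def _load_products(out: Path) -> list[chem_enum.Trisynthon]:
    df = pd.read_csv(out / "products.csv")
    return [
        chem_enum.Trisynthon(
            str(r.compound_id), (str(r.block1), str(r.block2), str(r.block3)), r.smiles
        )
        for r in df.itertuples()
    ]


def stage_simulate(cfg: dict, out: Path) -> list[str]:
    _require(out, "simulate", "products.csv")
    products = _load_products(out)
    sel = cfg["selection"]
    landscape = synthetic_del.AffinityLandscape(
        binder_ids=frozenset(sel["binder_ids"] or []),
        enrichment_multiplier=sel["enrichment_multiplier"],
        sticky_fraction=sel["sticky_fraction"],
        sticky_multiplier=sel["sticky_multiplier"],
    )
    records = synthetic_del.simulate_selection(
        products, landscape, sel["depth_per_condition"], seed=cfg["seed"]
    )
    _write_csv(synthetic_del.records_to_frame(records), out / "counts.csv")

    by_id = {t.compound_id: t for t in products}
    hit_id = sorted(landscape.binder_ids)[0]
    if hit_id not in by_id:
        raise PipelineError(f"binder {hit_id!r} not found in enumerated products")
    panel = synthetic_del.generate_derivative_panel(
        by_id[hit_id].product_smiles,
        n=cfg["panel"]["n"],
        seed=cfg["seed"] + 1,
        active_fraction=cfg["panel"]["active_fraction"],
    )
    _write_csv(panel.to_frame(), out / "panel.csv")
    return ["counts.csv", "panel.csv"]


def stage_score(cfg: dict, out: Path) -> list[str]:
    _require(out, "score", "counts.csv")
    records = synthetic_del.records_from_frame(pd.read_csv(out / "counts.csv"))
    weights = del_scoring.ScoreWeights(cfg["scoring"]["a"], cfg["scoring"]["b"])
    scored = del_scoring.compute_scores(records, weights, cfg["scoring"]["method"])
    _write_csv(del_scoring.scored_to_frame(scored), out / "scored.csv")
    return ["scored.csv"]


def stage_build(cfg: dict, out: Path) -> list[str]:
    _require(out, "build", "scored.csv", "products.csv", "panel.csv")
    scored = del_scoring.scored_from_frame(pd.read_csv(out / "scored.csv"))
    products = _load_products(out)
    panel = synthetic_del.DerivativePanel.from_frame(pd.read_csv(out / "panel.csv"))
    fp_config = _fp_config(cfg)
    X = chem_enum.fingerprint_matrix(
        (t.product_smiles for t in products), fp_config
    )
    fps = {t.compound_id: X[i] for i, t in enumerate(products)}
    sampling = dataset_builder.SamplingConfig(
        seed=cfg["seed"] + 2, **cfg["sampling"]
    )
    bundle = dataset_builder.build_splits(
        scored, panel, sampling, fps,
        valid1_size=cfg["splits"]["valid1_size"],
        test1_size=cfg["splits"]["test1_size"],
        fp_config=fp_config,
    )
    _write_csv(bundle.manifest(), out / "split_manifest.csv")
    np.savez_compressed(
        out / "splits.npz",
        **{
            name: getattr(bundle, name)
            for name in (
                "X_train", "y_train", "train_synthetic",
                "X_valid1", "y_valid1", "X_test1", "y_test1",
                "X_valid2", "y_valid2", "valid2_ic50",
                "X_test2", "y_test2", "test2_ic50",
            )
        },
        valid2_ids=np.asarray(bundle.valid2_ids),
        test2_ids=np.asarray(bundle.test2_ids),
        fp_n_bits=fp_config.n_bits,
        fp_radius=fp_config.radius,
    )
    return ["split_manifest.csv", "splits.npz"]


def _model_config(cfg: dict, n_bits: int):
    opts = {k: v for k, v in cfg["model"].items() if k != "kind"}
    kind = cfg["model"]["kind"]
    if kind == "mlp":
        return modeling.MLPConfig(
            input_dim=n_bits, seed=cfg["seed"] + 3, **opts
        )
    if kind == "gbm":
        return modeling.GBMConfig(seed=cfg["seed"] + 3, **opts)
    raise PipelineError(f"unknown model kind {kind!r}")


def stage_train(cfg: dict, out: Path) -> list[str]:
    _require(out, "train", "splits.npz")
    data = np.load(out / "splits.npz", allow_pickle=False)
    kind = cfg["model"]["kind"]
    config = _model_config(cfg, int(data["fp_n_bits"]))
    model = modeling.train_model(
        kind, config, data["X_train"], data["y_train"],
        valid=(data["X_valid1"], data["y_valid1"]),
    )
    model_file = "model_gbm.txt" if kind == "gbm" else "model_mlp.npz"
    model.save(str(out / model_file))
    sidecar = {
        "kind": kind,
        "config": {
            k: v for k, v in config.__dict__.items()
        },
        "fingerprint": {"n_bits": int(data["fp_n_bits"]),
                        "radius": int(data["fp_radius"])},
        "seed": cfg["seed"],
        "training_digest": hashlib.sha256(
            np.ascontiguousarray(data["X_train"]).tobytes()
        ).hexdigest()[:16],
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return [model_file, "model.json"]


def _load_model(cfg: dict, out: Path):
    sidecar = json.loads((out / "model.json").read_text())
    kind = sidecar["kind"]
    if kind == "gbm":
        return modeling.GBMModel.load(
            str(out / "model_gbm.txt"), modeling.GBMConfig(**sidecar["config"])
        )
    return modeling.MLPModel.load(
        str(out / "model_mlp.npz"), modeling.MLPConfig(**sidecar["config"])
    )


def _bundle_from_npz(data) -> dataset_builder.SplitBundle:
    n_train = len(data["y_train"])
    return dataset_builder.SplitBundle(
        X_train=data["X_train"], y_train=data["y_train"],
        train_row_ids=[""] * n_train, train_synthetic=data["train_synthetic"],
        X_valid1=data["X_valid1"], y_valid1=data["y_valid1"],
        valid1_ids=[""] * len(data["y_valid1"]),
        X_test1=data["X_test1"], y_test1=data["y_test1"],
        test1_ids=[""] * len(data["y_test1"]),
        X_valid2=data["X_valid2"], y_valid2=data["y_valid2"],
        valid2_ids=[str(s) for s in data["valid2_ids"]],
        valid2_ic50=data["valid2_ic50"],
        X_test2=data["X_test2"], y_test2=data["y_test2"],
        test2_ids=[str(s) for s in data["test2_ids"]],
        test2_ic50=data["test2_ic50"],
    )


def stage_evaluate(cfg: dict, out: Path) -> list[str]:
    _require(out, "evaluate", "splits.npz", "model.json")
    data = np.load(out / "splits.npz", allow_pickle=False)
    model = _load_model(cfg, out)
    bundle = _bundle_from_npz(data)
    report = modeling.evaluate_model(
        model, bundle, cfg["threshold"],
        hyperparameters={
            "model": cfg["model"]["kind"],
            "undersample_interval_n": cfg["sampling"]["undersample_interval_n"],
            "oversample_multiple": cfg["sampling"]["oversample_multiple"],
            "n_bits": int(data["fp_n_bits"]),
            "radius": int(data["fp_radius"]),
            "seed": cfg["seed"],
        },
    )
    (out / "metrics.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True)
    )
    return ["metrics.json"]


def stage_explain(cfg: dict, out: Path) -> list[str]:
    _require(out, "explain", "panel.csv", "model.json", "splits.npz")
    data = np.load(out / "splits.npz", allow_pickle=False)
    fp_config = FingerprintConfig(int(data["fp_n_bits"]), int(data["fp_radius"]))
    model = _load_model(cfg, out)
    panel = synthetic_del.DerivativePanel.from_frame(pd.read_csv(out / "panel.csv"))
    fps = [
        chem_enum.compute_fingerprint(r.smiles, fp_config) for r in panel.records
    ]
    preds = model.predict(np.asarray([fp.bits for fp in fps], dtype=np.float32))
    top = np.argsort(-preds)[: cfg["sar"]["top_n"]]
    sar_dir = out / "sar"
    sar_dir.mkdir(exist_ok=True)
    artifacts = []
    for i in top:
        rec = panel.records[int(i)]
        weights = eval_sar.bit_weights(model, fps[int(i)])
        awmap = eval_sar.atom_weights(weights, fps[int(i)])
        payload = awmap.to_dict()
        payload["derivative_id"] = rec.derivative_id
        payload["predicted_score"] = float(preds[int(i)])
        (sar_dir / f"{rec.derivative_id}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
        eval_sar.render_map(
            awmap, str(sar_dir / f"{rec.derivative_id}.png"),
            sigma=cfg["sar"]["sigma"],
        )
        artifacts.extend([f"sar/{rec.derivative_id}.json", f"sar/{rec.derivative_id}.png"])
    return artifacts


_STAGE_FN = {
    "enumerate": stage_enumerate,
    "simulate": stage_simulate,
    "score": stage_score,
    "build": stage_build,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "explain": stage_explain,
}


def run_pipeline(cfg: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order and append to the manifest."""
    stages = list(STAGES) if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    entry: dict = {
        "config_digest": _config_digest(cfg),
        "seed": cfg["seed"],
        "stages": {},
        "artifacts": {},
    }
    for stage in ordered:
        artifacts = _STAGE_FN[stage](cfg, out)
        entry["stages"][stage] = "ok"
        for name in artifacts:
            entry["artifacts"][name] = hashlib.sha256(
                (out / name).read_bytes()
            ).hexdigest()[:16]

    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists()
        else {"runs": []}
    )
    manifest["runs"].append(entry)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return entry
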