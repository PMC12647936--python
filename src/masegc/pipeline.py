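"""One-config orchestration: simulate -> preprocess -> balance -> encode ->
train -> evaluate, with a manifest tying every artifact to the config hash
and seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .config import PipelineConfig
from .errors import ConfigError, PipelineError
from .evaluate import AblationSpec, CrossValResult, ablation_run, cross_validate_pipeline
from .io_core import (
    Modality,
    MultiOmicsDataset,
    OmicsMatrix,
    align_samples,
    read_label_table,
    read_omics_matrix,
    write_label_table,
    write_omics_matrix,
)
from .synthetic_data import SimulationConfig, simulate_multiomics

__all__ = ["RunConfig", "validate_config", "run_all", "simulate_to_dir", "load_dataset"]

_DATA_KEYS = {"exon", "mrna", "mirna", "methylation", "labels", "transpose"}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Exactly one of ``simulate`` (generator settings) or ``data`` (per-modality
    TSV paths plus a label table) provides the input dataset.
    """

    pipeline: PipelineConfig
    simulate: SimulationConfig | None = None
    data: dict | None = None
    out_dir: str = "results"
    ablate: list[str] | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.data is None):
            raise ConfigError("exactly one of 'simulate' or 'data' must be given")
        if self.data is not None:
            unknown = sorted(set(self.data) - _DATA_KEYS)
            if unknown:
                raise ConfigError(f"unknown data key(s): {unknown}")
            if "labels" not in self.data:
                raise ConfigError("data section requires a 'labels' path")
            for key, value in self.data.items():
                if key != "transpose" and not Path(value).exists():
                    raise ConfigError(f"data file for {key!r} does not exist: {value}")

    def content_hash(self) -> str:
        payload = {
            "pipeline": asdict(self.pipeline),
            "simulate": asdict(self.simulate) if self.simulate else None,
            "data": self.data,
            "ablate": self.ablate,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(raw: str | dict) -> RunConfig:
    """Parse + validate a YAML/JSON run config; unknown keys are rejected
    with every problem listed. An empty config is valid and yields the full
    default pipeline (simulated input)."""
    if isinstance(raw, str):
        parsed = yaml.safe_load(raw) or {}
    else:
        parsed = dict(raw)
    if not isinstance(parsed, dict):
        raise ConfigError("config must be a mapping")
    known = {"pipeline", "simulate", "data", "out_dir", "ablate"}
    problems = [f"unknown config key {k!r}" for k in sorted(set(parsed) - known)]
    if problems:
        raise ConfigError("; ".join(problems))

    try:
        pipeline = PipelineConfig.from_dict(parsed.get("pipeline") or {})
    except (ConfigError, TypeError) as e:
        raise ConfigError(f"pipeline section: {e}") from e

    simulate = None
    if "simulate" in parsed or "data" not in parsed:
        sim_raw = dict(parsed.get("simulate") or {})
        sim_known = {f.name for f in fields(SimulationConfig)}
        unknown = sorted(set(sim_raw) - sim_known)
        if unknown:
            raise ConfigError(f"simulate section: unknown key(s) {unknown}")
        if "n_samples_per_class" in sim_raw:
            sim_raw["n_samples_per_class"] = tuple(sim_raw["n_samples_per_class"])
        simulate = SimulationConfig(**sim_raw)

    return RunConfig(
        pipeline=pipeline,
        simulate=simulate,
        data=parsed.get("data"),
        out_dir=str(parsed.get("out_dir", "results")),
        ablate=list(parsed["ablate"]) if parsed.get("ablate") else None,
    )


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write per-modality TSVs, the label TSV and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_multiomics(config)
    for modality, mat in dataset.modalities.items():
        write_omics_matrix(mat, out / f"{modality.value}.tsv")
    write_label_table(dataset.labels, out / "labels.tsv")
    truth.to_json(out / "ground_truth.json")
    (out / "sim_config.json").write_text(
        json.dumps({**asdict(config), "feature_dims": {m.value: d for m, d in config.feature_dims.items()}},
                   indent=1, default=str)
    )
    return out


def load_dataset(config: RunConfig) -> MultiOmicsDataset:
    if config.simulate is not None:
        dataset, _ = simulate_multiomics(config.simulate)
        return dataset
    transpose = bool(config.data.get("transpose", False))
    matrices = []
    for key in ("exon", "mrna", "mirna", "methylation"):
        if key in config.data:
            matrices.append(read_omics_matrix(config.data[key], Modality(key), transpose=transpose))
    if not matrices:
        raise ConfigError("data section names no modality files")
    labels = read_label_table(config.data["labels"])
    dataset, _report = align_samples(matrices, labels)
    return dataset


def _write_summary_tsv(result: CrossValResult, path: Path) -> None:
    cols = ["accuracy", "precision", "recall", "f1", "specificity"]
    lines = ["split\t" + "\t".join(cols)]
    for name, rep in (("validation", result.validation_pooled), ("test", result.test_pooled)):
        d = rep.as_dict(rounded=True)
        lines.append(name + "\t" + "\t".join(str(d[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def _write_fold_confusions(result: CrossValResult, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for i, rep in enumerate(result.fold_test):
        c = rep.counts
        (directory / f"fold{i}_confusion.tsv").write_text(
            f"\tpred_tumor\tpred_normal\ntumor\t{c.TP}\t{c.FN}\nnormal\t{c.FP}\t{c.TN}\n"
        )


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages and write results + manifest.

    Rerunning with the same config reproduces the outputs bit for bit.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.pipeline.seed,
        "paper_mode": config.pipeline.paper_mode,
        "stages": [],
    }
    try:
        if config.simulate is not None:
            simulate_to_dir(config.simulate, out / "simulated")
            manifest["stages"].append("simulate")
        dataset = load_dataset(config)
        manifest["n_samples"] = dataset.n_samples
        manifest["class_counts"] = {
            "tumor": int(dataset.y.sum()),
            "normal": int((dataset.y == 0).sum()),
        }
        manifest["stages"] += ["preprocess", "balance" if config.pipeline.balance else "balance:skipped",
                               "encode", "train", "evaluate"]

        if config.ablate:
            results = ablation_run(
                dataset, config.pipeline, [AblationSpec(e) for e in config.ablate]
            )
            table = ["setting\taccuracy\tprecision\trecall\tf1\tspecificity"]
            for name, res in results.items():
                d = res.test_pooled.as_dict(rounded=True)
                table.append(
                    "\t".join([name] + [str(d[c]) for c in
                                        ("accuracy", "precision", "recall", "f1", "specificity")])
                )
            (out / "ablation.tsv").write_text("\n".join(table) + "\n")
            for name, res in results.items():
                (out / f"metrics_{name}.json").write_text(res.as_json())
            result = results.get("none") or next(iter(results.values()))
        else:
            result = cross_validate_pipeline(dataset, config.pipeline)
            (out / "metrics.json").write_text(result.as_json())
        _write_summary_tsv(result, out / "summary.tsv")
        _write_fold_confusions(result, out / "confusion")
    except PipelineError as e:
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
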