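"""End-to-end pipeline: simulate -> diffmeth -> search -> fit -> signatures -> assoc -> report.

Every stage writes its TSV outputs plus a JSON manifest (inputs, seed, row
counts, package version) into the run directory. Reruns with the same config
are byte-identical; subset scoring uses per-subset seeds derived from the run
seed, so results are independent of evaluation order and worker count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import combo_search, covariate_assoc, diff_meth, pan_cancer_model, synthetic
from .data_model import BetaMatrix, read_beta_matrix, write_beta_matrix, write_sample_sheet
from .tumor_specific import scan_signatures

STAGES = ("simulate", "diffmeth", "search", "fit", "signatures", "assoc", "report")


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Single-document YAML-serializable pipeline configuration."""

    out_dir: str = "methpanel_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulate
    scale: float = 0.05  # fraction of the bundled cohort sample counts
    planted_probes: tuple[int, ...] = (3, 12, 14, 18, 20, 21)
    planted_delta: float = 2.0
    precision: float = 50.0
    patient_sd: float = 0.5
    # search
    k_min: int = 1
    k_max: int = 2
    n_boot: int = 50
    n_per_class: int = 700
    per_dataset: bool = True
    per_dataset_n_boot: int = 10
    filter_preset: str = "indiv084"
    workers: int = 1
    # fit / signatures
    n_folds: int = 10
    cutoff: float = 0.55
    n_components: int = 2
    signature_k: int = 3
    signature_max_subsets: int = 30
    signature_n_folds: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
        if self.filter_preset not in combo_search.FILTER_PRESETS:
            raise PipelineConfigError(f"unknown filter preset {self.filter_preset!r}")
        if self.workers < 1:
            raise PipelineConfigError("workers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "planted_probes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["planted_probes"] = list(d["planted_probes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _write_manifest(out: Path, stage: str, seed: int, inputs: list[str],
                    outputs: dict[str, int], extra: dict[str, Any] | None = None) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,  # file -> row count
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    (out / f"{stage}.manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run the enabled stages in dependency order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    enabled = [s for s in STAGES if s in config.stages]
    beta_path = out / "beta.tsv"
    sheet_path = out / "samples.tsv"
    needs_data = {"diffmeth", "search", "fit", "signatures", "assoc"}
    if needs_data & set(enabled) and "simulate" not in enabled:
        if not (beta_path.exists() and sheet_path.exists()):
            raise PipelineConfigError(
                "data-dependent stages enabled but simulate is off and "
                f"{beta_path} / {sheet_path} are missing"
            )

    bm = meta = None
    counts: dict[str, int] = {}

    if "simulate" in enabled:
        gen = synthetic.GeneratorConfig(
            precision=config.precision, patient_sd=config.patient_sd, seed=config.seed
        )
        gen = synthetic.scale_counts(gen, config.scale)
        gen = synthetic.planted_panel(gen, set(config.planted_probes), config.planted_delta)
        bm, meta = synthetic.generate_cohort(gen)
        write_beta_matrix(bm, beta_path)
        write_sample_sheet(meta, sheet_path)
        counts["simulate"] = bm.n_samples
        _write_manifest(out, "simulate", config.seed, [],
                        {"beta.tsv": bm.n_samples, "samples.tsv": len(meta)})

    if bm is None and needs_data & set(enabled):
        bm, meta = read_beta_matrix(beta_path, sheet_path)

    if "diffmeth" in enabled:
        results = diff_meth.differential_methylation(bm, meta)
        frame = diff_meth.results_to_frame(results)
        frame.to_csv(out / "diffmeth.tsv", sep="\t", index=False, float_format="%.6g")
        tallies = diff_meth.count_directions(results)
        tallies.to_csv(out / "diffmeth_counts.tsv", sep="\t")
        counts["diffmeth"] = len(frame)
        _write_manifest(out, "diffmeth", config.seed, ["beta.tsv", "samples.tsv"],
                        {"diffmeth.tsv": len(frame), "diffmeth_counts.tsv": len(tallies)})

    survivors_n = 0
    if "search" in enabled:
        scores = combo_search.search(
            bm, meta, k_min=config.k_min, k_max=config.k_max,
            n_boot=config.n_boot, n_per_class=config.n_per_class,
            seed=config.seed, per_dataset=config.per_dataset,
            per_dataset_n_boot=config.per_dataset_n_boot,
        )
        frame = combo_search.scores_to_frame(scores)
        frame.to_csv(out / "search.tsv", sep="\t", index=False, float_format="%.6g")
        preset = combo_search.FILTER_PRESETS[config.filter_preset]
        if config.per_dataset:
            surv = combo_search.filter_combos(scores, **preset)
        else:
            surv = sorted(
                (s for s in scores if s.pooled_mean_auc >= preset["min_mean_auc"]),
                key=lambda s: (-s.pooled_mean_auc, s.probe_subset),
            )
        surv_frame = combo_search.scores_to_frame(surv) if surv else pd.DataFrame()
        surv_frame.to_csv(out / "survivors.tsv", sep="\t", index=False, float_format="%.6g")
        survivors_n = len(surv)
        counts["search"] = len(frame)
        _write_manifest(out, "search", config.seed, ["beta.tsv", "samples.tsv"],
                        {"search.tsv": len(frame), "survivors.tsv": survivors_n},
                        {"preset": config.filter_preset})

    if "fit" in enabled:
        roc = pan_cancer_model.crossval_roc(
            bm, meta, config.planted_probes, n_folds=config.n_folds,
            seed=config.seed, cutoffs=(config.cutoff,),
        )
        pan_cancer_model.roc_to_frame(roc).to_csv(
            out / "roc.tsv", sep="\t", index=False, float_format="%.6g")
        metrics = pd.DataFrame(
            roc.threshold_metrics,
            columns=["cutoff", "sensitivity", "specificity", "accuracy"],
        )
        metrics.insert(0, "auc", roc.auc)
        metrics.to_csv(out / "fit_metrics.tsv", sep="\t", index=False, float_format="%.6g")
        model = pan_cancer_model.fit_panel(bm, meta, config.planted_probes)
        model.to_text(out / "model.txt")
        counts["fit"] = len(roc.fpr)
        _write_manifest(out, "fit", config.seed, ["beta.tsv", "samples.tsv"],
                        {"roc.tsv": len(roc.fpr), "fit_metrics.tsv": len(metrics)},
                        {"auc": roc.auc})

    if "signatures" in enabled:
        scan = scan_signatures(
            bm, meta, k=config.signature_k, n_components=config.n_components,
            n_folds=config.signature_n_folds, seed=config.seed,
            max_subsets=config.signature_max_subsets,
        )
        rows = [
            {"tumor_type": c, "subset": "-".join(map(str, sub)), "auc": auc,
             "n_components": config.n_components}
            for c, (sub, auc) in sorted(scan.per_class_best.items())
        ]
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "signatures.tsv", sep="\t", index=False, float_format="%.6g")
        counts["signatures"] = scan.n_subsets
        _write_manifest(out, "signatures", config.seed, ["beta.tsv", "samples.tsv"],
                        {"signatures.tsv": len(frame)},
                        {"n_subsets": scan.n_subsets,
                         "grand_mean_auc": scan.grand_mean_auc})

    if "assoc" in enabled:
        table = covariate_assoc.assoc_table(bm, meta)
        table.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.6g")
        tp = [m for m in meta]
        tissue = np.array([1.0 if m.tissue == "TP" else 0.0 for m in tp])
        stage = np.array([m.stage if m.stage is not None else np.nan for m in tp])
        first_probe = bm.values[bm.probe_ids[0]].to_numpy()
        # stage is tumor-only; pair NT stage to the patient's TP stage so the
        # interaction model has complete cases in both classes
        stage_by_patient = {
            m.patient_barcode: m.stage for m in tp if m.stage is not None
        }
        stage = np.array(
            [stage_by_patient.get(m.patient_barcode, np.nan) for m in tp], dtype=float
        )
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            lrt, df, p = covariate_assoc.stage_interaction_lrt(tissue, first_probe, stage)
        pd.DataFrame(
            [{"probe_id": bm.probe_ids[0], "lrt_statistic": lrt, "df": df, "p_value": p}]
        ).to_csv(out / "stage_interaction.tsv", sep="\t", index=False, float_format="%.6g")
        counts["assoc"] = len(table)
        _write_manifest(out, "assoc", config.seed, ["beta.tsv", "samples.tsv"],
                        {"assoc.tsv": len(table), "stage_interaction.tsv": 1})

    if "report" in enabled:
        report = {
            "stage_row_counts": counts,
            "n_subsets_enumerated": counts.get("search", 0),
            "n_survivors": survivors_n,
            "version": __version__,
        }
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
        _write_manifest(out, "report", config.seed, ["*.tsv"], {"report.json": 1})

    return out
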