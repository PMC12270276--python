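"""End-to-end orchestration of the multistage linkage analysis.

Stage order: metabolomics QC -> microbe group comparison -> PLSR linkage
(per ion mode) -> optional fMRI metric maps / cluster means -> correlation
screens -> chained mediation -> enrichment.  Every stage writes TSV/JSON
under the output directory; a manifest records package version, seeds and
SHA-256 hashes of all outputs so reruns are verifiable byte-for-byte.

The ``validation`` flag repeats every covariate-adjusted stage (screens and
mediation) with the configured extra covariates; QC and PLSR selection are
untouched by it.
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

from . import __version__, assoc_stats, enrichment, mediation, metabolome_qc
from . import plsr_link

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    subjects_path: str = ""
    panel_paths: dict = field(default_factory=dict)  # ion mode -> TSV path
    annotation_path: str | None = None
    bold_path: str | None = None
    mask_path: str | None = None
    labels_path: str | None = None
    tr: float = 2.0

    microbe_column: str = "microbe"
    group_column: str = "group"
    patient_label: str = "patient"
    imaging_columns: list = field(default_factory=list)
    behavior_columns: list = field(default_factory=list)

    base_covariates: list = field(default_factory=lambda: [
        "age", "gender", "education", "site"])
    volumetric_extra: list = field(default_factory=lambda: ["tiv"])
    functional_extra: list = field(default_factory=lambda: ["fd"])
    validation_extra: list = field(default_factory=lambda: [
        "antidepressant_type", "illness_duration", "bmi"])

    n_perm: int = 5000
    n_boot: int = 5000
    fdr_level: float = 0.05
    band: tuple = (0.01, 0.1)
    fcd_threshold: float = 0.25
    top_fraction: float = 0.20
    seed: int = 0
    validation: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class _Stage:
    """Context that prefixes any stage failure with the stage name."""

    def __init__(self, name: str, log: list):
        self.name, self.log = name, log

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") \
                from exc
        self.log.append(self.name)
        return False


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns a report dict (also written as
    ``summary.json`` alongside per-stage outputs and ``manifest.json``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list = []
    report: dict = {"version": __version__, "seed": config.seed,
                    "validation": config.validation}

    with _Stage("load_inputs", stages_done):
        subjects = pd.read_csv(config.subjects_path, sep="\t", index_col=0)
        panels = {mode: metabolome_qc.read_panel_tsv(p, ion_mode=mode)
                  for mode, p in config.panel_paths.items()}

    is_patient = subjects[config.group_column] == config.patient_label
    patients = subjects[is_patient]

    with _Stage("metabolome_qc", stages_done):
        processed = {}
        for mode, panel in panels.items():
            proc = metabolome_qc.run_qc(panel)
            processed[mode] = proc
            zdf = proc.z_matrix.copy()
            zdf.index.name = "subject_id"
            zdf.to_csv(out / f"qc_{mode}_zmatrix.tsv", sep="\t")
            _write_tsv(proc.filter_log, out / f"qc_{mode}_filterlog.tsv")
            report.setdefault("qc", {})[mode] = {
                "n_input": len(proc.filter_log),
                "n_kept": int(proc.filter_log["kept"].sum()),
            }

    with _Stage("group_comparison", stages_done):
        gt = assoc_stats.mann_whitney(
            subjects.loc[is_patient, config.microbe_column],
            subjects.loc[~is_patient, config.microbe_column])
        report["group_test"] = {
            "u": gt.u_statistic, "z": gt.z_value, "p": gt.p_value,
            "direction": gt.direction, "n_patients": gt.n_a,
            "n_controls": gt.n_b,
        }
        (out / "group_test.json").write_text(
            json.dumps(report["group_test"], indent=2, sort_keys=True))

    with _Stage("plsr_link", stages_done):
        plsr_results = {}
        for mode, proc in processed.items():
            z_pat = proc.z_matrix.loc[patients.index]
            res = plsr_link.fit_plsr(
                z_pat, patients[config.microbe_column].to_numpy(),
                n_perm=config.n_perm, seed=config.seed, ion_mode=mode,
                fraction=config.top_fraction)
            plsr_results[mode] = res
            (out / f"plsr_{mode}.json").write_text(res.to_json())
            _write_tsv(res.ranked_loadings(), out / f"plsr_{mode}_loadings.tsv")
            report.setdefault("plsr", {})[mode] = {
                "overall_r": res.overall_r, "p_perm": res.p_perm,
                "n_pos": len(res.plsr_pos), "n_neg": len(res.plsr_neg),
            }

    if config.bold_path and config.mask_path:
        with _Stage("rsfmri_metrics", stages_done):
            import nibabel as nib

            from . import rsfmri_metrics as rm
            bold = np.asarray(nib.load(config.bold_path).dataobj, dtype=float)
            mask = np.asarray(nib.load(config.mask_path).dataobj) > 0
            vol = rm.Volume4D(data=bold, tr=config.tr, mask=mask)
            maps = rm.compute_all_metrics(vol, band=tuple(config.band),
                                          fcd_threshold=config.fcd_threshold)
            if config.labels_path:
                labels = np.asarray(
                    nib.load(config.labels_path).dataobj).astype(int)
                tables = []
                for name, mm in maps.items():
                    t = rm.extract_cluster_means(mm, labels, mask)
                    t.insert(0, "metric", name)
                    tables.append(t)
                _write_tsv(pd.concat(tables, ignore_index=True),
                           out / "cluster_means.tsv")
            report["rsfmri_metrics"] = sorted(maps)

    # covariate sets: functional imaging features get +FD on top of the base
    base_cov = list(config.base_covariates)
    func_cov = base_cov + list(config.functional_extra)
    if config.validation:
        base_cov = base_cov + list(config.validation_extra)
        func_cov = func_cov + list(config.validation_extra)

    imaging_cols = [c for c in (config.imaging_columns or
                                [c for c in subjects.columns
                                 if c.startswith("img_")])]
    behavior_cols = list(config.behavior_columns) or [
        c for c in ("hamd", "hama", "bdi", "rsas", "rpas", "teps", "cpt_ip_2",
                    "cpt_ip_3", "cpt_ip_4", "dst_forward", "dst_backward")
        if c in subjects.columns]

    screens = {}
    with _Stage("correlation_screens", stages_done):
        img = patients[imaging_cols]
        screens["microbe_imaging"] = assoc_stats.correlation_screen(
            patients[[config.microbe_column]], img,
            patients[func_cov], fdr_level=config.fdr_level)
        metab_cols = []
        metab_frames = []
        for mode, res in plsr_results.items():
            sel = list(res.plsr_pos) + list(res.plsr_neg)
            zf = processed[mode].z_matrix.loc[patients.index, sel]
            zf = zf.rename(columns={c: f"{mode}:{c}" for c in sel})
            metab_frames.append(zf)
            metab_cols += list(zf.columns)
        metab = pd.concat(metab_frames, axis=1) if metab_frames else \
            pd.DataFrame(index=patients.index)
        screens["metab_imaging"] = assoc_stats.correlation_screen(
            metab, img, patients[func_cov], fdr_level=config.fdr_level)
        screens["imaging_behavior"] = assoc_stats.correlation_screen(
            img, patients[behavior_cols], patients[func_cov],
            fdr_level=config.fdr_level)
        for name, df in screens.items():
            _write_tsv(df, out / f"screen_{name}.tsv")
            report.setdefault("screens", {})[name] = {
                "n_pairs": len(df), "n_significant": int(df["significant"].sum()),
            }

    with _Stage("mediation", stages_done):
        candidates = mediation.chain_candidates(
            screens["metab_imaging"], screens["imaging_behavior"],
            q_threshold=config.fdr_level)
        med_data = pd.concat([metab, patients[imaging_cols],
                              patients[behavior_cols], patients[func_cov]],
                             axis=1)
        results = mediation.mediation_screen(
            med_data, candidates, covariate_columns=func_cov,
            n_boot=config.n_boot, seed=config.seed)
        med_df = mediation.results_frame(results)
        _write_tsv(med_df, out / "mediation.tsv")
        report["mediation"] = {
            "n_candidates": len(candidates),
            "n_significant": int(med_df["significant"].sum())
            if len(med_df) else 0,
        }

    if config.annotation_path:
        with _Stage("enrichment", stages_done):
            ann = enrichment.read_annotation_tsv(config.annotation_path)
            for mode, res in plsr_results.items():
                survivors = list(processed[mode].z_matrix.columns)
                ann_mode = ann.restrict(survivors)
                for set_name, sel in (("pos", res.plsr_pos),
                                      ("neg", res.plsr_neg)):
                    if not set(sel) & ann_mode.universe:
                        continue
                    er = enrichment.enrich(sel, ann_mode)
                    _write_tsv(enrichment.results_frame(er),
                               out / f"enrichment_{mode}_{set_name}.tsv")
                    report.setdefault("enrichment", {})[
                        f"{mode}_{set_name}"] = {
                        "n_pathways": len(er),
                        "n_significant": sum(r.q_fdr < config.fdr_level
                                             for r in er),
                    }

    report["stages"] = stages_done
    (out / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "validation": config.validation,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json" and p.is_file()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return report
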