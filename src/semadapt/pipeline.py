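"""End-to-end pipeline orchestration: simulate -> index -> select -> design ->
analyze, with per-stage seed substreams and a reproducibility manifest.

Every output file is a function of the configuration and the global seed; the
manifest records SHA-256 hashes of all inputs and outputs so identical
configurations yield identical hash sets (timestamps live only in the
manifest and are excluded from hashing).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as sio
from ._seed import stage_seed
from .analysis import (
    CONTRAST_SC,
    adaptation_contrasts,
    detect_roi_interactions,
    fit_adaptation_lmm,
    flag_adaptation,
    posthoc_categories,
)
from .brainmap import load_taxonomy, score_regions
from .design import build_runs, matched_design
from .literature import AtlasVolume, region_scores, records_to_table, table_to_records, to_mni
from .selection import SelectionConfig, select_rois
from .simulate import (
    BoldSimConfig,
    CorpusConfig,
    LexiconConfig,
    gen_atlas,
    gen_bold,
    gen_brainmap_profiles,
    gen_lexicon,
    gen_literature_corpus,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger("semadapt")

STAGES = ("simulate", "index", "select", "design", "analyze")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Pipeline configuration: stage toggles, per-stage options, global seed."""

    outdir: str = "semadapt_run"
    seed: int = 0
    stages: Mapping[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    inputs: Mapping[str, str] = field(default_factory=dict)
    corpus: Mapping = field(default_factory=dict)
    atlas: Mapping = field(default_factory=dict)
    profiles: Mapping = field(default_factory=dict)
    lexicon: Mapping = field(default_factory=dict)
    bold: Mapping = field(default_factory=dict)
    selection: Mapping = field(default_factory=dict)
    design: Mapping = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages in config: {sorted(unknown)}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: PipelineConfig) -> None:
    """Check that every enabled stage can obtain its inputs before running."""
    on = config.stages
    inputs = config.inputs

    def needs(stage: str, requirement: str, upstream: str, keys: tuple) -> None:
        if on[stage] and not on[upstream] and not all(k in inputs for k in keys):
            raise ConfigError(
                f"stage '{stage}' needs {requirement} from disabled stage "
                f"'{upstream}'; supply inputs {list(keys)} or enable it"
            )

    needs("index", "corpus/atlas/profiles", "simulate", ("corpus", "atlas", "profiles", "paradigms"))
    needs("select", "region scores", "index", ("regions", "bm_scores"))
    if on["design"] and not on["simulate"]:
        raise ConfigError(
            "stage 'design' rebuilds the lexicon from the simulate stage; enable "
            "'simulate' (lexicon files cannot round-trip the relatedness matrix)"
        )
    if on["analyze"] and "betas" not in inputs:
        if not on["design"]:
            raise ConfigError(
                "stage 'analyze' needs a trial design to simulate betas; enable "
                "'design' or supply a 'betas' input file"
            )
        if not on["select"]:
            raise ConfigError(
                "stage 'analyze' needs selected ROIs to simulate betas; enable "
                "'select' or supply a 'betas' input file"
            )


def _planted_adaptation(selected: pd.DataFrame, design_df: pd.DataFrame) -> dict:
    """Plant default-scale adaptation effects into the first two semantic ROIs."""
    semantic = selected.loc[selected["assigned_class"] == "semantic", "region_label"]
    semantic = [str(r) for r in semantic]
    cats = design_df.loc[design_df["condition"] == "SameCategory"]
    def _prefer(available, preferred):
        avail = sorted(available)
        return [c for c in preferred if c in avail] + [c for c in avail if c not in preferred]

    abs_cats = _prefer(cats.loc[cats["domain"] == "ABS", "prime_category"].unique(), ("EM", "ATT"))
    cnc_cats = _prefer(cats.loc[cats["domain"] == "CNC", "prime_category"].unique(), ("BIOL", "ART"))
    planted = {}
    if len(semantic) >= 1:
        for cat, eff in zip(abs_cats[:2], (-2800.0, -2750.0)):
            planted[(semantic[0], cat)] = eff
    if len(semantic) >= 2:
        for cat, eff in zip(cnc_cats[:2], (-3400.0, -2900.0)):
            planted[(semantic[1], cat)] = eff
    return planted


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    A stage failure aborts the run with the stage name and cause; outputs of
    completed stages are retained. The manifest lists package version, global
    and per-stage seeds, configuration, and the path + SHA-256 of every file
    read or written.
    """
    from . import __version__

    validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "package": "semadapt",
        "version": __version__,
        "seed": int(config.seed),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages_run": [],
        "outputs": {},
        "inputs": {k: str(v) for k, v in config.inputs.items()},
        "notes": {},
    }

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    state: dict = {}

    def run_stage(stage: str, fn) -> None:
        if not config.stages[stage]:
            return
        logger.info("running stage %s", stage)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages_run"].append(stage)

    # ---------------------------------------------------------------- simulate
    def _simulate() -> None:
        seed = stage_seed(config.seed, "simulate")
        corpus_cfg = CorpusConfig(**{"seed": seed, **config.corpus})
        records = gen_literature_corpus(corpus_cfg)
        corpus_path = outdir / "corpus.tsv"
        sio.write_table(records_to_table(records), corpus_path, sio.CORPUS_SCHEMA)
        emit("simulate", "corpus", corpus_path)
        state["records"] = records

        atlas_img = gen_atlas(**config.atlas) if config.atlas else gen_atlas(
            grid_shape=(6, 6, 6), parcel_size_mm=30.0, voxel_size_mm=3.0
        )
        atlas_path = outdir / "atlas.nii.gz"
        atlas_img.to_filename(str(atlas_path))
        emit("simulate", "atlas", atlas_path)
        state["atlas"] = AtlasVolume(atlas_img)

        # Profile the parcels hit by the planted corpus centers, classes
        # assigned round-robin semantic/control/ambiguous.
        centers = corpus_cfg.region_centers
        labels = []
        for c in centers:
            lab, _ = state["atlas"].label_at(c, search_radius_mm=6.0)
            if lab is not None and lab not in labels:
                labels.append(lab)
        classes = {
            str(lab): ("semantic", "control", "ambiguous")[i % 3]
            for i, lab in enumerate(labels)
        }
        prof_cfg = dict(config.profiles)
        profiles, paradigms = gen_brainmap_profiles(
            [str(l) for l in labels],
            prof_cfg.pop("planted_class", classes),
            seed=prof_cfg.pop("seed", stage_seed(config.seed, "profiles")),
            **prof_cfg,
        )
        prof_path, para_path = outdir / "profiles.tsv", outdir / "paradigms.tsv"
        sio.write_table(profiles, prof_path, sio.PROFILES_SCHEMA)
        sio.write_table(paradigms, para_path, sio.PARADIGMS_SCHEMA)
        emit("simulate", "profiles", prof_path)
        emit("simulate", "paradigms", para_path)
        state["profiles"], state["paradigms"] = profiles, paradigms
        manifest["notes"]["planted_region_classes"] = classes

        lex_cfg = LexiconConfig(
            **{"seed": stage_seed(config.seed, "lexicon"), **config.lexicon}
        )
        lex = gen_lexicon(lex_cfg)
        lex_path = outdir / "lexicon.tsv"
        sio.write_table(lex.words, lex_path)
        rel_path = outdir / "relatedness.tsv"
        lex.relatedness.to_csv(rel_path, sep="\t")
        emit("simulate", "lexicon", lex_path)
        emit("simulate", "relatedness", rel_path)
        state["lexicon"] = lex

    # ------------------------------------------------------------------- index
    def _index() -> None:
        if "records" not in state:
            records = table_to_records(
                sio.read_table(config.inputs["corpus"], sio.CORPUS_SCHEMA)
            )
            state["records"] = records
            state["atlas"] = AtlasVolume.from_file(config.inputs["atlas"])
            state["profiles"] = sio.read_table(config.inputs["profiles"], sio.PROFILES_SCHEMA)
            state["paradigms"] = sio.read_table(config.inputs["paradigms"], sio.PARADIGMS_SCHEMA)
        mni_records = [to_mni(r) for r in state["records"]]
        regions, unassigned = region_scores(mni_records, state["atlas"])
        reg_path = outdir / "regions.tsv"
        sio.write_table(regions, reg_path, sio.REGIONS_SCHEMA)
        emit("index", "regions", reg_path)
        if len(unassigned):
            un_path = outdir / "unassigned_foci.tsv"
            sio.write_table(unassigned, un_path)
            emit("index", "unassigned_foci", un_path)
        state["regions"] = regions

        bm = score_regions(state["profiles"], state["paradigms"], load_taxonomy())
        bm_path = outdir / "bm_scores.tsv"
        sio.write_table(bm, bm_path, sio.BM_SCORES_SCHEMA)
        emit("index", "bm_scores", bm_path)
        state["bm_scores"] = bm

    # ------------------------------------------------------------------ select
    def _select() -> None:
        if "regions" not in state:
            state["regions"] = sio.read_table(config.inputs["regions"], sio.REGIONS_SCHEMA)
            state["bm_scores"] = sio.read_table(config.inputs["bm_scores"], sio.BM_SCORES_SCHEMA)
        regions = state["regions"].copy()
        regions["region_label"] = regions["atlas_label"].astype(str)
        candidates = regions.merge(state["bm_scores"], on="region_label", how="inner")[
            [
                "region_label",
                "sensitivity_index",
                "correction_level_index",
                "control_type_mean",
                "domain_specificity",
            ]
        ].dropna()
        sel_cfg = SelectionConfig(**config.selection)
        selected, audit = select_rois(candidates, sel_cfg)
        roi_path, audit_path = outdir / "rois.tsv", outdir / "selection_audit.tsv"
        sio.write_table(selected, roi_path)
        sio.write_table(audit, audit_path)
        emit("select", "rois", roi_path)
        emit("select", "audit", audit_path)
        state["selected"] = selected

    # ------------------------------------------------------------------ design
    def _design() -> None:
        lex = state["lexicon"]
        seed = stage_seed(config.seed, "design")
        pairs, sw, report = matched_design(lex, seed=seed, **config.design)
        trials = build_runs(pairs, sw, seed=seed)
        design_path = outdir / "design.tsv"
        sio.write_table(trials, design_path, sio.DESIGN_SCHEMA)
        emit("design", "design", design_path)
        rep_path = outdir / "matching_report.tsv"
        sio.write_table(report, rep_path)
        emit("design", "matching_report", rep_path)
        manifest["notes"]["matching_pass"] = bool(report.attrs["pass"])
        state["design"] = trials

    # ----------------------------------------------------------------- analyze
    def _analyze() -> None:
        if "betas" in config.inputs:
            betas = sio.read_table(config.inputs["betas"], sio.BETAS_SCHEMA)
        else:
            rois = [str(r) for r in state["selected"]["region_label"]]
            if not rois:
                raise ValueError("no ROIs selected; cannot simulate betas")
            planted = config.bold.get(
                "adaptation_map", _planted_adaptation(state["selected"], state["design"])
            )
            bold_cfg = BoldSimConfig(
                **{
                    "seed": stage_seed(config.seed, "bold"),
                    **{k: v for k, v in config.bold.items() if k != "adaptation_map"},
                    "rois": rois,
                    "adaptation_map": planted,
                }
            )
            betas = gen_bold(bold_cfg, state["design"])
            manifest["notes"]["planted_adaptation"] = {
                f"{r}|{c}": v for (r, c), v in planted.items()
            }
        beta_path = outdir / "betas.tsv"
        sio.write_table(betas, beta_path, sio.BETAS_SCHEMA)
        emit("analyze", "betas", beta_path)

        contrasts = adaptation_contrasts(betas)
        con_path = outdir / "contrasts.tsv"
        sio.write_table(contrasts, con_path, sio.CONTRASTS_SCHEMA)
        emit("analyze", "contrasts", con_path)

        cat = contrasts[contrasts["granularity"] == "category"].rename(
            columns={"contrast": "condition"}
        )
        lmm = fit_adaptation_lmm(cat)
        terms_path = outdir / "lmm_terms.tsv"
        sio.write_table(lmm.term_tests, terms_path)
        emit("analyze", "lmm_terms", terms_path)
        var_path = outdir / "lmm_variance.json"
        var_path.write_text(
            json.dumps(
                {
                    "var_subject": lmm.var_subject,
                    "var_residual": lmm.var_residual,
                    "icc": lmm.icc,
                    "wald_z_subject": lmm.wald_z_subject,
                    "p_subject": lmm.p_subject,
                    "formula": lmm.formula,
                    "n_obs": lmm.n_obs,
                    "n_subjects": lmm.n_subjects,
                },
                indent=2,
            )
        )
        emit("analyze", "lmm_variance", var_path)

        probe = detect_roi_interactions(cat)
        probe_path = outdir / "roi_interactions.tsv"
        sio.write_table(probe, probe_path)
        emit("analyze", "roi_interactions", probe_path)

        post_rows, flag_rows = [], []
        sc = contrasts[
            (contrasts["granularity"] == "category") & (contrasts["contrast"] == CONTRAST_SC)
        ]
        for roi in sorted(sc["roi"].unique()):
            for domain in sorted(sc.loc[sc["roi"] == roi, "domain"].unique()):
                cats = sc[(sc["roi"] == roi) & (sc["domain"] == domain)]["category"].unique()
                if len(cats) >= 2:
                    ph = posthoc_categories(contrasts, roi, domain)
                    for _, row in ph["pairwise"].iterrows():
                        post_rows.append(
                            {
                                "roi": roi,
                                "domain": domain,
                                "omnibus_test": ph["omnibus"]["test"],
                                "omnibus_statistic": ph["omnibus"]["statistic"],
                                "omnibus_p": ph["omnibus"]["p_value"],
                                **row.to_dict(),
                            }
                        )
                for cat_ in sorted(cats):
                    flag_rows.append(
                        {
                            "roi": roi,
                            "domain": domain,
                            "category": cat_,
                            "flag": flag_adaptation(contrasts, roi, cat_),
                        }
                    )
        post_path = outdir / "posthoc.tsv"
        sio.write_table(pd.DataFrame(post_rows), post_path)
        emit("analyze", "posthoc", post_path)
        flag_path = outdir / "adaptation_flags.tsv"
        sio.write_table(pd.DataFrame(flag_rows), flag_path)
        emit("analyze", "adaptation_flags", flag_path)

    run_stage("simulate", _simulate)
    run_stage("index", _index)
    run_stage("select", _select)
    run_stage("design", _design)
    run_stage("analyze", _analyze)

    manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
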