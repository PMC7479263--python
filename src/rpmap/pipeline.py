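"""One-command experiment runner reproducing the three-experiment study
design on phantom data.

Experiment 1 — five observers annotate the multi-annotator (MA) cohort;
ordinal Krippendorff's alpha is computed once per observer footprint with
slide-bootstrap 95% CIs.

Experiment 2 — per-observer one-component PLS models are trained on
lesion-wise medians from the MA cohort (plus shared unlabeled-consensus
controls) and applied voxel-wise to the single-annotator (SA) cohort; the
per-model mean predicted density over the SA evaluation lesions is compared
by repeated-measures ANOVA with Tukey HSD.

Experiment 3 — the consensus map (voxel-wise mean of the five models) is
scored lesion-wise against the high-grade vs low-grade/benign task,
with bootstrap AUC CIs and a Hanley–McNeil correlated-ROC z-test against
the ADC feature evaluated under identical conditions.

The MA and SA cohorts come from disjoint synthetic patients (disjoint
random substreams and patient ids), mirroring the nonoverlapping patient
split of the study design. Everything is deterministic given the one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cohort as coh
from . import evaluation as ev
from . import io as rio
from . import plsmap
from .phantom import (AnnotatorProfile, PhantomConfig, Slide, annotate_cohort,
                      default_annotator_profiles, generate_cohort)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _derive_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class ExperimentConfig:
    """Study-scale configuration for :func:`run_experiments`."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    annotators: list[AnnotatorProfile] = field(default_factory=default_annotator_profiles)
    ma_patients: int = 12
    sa_patients: int = 8
    slides_per_patient: int = 2
    min_area_vox: int = 201
    k_consensus_rois: int = 4
    n_boot: int = 500
    hgpin_group: str = "benign"
    adc_feature: str = "ADC_0_1000"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ma_patients < 1 or self.sa_patients < 1 or self.slides_per_patient < 1:
            raise ValueError("patient and slide counts must be positive")
        if not self.annotators:
            raise ValueError("need at least one annotator profile")

    def config_hash(self) -> str:
        payload = {
            "ma_patients": self.ma_patients, "sa_patients": self.sa_patients,
            "slides_per_patient": self.slides_per_patient,
            "min_area_vox": self.min_area_vox,
            "k_consensus_rois": self.k_consensus_rois, "n_boot": self.n_boot,
            "hgpin_group": self.hgpin_group, "adc_feature": self.adc_feature,
            "seed": self.seed, "grid": list(self.phantom.grid_shape),
            "annotators": [a.name for a in self.annotators],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def generate_split(config: ExperimentConfig) -> tuple[list[Slide], list[Slide]]:
    """Disjoint MA and SA cohorts; MA annotated by all observers, SA by the
    first observer only (the single-annotator pathologist)."""
    ma_cfg = replace(config.phantom, n_patients=config.ma_patients,
                     slides_per_patient=config.slides_per_patient,
                     seed=_derive_seed(config.seed, 0))
    sa_cfg = replace(config.phantom, n_patients=config.sa_patients,
                     slides_per_patient=config.slides_per_patient,
                     seed=_derive_seed(config.seed, 1))
    ma = generate_cohort(ma_cfg)
    sa = generate_cohort(sa_cfg)
    for s in ma:
        s.slide_id, s.patient_id = f"MA-{s.slide_id}", f"MA-{s.patient_id}"
    for s in sa:
        s.slide_id, s.patient_id = f"SA-{s.slide_id}", f"SA-{s.patient_id}"
    annotate_cohort(ma, config.annotators, seed=ma_cfg.seed)
    annotate_cohort(sa, config.annotators[:1], seed=sa_cfg.seed)
    return ma, sa


def build_ma_training(ma: list[Slide], config: ExperimentConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-observer rows, shared consensus-control rows) over MA slides."""
    obs_rows, shared_rows = [], []
    for slide in ma:
        vox = slide.features.voxel_area_mm2
        for obs in slide.annotations.observers:
            lesions = coh.extract_lesions(
                slide.annotations[obs], slide.prostate_mask,
                slide_id=slide.slide_id, observer=obs, voxel_area_mm2=vox,
                min_area_vox=config.min_area_vox)
            if lesions:
                obs_rows.append(coh.build_training_table(
                    lesions, slide.features, slide.truth_density,
                    hgpin_group=config.hgpin_group))
        rois = coh.consensus_unlabeled_rois(
            slide.annotations, slide.prostate_mask, k=config.k_consensus_rois,
            slide_id=slide.slide_id, voxel_area_mm2=vox)
        shared_rows.append(coh.build_training_table(
            rois, slide.features, slide.truth_density,
            hgpin_group=config.hgpin_group))
    obs_table = (pd.concat(obs_rows, ignore_index=True) if obs_rows
                 else pd.DataFrame())
    shared = pd.concat(shared_rows, ignore_index=True)
    return obs_table, shared


def build_sa_evaluation(sa: list[Slide], models: dict[str, plsmap.Pls1Model],
                        config: ExperimentConfig) -> pd.DataFrame:
    """Lesion-wise SA evaluation table: per-model and consensus predicted
    density, the ADC feature median, and the binary high-grade label."""
    rows = []
    obs_names = sorted(models)
    sa_observer = sa[0].annotations.observers[0]
    for slide in sa:
        vox = slide.features.voxel_area_mm2
        lesions = coh.extract_lesions(
            slide.annotations[sa_observer], slide.prostate_mask,
            slide_id=slide.slide_id, observer=sa_observer,
            voxel_area_mm2=vox, min_area_vox=config.min_area_vox,
            include_labels=(2, 3, 4, 5, 6))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            lesions += coh.select_controls(
                "atrophy", slide.annotations, slide.prostate_mask,
                observer=sa_observer, slide_id=slide.slide_id,
                voxel_area_mm2=vox, min_area_vox=config.min_area_vox)
        for w in caught:  # slides without atrophy are expected in a cohort
            logger.debug("%s", w.message)
        if not lesions:
            continue
        maps = {o: plsmap.predict_map(models[o], slide.features) for o in obs_names}
        cons = plsmap.consensus_map([maps[o] for o in obs_names])
        adc = slide.features.feature(config.adc_feature)
        for les in lesions:
            rec = {"lesion_id": les.lesion_id, "slide_id": les.slide_id,
                   "class": les.class_label,
                   "group": coh.lesion_group(les.class_label, config.hgpin_group),
                   "area_vox": les.area_vox}
            for o in obs_names:
                rec[f"pred_{o}"] = plsmap.roi_prediction(maps[o], les)
            rec["pred_consensus"] = plsmap.roi_prediction(cons, les)
            rec["adc"] = float(np.median(adc[les.rows, les.cols]))
            rows.append(rec)
    return pd.DataFrame(rows)


def run_experiments(config: ExperimentConfig, outdir: Path | None = None) -> dict:
    """Execute the three experiments end to end; returns the report dict.

    With ``outdir`` set, also writes report.json, the agreement / training /
    evaluation CSVs, and the per-observer model JSONs.
    """
    ma, sa = generate_split(config)

    # ---- Experiment 1: inter-observer agreement on the MA cohort
    agree = agr.cohort_agreement([s.annotations for s in ma],
                                 n_boot=config.n_boot,
                                 seed=_derive_seed(config.seed, 2))
    agree_records = [
        {"footprint_observer": r.footprint_observer, "alpha": r.alpha,
         "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "n_units": r.n_units}
        for r in agree
    ]

    # ---- Experiment 2: per-observer PLS models -> SA predictions -> ANOVA
    obs_table, shared = build_ma_training(ma, config)
    if obs_table.empty:
        raise RuntimeError("experiment 2: no training lesions survived the filter")
    models = plsmap.fit_observer_models(obs_table, shared_rows=shared)
    obs_names = sorted(models)
    eval_table = build_sa_evaluation(sa, models, config)
    if eval_table.empty:
        raise RuntimeError("experiment 3: no SA evaluation lesions")
    Y = eval_table[[f"pred_{o}" for o in obs_names]].to_numpy()
    anova = ev.rm_anova_tukey(Y, model_names=obs_names)

    # ---- Experiment 3: consensus vs ADC ROC comparison
    labels = ev.classification_labels(eval_table["group"])
    adc_scores, adc_sign = ev.orient_scores(eval_table["adc"].to_numpy(), labels)
    conditions = {o: eval_table[f"pred_{o}"].to_numpy() for o in obs_names}
    conditions["consensus"] = eval_table["pred_consensus"].to_numpy()
    conditions["ADC"] = adc_scores
    auc_report = {}
    for i, (name, scores) in enumerate(conditions.items()):
        roc = ev.empirical_roc(scores, labels)
        ci = ev.auc_bootstrap_ci(scores, labels, n_boot=config.n_boot,
                                 seed=_derive_seed(config.seed, 100 + i))
        auc_report[name] = {"auc": roc.auc, "ci_lo": ci[0], "ci_hi": ci[1]}
    comparison = ev.roc_compare(conditions["consensus"], conditions["ADC"], labels)

    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "cohort": {
            "ma_slides": len(ma), "sa_slides": len(sa),
            "n_eval_lesions": int(len(eval_table)),
            "n_positives": int(labels.sum()),
            "n_negatives": int((labels == 0).sum()),
            "n_training_rows": {o: int((obs_table["observer"] == o).sum())
                                + int(len(shared)) for o in obs_names},
        },
        "experiment1": {"footprints": agree_records},
        "experiment2": {
            "anova": {"F": anova.F, "df_model": anova.df_model,
                      "df_error": anova.df_error, "p": anova.p,
                      "degenerate": anova.degenerate,
                      "model_means": {o: float(m) for o, m in
                                      zip(obs_names, anova.model_means)}},
            "tukey": anova.tukey.to_dict(orient="records"),
        },
        "experiment3": {
            "auc": auc_report,
            "adc_orientation": adc_sign,
            "consensus_vs_adc": {
                "A1": comparison.A1, "A2": comparison.A2,
                "SE1": comparison.SE1, "SE2": comparison.SE2,
                "N1": comparison.N1, "N2": comparison.N2,
                "r": comparison.r, "z": comparison.z, "p": comparison.p,
            },
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        rio.write_table(pd.DataFrame(agree_records), outdir / "agreement.csv")
        rio.write_table(pd.concat([obs_table, shared], ignore_index=True),
                        outdir / "training_table.csv")
        rio.write_table(eval_table, outdir / "eval_lesions.csv")
        for o in obs_names:
            rio.write_model(models[o], outdir / f"model_{o}.json")
    return report
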