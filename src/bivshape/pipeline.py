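"""End-to-end orchestration of the shape-analysis pipeline.

Stage order mirrors the analysis itself: simulate a patient-like and a
control-like cohort -> rigidly align the pooled population -> fit PCA
shape models -> currents distances to the control mean (leave-one-out)
-> summed loading scores -> kNN leave-one-out classification with ROC
-> univariate association screen of patient loadings against clinical
indices.  Every stage is a pure function of (config, seed); a rerun
with the same config reproduces all CSV outputs bitwise.

Three models are fitted: one per group (whose variance fractions and
80 %-mode count describe each population's own shape structure, as in a
per-population analysis) and one pooled model used to express patients
and controls on common mode axes for scoring and correlation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associations import association_screen
from .classify import confusion_metrics, knn_loo, roc_and_cutoff
from .currents import KernelParams, loo_distance_to_mean
from .errors import ConfigurationError
from .mesh import save_ply
from .preprocess import rigid_align_population
from .shape_model import (
    build_population,
    fit_pca,
    loo_summed_scores,
    mode_at_sd,
    n_modes_for_variance,
)
from .synthetic import (
    MODE_IDS,
    ClinicalLink,
    CohortSpec,
    ModeBasis,
    make_template_biventricle,
    sample_clinical_indices,
    sample_cohort,
)

#: Planted group effect for the patient-like cohort: mean loading shift
#: per mode in SD units.  Free parameters of the simulation, not
#: estimates of any real cohort; chosen to give clear but imperfect
#: group separation.
DEFAULT_ARVC_OFFSETS = {
    "dilation": 1.5,
    "rvot_elong": 0.8,
    "septal_tilt": 0.5,
    "length": 0.8,
    "inlet_outlet_bulge": 0.8,
}

#: Default stochastic links from planted loadings to clinical indices.
DEFAULT_CLINICAL_LINKS = (
    ClinicalLink("tfc_major", "dilation", 1.0),
    ClinicalLink("tfc_minor", "rvot_elong", 0.5),
    ClinicalLink("cmr_major", "dilation", 1.0),
    ClinicalLink("cmr_minor", "rvot_elong", 0.5),
    ClinicalLink("vt_vf", "length", 1.5),
    ClinicalLink("icd", "length", 1.0),
    ClinicalLink("cardiac_arrest", "length", 1.0),
    ClinicalLink("syncope", "inlet_outlet_bulge", 1.2),
    ClinicalLink("ecg_major", "dilation", 1.5),
    ClinicalLink("sa_ecg", "septal_tilt", 1.0),
    ClinicalLink("fat", "dilation", 0.5),
    ClinicalLink("fibrosis", "dilation", 1.0),
)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every run writes a manifest."""

    n_arvc: int = 27
    n_control: int = 21
    circumferential_resolution: int = 24
    axial_resolution: int = 12
    sigma_w: float = 10.0
    variance_threshold: float = 0.8
    k: int = 3
    phase: str = "ES"
    seed: int = 0
    out_dir: str = "bivshape_out"
    write_meshes: bool = False
    group_separation: float = 1.0  # scales DEFAULT_ARVC_OFFSETS

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.phase not in ("ED", "ES"):
            raise ConfigurationError("phase must be ED or ES")
        if not 0 <= cfg.variance_threshold <= 1:
            raise ConfigurationError("variance_threshold must be in [0, 1]")
        if cfg.k < 1:
            raise ConfigurationError("k must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("config must be a flat key: value mapping")
        return cls.from_dict(d)


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    config: PipelineConfig
    report: dict
    variance_fractions: dict  # group -> array
    distances: pd.DataFrame
    scores: pd.DataFrame
    associations: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path, artifacts: list) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
    artifacts.append(str(path.name))


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    seed = int(config.seed)

    # --- simulate -------------------------------------------------------
    template = make_template_biventricle(
        config.circumferential_resolution, config.axial_resolution
    )
    basis = ModeBasis(template)
    offsets = {
        k: v * config.group_separation for k, v in DEFAULT_ARVC_OFFSETS.items()
    }
    arvc_spec = CohortSpec(
        n_subjects=config.n_arvc,
        group_label="ARVC",
        seed=seed,
        clinical_links=DEFAULT_CLINICAL_LINKS,
        mode_mean_offsets=offsets,
    )
    ctrl_spec = CohortSpec(
        n_subjects=config.n_control,
        group_label="control",
        seed=seed + 1_000_003,
    )
    arvc_meshes, z_arvc = sample_cohort(arvc_spec, template, basis)
    ctrl_meshes, z_ctrl = sample_cohort(ctrl_spec, template, basis)
    clinical = sample_clinical_indices(
        z_arvc, DEFAULT_CLINICAL_LINKS, seed=seed + 7
    )
    groups = ["ARVC"] * config.n_arvc + ["control"] * config.n_control
    ids = [f"ARVC_{i:02d}" for i in range(config.n_arvc)] + [
        f"CTRL_{i:02d}" for i in range(config.n_control)
    ]
    _write_csv(
        pd.DataFrame(
            np.vstack([z_arvc, z_ctrl]),
            columns=[f"true_{m}" for m in MODE_IDS],
        ).assign(subject_id=ids, group=groups),
        out / "true_loadings.csv",
        artifacts,
    )
    _write_csv(clinical, out / "clinical_indices.csv", artifacts)

    # --- preprocess: generalised Procrustes, no scaling -----------------
    pooled = arvc_meshes + ctrl_meshes
    aligned, transforms = rigid_align_population(pooled)
    rows = [
        np.concatenate([t.rotation.ravel(), t.translation]) for t in transforms
    ]
    _write_csv(
        pd.DataFrame(
            rows,
            columns=[f"r{i}{j}" for i in range(3) for j in range(3)]
            + ["tx", "ty", "tz"],
        ).assign(subject_id=ids),
        out / "transforms.csv",
        artifacts,
    )
    arvc_aligned = aligned[: config.n_arvc]
    ctrl_aligned = aligned[config.n_arvc :]

    # --- fit shape models ----------------------------------------------
    phase = config.phase
    pops = {
        "ARVC": build_population(arvc_aligned, phase, subject_ids=tuple(ids[: config.n_arvc])),
        "control": build_population(ctrl_aligned, phase, subject_ids=tuple(ids[config.n_arvc :])),
        "pooled": build_population(aligned, phase, subject_ids=tuple(ids)),
    }
    models, loadings, fractions = {}, {}, {}
    for name, pop in pops.items():
        models[name], loadings[name] = fit_pca(pop)
        fractions[name] = models[name].variance_fractions
    frac_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "group": name,
                    "mode": np.arange(1, len(fr) + 1),
                    "variance_fraction": fr,
                }
            )
            for name, fr in fractions.items()
        ]
    )
    _write_csv(frac_df, out / "variance_fractions.csv", artifacts)
    n80 = {
        name: n_modes_for_variance(models[name], config.variance_threshold)
        for name in models
    }

    if config.write_meshes:
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for name in ("ARVC", "control"):
            for kmode in range(1, min(5, models[name].n_modes) + 1):
                for s in (-1.0, 1.0):
                    tag = "m" if s < 0 else "p"
                    save_ply(
                        mode_at_sd(models[name], kmode, s),
                        mesh_dir / f"{name}_mode{kmode}_{tag}1sd",
                    )
        artifacts.append("meshes/")

    # --- currents distances (LOO against control mean) ------------------
    kernel = KernelParams(sigma_w=config.sigma_w)
    internal, external = loo_distance_to_mean(
        ctrl_aligned, arvc_aligned, kernel
    )
    dist_df = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "distance": np.concatenate([external, internal]),
        }
    )
    _write_csv(dist_df, out / "currents_distances.csv", artifacts)

    # --- summed loading scores (pooled model, LOO control stats) --------
    n_score_modes = min(5, models["pooled"].n_modes)
    ctrl_load = loadings["pooled"][config.n_arvc :]
    arvc_load = loadings["pooled"][: config.n_arvc]
    ctrl_scores, arvc_scores = loo_summed_scores(
        ctrl_load, arvc_load, fractions["pooled"], n_modes=n_score_modes
    )
    score_df = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "score": np.concatenate([arvc_scores, ctrl_scores]),
        }
    )
    _write_csv(score_df, out / "summed_scores.csv", artifacts)

    # --- kNN LOO classification + ROC on each scalar feature ------------
    report: dict = {
        "seed": seed,
        "phase": phase,
        "k": config.k,
        "sigma_w": config.sigma_w,
        "n_modes_80pct": n80,
        "variance_fractions_arvc_first5": [
            float(v) for v in fractions["ARVC"][:5]
        ],
    }
    for feat_name, df in (("currents_distance", dist_df), ("summed_score", score_df)):
        col = "distance" if feat_name == "currents_distance" else "score"
        preds = knn_loo(
            df[col].to_numpy(), df["group"].to_numpy(), k=config.k,
            subject_ids=df["subject_id"].to_numpy(),
        )
        acc, sens, spec = confusion_metrics(preds)
        roc = roc_and_cutoff(df[col].to_numpy(), df["group"].to_numpy())
        _write_csv(
            pd.DataFrame(
                {
                    "subject_id": [p.subject_id for p in preds],
                    "true_label": [p.true_label for p in preds],
                    "predicted_label": [p.predicted_label for p in preds],
                    "probability_arvc": [p.probability_arvc for p in preds],
                }
            ),
            out / f"predictions_{feat_name}.csv",
            artifacts,
        )
        _write_csv(
            pd.DataFrame(roc.roc_points, columns=["fpr", "tpr"]),
            out / f"roc_{feat_name}.csv",
            artifacts,
        )
        report[feat_name] = {
            "loo_knn_accuracy": acc,
            "loo_knn_sensitivity": sens,
            "loo_knn_specificity": spec,
            "roc_auc": roc.auc,
            "roc_accuracy": roc.accuracy,
            "roc_sensitivity": roc.sensitivity,
            "roc_specificity": roc.specificity,
            "optimal_cutoff": roc.optimal_cutoff,
        }

    # --- associations: patient loadings vs clinical indices -------------
    assoc = association_screen(
        loadings["pooled"][: config.n_arvc, :n_score_modes],
        clinical.drop(columns=["subject_id"]),
        n_modes=n_score_modes,
    )
    _write_csv(assoc, out / "associations.csv", artifacts)
    report["n_significant_associations"] = int(assoc["significant"].sum())
    report["associations_note"] = "p-values uncorrected for multiple testing"

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    artifacts.append("report.json")

    manifest = {
        "package": "bivshape",
        "version": __version__,
        "numpy": np.__version__,
        "config": asdict(config),
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        report=report,
        variance_fractions=fractions,
        distances=dist_df,
        scores=score_df,
        associations=assoc,
        manifest=manifest,
    )
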