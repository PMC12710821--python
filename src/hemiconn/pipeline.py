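"""Orchestration of the three analyses over a cohort, from one config.

Analysis 1: hemisphere-chirality classification on the dextral subset
(stratified 5-fold, configurable model families), plus the maximal-model
LDA trained on the full subset, its LD1 scores/correlation, and the
network enrichment of its scalings.

Analysis 2: the same chirality classification on the sinistral subset,
a size-matched dextral control (training folds subsampled to the size of
the sinistral training portion), and a paired comparison of fold-wise MCC
between full-dextral and size-matched runs.

Analysis 3: four-way (chirality x handedness) classification on the
hemiconnectomes, with and without minority oversampling, decomposed into
chirality and handedness performance; handedness-only classification on
the full connectome and transconnectome; and the hemisphere-space
statistics (Z(LD1) group ANOVA, LD1 correlations, and the
linear/segmented/quadratic LD1_dist ~ EHI model comparison).

Every stochastic stage draws its seed deterministically from a single
master seed, so partial reruns match full runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from hemiconn import classify, enrichment, hemispace
from hemiconn.connectome import (
    ConnectivityMatrix,
    ParcelAtlas,
    extract_features,
    subject_connectivity,
)
from hemiconn.synthetic import Cohort, CohortSpec, generate_cohort

__all__ = [
    "RunConfig",
    "stage_seed",
    "connectivity_matrices",
    "chirality_dataset",
    "fourway_dataset",
    "subject_dataset",
    "run_analysis",
    "validate_inputs",
]

_STAGES = (
    "cohort",
    "folds_dextral",
    "folds_sinistral",
    "folds_all",
    "enrichment",
    "bootstrap",
    "hc74",
    "breakpoint_boot",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    idx = _STAGES.index(stage)
    state = np.random.SeedSequence([int(master_seed), idx]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    n_subjects: int = 200
    parcels_per_hemi: int = 40
    timepoints: int = 300
    n_folds: int = 5
    models: tuple[str, ...] = ("LDA",)
    perm_reps: int = 500
    bootstrap_reps: int = 1000
    alpha: float = 0.01
    analyses: tuple[int, ...] = (1, 2, 3)
    seed: int = 0
    distance_n_boot: int = 200
    cohort_dir: str | None = None
    extra_spec: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("models",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "analyses" in data and isinstance(data["analyses"], list):
            data["analyses"] = tuple(int(a) for a in data["analyses"])
        return cls(**data)

    def to_dict(self) -> dict:
        from hemiconn.synthetic import DistanceModel, EhiModel

        out = vars(self).copy()
        out["models"] = list(self.models)
        out["analyses"] = list(self.analyses)
        extra = {}
        for key, value in self.extra_spec.items():
            if isinstance(value, (EhiModel, DistanceModel)):
                extra[key] = vars(value).copy()
            elif key == "asymmetry_map":
                extra[key] = {f"{a}|{b}": float(v) for (a, b), v in value.items()}
            elif key == "networks":
                extra[key] = [list(t) for t in value]
            else:
                extra[key] = value
        out["extra_spec"] = extra
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def cohort_spec(self) -> CohortSpec:
        from hemiconn.synthetic import spec_from_dict

        data = dict(self.extra_spec)
        data.update(
            n_subjects=self.n_subjects,
            parcels_per_hemi=self.parcels_per_hemi,
            timepoints=self.timepoints,
            seed=stage_seed(self.seed, "cohort"),
        )
        return spec_from_dict(data)


def connectivity_matrices(cohort: Cohort) -> list[ConnectivityMatrix]:
    """Fisher-Z connectivity matrix for every subject."""
    return [
        subject_connectivity(s.subject_id, s.timeseries_lh, s.timeseries_rh)
        for s in cohort.subjects
    ]


def chirality_dataset(
    matrices: Sequence[ConnectivityMatrix], atlas: ParcelAtlas
) -> dict:
    """Two hemiconnectome samples per subject, labelled LH / RH."""
    X, y, subjects = [], [], []
    for cm in matrices:
        for kind, label in (("HC-LH", "LH"), ("HC-RH", "RH")):
            X.append(extract_features(cm, atlas, kind).vector)
            y.append(label)
            subjects.append(cm.subject_id)
    return {"X": np.asarray(X), "y": np.asarray(y), "subjects": np.asarray(subjects)}


def fourway_dataset(
    matrices: Sequence[ConnectivityMatrix],
    atlas: ParcelAtlas,
    handedness: Mapping[str, str],
) -> dict:
    """Hemiconnectome samples labelled with the four-way outcome."""
    base = chirality_dataset(matrices, atlas)
    y4 = np.array(
        [
            classify.fourway_label(h, handedness[s])
            for h, s in zip(base["y"], base["subjects"])
        ]
    )
    return {"X": base["X"], "y": y4, "subjects": base["subjects"], "hemi": base["y"]}


def subject_dataset(
    matrices: Sequence[ConnectivityMatrix],
    atlas: ParcelAtlas,
    handedness: Mapping[str, str],
    kind: str,
) -> dict:
    """One sample per subject (FC or TC features), labelled by handedness."""
    X, y, subjects = [], [], []
    for cm in matrices:
        X.append(extract_features(cm, atlas, kind).vector)
        y.append(handedness[cm.subject_id])
        subjects.append(cm.subject_id)
    return {"X": np.asarray(X), "y": np.asarray(y), "subjects": np.asarray(subjects)}


def _runs_to_dict(runs: Sequence[classify.ClassificationRun]) -> list[dict]:
    return [r.to_dict() for r in runs]


def run_analysis(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the configured analyses and return the report bundle."""
    if cohort is None:
        if config.cohort_dir is not None:
            from hemiconn.synthetic import read_cohort

            cohort = read_cohort(config.cohort_dir)
        else:
            cohort = generate_cohort(config.cohort_spec())
    atlas = cohort.atlas
    meta = cohort.metadata
    handedness = dict(zip(meta["subject_id"], meta["handedness"]))
    ehi = dict(zip(meta["subject_id"], meta["ehi"]))
    matrices = connectivity_matrices(cohort)
    by_subject = {m.subject_id: m for m in matrices}
    dextral_ids = meta.loc[meta["handedness"] == "dextral", "subject_id"].tolist()
    sinistral_ids = meta.loc[meta["handedness"] == "sinistral", "subject_id"].tolist()

    report: dict = {
        "manifest": {
            "config": config.to_dict(),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
            "n_dextral": len(dextral_ids),
            "n_sinistral": len(sinistral_ids),
        }
    }

    def chir_data(ids: Sequence[str]) -> dict:
        return chirality_dataset([by_subject[s] for s in ids], atlas)

    if 1 in config.analyses:
        data = chir_data(dextral_ids)
        runs = [
            classify.cross_validated_run(
                data["X"], data["y"], data["subjects"], handedness,
                model_kind=m, input_kind="HC", outcome="chirality",
                n_folds=config.n_folds,
                seed=stage_seed(config.seed, "folds_dextral"),
                bootstrap_reps=config.bootstrap_reps,
            )
            for m in config.models
        ]
        enr = enrichment.enrichment_analysis(
            data["X"], data["y"], data["subjects"], atlas,
            reps=config.perm_reps, alpha=config.alpha,
            seed=stage_seed(config.seed, "enrichment"),
        )
        lda, sign = classify.fit_oriented_lda(data["X"], data["y"])
        scores = hemispace.ld1_scores(lda, data["X"], sign)
        lh_scores = scores[data["y"] == "LH"]
        rh_scores = scores[data["y"] == "RH"]
        r, p = hemispace.ld1_correlation(lh_scores, rh_scores)
        report["analysis1"] = {
            "classification": _runs_to_dict(runs),
            "enrichment": {
                "group_table": enr.group_table().to_dict(orient="list"),
                "n_significant": int(enr.mask.sum()),
                "n_lh_greater": enr.n_lh_greater,
                "n_rh_greater": enr.n_rh_greater,
            },
            "ld1": {
                "lh_mean": float(lh_scores.mean()),
                "rh_mean": float(rh_scores.mean()),
                "correlation_r": r,
                "correlation_p": p,
            },
        }

    if 2 in config.analyses:
        if len(sinistral_ids) < config.n_folds:
            raise ValueError("analysis 2 needs at least n_folds sinistral subjects")
        sin_data = chir_data(sinistral_ids)
        sin_runs = [
            classify.cross_validated_run(
                sin_data["X"], sin_data["y"], sin_data["subjects"], handedness,
                model_kind=m, input_kind="HC(L)", outcome="chirality",
                n_folds=config.n_folds,
                seed=stage_seed(config.seed, "folds_sinistral"),
                bootstrap_reps=config.bootstrap_reps,
            )
            for m in config.models
        ]
        target = classify.default_subsample_target(len(sinistral_ids))
        dex_data = chir_data(dextral_ids)
        full_runs = [
            classify.cross_validated_run(
                dex_data["X"], dex_data["y"], dex_data["subjects"], handedness,
                model_kind=m, input_kind="HC", outcome="chirality",
                n_folds=config.n_folds,
                seed=stage_seed(config.seed, "folds_dextral"),
                bootstrap_reps=config.bootstrap_reps,
            )
            for m in config.models
        ]
        matched_runs = [
            classify.cross_validated_run(
                dex_data["X"], dex_data["y"], dex_data["subjects"], handedness,
                model_kind=m, input_kind=f"HC{target}", outcome="chirality",
                n_folds=config.n_folds,
                seed=stage_seed(config.seed, "folds_dextral"),
                subsample_train=target,
                bootstrap_reps=config.bootstrap_reps,
            )
            for m in config.models
        ]
        full_mcc = [m for r in full_runs for m in r.fold_mcc]
        matched_mcc = [m for r in matched_runs for m in r.fold_mcc]
        try:
            paired = classify.compare_mcc_paired(matched_mcc, full_mcc)
        except ValueError:
            paired = {"mean_diff": 0.0, "t": None, "df": len(full_mcc) - 1,
                      "p": None, "d": None, "note": "degenerate differences"}
        report["analysis2"] = {
            "sinistral_classification": _runs_to_dict(sin_runs),
            "size_matched_control": _runs_to_dict(matched_runs),
            "subsample_target": target,
            "paired_mcc_comparison": paired,
        }

    if 3 in config.analyses:
        data4 = fourway_dataset(matrices, atlas, handedness)
        fourway_runs, handed_runs = [], []
        for oversample, tag in ((False, "HC"), (True, "HCO")):
            for m in config.models:
                run = classify.cross_validated_run(
                    data4["X"], data4["y"], data4["subjects"], handedness,
                    model_kind=m, input_kind=tag, outcome="fourway",
                    n_folds=config.n_folds,
                    seed=stage_seed(config.seed, "folds_all"),
                    oversample=oversample,
                    bootstrap_reps=config.bootstrap_reps,
                )
                fourway_runs.append(run)
                hemi_true, hand_true = classify.decompose_fourway(run.y_true)
                hemi_pred, hand_pred = classify.decompose_fourway(run.y_pred)
                handed_runs.append(
                    {
                        "model_kind": m,
                        "input_kind": tag,
                        "chirality_mcc": classify.mcc(
                            classify.confusion(hemi_true, hemi_pred)
                        ),
                        "handedness_mcc": classify.mcc(
                            classify.confusion(hand_true, hand_pred)
                        ),
                    }
                )
        for kind in ("FC", "TC"):
            datak = subject_dataset(matrices, atlas, handedness, kind)
            for m in config.models:
                run = classify.cross_validated_run(
                    datak["X"], datak["y"], datak["subjects"], handedness,
                    model_kind=m, input_kind=kind, outcome="handedness",
                    n_folds=config.n_folds,
                    seed=stage_seed(config.seed, "folds_all"),
                    bootstrap_reps=config.bootstrap_reps,
                )
                handed_runs.append(
                    {
                        "model_kind": m,
                        "input_kind": kind,
                        "handedness_mcc": float(run.mcc_point),
                    }
                )

        # hemisphere space from the maximal four-way model's LD1
        lda4, sign4 = classify.fit_oriented_lda(data4["X"], data4["hemi"])
        scores = hemispace.ld1_scores(lda4, data4["X"], sign4)
        is_lh = data4["hemi"] == "LH"
        subj_order = data4["subjects"][is_lh]
        lh_scores = scores[is_lh]
        rh_scores = scores[~is_lh]
        z = np.empty_like(scores)
        z[is_lh] = hemispace.z_within_group(lh_scores, np.zeros(lh_scores.size))
        z[~is_lh] = hemispace.z_within_group(rh_scores, np.zeros(rh_scores.size))
        # orient so positive Z(LD1) = a hemisphere farther out on its own side
        z_dir = np.where(is_lh, -z, z)
        hand_per_sample = np.array([handedness[s] for s in data4["subjects"]])
        z_anova = hemispace.group_distance_test(z_dir, hand_per_sample)
        dist = hemispace.ld1_dist(lh_scores, rh_scores)
        ehi_vals = np.array([ehi[s] for s in subj_order])
        fits = hemispace.fit_distance_models(
            ehi_vals, dist, n_boot=config.distance_n_boot,
            seed=stage_seed(config.seed, "breakpoint_boot"),
        )
        comparisons = {
            "linear_vs_segmented1": hemispace.compare_nested(
                fits["linear"], fits["segmented1"]
            ),
            "segmented1_vs_segmented2": hemispace.compare_nested(
                fits["segmented1"], fits["segmented2"]
            ),
            "linear_vs_quadratic": hemispace.compare_nested(
                fits["linear"], fits["quadratic"]
            ),
        }
        report["analysis3"] = {
            "fourway_classification": _runs_to_dict(fourway_runs),
            "decomposed_and_handedness": handed_runs,
            "hemisphere_space": {
                "z_ld1_anova": z_anova,
                "distance_fits": {
                    k: {
                        "aic": f.aic,
                        "r2": f.r2,
                        "breakpoints": None
                        if f.breakpoints is None
                        else f.breakpoints.tolist(),
                        "breakpoint_se": None
                        if f.breakpoint_se is None
                        else np.asarray(f.breakpoint_se).tolist(),
                        "vertex": f.vertex,
                        "opens_downward": f.opens_downward,
                    }
                    for k, f in fits.items()
                },
                "comparisons": comparisons,
            },
        }

    return report


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def validate_inputs(cohort_dir: str | Path) -> list[str]:
    """Validate an on-disk cohort; returns a list of violations (empty = OK)."""
    src = Path(cohort_dir)
    violations: list[str] = []
    meta_path = src / "subjects.tsv"
    atlas_path = src / "parcels.tsv"
    if not meta_path.exists():
        return [f"missing metadata table {meta_path}"]
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("subject_id", "ehi", "handedness"):
        if col not in meta.columns:
            violations.append(f"subjects.tsv missing column {col!r}")
    if "ehi" in meta.columns:
        ehi = pd.to_numeric(meta["ehi"], errors="coerce")
        missing = meta.loc[ehi.isna(), "subject_id"].tolist()
        if missing:
            violations.append(f"subjects with missing/non-numeric EHI: {missing}")
        bad = meta.loc[(ehi < -100) | (ehi > 100), "subject_id"].tolist()
        if bad:
            violations.append(f"subjects with EHI outside [-100, 100]: {bad}")
    if atlas_path.exists():
        try:
            ParcelAtlas.from_tsv(atlas_path)
        except ValueError as exc:
            violations.append(f"atlas: {exc}")
    else:
        violations.append(f"missing parcel table {atlas_path}")
    for sid in meta.get("subject_id", pd.Series(dtype=str)):
        for hemi in ("LH", "RH"):
            ts = src / f"{sid}_{hemi}.tsv"
            if not ts.exists():
                violations.append(f"missing timeseries {ts.name}")
                continue
            arr = np.loadtxt(ts, delimiter="\t")
            if not np.all(np.isfinite(arr)):
                violations.append(f"non-finite values in {ts.name}")
    for mat in sorted(src.glob("*_matrix.tsv")):
        arr = np.loadtxt(mat, delimiter="\t")
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            violations.append(f"{mat.name}: matrix is not square")
        elif not np.allclose(arr, arr.T, atol=1e-8):
            i, j = np.unravel_index(np.argmax(np.abs(arr - arr.T)), arr.shape)
            violations.append(f"{mat.name}: asymmetric at indices ({i}, {j})")
    return violations
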