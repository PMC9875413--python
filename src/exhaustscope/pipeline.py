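"""End-to-end orchestration: simulate, extract, filter, select, fit, evaluate.

The training arm mirrors the design of the study this package
re-implements: a checkpoint-inhibitor (ICI) surrogate cohort mixing two
tumor-line timecourses — an ICI-resistant, highly exhausted LLC-like
line and an ICI-responsive, less exhausted B16-like line, sampled at
days 0/7/22 — so the cohort spans low and high terminal-Tex fractions.
The validation arm applies the frozen model to an independently seeded
post-irradiation (RT) cohort following the LLC timecourse over days
0–21. Feature robustness is established on a separate test–retest
cohort before any modeling.

Every run is a pure function of its :class:`RunConfig`; the config hash
is stamped into all tabular outputs and the run manifest lists each
artifact with its checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import extract
from .imaging import to_suv
from .model import (
    SCORE_FEATURES,
    ScoreModel,
    SelectionResult,
    brier_score,
    c_index,
    calibration_curve,
    fit_score_model,
    select_all_characteristics,
    t_exhaustion_score,
)
from .phantom import (
    CohortSubject,
    PerturbationParams,
    PhantomSpec,
    b16_ici_timecourse,
    generate_cohort_schedule,
    generate_test_retest_pair,
    llc_ici_timecourse,
    llc_rt_timecourse,
)
from .robustness import RobustnessReport, filter_features
from .texture import DiscretizationConfig, TextureConfig

__all__ = [
    "RunConfig",
    "EvaluationReport",
    "TrainingResult",
    "build_feature_table",
    "run_training_arm",
    "run_validation_arm",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    n_train: int = 20
    n_validation: int = 20
    n_retest: int = 30
    seed: int = 42
    n_levels: int = 64
    glcm_distance: int = 1
    heterogeneity_gain: float = 1.0
    noise_sigma: float = 0.02
    shift_sd_mm: float = 0.25
    intensity_scale_sd: float = 0.02
    ct_ccc_threshold: float = 0.75
    pet_ccc_threshold: float = 0.65
    calibration_bins: int = 5

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def phantom_spec(self, seed: int = 0) -> PhantomSpec:
        return PhantomSpec(
            heterogeneity_gain=self.heterogeneity_gain,
            noise_sigma=self.noise_sigma,
            seed=seed,
        )

    def disc(self) -> DiscretizationConfig:
        return DiscretizationConfig(n_levels=self.n_levels)

    def tex(self) -> TextureConfig:
        return TextureConfig(distance=self.glcm_distance)


@dataclass
class EvaluationReport:
    """Discrimination and calibration of a score model on one cohort."""

    arm: str
    c_index: float
    brier: float
    calibration: pd.DataFrame
    call_rate: float
    n: int
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "c_index": self.c_index,
            "brier": self.brier,
            "call_rate": self.call_rate,
            "n": self.n,
            "config_hash": self.config_hash,
            "calibration": self.calibration.to_dict(orient="records"),
        }


@dataclass
class TrainingResult:
    model: ScoreModel
    selection: SelectionResult
    robustness: dict[str, RobustnessReport]
    evaluation: EvaluationReport
    pet_features: pd.DataFrame
    ct_features: pd.DataFrame
    truth: pd.DataFrame
    config: RunConfig = field(repr=False, default=RunConfig())


def build_feature_table(subjects: list[CohortSubject], catalog: str, cfg: RunConfig) -> pd.DataFrame:
    """Extract one catalog for every subject into a subjects x features frame."""
    rows, index = [], []
    for s in subjects:
        if catalog.upper() == "PET":
            fv = extract(to_suv(s.pet), s.mask, "PET", cfg.disc(), cfg.tex())
        else:
            fv = extract(s.ct, s.mask, "CT", cfg.disc(), cfg.tex())
        rows.append(fv.values)
        index.append(s.subject_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))


def _truth_table(subjects: list[CohortSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "day": [s.day for s in subjects],
            "early_tex_frac": [s.state.early_tex_frac for s in subjects],
            "terminal_tex_frac": [s.state.terminal_tex_frac for s in subjects],
            "e_t_ratio": [s.state.e_t_ratio for s in subjects],
            "pd1_mfi": [s.state.pd1_mfi for s in subjects],
            "label_high": [bool(s.state.label_high) for s in subjects],
        }
    ).set_index("subject_id")


def _training_schedule(n: int):
    """Alternate LLC-like and B16-like ICI subjects across days 0/7/22."""
    llc, b16 = llc_ici_timecourse(), b16_ici_timecourse()
    days = (0, 7, 22)
    return [((llc, b16)[i % 2], days[(i // 2) % 3]) for i in range(n)]


def _validation_schedule(n: int):
    """Post-irradiation LLC subjects cycling through days 0-21."""
    rt = llc_rt_timecourse()
    return [(rt, rt.timepoints[i % len(rt.timepoints)]) for i in range(n)]


def _retest_tables(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """PET and CT feature tables for a seeded test-retest cohort.

    The retest perturbation moves only the PET acquisition; CT test and
    retest scans come from the re-realized pair's masks applied to the
    per-realization CT volumes, so CT robustness reflects the mask
    re-rasterization under repositioning.
    """
    rt = llc_rt_timecourse()
    schedule = [(rt, rt.timepoints[i % len(rt.timepoints)]) for i in range(cfg.n_retest)]
    subjects = generate_cohort_schedule(
        schedule, cfg.phantom_spec(), seed=cfg.seed + 1_000_003
    )
    perturb = PerturbationParams(
        shift_sd_mm=cfg.shift_sd_mm,
        intensity_scale_sd=cfg.intensity_scale_sd,
        noise_sigma=cfg.noise_sigma,
    )
    pet_t, pet_r, ct_t, ct_r = [], [], [], []
    index = []
    for s in subjects:
        (p1, m1), (p2, m2) = generate_test_retest_pair(s.spec, s.state, perturb)
        pet_t.append(extract(to_suv(p1), m1, "PET", cfg.disc(), cfg.tex()).values)
        pet_r.append(extract(to_suv(p2), m2, "PET", cfg.disc(), cfg.tex()).values)
        # CT: same anatomy, sampled under the two mask positionings
        ct_t.append(extract(s.ct, m1, "CT", cfg.disc(), cfg.tex()).values)
        ct_r.append(extract(s.ct, m2, "CT", cfg.disc(), cfg.tex()).values)
        index.append(s.subject_id)
    idx = pd.Index(index, name="subject_id")
    return (
        pd.DataFrame(pet_t, index=idx),
        pd.DataFrame(pet_r, index=idx),
        pd.DataFrame(ct_t, index=idx),
        pd.DataFrame(ct_r, index=idx),
    )


def _evaluate(
    model: ScoreModel, features: pd.DataFrame, labels: np.ndarray, arm: str, cfg: RunConfig
) -> EvaluationReport:
    probs = np.array(
        [t_exhaustion_score(model, row)[1] for _, row in features.iterrows()]
    )
    return EvaluationReport(
        arm=arm,
        c_index=c_index(probs, labels),
        brier=brier_score(probs, labels),
        calibration=calibration_curve(probs, labels, cfg.calibration_bins),
        call_rate=float((probs > 0.5).mean()),
        n=len(labels),
        config_hash=cfg.hash(),
    )


def run_training_arm(cfg: RunConfig = RunConfig(), out_dir: str | Path | None = None) -> TrainingResult:
    """Execute the full training pipeline on the ICI surrogate cohort.

    Stages: simulate the mixed cohort, extract PET (on SUV) and CT
    features, establish feature robustness on a separate test–retest
    cohort, run LASSO screening per exhaustion characteristic over the
    robust features, refit the three-feature logistic model, and
    evaluate it on the training cohort.
    """
    subjects = generate_cohort_schedule(
        _training_schedule(cfg.n_train), cfg.phantom_spec(), seed=cfg.seed
    )
    truth = _truth_table(subjects)
    pet = build_feature_table(subjects, "PET", cfg)
    ct = build_feature_table(subjects, "CT", cfg)

    pet_t, pet_r, ct_t, ct_r = _retest_tables(cfg)
    rob = {
        "PET": filter_features(pet_t, pet_r, "PET", cfg.pet_ccc_threshold),
        "CT": filter_features(ct_t, ct_r, "CT", cfg.ct_ccc_threshold),
    }

    missing = [f for f in SCORE_FEATURES if f not in rob["PET"].retained]
    if missing:
        raise RuntimeError(
            f"score features failed the PET robustness filter: {missing}"
        )

    selection = SelectionResult(entries={})
    for modality, table in (("PET", pet), ("CT", ct)):
        sel = select_all_characteristics(
            table[list(rob[modality].retained)],
            truth,
            binary_label=truth["label_high"].to_numpy(),
            seed=cfg.seed,
        )
        selection.entries.update(
            {f"{modality}:{k}": v for k, v in sel.entries.items()}
        )

    model = fit_score_model(pet, truth["terminal_tex_frac"].to_numpy(), SCORE_FEATURES)
    evaluation = _evaluate(
        model, pet, truth["label_high"].to_numpy(dtype=int), "training", cfg
    )
    result = TrainingResult(
        model=model,
        selection=selection,
        robustness=rob,
        evaluation=evaluation,
        pet_features=pet,
        ct_features=ct,
        truth=truth,
        config=cfg,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def run_validation_arm(
    cfg: RunConfig = RunConfig(), model: ScoreModel | None = None
) -> tuple[EvaluationReport, pd.DataFrame, pd.DataFrame]:
    """Apply a frozen model to the independently seeded RT cohort.

    Returns the evaluation report plus the validation feature and truth
    tables. The validation cohort uses its own median split for the
    high/low outcome, per the cutoff definition of the score.
    """
    if model is None:
        model = run_training_arm(cfg).model
    missing = [f for f in SCORE_FEATURES if f not in model.feature_names]
    if missing:
        raise ValueError(f"model does not carry the score features: {missing}")
    subjects = generate_cohort_schedule(
        _validation_schedule(cfg.n_validation),
        cfg.phantom_spec(),
        seed=cfg.seed + 2_000_003,
    )
    truth = _truth_table(subjects)
    pet = build_feature_table(subjects, "PET", cfg)
    report = _evaluate(
        model, pet, truth["label_high"].to_numpy(dtype=int), "validation", cfg
    )
    return report, pet, truth


# --------------------------------------------------------------------------
# Output artifacts


def _write_outputs(result: TrainingResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    h = result.config.hash()

    def stamp(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["config_hash"] = h
        return df

    artifacts: dict[str, Path] = {}

    def save_csv(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        stamp(df).to_csv(path)
        artifacts[name] = path

    def save_json(name: str, payload: dict) -> None:
        path = out_dir / name
        payload = {**payload, "config_hash": h}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        artifacts[name] = path

    save_csv("pet_features.csv", result.pet_features)
    save_csv("ct_features.csv", result.ct_features)
    save_csv("ground_truth.csv", result.truth)
    save_csv("selection.csv", result.selection.to_frame().set_index("characteristic"))
    for modality, rep in result.robustness.items():
        save_csv(f"robustness_{modality.lower()}.csv", rep.to_frame().set_index("feature"))
    save_json("model.json", result.model.to_dict())
    save_json("evaluation_training.json", result.evaluation.to_dict())
    save_json("config.json", result.config.to_dict())

    manifest = {
        "config_hash": h,
        "artifacts": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(artifacts.items())
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
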