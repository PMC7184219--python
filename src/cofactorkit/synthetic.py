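"""Synthetic study-condition generators.

Emulates the data shapes of a cofactor-supplementation calibration
study: a nine-subject cohort given one oral bolus at t=0 with ~8 plasma
draws over 24 h, and a two-arm omics design (supplementation vs
water-only fasting control) with a shared fasting drift plus
supplementation-specific effects, multiplicative lognormal measurement
noise, detection-floor censoring and missing values.

Measurement noise is multiplicative lognormal (concentrations are
positive and LC-MS noise has a roughly constant CV); subject baselines
vary lognormally around the true C0 (default CV 15%).  Every generator
is seed-deterministic and emits a ground-truth manifest alongside the
data so downstream estimates can be checked against what generated them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import PKParameters, SubjectSeries, solve_compartments
from .toynet import build_toy_liver_network, toy_manifest  # noqa: F401 re-export

__all__ = [
    "DEFAULT_SAMPLE_TIMES",
    "COCKTAIL_DOSES_G",
    "PKCohortSpec",
    "OmicsDesignSpec",
    "generate_pk_cohort",
    "generate_omics_study",
    "build_toy_liver_network",
    "toy_manifest",
    "cohort_to_frame",
]

#: supplementation-day blood-draw grid (h); stand-in for the study's 8 draws
DEFAULT_SAMPLE_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 24.0)

#: single oral bolus at t=0, grams per compound
COCKTAIL_DOSES_G = {"serine": 20.0, "carnitine": 3.0, "nac": 5.0, "nr": 1.0}


class SyntheticSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class PKCohortSpec:
    """Design of a synthetic single-bolus PK cohort for one compound."""

    compound: str
    true_params: PKParameters
    dose_g: float
    n_subjects: int = 9
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    noise_cv: float = 0.1
    baseline_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SyntheticSpecError("n_subjects must be >= 1")
        t = np.asarray(self.sample_times, dtype=float)
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise SyntheticSpecError(
                "sample_times must start at 0 and be strictly increasing"
            )
        if self.noise_cv < 0 or self.baseline_cv < 0:
            raise SyntheticSpecError("noise/baseline CV must be >= 0")
        if self.dose_g < 0:
            raise SyntheticSpecError("dose must be >= 0")


def _model_values(params: PKParameters, dose_g: float, times: np.ndarray) -> np.ndarray:
    """Noiseless model concentrations at arbitrary (sorted) times."""
    if times[-1] == 0:
        return np.full(times.size, params.c0)
    # fine uniform grid covering the sample times, then exact index lookup
    step = 0.01
    _, states = solve_compartments(params, dose_g, float(times[-1]), step)
    idx = np.round(times / step).astype(int)
    return params.c0 + states[idx, 2]


def generate_pk_cohort(
    spec: PKCohortSpec,
) -> tuple[list[SubjectSeries], dict]:
    """Simulate per-subject plasma series plus a ground-truth manifest.

    Each subject's series is the noiseless model solution at the sample
    times (with a subject-specific lognormal baseline around the true C0)
    multiplied by lognormal measurement noise.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times, dtype=float)
    baselines = spec.true_params.c0 * _lognormal_factors(
        rng, spec.baseline_cv, spec.n_subjects
    )
    series = []
    for i in range(spec.n_subjects):
        p_i = PKParameters(
            k1=spec.true_params.k1,
            k2=spec.true_params.k2,
            c0=float(baselines[i]),
            scale=spec.true_params.scale,
            bioavailability=spec.true_params.bioavailability,
        )
        clean = _model_values(p_i, spec.dose_g, times)
        noisy = clean * _lognormal_factors(rng, spec.noise_cv, times.size)
        series.append(
            SubjectSeries(
                subject_id=f"S{i + 1}",
                compound=spec.compound,
                time_h=times,
                concentration=noisy,
            )
        )
    manifest = {
        "compound": spec.compound,
        "true_params": {
            "k1": spec.true_params.k1,
            "k2": spec.true_params.k2,
            "c0": spec.true_params.c0,
            "scale": spec.true_params.scale,
            "bioavailability": spec.true_params.bioavailability,
        },
        "dose_g": spec.dose_g,
        "subject_baselines": [float(b) for b in baselines],
        "sample_times_h": list(map(float, times)),
        "noise_cv": spec.noise_cv,
        "baseline_cv": spec.baseline_cv,
        "seed": spec.seed,
    }
    return series, manifest


def cohort_to_frame(series: list[SubjectSeries]) -> pd.DataFrame:
    """Long-format view of a cohort (subject_id, compound, time_h, value)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "compound": s.compound,
                "time_h": t,
                "value": v,
            }
            for s in series
            for t, v in zip(s.time_h, s.concentration)
        ]
    )


@dataclass(frozen=True)
class OmicsDesignSpec:
    """Two-arm longitudinal omics design.

    ``effect_suppl`` maps analyte -> log-fold-change trajectory (one value
    per sample time) applied only in the supplementation arm;
    ``effect_drift`` is the shared fasting drift applied to both arms.
    Analytes without an entry get a zero trajectory.
    """

    analytes: tuple[str, ...]
    effect_suppl: dict[str, tuple[float, ...]] = field(default_factory=dict)
    effect_drift: dict[str, tuple[float, ...]] = field(default_factory=dict)
    n_subjects_suppl: int = 9
    n_subjects_control: int = 10
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    baseline_mean: float = 1.0
    baseline_cv: float = 0.15
    noise_cv: float = 0.2
    missing_rate: float = 0.05
    detection_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise SyntheticSpecError("missing_rate must be in [0, 1)")
        nt = len(self.sample_times)
        for table_name, table in (
            ("effect_suppl", self.effect_suppl),
            ("effect_drift", self.effect_drift),
        ):
            for analyte, traj in table.items():
                if analyte not in self.analytes:
                    raise SyntheticSpecError(
                        f"{table_name} references unknown analyte '{analyte}'"
                    )
                if len(traj) != nt:
                    raise SyntheticSpecError(
                        f"{table_name}[{analyte}] must have one value per sample time"
                    )


def generate_omics_study(
    spec: OmicsDesignSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate supplementation and control panels plus a manifest.

    ``value = baseline * exp(drift + arm_effect) * noise``; values below
    the detection floor are censored to missing, then a further
    ``missing_rate`` fraction is dropped at random.  The t=0 record is
    never removed, so the baseline-normalization contract holds.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times, dtype=float)
    nt = times.size
    zeros = tuple(0.0 for _ in range(nt))

    def arm_panel(arm: str, n_subjects: int, prefix: str) -> pd.DataFrame:
        records = []
        for i in range(n_subjects):
            sid = f"{prefix}{i + 1}"
            for analyte in spec.analytes:
                base = spec.baseline_mean * float(
                    _lognormal_factors(rng, spec.baseline_cv, 1)[0]
                )
                drift = np.asarray(spec.effect_drift.get(analyte, zeros))
                eff = (
                    np.asarray(spec.effect_suppl.get(analyte, zeros))
                    if arm == "supplementation"
                    else np.zeros(nt)
                )
                noise = _lognormal_factors(rng, spec.noise_cv, nt)
                vals = base * np.exp(drift + eff) * noise
                vals = np.where(vals < spec.detection_floor, np.nan, vals)
                if spec.missing_rate > 0:
                    drop = rng.random(nt) < spec.missing_rate
                    drop[0] = False  # keep the baseline record
                    vals = np.where(drop, np.nan, vals)
                for t, v in zip(times, vals):
                    records.append(
                        {
                            "subject_id": sid,
                            "arm": arm,
                            "analyte": analyte,
                            "time_h": t,
                            "value": v,
                        }
                    )
        return pd.DataFrame(records)

    panel_suppl = arm_panel("supplementation", spec.n_subjects_suppl, "P")
    panel_ctrl = arm_panel("control", spec.n_subjects_control, "C")
    manifest = {
        "analytes": list(spec.analytes),
        "effect_suppl": {k: list(v) for k, v in spec.effect_suppl.items()},
        "effect_drift": {k: list(v) for k, v in spec.effect_drift.items()},
        "sample_times_h": list(map(float, times)),
        "n_subjects": {
            "supplementation": spec.n_subjects_suppl,
            "control": spec.n_subjects_control,
        },
        "noise_cv": spec.noise_cv,
        "baseline_cv": spec.baseline_cv,
        "missing_rate": spec.missing_rate,
        "detection_floor": spec.detection_floor,
        "seed": spec.seed,
    }
    return panel_suppl, panel_ctrl, manifest


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
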