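"""End-to-end pipeline driver: synthetic generation -> stats -> PK fit ->
dose optimization -> network conditioning.

A single :class:`RunConfig` seed fans out to per-stage seeds by stable
hashing, so each stage is independently reproducible.  Every stage
writes its artifacts under the run directory together with a provenance
record (config hash, stage seeds, package versions); stages never mutate
another stage's inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gem, stats, synthetic, toynet
from .pk import (
    PKParameters,
    SubjectSeries,
    find_dose,
    fit_pooled,
    interpolate_subject,
    long_term_increase,
    mean_curve,
    DoseRegimen,
)

log = logging.getLogger("cofactorkit")

#: per-compound daily safety caps (g/day); NR is fixed at 1 g twice daily
#: from literature and is not modeled
DEFAULT_DAILY_CAPS_G = {"serine": 25.5, "carnitine": 7.0, "nac": 6.0}

#: plausible "true" parameters for the synthetic cohorts: gut/elimination
#: rates as estimated for the three modeled compounds, baselines at
#: physiological plasma scale (µM), and scales set so a 100% long-term
#: increase needs a supplementation-sized daily dose (~25.5 / 16.6 /
#: 4.94 g/day respectively)
DEFAULT_TRUE_PARAMS = {
    "serine": PKParameters(k1=0.60916, k2=18.16688, c0=100.0, scale=1709.8),
    "carnitine": PKParameters(k1=0.20350, k2=1.67995, c0=40.0, scale=97.15),
    "nac": PKParameters(k1=0.29173, k2=28.32394, c0=5.0, scale=687.9),
}


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    compounds: tuple[str, ...] = ("serine", "carnitine", "nac")
    doses_g: dict = field(
        default_factory=lambda: dict(synthetic.COCKTAIL_DOSES_G)
    )
    daily_caps_g: dict = field(default_factory=lambda: dict(DEFAULT_DAILY_CAPS_G))
    bioavailability: dict = field(default_factory=dict)  # default 1.0 per compound
    target_increase_pct: float = 100.0
    n_subjects: int = 9
    noise_cv: float = 0.1
    interp_step_h: float = 0.25
    fit_starts_per_axis: int = 4
    n_analytes: int = 20
    gem_samples: int = 200
    gem_objective_fraction: float = 0.9
    gem_energy_kcal_per_h: float = 0.05  # toy-scaled maintenance floor
    stages: tuple[str, ...] = ("synth", "stats", "fit-pk", "dose-opt", "gem")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["compounds"] = list(self.compounds)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _provenance(config: RunConfig, stage: str) -> dict:
    import cobra
    import scipy

    return {
        "stage": stage,
        "config_hash": config.config_hash,
        "stage_seed": config.stage_seed(stage),
        "versions": {
            "cofactorkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "cobra": cobra.__version__,
        },
    }


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _default_effects(analytes: list[str], n_times: int) -> tuple[dict, dict]:
    """Supplementation effects for the first few analytes, mild shared drift."""
    ramp = tuple(np.linspace(0, 1, n_times))
    eff = {}
    for i, a in enumerate(analytes[:6]):
        sign = 1.0 if i % 2 == 0 else -1.0
        eff[a] = tuple(sign * 0.7 * r for r in ramp)
    drift = {a: tuple(-0.1 * r for r in ramp) for a in analytes}
    return eff, drift


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(config.to_dict(), out / "config.json")

    cohorts: dict[str, list[SubjectSeries]] = {}
    panels = None
    fits: dict[str, PKParameters] = {}

    if "synth" in config.stages:
        seed = config.stage_seed("synth")
        sdir = out / "synth"
        sdir.mkdir(exist_ok=True)
        frames = []
        for i, compound in enumerate(config.compounds):
            spec = synthetic.PKCohortSpec(
                compound=compound,
                true_params=DEFAULT_TRUE_PARAMS[compound],
                dose_g=config.doses_g.get(compound, 1.0),
                n_subjects=config.n_subjects,
                noise_cv=config.noise_cv,
                seed=seed + i,
            )
            series, manifest = synthetic.generate_pk_cohort(spec)
            cohorts[compound] = series
            frames.append(synthetic.cohort_to_frame(series))
            _write_json(manifest, sdir / f"pk_{compound}_manifest.json")
        pd.concat(frames).to_csv(sdir / "pk_cohort.csv", index=False)

        analytes = [f"analyte_{i + 1:02d}" for i in range(config.n_analytes)]
        eff, drift = _default_effects(analytes, len(synthetic.DEFAULT_SAMPLE_TIMES))
        ospec = synthetic.OmicsDesignSpec(
            analytes=tuple(analytes),
            effect_suppl=eff,
            effect_drift=drift,
            seed=seed + 100,
        )
        p_sup, p_ctl, omanifest = synthetic.generate_omics_study(ospec)
        panels = (p_sup, p_ctl)
        p_sup.to_csv(sdir / "omics_supplementation.csv", index=False)
        p_ctl.to_csv(sdir / "omics_control.csv", index=False)
        _write_json(omanifest, sdir / "omics_manifest.json")

        model = toynet.build_toy_liver_network()
        gem.save_network(model, str(sdir / "toy_liver.xml"))
        gem.save_network(model, str(sdir / "toy_liver.json"))
        _write_json(_provenance(config, "synth"), sdir / "provenance.json")
        log.info("synth stage complete")

    if "stats" in config.stages and panels is not None:
        p_sup, p_ctl = panels
        tdir = out / "stats"
        tdir.mkdir(exist_ok=True)
        fc_sup = stats.normalize_to_baseline(p_sup)
        fc_ctl = stats.normalize_to_baseline(p_ctl)
        base_tab = stats.anova_vs_baseline(fc_sup)
        between = stats.between_study_anova(fc_sup, fc_ctl)
        base_tab.to_csv(tdir / "anova_vs_baseline.tsv", sep="\t", index=False)
        between.to_csv(tdir / "anova_between_arms.tsv", sep="\t", index=False)
        stats.count_significant(between, min_timepoints=3).to_csv(
            tdir / "significant_ge3_timepoints.tsv", sep="\t", index=False
        )
        _write_json(_provenance(config, "stats"), tdir / "provenance.json")
        log.info("stats stage complete")

    if "fit-pk" in config.stages and cohorts:
        fdir = out / "fit_pk"
        fdir.mkdir(exist_ok=True)
        grid = np.arange(0.0, 24.0 + 1e-9, config.interp_step_h)
        for compound, series in cohorts.items():
            interps = [interpolate_subject(s, grid) for s in series]
            target = mean_curve(interps)
            fit = fit_pooled(
                target,
                dose_g=config.doses_g.get(compound, 1.0),
                bioavailability=config.bioavailability.get(compound, 1.0),
                n_starts_per_axis=config.fit_starts_per_axis,
            )
            fits[compound] = fit.params
            _write_json(
                {
                    "compound": compound,
                    "params": {
                        "k1": fit.params.k1,
                        "k2": fit.params.k2,
                        "c0": fit.params.c0,
                        "scale": fit.params.scale,
                    },
                    "rse_percent": fit.rse_percent,
                    "rss": fit.rss,
                    "converged": fit.converged,
                },
                fdir / f"fit_{compound}.json",
            )
        _write_json(_provenance(config, "fit-pk"), fdir / "provenance.json")
        log.info("fit-pk stage complete")

    if "dose-opt" in config.stages and fits:
        ddir = out / "dose_opt"
        ddir.mkdir(exist_ok=True)
        report = {}
        for compound, params in fits.items():
            rec = find_dose(
                params,
                config.target_increase_pct,
                daily_cap_g=config.daily_caps_g.get(compound),
            )
            simulated = long_term_increase(
                params,
                DoseRegimen.twice_daily(rec.dose_per_administration_g, days=14),
            )
            report[compound] = {
                "dose_per_administration_g": rec.dose_per_administration_g,
                "achieved_increase_pct": rec.achieved_increase_pct,
                "simulated_increase_pct": simulated,
                "capped": rec.capped,
            }
        _write_json(report, ddir / "dose_report.json")
        _write_json(_provenance(config, "dose-opt"), ddir / "provenance.json")
        log.info("dose-opt stage complete")

    if "gem" in config.stages:
        gdir = out / "gem"
        gdir.mkdir(exist_ok=True)
        seed = config.stage_seed("gem")
        model = toynet.build_toy_liver_network()
        gem.set_atp_maintenance(
            model, energy_kcal_per_h=config.gem_energy_kcal_per_h
        )
        weights = gem.build_fao_objective(model)
        gem.set_objective(model, weights)
        reference = gem.compute_reference(
            model,
            n=config.gem_samples,
            seed=seed,
            objective_fraction=config.gem_objective_fraction,
        )
        records = toynet.supplementation_records()
        conditioned = gem.apply_fold_change_constraints(model, reference, records)
        personalized = gem.personalized_fluxes(
            conditioned,
            n=config.gem_samples,
            seed=seed + 1,
            objective_fraction=config.gem_objective_fraction,
        )
        reference.fluxes.rename("mean_flux").to_csv(
            gdir / "reference_fluxes.tsv", sep="\t"
        )
        personalized.fluxes.rename("mean_flux").to_csv(
            gdir / "personalized_fluxes.tsv", sep="\t"
        )
        report = gem.compare_states(
            reference, personalized, toynet.toy_manifest()["pathways"]
        )
        for base in ("nad", "carn"):
            report.loc[len(report)] = {
                "pathway": f"{base}_turnover",
                "reference_flux": gem.turnover_flux(reference.fluxes, model, base),
                "personalized_flux": gem.turnover_flux(
                    personalized.fluxes, conditioned, base
                ),
                "ratio": np.nan,
                "direction": "",
            }
        report.to_csv(gdir / "change_report.tsv", sep="\t", index=False)
        _write_json(
            {**_provenance(config, "gem"), "objective_weights": weights},
            gdir / "provenance.json",
        )
        log.info("gem stage complete")

    summary = {
        "config_hash": config.config_hash,
        "stages_run": list(config.stages),
        "dose_report": (
            json.loads((out / "dose_opt" / "dose_report.json").read_text())
            if (out / "dose_opt" / "dose_report.json").exists()
            else None
        ),
    }
    _write_json(summary, out / "summary.json")
    return out


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Schema checks for pipeline inputs.

    ``paths`` maps kind ('panel' or 'model') to a file path.  Returns a
    list of issue records (empty = all clean): malformed rows, duplicate
    keys, missing t=0 baselines, and reactions with lb > ub.
    """
    issues: list[dict] = []
    for kind, path in paths.items():
        if kind.startswith("panel"):
            df = pd.read_csv(path)
            missing_cols = [c for c in stats.PANEL_COLUMNS if c not in df.columns]
            if missing_cols:
                issues.append(
                    {"file": path, "issue": f"missing columns {missing_cols}"}
                )
                continue
            dup = df.duplicated(["subject_id", "analyte", "time_h"])
            if dup.any():
                issues.append(
                    {"file": path, "issue": f"{int(dup.sum())} duplicate keys"}
                )
            has_base = df[df["time_h"] == 0].groupby(["subject_id", "analyte"]).size()
            all_pairs = df.groupby(["subject_id", "analyte"]).size()
            for key in all_pairs.index.difference(has_base.index):
                issues.append(
                    {
                        "file": path,
                        "issue": "missing t=0 baseline",
                        "subject_id": key[0],
                        "analyte": key[1],
                    }
                )
        elif kind.startswith("model"):
            if str(path).endswith(".json"):
                # check raw bounds first: the loader itself refuses lb > ub
                raw = json.loads(Path(path).read_text())
                for rxn in raw.get("reactions", []):
                    if rxn.get("lower_bound", 0) > rxn.get("upper_bound", 0):
                        issues.append(
                            {"file": path, "issue": "lb > ub", "reaction": rxn["id"]}
                        )
                if issues:
                    continue
            model = gem.load_network(path)
            for rxn in model.reactions:
                if rxn.lower_bound > rxn.upper_bound:
                    issues.append(
                        {"file": path, "issue": "lb > ub", "reaction": rxn.id}
                    )
        else:
            issues.append({"file": path, "issue": f"unknown input kind '{kind}'"})
    return issues
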