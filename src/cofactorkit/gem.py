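"""Conditioning a metabolic network on plasma metabolite fold changes.

The workflow mirrors relative-metabolic-difference (RMetD-style)
conditioning of a liver model:

1.  Prepare the reference model — reversibility-based default bounds, an
    ATP-maintenance floor representing resting hepatic energy
    expenditure, and a mitochondrial fatty-acid-oxidation (FAO) objective
    in which each reaction is weighted by the FADH2 + NADH it produces.
2.  Sample the reference flux space (hit-and-run, optionally restricted
    to near-optimal FAO) and average the samples into a reference state.
3.  Remap each measured metabolite's exchange bounds around its reference
    flux magnitude ``v`` according to the plasma fold change ``f``:

    ================  ==================  =====================
    exchange mode      plasma direction    new magnitude bounds
    ================  ==================  =====================
    uptake             decreased           [v, f*v]
    secretion          decreased           [v/f, v]
    uptake             increased           [v/f, v]
    secretion          increased           [v, f*v]
    ================  ==================  =====================

    A plasma drop of a metabolite the liver takes up is read as increased
    hepatic consumption, so the uptake floor rises to the reference flux
    and the ceiling to ``f`` times it; the remaining cases are the mirror
    images.  All rule arithmetic is done on magnitudes (uptake is
    negative flux internally) and the sign convention is restored on
    output.
4.  Re-sample the conditioned model and compare mean fluxes, including
    per-metabolite turnover (total production, = consumption at steady
    state, summed over compartments).

The network container, SBML/JSON IO, FBA and the ACHR sampler come from
cobrapy; the conditioning rules and summaries are defined here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model
from cobra.io import (
    load_json_model,
    read_sbml_model,
    save_json_model,
    write_sbml_model,
)
from cobra.sampling import ACHRSampler
from cobra.util.solver import fix_objective_as_constraint

__all__ = [
    "FoldChangeRecord",
    "ReferenceState",
    "InfeasibleModelError",
    "load_network",
    "save_network",
    "apply_reversibility_bounds",
    "set_atp_maintenance",
    "build_fao_objective",
    "set_objective",
    "sample_fluxes",
    "compute_reference",
    "apply_fold_change_constraints",
    "personalized_fluxes",
    "turnover_flux",
    "compare_states",
]

STEADY_STATE_TOL = 1e-6
ZERO_FLUX_TOL = 1e-9


class GEMValidationError(ValueError):
    """Raised for malformed networks or records."""


class InfeasibleModelError(RuntimeError):
    """Raised when a (conditioned) model has an empty flux space."""


@dataclass(frozen=True)
class FoldChangeRecord:
    """Plasma fold change of one metabolite for one subject.

    ``fold_change`` is >= 1; the sign of the change is carried by
    ``direction`` ('increased' or 'decreased'), so a halving is
    ``fold_change=2, direction='decreased'``.
    """

    metabolite_id: str
    fold_change: float
    direction: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.fold_change < 1.0:
            raise GEMValidationError(
                "fold_change must be >= 1 (direction carries the sign)"
            )
        if self.direction not in ("increased", "decreased"):
            raise GEMValidationError("direction must be 'increased' or 'decreased'")


@dataclass(frozen=True)
class ReferenceState:
    """Mean sampled flux per reaction."""

    fluxes: pd.Series
    n_samples: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# IO and model preparation
# ---------------------------------------------------------------------------


def load_network(path: str) -> Model:
    """Load a model from SBML L3 (.xml/.sbml) or the cobrapy JSON mirror."""
    p = str(path)
    if p.endswith(".json"):
        return load_json_model(p)
    if p.endswith((".xml", ".sbml")):
        return read_sbml_model(p)
    raise GEMValidationError(f"unrecognized model format: {p}")


def save_network(model: Model, path: str) -> None:
    p = str(path)
    if p.endswith(".json"):
        save_json_model(model, p)
    elif p.endswith((".xml", ".sbml")):
        write_sbml_model(model, p)
    else:
        raise GEMValidationError(f"unrecognized model format: {p}")


def apply_reversibility_bounds(model: Model, inf_value: float = math.inf) -> Model:
    """Default internal-reaction bounds before data constraints.

    Reversible internal reactions get (-inf, +inf) and irreversible ones
    (0, +inf); exchanges are untouched.  Pass a finite ``inf_value`` (the
    sampler needs a bounded polytope) to cap the unlimited bounds.
    """
    for rxn in model.reactions:
        if rxn.boundary:
            continue
        if rxn.reversibility or rxn.lower_bound < 0:
            rxn.bounds = (-inf_value, inf_value)
        else:
            rxn.bounds = (0.0, inf_value)
    return model


def set_atp_maintenance(
    model: Model,
    energy_kcal_per_h: float = 15.0,
    delta_g_kj_per_mol: float = 51.77,
    reaction_id: str = "ATPM",
) -> float:
    """Floor the ATP-hydrolysis reaction at the resting energy expenditure.

    ``lower bound = energy * 4.184 / delta_G * 1000`` mmol ATP/h — e.g.
    15 kcal/liver/h at 51.77 kJ/mol gives ~1,212 mmol/h.  Returns the
    bound applied.
    """
    if reaction_id not in model.reactions:
        raise GEMValidationError(f"ATP maintenance reaction '{reaction_id}' not found")
    lb = energy_kcal_per_h * 4.184 / delta_g_kj_per_mol * 1000.0
    rxn = model.reactions.get_by_id(reaction_id)
    rxn.bounds = (lb, max(rxn.upper_bound, lb))
    return lb


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def build_fao_objective(
    model: Model,
    fao_subsystem: str = "Fatty acid oxidation",
    mito_compartment: str = "m",
    fadh2_base_id: str = "fadh2",
    nadh_base_id: str = "nadh",
) -> dict[str, float]:
    """Weighted mitochondrial fatty-acid-oxidation objective.

    Selects reactions tagged with ``fao_subsystem`` that act in the
    mitochondrial compartment; each is weighted by the stoichiometric
    FADH2 plus NADH it *produces* (consumption contributes nothing).
    """
    weights: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.subsystem != fao_subsystem:
            continue
        if not any(met.compartment == mito_compartment for met in rxn.metabolites):
            continue
        w = 0.0
        for met, coeff in rxn.metabolites.items():
            base = met.id.rsplit("_", 1)[0]
            if met.compartment == mito_compartment and base in (
                fadh2_base_id,
                nadh_base_id,
            ):
                w += max(coeff, 0.0)
        if w > 0:
            weights[rxn.id] = w
    if not weights:
        raise GEMValidationError(
            f"no reactions matched subsystem '{fao_subsystem}' in compartment "
            f"'{mito_compartment}' producing {fadh2_base_id}/{nadh_base_id}"
        )
    return weights


def set_objective(model: Model, weights: dict[str, float]) -> Model:
    """Install a weighted maximization objective on ``model``."""
    expr = sum(
        w * model.reactions.get_by_id(rid).flux_expression for rid, w in weights.items()
    )
    model.objective = model.problem.Objective(expr, direction="max")
    return model


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_fluxes(
    model: Model,
    n: int = 1000,
    seed: int | None = None,
    thinning: int = 100,
    objective_fraction: float | None = 0.9,
) -> pd.DataFrame:
    """Hit-and-run (ACHR) samples of the flux polytope.

    With ``objective_fraction`` gamma in (0, 1], the objective is first
    constrained to >= gamma times its optimum, restricting sampling to the
    near-optimal region; ``None`` or 0 samples the full space.  Samples
    are seed-deterministic and each satisfies steady state and bounds.
    """
    with model as m:
        opt = m.slim_optimize(error_value=np.nan)
        if np.isnan(opt):
            raise InfeasibleModelError(_diagnose(model))
        if objective_fraction:
            fix_objective_as_constraint(m, fraction=objective_fraction)
        sampler = ACHRSampler(m, thinning=thinning, seed=seed)
        samples = sampler.sample(n)
    return samples


def compute_reference(
    model: Model,
    n: int = 1000,
    seed: int | None = None,
    thinning: int = 100,
    objective_fraction: float | None = 0.9,
) -> ReferenceState:
    """Average sampled fluxes into a representative reference state."""
    samples = sample_fluxes(
        model, n=n, seed=seed, thinning=thinning, objective_fraction=objective_fraction
    )
    return ReferenceState(fluxes=samples.mean(axis=0), n_samples=n, seed=seed)


personalized_fluxes = compute_reference
"""Mean flux distribution of a conditioned model (same procedure as the
reference: sample, then average)."""


def _diagnose(model: Model, candidates: list[str] | None = None) -> str:
    """Best-effort minimal infeasible-bound diagnosis by greedy relaxation."""
    rxns = candidates or [r.id for r in model.exchanges]
    culprits = []
    with model as m:
        for rid in rxns:
            r = m.reactions.get_by_id(rid)
            old = r.bounds
            r.bounds = (-1000.0, 1000.0)
            if not np.isnan(m.slim_optimize(error_value=np.nan)):
                culprits.append(f"{rid} {old}")
                r.bounds = old
                break
            # keep relaxed and continue searching
            culprits.append(f"{rid} {old}")
    return (
        "model is infeasible; bounds implicated (greedy relaxation): "
        + (", ".join(culprits) if culprits else "none isolated")
    )


# ---------------------------------------------------------------------------
# fold-change conditioning
# ---------------------------------------------------------------------------


def _exchange_for(model: Model, metabolite_id: str):
    met = model.metabolites.get_by_id(metabolite_id)
    boundary = sorted((r for r in met.reactions if r.boundary), key=lambda r: r.id)
    # prefer proper exchange reactions over sinks/demands
    exchanges = [r for r in boundary if r.id.startswith("EX_")] or boundary
    if not exchanges:
        raise GEMValidationError(
            f"metabolite '{metabolite_id}' has no exchange reaction"
        )
    return exchanges[0]


def apply_fold_change_constraints(
    model: Model,
    reference: ReferenceState,
    records: list[FoldChangeRecord],
    epsilon: float = 1e-3,
    default_exchange_bound: float = 1000.0,
) -> Model:
    """Return a copy of ``model`` with exchange bounds remapped (see module
    docstring table).

    Reference fluxes below ``ZERO_FLUX_TOL`` give a degenerate rule: the
    magnitude bounds fall back to ``[0, epsilon * default_exchange_bound]``
    in the exchange's reference direction, with a warning.
    """
    conditioned = model.copy()
    for rec in records:
        rxn = _exchange_for(conditioned, rec.metabolite_id)
        v_ref = float(reference.fluxes.get(rxn.id, np.nan))
        if np.isnan(v_ref):
            raise GEMValidationError(
                f"no reference flux for exchange '{rxn.id}' "
                f"({rec.metabolite_id})"
            )
        uptake = v_ref < 0
        v = abs(v_ref)
        f = rec.fold_change
        if v < ZERO_FLUX_TOL:
            warnings.warn(
                f"degenerate fold-change rule for {rxn.id}: reference flux ~0; "
                f"bounds set to [0, {epsilon * default_exchange_bound}]"
            )
            lo_mag, hi_mag = 0.0, epsilon * default_exchange_bound
            uptake = rxn.lower_bound < 0  # direction from the bound structure
        elif (uptake and rec.direction == "decreased") or (
            not uptake and rec.direction == "increased"
        ):
            lo_mag, hi_mag = v, f * v
        else:
            lo_mag, hi_mag = v / f, v
        if uptake:
            rxn.bounds = (-hi_mag, -lo_mag)
        else:
            rxn.bounds = (lo_mag, hi_mag)
    if np.isnan(conditioned.slim_optimize(error_value=np.nan)):
        raise InfeasibleModelError(
            _diagnose(
                conditioned,
                [_exchange_for(conditioned, r.metabolite_id).id for r in records],
            )
        )
    return conditioned


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def turnover_flux(
    fluxes: pd.Series,
    model: Model,
    metabolite_base_id: str,
    halved: bool = True,
) -> float:
    """Total turnover of a metabolite summed over all compartments.

    Per compartment the turnover is half the total absolute carried flux,
    ``0.5 * sum_j |s_ij * v_j|``, since production equals consumption at
    steady state.  ``halved=False`` gives the literal unsummed absolute
    flux (double-counting production and consumption).
    """
    mets = [
        m
        for m in model.metabolites
        if m.id.rsplit("_", 1)[0] == metabolite_base_id
    ]
    if not mets:
        raise GEMValidationError(f"metabolite '{metabolite_base_id}' not in model")
    total = 0.0
    for met in mets:
        # met.reactions is an unordered set; sort for reproducible summation
        carried = sum(
            abs(rxn.metabolites[met] * fluxes.get(rxn.id, 0.0))
            for rxn in sorted(met.reactions, key=lambda r: r.id)
        )
        total += carried / 2.0 if halved else carried
    return float(total)


def compare_states(
    reference: ReferenceState,
    personalized: ReferenceState,
    pathways: dict[str, list[str]],
    rel_tol: float = 0.02,
) -> pd.DataFrame:
    """Per-pathway mean-flux comparison between reference and conditioned.

    The pathway flux is the sum of member-reaction mean fluxes; the
    direction label is 'increased'/'decreased' when the ratio moves more
    than ``rel_tol`` from 1, else 'unchanged'.
    """
    rows = []
    for name, rids in pathways.items():
        ref = float(sum(reference.fluxes.get(r, 0.0) for r in rids))
        per = float(sum(personalized.fluxes.get(r, 0.0) for r in rids))
        ratio = per / ref if abs(ref) > ZERO_FLUX_TOL else np.inf if per else 1.0
        if ratio > 1 + rel_tol:
            direction = "increased"
        elif ratio < 1 - rel_tol:
            direction = "decreased"
        else:
            direction = "unchanged"
        rows.append(
            {
                "pathway": name,
                "reference_flux": ref,
                "personalized_flux": per,
                "ratio": ratio,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
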