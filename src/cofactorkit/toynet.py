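"""Hand-curated toy liver network for exercising the conditioning workflow.

A ~60-reaction, three-compartment (extracellular ``e``, cytosol ``c``,
mitochondrion ``m``) stoichiometric model containing the pathways the
cofactor cocktail is meant to engage: glucose uptake and glycolysis,
mitochondrial beta-oxidation fed through the carnitine shuttle, serine →
glycine → glutathione synthesis together with NAC-derived cysteine, BCAA
uptake and oxidation, nicotinamide/NAD salvage, an ATP-hydrolysis
maintenance reaction, a lipoprotein-secretion proxy, and exchange
reactions for every boundary metabolite.

Reactions are mass-balanced on toy formulas tracking C, N and S only
(cofactor pairs NAD/NADH, FAD/FADH2 and ATP/ADP share a formula, i.e.
hydrogen and phosphate transfer are not tracked; N-methylnicotinamide
keeps the nicotinamide formula).  The fixture is deterministic — it is
written by hand, not sampled — so flux expectations are stable.

Deliberate capacity structure: the TCA acetyl-CoA sink is capped
(``TCA`` ub = 2), so fatty-acid oxidation beyond that must export acetyl
units as acetyl-carnitine, which consumes carnitine.  Carnitine uptake
therefore limits the attainable beta-oxidation flux, and closing or
raising the carnitine exchange moves the FAO optimum — the behaviour the
supplementation scenario probes.
"""

from __future__ import annotations

from cobra import Metabolite, Model, Reaction

BIG = 1000.0  # finite stand-in for an unlimited bound

#: subsystem tag carrying the mitochondrial fatty-acid-oxidation reactions
FAO_SUBSYSTEM = "Fatty acid oxidation"

# id (without compartment suffix) -> toy formula
_FORMULAS = {
    "glc": "C6",
    "pyr": "C3",
    "accoa": "C2",  # acetyl carbons only; CoA treated as carrier
    "fa": "C16",
    "facar": "C23N1",
    "carn": "C7N1",
    "accar": "C9N1",
    "ser": "C3N1",
    "gly": "C2N1",
    "for": "C1",
    "cys": "C3N1S1",
    "nac": "C5N1S1",
    "ac": "C2",
    "glu": "C5N1",
    "gsh": "C10N3S1",
    "bcaa": "C6N1",
    "nh3": "N1",
    "nam": "C6N2",
    "nad": "C6N2",
    "nadh": "C6N2",
    "mnam": "C6N2",
    "fad": "",
    "fadh2": "",
    "atp": "C10N5",
    "adp": "C10N5",
    "o2": "",
    "co2": "C1",
    "h2o": "",
    "lipo": "C64",
}

# (id, stoichiometry, lb, ub, subsystem); stoichiometry maps met-id
# (with compartment suffix) -> coefficient
_REACTIONS = [
    # --- exchange reactions (one boundary metabolite each) ---
    # generic metabolites: uptake and secretion capped at 1
    ("EX_glc_e", {"glc_e": -1}, -1, 1, "Exchange"),
    ("EX_fa_e", {"fa_e": -1}, -1, 1, "Exchange"),
    ("EX_bcaa_e", {"bcaa_e": -1}, -1, 1, "Exchange"),
    ("EX_glu_e", {"glu_e": -1}, -1, 1, "Exchange"),
    ("EX_gly_e", {"gly_e": -1}, -1, 1, "Exchange"),
    # cocktail substances: uptake forced into [0.1, 1]
    ("EX_ser_e", {"ser_e": -1}, -1, -0.1, "Exchange"),
    ("EX_carn_e", {"carn_e": -1}, -1, -0.1, "Exchange"),
    ("EX_nac_e", {"nac_e": -1}, -1, -0.1, "Exchange"),
    ("EX_nam_e", {"nam_e": -1}, -1, -0.1, "Exchange"),
    # cysteine: uptake only (tied to the supplementation)
    ("EX_cys_e", {"cys_e": -1}, -1, 0, "Exchange"),
    # unlimited species
    ("EX_o2_e", {"o2_e": -1}, -BIG, 0, "Exchange"),
    ("EX_co2_e", {"co2_e": -1}, 0, BIG, "Exchange"),
    ("EX_h2o_e", {"h2o_e": -1}, -BIG, BIG, "Exchange"),
    # secreted products
    ("EX_gsh_e", {"gsh_e": -1}, 0, BIG, "Exchange"),
    ("EX_lipo_e", {"lipo_e": -1}, 0, BIG, "Exchange"),
    ("EX_for_e", {"for_e": -1}, 0, BIG, "Exchange"),
    ("EX_ac_e", {"ac_e": -1}, 0, BIG, "Exchange"),
    ("EX_accar_e", {"accar_e": -1}, 0, BIG, "Exchange"),
    ("EX_mnam_e", {"mnam_e": -1}, 0, BIG, "Exchange"),
    ("EX_nh3_e", {"nh3_e": -1}, 0, BIG, "Exchange"),
    # --- transport ---
    ("GLCt", {"glc_e": -1, "glc_c": 1}, 0, BIG, "Transport"),
    ("FAt", {"fa_e": -1, "fa_c": 1}, 0, BIG, "Transport"),
    ("SERt", {"ser_e": -1, "ser_c": 1}, 0, BIG, "Transport"),
    ("CARNt", {"carn_e": -1, "carn_c": 1}, 0, BIG, "Transport"),
    ("NACt", {"nac_e": -1, "nac_c": 1}, 0, BIG, "Transport"),
    ("CYSt", {"cys_e": -1, "cys_c": 1}, 0, BIG, "Transport"),
    ("NAMt", {"nam_e": -1, "nam_c": 1}, 0, BIG, "Transport"),
    ("BCAAt", {"bcaa_e": -1, "bcaa_c": 1}, 0, BIG, "Transport"),
    ("GLUt", {"glu_e": -1, "glu_c": 1}, 0, BIG, "Transport"),
    ("GLYt", {"gly_c": -1, "gly_e": 1}, -BIG, BIG, "Transport"),
    ("O2t", {"o2_e": -1, "o2_m": 1}, 0, BIG, "Transport"),
    ("CO2t", {"co2_m": -1, "co2_e": 1}, 0, BIG, "Transport"),
    ("H2Ot", {"h2o_m": -1, "h2o_e": 1}, -BIG, BIG, "Transport"),
    ("FORt", {"for_c": -1, "for_e": 1}, 0, BIG, "Transport"),
    ("ACt", {"ac_c": -1, "ac_e": 1}, 0, BIG, "Transport"),
    ("GSHt", {"gsh_c": -1, "gsh_e": 1}, 0, BIG, "Transport"),
    ("LIPOt", {"lipo_c": -1, "lipo_e": 1}, 0, BIG, "Transport"),
    ("MNAMt", {"mnam_c": -1, "mnam_e": 1}, 0, BIG, "Transport"),
    ("NH3t", {"nh3_m": -1, "nh3_e": 1}, 0, BIG, "Transport"),
    ("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0, BIG, "Transport"),
    ("FACARtm", {"facar_c": -1, "facar_m": 1}, 0, BIG, "Carnitine shuttle"),
    ("CARNtcm", {"carn_m": -1, "carn_c": 1}, -BIG, BIG, "Carnitine shuttle"),
    ("ACCARtm", {"accar_m": -1, "accar_c": 1}, 0, BIG, "Carnitine shuttle"),
    ("ACCARt", {"accar_c": -1, "accar_e": 1}, 0, BIG, "Transport"),
    ("NADt", {"nad_c": -1, "nad_m": 1}, -BIG, BIG, "Transport"),
    # malate-aspartate shuttle proxy: moves cytosolic reducing equivalents
    ("MASHTL", {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1}, 0, BIG,
     "Transport"),
    # --- core metabolism ---
    ("GLYCOLYSIS",
     {"glc_c": -1, "nad_c": -2, "adp_c": -2, "pyr_c": 2, "nadh_c": 2, "atp_c": 2},
     0, BIG, "Glycolysis"),
    ("PDH",
     {"pyr_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1},
     0, BIG, "Pyruvate metabolism"),
    ("CPT1", {"fa_c": -1, "carn_c": -1, "facar_c": 1}, 0, BIG, "Carnitine shuttle"),
    ("CPT2", {"facar_m": -1, "fa_m": 1, "carn_m": 1}, 0, BIG, "Carnitine shuttle"),
    ("FAOX",
     {"fa_m": -1, "fad_m": -7, "nad_m": -7,
      "accoa_m": 8, "fadh2_m": 7, "nadh_m": 7},
     0, BIG, FAO_SUBSYSTEM),
    # capped acetyl-CoA sink: excess acetyl units must leave as acetyl-carnitine
    ("TCA",
     {"accoa_m": -1, "nad_m": -3, "fad_m": -1,
      "co2_m": 2, "nadh_m": 3, "fadh2_m": 1},
     0, 2, "TCA cycle"),
    ("ACCARS", {"accoa_m": -1, "carn_m": -1, "accar_m": 1}, 0, BIG,
     "Carnitine shuttle"),
    ("ETC_NADH",
     {"nadh_m": -1, "o2_m": -0.5, "adp_c": -2.5,
      "nad_m": 1, "h2o_m": 1, "atp_c": 2.5},
     0, BIG, "Oxidative phosphorylation"),
    ("ETC_FADH2",
     {"fadh2_m": -1, "o2_m": -0.5, "adp_c": -1.5,
      "fad_m": 1, "h2o_m": 1, "atp_c": 1.5},
     0, BIG, "Oxidative phosphorylation"),
    ("ATPM", {"atp_c": -1, "adp_c": 1}, 0, BIG, "Maintenance"),
    ("SHMT", {"ser_c": -1, "gly_c": 1, "for_c": 1}, 0, BIG,
     "Serine and glycine metabolism"),
    ("NACDEAC", {"nac_c": -1, "cys_c": 1, "ac_c": 1}, 0, BIG,
     "Cysteine metabolism"),
    ("GSHS",
     {"glu_c": -1, "cys_c": -1, "gly_c": -1, "atp_c": -1, "gsh_c": 1, "adp_c": 1},
     0, BIG, "Glutathione synthesis"),
    ("BCAAtm", {"bcaa_c": -1, "bcaa_m": 1}, 0, BIG, "Transport"),
    ("BCAAOX",
     {"bcaa_m": -1, "fad_m": -1, "nad_m": -1,
      "accoa_m": 3, "nh3_m": 1, "fadh2_m": 1, "nadh_m": 1},
     0, BIG, "BCAA oxidation"),
    # NAD salvage / degradation kept at modest capacity so the nam<->nad
    # interconversion cannot run as a large futile cycle
    ("NADS", {"nam_c": -1, "nad_c": 1}, 0, 1, "NAD metabolism"),
    ("NADD", {"nad_m": -1, "nam_c": 1}, 0, 1, "NAD metabolism"),
    ("NNMT", {"nam_c": -1, "mnam_c": 1}, 0, BIG, "NAD metabolism"),
    ("LIPOS", {"fa_c": -4, "atp_c": -1, "lipo_c": 1, "adp_c": 1}, 0, BIG,
     "Lipoprotein assembly"),
]


def build_toy_liver_network() -> Model:
    """Construct the deterministic toy liver model (see module docstring)."""
    model = Model("toy_liver")
    model.compartments = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}
    mets: dict[str, Metabolite] = {}
    for rid, stoich, lb, ub, subsystem in _REACTIONS:
        rxn = Reaction(rid, lower_bound=float(lb), upper_bound=float(ub))
        rxn.subsystem = subsystem
        coeffs = {}
        for mid, coeff in stoich.items():
            if mid not in mets:
                base, comp = mid.rsplit("_", 1)
                mets[mid] = Metabolite(
                    mid, formula=_FORMULAS[base] or None, compartment=comp, name=base
                )
            coeffs[mets[mid]] = float(coeff)
        rxn.add_metabolites(coeffs)
        model.add_reactions([rxn])
    model.objective = "FAOX"
    return model


def supplementation_records(fold_change: float = 2.0):
    """Fold-change records emulating the cocktail-supplementation scenario.

    The cofactors (serine, carnitine, NAC, nicotinamide) and the
    substrates the activated liver draws harder on (fatty acids, BCAAs)
    are recorded as plasma-decreased — for an uptaken metabolite that
    reads as increased consumption, so the uptake bounds move up to
    ``[v, f*v]``.  Glucose is recorded plasma-increased (consumption
    down), so glycolytic flux must not increase.
    """
    from .gem import FoldChangeRecord

    recs = [
        FoldChangeRecord("ser_e", fold_change, "decreased"),
        FoldChangeRecord("carn_e", fold_change, "decreased"),
        FoldChangeRecord("nac_e", fold_change, "decreased"),
        FoldChangeRecord("nam_e", fold_change, "decreased"),
        FoldChangeRecord("cys_e", fold_change, "decreased"),
        FoldChangeRecord("fa_e", fold_change, "decreased"),
        FoldChangeRecord("bcaa_e", fold_change, "decreased"),
        FoldChangeRecord("glc_e", 1.5, "increased"),
    ]
    return recs


def toy_manifest() -> dict:
    """Counts and landmark reaction ids, for validation and tests."""
    return {
        "n_reactions": len(_REACTIONS),
        "n_metabolites": len(
            {mid for _, st, *_ in _REACTIONS for mid in st}
        ),
        "fao_reaction": "FAOX",
        "atp_maintenance": "ATPM",
        "pathways": {
            "fatty_acid_oxidation": ["FAOX"],
            "glutathione_synthesis": ["GSHS"],
            "bcaa_oxidation": ["BCAAOX"],
            "glycolysis": ["GLYCOLYSIS"],
            "lipoprotein_secretion": ["LIPOS"],
        },
        "cocktail_exchanges": ["EX_ser_e", "EX_carn_e", "EX_nac_e", "EX_nam_e"],
    }
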