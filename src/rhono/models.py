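"""Concrete model builders: two-node motif, initial RhoA-NO model, extension with tension.

Three models of the RhoA / nitric-oxide mutual-antagonism network:

* :func:`build_two_node` — the minimal two-species double-negative motif
  with pure mass-action kinetics (zeroth-order synthesis, first-order decay,
  bimolecular cross-inhibition).  Provably monostable for every positive
  parameter combination.
* :func:`build_initial_model` — the biochemical network: HGF-driven RhoA
  activation, ROCK, phospho-Akt, eNOS transcription/translation/S1177
  phosphorylation, NO, cGMP and PKG, with the two antagonism arms
  ki1 (ROCK represses Akt phosphorylation) and ki2 (active RhoA destabilises
  eNOS mRNA) and PKG-mediated RhoA-Ser188 phosphorylation closing the
  double-negative loop.  31 reactions, 11 state variables.
* :func:`build_extended_model` — the initial network plus a scalar
  cytoskeletal-tension surrogate: ROCK generates tension, tension activates
  RhoA (mechanical positive feedback), and the NO/cGMP arm dissipates
  tension.  35 reactions, 12 state variables, 36 perturbable parameters.

The full supplementary kinetics of the original study are not public in the
sources bundled here, so the 11- and 12-state networks are *synthetic
reconstructions*: topology, species list, rate-law families and parameter
names follow the published description, and the baseline values below were
calibrated once so that the reconstruction reproduces the published
qualitative regime (bistable baseline; stable-branch NO spanning roughly
1-8 nM without tension and widening several-fold with tension).  Absolute
magnitudes are qualitative, as in the original analysis.
"""

from __future__ import annotations

from .network_core import (
    ModelDefinition,
    ParameterSet,
    Reaction,
    SpeciesState,
)

__all__ = [
    "build_two_node",
    "build_initial_model",
    "build_extended_model",
    "perturbable_parameters",
    "TWO_NODE_SPECIES",
    "INITIAL_SPECIES",
    "EXTENDED_SPECIES",
]

TWO_NODE_SPECIES = ["A", "B"]

INITIAL_SPECIES = [
    "RhoA_GDP", "RhoA_GTP", "RhoA_pS188", "ROCK", "pAkt",
    "eNOS_mRNA", "eNOS", "peNOS", "NO", "cGMP", "PKG",
]

EXTENDED_SPECIES = INITIAL_SPECIES + ["Tension"]

#: clamped growth-factor stimulus (dimensionless input level)
HGF_INPUT = 1.0

# Baseline rate constants for the reconstructed biochemical model.
# Units: zeroth-order nM/t, first-order 1/t, bimolecular 1/(nM t);
# Kmcgmp nM; ncgmp dimensionless.  Calibrated once (see docs/methods.md).
INITIAL_BASELINE: dict[str, float] = {
    # RhoA module
    "k1": 1.4,       # RhoA synthesis (as GDP-bound)
    "kdeg1": 0.01,   # RhoA_GDP degradation
    "k2": 0.5,      # HGF-driven RhoA activation (GEF activity)
    "kb2": 0.005,    # basal RhoA activation
    "k3": 0.5,       # intrinsic GTP hydrolysis (inactivation)
    "k4": 0.25,       # PKG-mediated Ser188 phosphorylation of active RhoA
    "k5": 0.2,       # Ser188 dephosphorylation (back to GDP pool)
    "kdeg2": 0.005,   # phospho-RhoA degradation
    # ROCK
    "k12": 0.1,      # ROCK activation by active RhoA
    "kdeg4": 0.1,    # ROCK inactivation/degradation
    # Akt
    "k6": 1.0,       # HGF-driven Akt phosphorylation
    "kb1": 0.05,     # basal Akt phosphorylation
    "kdeg3": 0.1,    # Akt dephosphorylation
    "ki1": 0.01,     # ROCK inhibition of Akt phosphorylation (antagonism arm 1)
    # eNOS expression
    "k7": 0.1,       # eNOS transcription
    "kdeg5": 0.05,   # eNOS mRNA turnover
    "ki2": 0.003,    # RhoA-mediated eNOS mRNA destabilisation (antagonism arm 2)
    "k8": 0.5,       # translation
    "kdeg6": 0.1,    # eNOS protein degradation
    # eNOS activation
    "k9": 0.02,      # Akt-mediated S1177 phosphorylation
    "k10": 0.2,      # S1177 dephosphorylation
    "kdeg7": 0.05,   # phospho-eNOS degradation
    # NO / cGMP / PKG
    "k11": 2.0,      # NO production by phospho-eNOS
    "k13": 0.1,      # basal NO production by unphosphorylated eNOS
    "kdeg8": 0.5,    # NO consumption (scavenging/diffusion)
    "kox": 0.01,     # second-order NO autoxidation
    "k14": 0.5,      # soluble guanylyl cyclase: NO -> cGMP
    "kdeg9": 0.5,    # basal cGMP hydrolysis (PDE)
    "kpde": 0.005,   # PKG-stimulated cGMP hydrolysis (negative feedback)
    "k15": 1.0,      # PKG activation, Hill in cGMP
    "Kmcgmp": 3.0,   # cGMP half-activation constant of the Hill term
    "ncgmp": 2.2,    # Hill coefficient (structural cooperativity, not perturbed)
    "kdeg10": 0.1,   # PKG inactivation
}

# Tension extension: three additional rate constants.
TENSION_BASELINE: dict[str, float] = {
    "k16": 0.02,     # ROCK-driven tension generation
    "k17": 0.005,   # tension-mediated RhoA activation (mechanical feedback)
    "k18": 0.05,     # NO/cGMP-driven tension dissipation
    "kdeg11": 0.05,  # basal tension relaxation
}

#: parameters treated as structural constants, excluded from robustness grids
STRUCTURAL_PARAMETERS = ("ncgmp",)


def build_two_node(
    ksynthA: float, kdegA: float, ksynthB: float, kdegB: float,
    kiA: float, kiB: float,
) -> tuple[ModelDefinition, ParameterSet]:
    """Minimal two-species mutual-antagonism motif, pure mass action.

    dA/dt = ksynthA - kdegA*A - kiB*A*B
    dB/dt = ksynthB - kdegB*B - kiA*A*B

    ``kiA`` is the rate constant of the inhibition exerted *by* A on B and
    vice versa; setting both to zero decouples the species into independent
    birth-death processes.  Synthesis and degradation constants must be
    strictly positive; the inhibition constants may be zero.
    """
    for name, v in [("ksynthA", ksynthA), ("kdegA", kdegA),
                    ("ksynthB", ksynthB), ("kdegB", kdegB)]:
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    for name, v in [("kiA", kiA), ("kiB", kiB)]:
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")

    model = ModelDefinition(
        name="two_node",
        species=[SpeciesState("A", role="generic antagonist"),
                 SpeciesState("B", role="generic antagonist")],
        reactions=[
            Reaction("synthA", "synthesis", products={"A": 1}, parameters=["ksynthA"]),
            Reaction("degA", "decay", substrates={"A": 1}, parameters=["kdegA"]),
            Reaction("synthB", "synthesis", products={"B": 1}, parameters=["ksynthB"]),
            Reaction("degB", "decay", substrates={"B": 1}, parameters=["kdegB"]),
            Reaction("inhibA", "mass_action", substrates={"A": 1},
                     modifiers=[("B", 1)], parameters=["kiB"],
                     note="B removes A, bimolecular"),
            Reaction("inhibB", "mass_action", substrates={"B": 1},
                     modifiers=[("A", 1)], parameters=["kiA"],
                     note="A removes B, bimolecular"),
        ],
        provenance={"kinetics": "mass action throughout"},
    )
    params = ParameterSet(
        {"ksynthA": ksynthA, "kdegA": kdegA, "ksynthB": ksynthB,
         "kdegB": kdegB, "kiA": kiA, "kiB": kiB},
        provenance="two-node motif constants",
    )
    return model, params


def _initial_reactions() -> list[Reaction]:
    R = Reaction
    return [
        # RhoA module
        R("r01", "synthesis", products={"RhoA_GDP": 1}, parameters=["k1"],
          note="RhoA expression into the inactive pool"),
        R("r02", "decay", substrates={"RhoA_GDP": 1}, parameters=["kdeg1"]),
        R("r03", "mass_action", substrates={"RhoA_GDP": 1},
          products={"RhoA_GTP": 1}, modifiers=[("HGF", 1)], parameters=["k2"],
          note="HGF-stimulated GEF-mediated activation"),
        R("r04", "mass_action", substrates={"RhoA_GTP": 1},
          products={"RhoA_GDP": 1}, parameters=["k3"],
          note="intrinsic GTP hydrolysis"),
        R("r05", "mass_action", substrates={"RhoA_GTP": 1},
          products={"RhoA_pS188": 1}, modifiers=[("PKG", 1)], parameters=["k4"],
          note="PKG phosphorylates RhoA at Ser188 (NO arm antagonises RhoA)"),
        R("r06", "mass_action", substrates={"RhoA_pS188": 1},
          products={"RhoA_GDP": 1}, parameters=["k5"],
          note="Ser188 dephosphorylation returns RhoA to the inactive pool"),
        R("r07", "decay", substrates={"RhoA_pS188": 1}, parameters=["kdeg2"]),
        # ROCK
        R("r08", "synthesis", products={"ROCK": 1},
          modifiers=[("RhoA_GTP", 1)], parameters=["k12"],
          note="ROCK activation proportional to active RhoA"),
        R("r09", "decay", substrates={"ROCK": 1}, parameters=["kdeg4"]),
        # Akt
        R("r10", "synthesis", products={"pAkt": 1}, modifiers=[("HGF", 1)],
          parameters=["k6"], note="HGF-driven Akt phosphorylation"),
        R("r11", "decay", substrates={"pAkt": 1}, parameters=["kdeg3"]),
        R("r12", "mass_action", substrates={"pAkt": 1},
          modifiers=[("ROCK", 1)], parameters=["ki1"],
          note="ROCK inhibition of Akt phosphorylation (antagonism arm 1)"),
        # eNOS expression
        R("r13", "synthesis", products={"eNOS_mRNA": 1}, parameters=["k7"]),
        R("r14", "decay", substrates={"eNOS_mRNA": 1}, parameters=["kdeg5"]),
        R("r15", "mass_action", substrates={"eNOS_mRNA": 1},
          modifiers=[("RhoA_GTP", 1)], parameters=["ki2"],
          note="RhoA destabilises eNOS mRNA (antagonism arm 2)"),
        R("r16", "synthesis", products={"eNOS": 1},
          modifiers=[("eNOS_mRNA", 1)], parameters=["k8"], note="translation"),
        R("r17", "decay", substrates={"eNOS": 1}, parameters=["kdeg6"]),
        # eNOS activation
        R("r18", "mass_action", substrates={"eNOS": 1}, products={"peNOS": 1},
          modifiers=[("pAkt", 1)], parameters=["k9"],
          note="Akt phosphorylates eNOS at S1177"),
        R("r19", "mass_action", substrates={"peNOS": 1}, products={"eNOS": 1},
          parameters=["k10"]),
        R("r20", "decay", substrates={"peNOS": 1}, parameters=["kdeg7"]),
        # NO / cGMP / PKG
        R("r21", "synthesis", products={"NO": 1}, modifiers=[("peNOS", 1)],
          parameters=["k11"], note="NO synthesis by active eNOS"),
        R("r22", "synthesis", products={"NO": 1}, modifiers=[("eNOS", 1)],
          parameters=["k13"], note="basal NO synthesis"),
        R("r23", "decay", substrates={"NO": 1}, parameters=["kdeg8"]),
        R("r24", "synthesis", products={"cGMP": 1}, modifiers=[("NO", 1)],
          parameters=["k14"], note="soluble guanylyl cyclase"),
        R("r25", "decay", substrates={"cGMP": 1}, parameters=["kdeg9"]),
        R("r26", "hill", products={"PKG": 1}, modifiers=[("cGMP", 1)],
          parameters=["k15", "Kmcgmp", "ncgmp"],
          note="ultrasensitive PKG activation by cGMP"),
        R("r27", "decay", substrates={"PKG": 1}, parameters=["kdeg10"]),
        R("r28", "mass_action", substrates={"cGMP": 1}, modifiers=[("PKG", 1)],
          parameters=["kpde"], note="PKG-stimulated PDE5 negative feedback"),
        # basal fluxes
        R("r29", "synthesis", products={"pAkt": 1}, parameters=["kb1"],
          note="basal Akt phosphorylation"),
        R("r30", "mass_action", substrates={"RhoA_GDP": 1},
          products={"RhoA_GTP": 1}, parameters=["kb2"],
          note="basal RhoA activation"),
        R("r31", "mass_action", substrates={"NO": 2}, parameters=["kox"],
          note="second-order NO autoxidation"),
    ]


def _tension_reactions() -> list[Reaction]:
    R = Reaction
    return [
        R("r32", "synthesis", products={"Tension": 1},
          modifiers=[("ROCK", 1)], parameters=["k16"],
          note="ROCK-driven actomyosin tension generation"),
        R("r33", "mass_action", substrates={"RhoA_GDP": 1},
          products={"RhoA_GTP": 1}, modifiers=[("Tension", 1)],
          parameters=["k17"],
          note="tension activates RhoA: mechanical positive feedback"),
        R("r34", "mass_action", substrates={"Tension": 1},
          modifiers=[("cGMP", 1)], parameters=["k18"],
          note="NO/cGMP arm dissipates tension"),
        R("r35", "decay", substrates={"Tension": 1}, parameters=["kdeg11"],
          note="basal viscoelastic relaxation"),
    ]


def _species(names: list[str]) -> list[SpeciesState]:
    roles = {
        "RhoA_GDP": "small GTPase, inactive pool",
        "RhoA_GTP": "small GTPase, active",
        "RhoA_pS188": "Ser188-phosphorylated RhoA (inactivated)",
        "ROCK": "Rho-associated kinase, active",
        "pAkt": "phosphorylated Akt",
        "eNOS_mRNA": "eNOS transcript",
        "eNOS": "eNOS protein, unphosphorylated",
        "peNOS": "S1177-phosphorylated eNOS (active)",
        "NO": "nitric oxide, second messenger",
        "cGMP": "cyclic GMP, second messenger",
        "PKG": "protein kinase G, active",
        "Tension": "cytoskeletal tension, mechanical surrogate",
    }
    return [SpeciesState(n, role=roles[n]) for n in names]


def build_initial_model() -> tuple[ModelDefinition, ParameterSet]:
    """Biochemical RhoA-NO mutual-antagonism network: 31 reactions, 11 ODEs."""
    model = ModelDefinition(
        name="initial",
        species=_species(INITIAL_SPECIES),
        reactions=_initial_reactions(),
        inputs={"HGF": HGF_INPUT},
        provenance={
            "status": "synthetic reconstruction, calibrated to the published "
                      "qualitative regime",
            "kinetics": "mass action; Hill activation of PKG by cGMP",
        },
    )
    params = ParameterSet(dict(INITIAL_BASELINE),
                          provenance="reconstructed baseline")
    return model, params


def build_extended_model() -> tuple[ModelDefinition, ParameterSet]:
    """Tension-extended network: 35 reactions, 12 ODEs, 36 perturbable parameters."""
    model = ModelDefinition(
        name="extended",
        species=_species(EXTENDED_SPECIES),
        reactions=_initial_reactions() + _tension_reactions(),
        inputs={"HGF": HGF_INPUT},
        provenance={
            "status": "synthetic reconstruction, calibrated to the published "
                      "qualitative regime",
            "kinetics": "mass action; Hill activation of PKG by cGMP; "
                        "tension treated as a network species",
        },
    )
    params = ParameterSet(dict(INITIAL_BASELINE) | dict(TENSION_BASELINE),
                          provenance="reconstructed baseline")
    return model, params


def perturbable_parameters(params: ParameterSet) -> list[str]:
    """Rate constants subject to single-parameter robustness analysis.

    All named constants except structural ones (the Hill cooperativity
    ``ncgmp``), giving 32 perturbable parameters for the initial model and
    36 for the tension-extended model.
    """
    return [n for n in params.names() if n not in STRUCTURAL_PARAMETERS]
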