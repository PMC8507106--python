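"""Reaction-network representation and ODE assembly.

A model is a list of species plus a list of typed reactions (zeroth-order
synthesis, first-order decay, mass action, Michaelis-Menten, Hill).  The
:func:`assemble` operation compiles a model together with a parameter set
into a :class:`RateField` — a fast vectorised right-hand side plus a
finite-difference Jacobian — suitable for stiff integration, Newton
refinement and continuation.

Conventions
-----------
* Concentrations are in nM; time is in model time units (the underlying
  study is qualitative and fixes no physical time scale).
* Clamped inputs (e.g. a constant growth-factor stimulus) live in
  ``ModelDefinition.inputs`` and never become state variables; reactions may
  reference them as modifiers, and their values are folded into the rate
  coefficients at assembly time.
* Activator modifiers multiply the rate mass-action style; inhibitor
  modifiers contribute a divisive factor K/(K + [X]) with their own
  half-inhibition constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpeciesState",
    "Reaction",
    "ModelDefinition",
    "ParameterSet",
    "RateField",
    "ModelAssemblyError",
    "assemble",
    "count_reactions",
    "model_to_json",
    "model_from_json",
]

#: rate-law kinds understood by the assembler
RATE_LAW_KINDS = ("synthesis", "decay", "mass_action", "michaelis_menten", "hill")


class ModelAssemblyError(ValueError):
    """Raised when a model fails validation or assembly."""


@dataclass
class SpeciesState:
    """One chemical (or mechanical surrogate) state variable.

    Parameters
    ----------
    name : str
        Unique identifier within the model.
    concentration : float
        Default initial concentration, nM.  Must be nonnegative.
    role : str
        Free annotation (enzyme, second messenger, mechanical surrogate, ...).
    """

    name: str
    concentration: float = 0.0
    role: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ModelAssemblyError(
                f"species {self.name!r}: negative initial concentration"
            )


@dataclass
class Reaction:
    """A single typed reaction.

    ``substrates`` / ``products`` map species names to integer
    stoichiometries.  ``modifiers`` is a list of ``(name, sign)`` pairs with
    sign +1 (activator, multiplies the rate) or -1 (inhibitor, divisive
    K/(K+[X]) factor).  ``parameters`` lists parameter names in kind-specific
    order:

    * synthesis / decay / mass_action: ``[k]`` then one half-inhibition
      constant per inhibitor modifier;
    * michaelis_menten: ``[kcat, Km]`` (+ inhibitor constants);
    * hill: ``[k, K_half, n_hill]`` — the regulator is the first activator
      modifier if present, otherwise the sole substrate.
    """

    id: str
    kind: str
    substrates: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    modifiers: list[tuple[str, int]] = field(default_factory=list)
    parameters: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise ModelAssemblyError(
                f"reaction {self.id!r}: unknown rate-law kind {self.kind!r}"
            )
        n_inhib = sum(1 for _, s in self.modifiers if s < 0)
        base = {"synthesis": 1, "decay": 1, "mass_action": 1,
                "michaelis_menten": 2, "hill": 3}[self.kind]
        if len(self.parameters) != base + n_inhib:
            raise ModelAssemblyError(
                f"reaction {self.id!r} ({self.kind}): expected "
                f"{base + n_inhib} parameter names, got {len(self.parameters)}"
            )
        if self.kind == "decay" and len(self.substrates) != 1:
            raise ModelAssemblyError(
                f"reaction {self.id!r}: first-order decay needs one substrate"
            )
        if self.kind == "michaelis_menten" and len(self.substrates) != 1:
            raise ModelAssemblyError(
                f"reaction {self.id!r}: Michaelis-Menten needs one substrate"
            )
        if self.kind == "hill":
            has_act = any(s > 0 for _, s in self.modifiers)
            if not has_act and len(self.substrates) != 1:
                raise ModelAssemblyError(
                    f"reaction {self.id!r}: Hill needs a regulator "
                    "(activator modifier or single substrate)"
                )


@dataclass
class ModelDefinition:
    """Species + reactions + clamped inputs; the unit of serialization."""

    name: str
    species: list[SpeciesState]
    reactions: list[Reaction]
    inputs: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelAssemblyError(f"duplicate species names: {dup}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def state_species(self) -> list[str]:
        """Names of species that become ODE state variables (not clamped)."""
        return [s.name for s in self.species if s.name not in self.inputs]


@dataclass
class ParameterSet:
    """Named rate constants with units and provenance.

    Values must be nonnegative; zero is allowed only to switch a term off
    (e.g. decoupling the two-node motif).  Perturbation always requires a
    strictly positive result.
    """

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ModelAssemblyError(f"parameter {k!r}: invalid value {v!r}")

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.units), self.provenance)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def names(self) -> list[str]:
        return list(self.values)


@dataclass
class RateField:
    """Assembled ODE right-hand side.

    ``evaluator(t, x) -> dx/dt`` and ``jacobian(x) -> (dim, dim)`` matrix
    (central finite differences of the evaluator).
    """

    dimension: int
    evaluator: Callable[[float, np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    species_names: list[str] = field(default_factory=list)

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.evaluator(t, x)


# ---------------------------------------------------------------------------
# assembly


def _resolve(name: str, idx: dict[str, int], inputs: dict[str, float],
             rid: str) -> tuple[int | None, float]:
    """Return (state index, 1.0) or (None, clamped value) for a name."""
    if name in idx:
        return idx[name], 1.0
    if name in inputs:
        return None, float(inputs[name])
    raise ModelAssemblyError(f"reaction {rid!r}: unknown species {name!r}")


def assemble(model: ModelDefinition, params: ParameterSet) -> RateField:
    """Compile a model + parameter set into an evaluable rate field.

    Each reaction contributes ``rate * (products - substrates)`` to the
    state derivative.  Power-law parts (mass action, substrates, activator
    modifiers) are evaluated via a precomputed exponent matrix; saturating
    parts (Michaelis-Menten, Hill, inhibitor factors) are applied on top.

    Raises
    ------
    ModelAssemblyError
        On an unresolved parameter name ("missing parameter"), an unknown
        species reference, or a species/parameter name collision.
    """
    state_names = model.state_species()
    idx = {n: i for i, n in enumerate(state_names)}
    dim = len(state_names)

    collide = set(model.species_names) & set(params.values)
    if collide:
        raise ModelAssemblyError(
            f"species/parameter name collision: {sorted(collide)}"
        )

    n_r = len(model.reactions)
    coef = np.zeros(n_r)
    expo = np.zeros((n_r, dim))
    stoich = np.zeros((dim, n_r))
    # saturating extras: list of (reaction index, callable(x) -> factor)
    sat_terms: list[tuple[int, Callable[[np.ndarray], float]]] = []

    for r_i, rxn in enumerate(model.reactions):
        for pname in rxn.parameters:
            if pname not in params:
                raise ModelAssemblyError(
                    f"missing parameter {pname!r} (reaction {rxn.id!r})"
                )
        p_iter = iter(rxn.parameters)
        k = params[next(p_iter)]
        c = k
        hill_reg: str | None = None  # regulator consumed by the Hill factor

        # stoichiometry
        for name, st in rxn.substrates.items():
            j, _ = _resolve(name, idx, model.inputs, rxn.id)
            if j is not None:
                stoich[j, r_i] -= st
        for name, st in rxn.products.items():
            j, _ = _resolve(name, idx, model.inputs, rxn.id)
            if j is not None:
                stoich[j, r_i] += st

        # power-law factors: substrates (except MM substrate) + activators
        if rxn.kind in ("decay", "mass_action"):
            for name, st in rxn.substrates.items():
                j, v = _resolve(name, idx, model.inputs, rxn.id)
                if j is None:
                    c *= v ** st
                else:
                    expo[r_i, j] += st
        elif rxn.kind == "michaelis_menten":
            (sname, _), = rxn.substrates.items()
            sj, sval = _resolve(sname, idx, model.inputs, rxn.id)
            Km = params[next(p_iter)]
            if sj is None:
                c *= sval / (Km + sval)
            else:
                sat_terms.append(
                    (r_i, lambda x, j=sj, K=Km: max(x[j], 0.0) / (K + max(x[j], 0.0)))
                )
        elif rxn.kind == "hill":
            Kh = params[next(p_iter)]
            nh = params[next(p_iter)]
            acts = [n for n, s in rxn.modifiers if s > 0]
            reg = acts[0] if acts else next(iter(rxn.substrates))
            if acts:
                hill_reg = reg
            rj, rval = _resolve(reg, idx, model.inputs, rxn.id)
            if rj is None:
                c *= rval ** nh / (Kh ** nh + rval ** nh)
            else:
                def _hill(x, j=rj, K=Kh, n=nh):
                    v = max(x[j], 0.0)
                    return v ** n / (K ** n + v ** n) if v > 0 else 0.0
                sat_terms.append((r_i, _hill))
        # synthesis: no substrate factor

        # modifiers
        for name, sign in rxn.modifiers:
            if sign > 0 and name == hill_reg:
                hill_reg = None  # already consumed by the Hill factor
                continue
            j, v = _resolve(name, idx, model.inputs, rxn.id)
            if sign > 0:
                if j is None:
                    c *= v
                else:
                    expo[r_i, j] += 1
            else:
                Ki = params[next(p_iter)]
                if j is None:
                    c *= Ki / (Ki + v)
                else:
                    sat_terms.append(
                        (r_i, lambda x, jj=j, K=Ki: K / (K + max(x[jj], 0.0)))
                    )
        coef[r_i] = c

    def evaluator(t: float, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # x**e with integral exponents; negative transients are admissible
        rates = coef * np.prod(np.power(x[None, :], expo), axis=1)
        for r_i, f in sat_terms:
            rates[r_i] *= f(x)
        return stoich @ rates

    def jacobian(x: np.ndarray) -> np.ndarray:
        return finite_difference_jacobian(evaluator, x)

    return RateField(dimension=dim, evaluator=evaluator, jacobian=jacobian,
                     species_names=state_names)


def finite_difference_jacobian(
    f: Callable[[float, np.ndarray], np.ndarray],
    x: np.ndarray,
    rel_step: float = 3e-7,
) -> np.ndarray:
    """Central-difference Jacobian of ``f(t=0, x)`` with per-component steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (f(0.0, xp) - f(0.0, xm)) / (2 * h)
    return J


def count_reactions(model: ModelDefinition) -> int:
    """Number of reaction records in the model."""
    return len(model.reactions)


# ---------------------------------------------------------------------------
# serialization (JSON dialect; round-trips losslessly)


def model_to_json(model: ModelDefinition, params: ParameterSet | None = None) -> str:
    doc = {
        "name": model.name,
        "species": [asdict(s) for s in model.species],
        "reactions": [
            {
                "id": r.id, "kind": r.kind, "substrates": r.substrates,
                "products": r.products,
                "modifiers": [[n, s] for n, s in r.modifiers],
                "parameters": r.parameters, "note": r.note,
            }
            for r in model.reactions
        ],
        "inputs": model.inputs,
        "provenance": model.provenance,
    }
    if params is not None:
        doc["parameter_values"] = params.values
        doc["parameter_units"] = params.units
        doc["parameter_provenance"] = params.provenance
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> tuple[ModelDefinition, ParameterSet | None]:
    doc = json.loads(text)
    model = ModelDefinition(
        name=doc["name"],
        species=[SpeciesState(**s) for s in doc["species"]],
        reactions=[
            Reaction(
                id=r["id"], kind=r["kind"],
                substrates={k: int(v) for k, v in r["substrates"].items()},
                products={k: int(v) for k, v in r["products"].items()},
                modifiers=[(n, int(s)) for n, s in r["modifiers"]],
                parameters=list(r["parameters"]), note=r.get("note", ""),
            )
            for r in doc["reactions"]
        ],
        inputs={k: float(v) for k, v in doc["inputs"].items()},
        provenance=dict(doc.get("provenance", {})),
    )
    params = None
    if "parameter_values" in doc:
        params = ParameterSet(
            {k: float(v) for k, v in doc["parameter_values"].items()},
            dict(doc.get("parameter_units", {})),
            doc.get("parameter_provenance", ""),
        )
    return model, params
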