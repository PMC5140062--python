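"""Reaction-network models at two tiers of mechanistic realism.

A :class:`ReactionNetwork` holds species, reactions and rate parameters and
can be written at the *approximate* tier (Michaelis-Menten rate laws, each
enzymatic conversion summarized by ``k_cat`` and ``K_M``) or at the
*mechanistic* tier (elementary mass-action steps ``E + S <-> ES -> E + P``
with ``k_f``, ``k_r``, ``k_cat``).  :func:`expand_to_mass_action` converts the
former into the latter, introducing one enzyme-substrate complex species and
one extra rate constant per converted reaction; the two tiers are linked by
the Michaelis constant ``K_M = (k_r + k_cat) / k_f``.

The module also houses the six-parameter DNA-repair kinetics that combine the
lethal/potentially-lethal (LPL) and repair-saturation (RS) models of
post-irradiation lesion processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "DNARepairModel",
    "NetworkStructureError",
    "expand_to_mass_action",
    "mm_validity_ratio",
    "dna_repair_rhs",
    "lpl_rhs",
    "rs_rhs",
    "load_network",
    "michaelis_constant",
]

MICHAELIS_MENTEN = "michaelis_menten"
MASS_ACTION_ENZYMATIC = "mass_action_enzymatic"
MASS_ACTION_ELEMENTARY = "mass_action_elementary"

_KINDS = (MICHAELIS_MENTEN, MASS_ACTION_ENZYMATIC, MASS_ACTION_ELEMENTARY)


class NetworkStructureError(ValueError):
    """A reaction references an undeclared species or is otherwise malformed."""


@dataclass(frozen=True)
class Species:
    name: str
    initial: float = 0.0

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise ValueError(f"initial concentration of {self.name!r} is negative")


@dataclass(frozen=True)
class Reaction:
    """One reaction; rate constants are referenced by *parameter name*.

    ``substrates`` / ``products`` are ``(species, stoichiometry)`` pairs.
    For ``michaelis_menten`` the rate law is
    ``v = k_cat * [E] * [S] / (K_M + [S])`` with a single substrate.
    ``mass_action_enzymatic`` bundles the three elementary steps of the
    enzyme mechanism and names the complex species via ``complex_species``.
    ``mass_action_elementary`` is plain mass action
    ``v = k * prod [X_i]^s_i``.
    """

    name: str
    kind: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    enzyme: str | None = None
    complex_species: str | None = None
    # parameter-name slots; which are used depends on `kind`
    k_cat: str | None = None
    K_M: str | None = None
    k_f: str | None = None
    k_r: str | None = None
    k: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise NetworkStructureError(f"unknown reaction kind {self.kind!r}")
        if self.kind == MICHAELIS_MENTEN:
            if self.enzyme is None:
                raise NetworkStructureError(
                    f"Michaelis-Menten reaction {self.name!r} has no enzyme species"
                )
            if self.k_cat is None or self.K_M is None:
                raise NetworkStructureError(
                    f"reaction {self.name!r} needs k_cat and K_M parameter names"
                )
            if len(self.substrates) != 1:
                raise NetworkStructureError(
                    f"MM reaction {self.name!r} must have exactly one substrate"
                )
        elif self.kind == MASS_ACTION_ENZYMATIC:
            missing = [s for s in ("k_f", "k_r", "k_cat") if getattr(self, s) is None]
            if missing:
                raise NetworkStructureError(
                    f"reaction {self.name!r} lacks parameter slots {missing}"
                )
            if self.enzyme is None or self.complex_species is None:
                raise NetworkStructureError(
                    f"enzymatic mass-action reaction {self.name!r} needs enzyme "
                    "and complex_species"
                )
        elif self.kind == MASS_ACTION_ELEMENTARY and self.k is None:
            raise NetworkStructureError(f"reaction {self.name!r} needs a rate constant k")

    def referenced_species(self) -> set[str]:
        out = {s for s, _ in self.substrates} | {s for s, _ in self.products}
        if self.enzyme:
            out.add(self.enzyme)
        if self.complex_species:
            out.add(self.complex_species)
        return out

    def parameter_names(self) -> tuple[str, ...]:
        if self.kind == MICHAELIS_MENTEN:
            return (self.k_cat, self.K_M)
        if self.kind == MASS_ACTION_ENZYMATIC:
            return (self.k_f, self.k_r, self.k_cat)
        return (self.k,)


def michaelis_constant(k_f: float, k_r: float, k_cat: float) -> float:
    """Michaelis constant of the two-step enzyme mechanism, (k_r + k_cat)/k_f."""
    return (k_r + k_cat) / k_f


def mm_validity_ratio(E: float, S: float, K_M: float) -> float:
    """Validity ratio [E]/([S] + K_M) of the Michaelis-Menten reduction.

    Values much smaller than one indicate the reduction is locally valid;
    note this is a single-reaction condition and need not guarantee accuracy
    in a network context.
    """
    if E < 0:
        raise ValueError("enzyme concentration must be nonnegative")
    denom = S + K_M
    if denom <= 0:
        raise ZeroDivisionError("S + K_M must be positive")
    return E / denom


@dataclass
class ReactionNetwork:
    """Species, reactions and positive rate parameters of one kinetic model.

    ``parameters`` maps parameter name to value (strictly positive; fitting
    works on the natural-log scale).  ``observables`` maps an observable name
    to a linear combination of species, ``{species: coefficient}``; when
    empty, every species is its own observable.
    """

    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, float]
    observables: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        declared = {s.name for s in self.species}
        if len(declared) != len(self.species):
            raise NetworkStructureError("duplicate species names")
        for rxn in self.reactions:
            undeclared = rxn.referenced_species() - declared
            if undeclared:
                raise NetworkStructureError(
                    f"reaction {rxn.name!r} references undeclared species {sorted(undeclared)}"
                )
            for pname in rxn.parameter_names():
                if pname not in self.parameters:
                    raise NetworkStructureError(
                        f"reaction {rxn.name!r} references undeclared parameter {pname!r}"
                    )
        for pname, value in self.parameters.items():
            if not value > 0:
                raise NetworkStructureError(f"parameter {pname!r} must be positive, got {value}")
        for oname, combo in self.observables.items():
            bad = set(combo) - declared
            if bad:
                raise NetworkStructureError(
                    f"observable {oname!r} references undeclared species {sorted(bad)}"
                )

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.parameters)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def parameter_vector(self) -> np.ndarray:
        return np.array([self.parameters[p] for p in self.parameters], dtype=float)

    def log_parameter_vector(self) -> np.ndarray:
        return np.log(self.parameter_vector())

    def with_parameters(self, values) -> "ReactionNetwork":
        """Copy of the network with a new parameter vector (natural scale)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_parameters,):
            raise ValueError("parameter vector length mismatch")
        params = dict(zip(self.parameters, values.tolist()))
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=params,
            observables={k: dict(v) for k, v in self.observables.items()},
        )

    def observable_map(self) -> dict[str, dict[str, float]]:
        if self.observables:
            return self.observables
        return {s.name: {s.name: 1.0} for s in self.species}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    # -- kinetics ----------------------------------------------------------
    def _elementary_terms(self):
        """Flatten reactions into (param_name, reactant stoich dict, net stoich dict)
        triples, one per elementary flux, MM rate laws kept intact.

        Returns a list of ('mm', rxn) or ('elem', pname, reactants, net).
        """
        terms = []
        for rxn in self.reactions:
            if rxn.kind == MICHAELIS_MENTEN:
                terms.append(("mm", rxn))
            elif rxn.kind == MASS_ACTION_ELEMENTARY:
                reactants = {}
                net = {}
                for s, n in rxn.substrates:
                    reactants[s] = reactants.get(s, 0) + n
                    net[s] = net.get(s, 0) - n
                for s, n in rxn.products:
                    net[s] = net.get(s, 0) + n
                terms.append(("elem", rxn.k, reactants, net))
            else:  # enzymatic mass action: three elementary steps
                (sub, _), = rxn.substrates
                E, ES = rxn.enzyme, rxn.complex_species
                terms.append(("elem", rxn.k_f, {E: 1, sub: 1}, {E: -1, sub: -1, ES: +1}))
                terms.append(("elem", rxn.k_r, {ES: 1}, {ES: -1, E: +1, sub: +1}))
                net_cat = {ES: -1, E: +1}
                for s, n in rxn.products:
                    net_cat[s] = net_cat.get(s, 0) + n
                terms.append(("elem", rxn.k_cat, {ES: 1}, net_cat))
        return terms

    def compile(self):
        """Compile the network into RHS and analytic Jacobian callables.

        Returns ``(rhs, jac_y, jac_p)`` each taking ``(t, y, p)`` with ``p``
        the parameter vector on the *natural* scale in declaration order.
        ``jac_p`` is d(rhs)/d(p) (natural scale); log-scale sensitivities are
        obtained downstream by the chain rule.
        """
        sidx = {s.name: i for i, s in enumerate(self.species)}
        pidx = {p: i for i, p in enumerate(self.parameters)}
        n_s, n_p = len(sidx), len(pidx)
        terms = self._elementary_terms()

        prepared = []
        for term in terms:
            if term[0] == "mm":
                rxn = term[1]
                (sub, sub_sto), = rxn.substrates
                net = {sub: -sub_sto}
                for s, n in rxn.products:
                    net[s] = net.get(s, 0) + n
                prepared.append((
                    "mm",
                    sidx[rxn.enzyme],
                    sidx[sub],
                    pidx[rxn.k_cat],
                    pidx[rxn.K_M],
                    [(sidx[s], float(n)) for s, n in net.items()],
                ))
            else:
                _, pname, reactants, net = term
                prepared.append((
                    "elem",
                    pidx[pname],
                    [(sidx[s], n) for s, n in reactants.items()],
                    [(sidx[s], float(n)) for s, n in net.items()],
                ))

        def rhs(t, y, p):
            dy = np.zeros(n_s)
            for term in prepared:
                if term[0] == "mm":
                    _, iE, iS, ikcat, iKM, net = term
                    v = p[ikcat] * y[iE] * y[iS] / (p[iKM] + y[iS])
                else:
                    _, ik, reactants, net = term
                    v = p[ik]
                    for i, n in reactants:
                        v *= y[i] ** n
                for i, c in net:
                    dy[i] += c * v
            return dy

        def jac_y(t, y, p):
            J = np.zeros((n_s, n_s))
            for term in prepared:
                if term[0] == "mm":
                    _, iE, iS, ikcat, iKM, net = term
                    den = p[iKM] + y[iS]
                    dv = {iE: p[ikcat] * y[iS] / den,
                          iS: p[ikcat] * y[iE] * p[iKM] / den**2}
                    # enzyme == substrate is structurally possible; merge
                    if iE == iS:
                        dv = {iE: p[ikcat] * (2 * y[iE] * den - y[iE] ** 2) / den**2}
                else:
                    _, ik, reactants, net = term
                    dv = {}
                    for j, nj in reactants:
                        g = p[ik] * nj
                        for i, n in reactants:
                            g *= y[i] ** (n - 1 if i == j else n)
                        dv[j] = dv.get(j, 0.0) + g
                for i, c in net:
                    for j, g in dv.items():
                        J[i, j] += c * g
            return J

        def jac_p(t, y, p):
            J = np.zeros((n_s, n_p))
            for term in prepared:
                if term[0] == "mm":
                    _, iE, iS, ikcat, iKM, net = term
                    den = p[iKM] + y[iS]
                    v = p[ikcat] * y[iE] * y[iS] / den
                    dv = {ikcat: v / p[ikcat], iKM: -v / den}
                else:
                    _, ik, reactants, net = term
                    v = 1.0
                    for i, n in reactants:
                        v *= y[i] ** n
                    dv = {ik: v}
                for i, c in net:
                    for j, g in dv.items():
                        J[i, j] += c * g
            return J

        return rhs, jac_y, jac_p

    def enzyme_conservation_pairs(self) -> list[tuple[str, str]]:
        """(enzyme, complex) pairs whose summed concentration is conserved.

        Only enzymes that appear in a single enzymatic reaction and nowhere
        else are reported.
        """
        pairs = []
        for rxn in self.reactions:
            if rxn.kind != MASS_ACTION_ENZYMATIC:
                continue
            others = [r for r in self.reactions if r is not rxn]
            if all(rxn.enzyme not in r.referenced_species() for r in others):
                pairs.append((rxn.enzyme, rxn.complex_species))
        return pairs


def expand_to_mass_action(
    net: ReactionNetwork, km_split: float = 0.5
) -> tuple[ReactionNetwork, dict[str, dict[str, str]]]:
    """Replace every Michaelis-Menten reaction by its mass-action mechanism.

    Each MM reaction gains an enzyme-substrate complex species (initialized at
    zero — the complex does not pre-exist) and trades its two constants
    (k_cat, K_M) for three (k_f, k_r, k_cat), a net gain of one parameter per
    reaction.  The default back-mapping fixes the expansion's one free choice
    by putting a fraction ``km_split`` of K_M into the unbinding pathway:
    ``k_r = km_split * K_M * k_f`` and ``k_f = k_cat / ((1 - km_split) * K_M)``
    so that ``(k_r + k_cat)/k_f == K_M`` holds exactly.

    Returns the expanded network and a per-reaction mapping record
    ``{reaction: {"k_f": name, "k_r": name, "k_cat": name,
    "old_k_cat": name, "old_K_M": name}}``.
    """
    if not 0 < km_split < 1:
        raise ValueError("km_split must lie strictly between 0 and 1")
    species = list(net.species)
    declared = {s.name for s in species}
    reactions: list[Reaction] = []
    params = dict(net.parameters)
    mapping: dict[str, dict[str, str]] = {}

    for rxn in net.reactions:
        if rxn.kind != MICHAELIS_MENTEN:
            reactions.append(rxn)
            continue
        if rxn.enzyme is None:  # pragma: no cover - blocked at Reaction level
            raise NetworkStructureError(
                f"MM reaction {rxn.name!r} has no enzyme species; cannot expand"
            )
        es_name = f"{rxn.enzyme}_{rxn.substrates[0][0]}_complex"
        while es_name in declared:
            es_name += "_"
        declared.add(es_name)
        species.append(Species(es_name, 0.0))

        kcat_val = params.pop(rxn.k_cat)
        km_val = params.pop(rxn.K_M)
        kf_name, kr_name = f"{rxn.name}_k_f", f"{rxn.name}_k_r"
        kcat_name = f"{rxn.name}_k_cat"
        k_f = kcat_val / ((1.0 - km_split) * km_val)
        k_r = km_split * km_val * k_f
        params[kf_name] = k_f
        params[kr_name] = k_r
        params[kcat_name] = kcat_val

        reactions.append(Reaction(
            name=rxn.name,
            kind=MASS_ACTION_ENZYMATIC,
            substrates=rxn.substrates,
            products=rxn.products,
            enzyme=rxn.enzyme,
            complex_species=es_name,
            k_f=kf_name,
            k_r=kr_name,
            k_cat=kcat_name,
        ))
        mapping[rxn.name] = {
            "k_f": kf_name, "k_r": kr_name, "k_cat": kcat_name,
            "old_k_cat": rxn.k_cat, "old_K_M": rxn.K_M,
        }

    expanded = ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=params,
        observables={k: dict(v) for k, v in net.observables.items()},
    )
    return expanded, mapping


# ---------------------------------------------------------------------------
# DNA-repair kinetics (LPL + RS composite)
# ---------------------------------------------------------------------------

DNA_PARAM_NAMES = ("delta1", "delta2", "lambda1", "lambda2", "lambda3", "epsilon")


@dataclass(frozen=True)
class DNARepairModel:
    """Composite lesion-kinetics model combining LPL and RS mechanisms.

    State: u(t) repairable (potentially lethal) lesions, v(t) non-repairable
    (lethal) lesions.  Parameters (all nonnegative):

    - delta1, delta2: lesion induction rates per unit dose (1/Gy) for the
      repairable and lethal pools;
    - lambda1: first-order repair rate (1/h), saturable via epsilon;
    - lambda2: fixation rate (1/h) converting repairable to lethal lesions;
    - lambda3: binary-misrepair rate (1/(lesion h));
    - epsilon: repair-saturation parameter (1/lesion).

    delta2 = lambda2 = epsilon = 0 recovers the LPL model;
    delta2 = lambda3 = 0 recovers the RS model.
    """

    delta1: float
    delta2: float
    lambda1: float
    lambda2: float
    lambda3: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in DNA_PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_vector(cls, p) -> "DNARepairModel":
        return cls(*(float(x) for x in p))

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DNA_PARAM_NAMES], dtype=float)

    def is_lpl(self) -> bool:
        return self.delta2 == self.lambda2 == self.epsilon == 0

    def is_rs(self) -> bool:
        return self.delta2 == self.lambda3 == 0

    def reduce(self, which: str) -> "DNARepairModel":
        """Exact reduction to the named sub-model ('lpl' or 'rs')."""
        if which == "lpl":
            return replace(self, delta2=0.0, lambda2=0.0, epsilon=0.0)
        if which == "rs":
            return replace(self, delta2=0.0, lambda3=0.0)
        raise ValueError(f"unknown reduction {which!r}")


def dna_repair_rhs(state, t: float, dose_rate: float, model: DNARepairModel):
    """Time derivatives (du/dt, dv/dt) of the composite lesion model.

    du/dt = delta1*r - lambda1*u/(1 + epsilon*u) - lambda2*u - lambda3*u^2
    dv/dt = delta2*r + lambda2*u + lambda3*u^2

    with r the (piecewise-constant) dose rate.
    """
    u, v = state
    if u < 0 or v < 0:
        raise ValueError("lesion counts must be nonnegative")
    if dose_rate < 0:
        raise ValueError("dose rate must be nonnegative")
    du = (model.delta1 * dose_rate
          - model.lambda1 * u / (1.0 + model.epsilon * u)
          - model.lambda2 * u
          - model.lambda3 * u * u)
    dv = model.delta2 * dose_rate + model.lambda2 * u + model.lambda3 * u * u
    return du, dv


def lpl_rhs(state, t, dose_rate, delta1, lambda1, lambda3):
    """Hand-coded LPL right-hand side (reference form for the reduction)."""
    u, v = state
    du = delta1 * dose_rate - lambda1 * u - lambda3 * u * u
    dv = lambda3 * u * u
    return du, dv


def rs_rhs(state, t, dose_rate, delta1, lambda1, lambda2, epsilon):
    """Hand-coded RS right-hand side (reference form for the reduction)."""
    u, v = state
    du = delta1 * dose_rate - lambda1 * u / (1.0 + epsilon * u) - lambda2 * u
    dv = lambda2 * u
    return du, dv


# ---------------------------------------------------------------------------
# Declarative config I/O
# ---------------------------------------------------------------------------

def load_network(source) -> ReactionNetwork:
    """Build a :class:`ReactionNetwork` from a YAML/JSON mapping or file path.

    Schema::

        species: {A: 1.0, E1: 0.1, ...}
        parameters: {kcat1: 2.0, KM1: 10.0, ...}
        reactions:
          - {name: r1, kind: michaelis_menten, enzyme: E1,
             substrates: [[A, 1]], products: [[B, 1]], k_cat: kcat1, K_M: KM1}
        observables: {B_total: {B: 1.0}}
    """
    if isinstance(source, (str,)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        cfg = source
    species = [Species(name, float(init)) for name, init in cfg["species"].items()]
    reactions = []
    for r in cfg.get("reactions", []):
        reactions.append(Reaction(
            name=r["name"],
            kind=r["kind"],
            substrates=tuple((s, int(n)) for s, n in r.get("substrates", [])),
            products=tuple((s, int(n)) for s, n in r.get("products", [])),
            enzyme=r.get("enzyme"),
            complex_species=r.get("complex_species"),
            k_cat=r.get("k_cat"),
            K_M=r.get("K_M"),
            k_f=r.get("k_f"),
            k_r=r.get("k_r"),
            k=r.get("k"),
        ))
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters={k: float(v) for k, v in cfg.get("parameters", {}).items()},
        observables={k: {s: float(c) for s, c in v.items()}
                     for k, v in (cfg.get("observables") or {}).items()},
    )
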