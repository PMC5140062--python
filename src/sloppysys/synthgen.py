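"""Synthetic data with the statistical structure the analysis assumes.

Data are generated as d_i = y_i(theta) + sigma_i xi_i + f_true sigma_i xi'_i
with independent standard-normal draws: ordinary measurement noise at a
fractional scale (default 10% of the signal) plus an optional true
discrepancy term used to validate the f estimator.  The module also builds
the two shipped truth-vs-approximation scenarios: a small enzyme cascade
whose mechanistic (mass-action) tier generates data fitted by its
Michaelis-Menten reduction, and the DNA-repair scenario in which the
six-parameter composite lesion model generates split-dose survival data
fitted by its RS reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import Dataset
from .networks import (
    MASS_ACTION_ENZYMATIC,
    MICHAELIS_MENTEN,
    DNARepairModel,
    Reaction,
    ReactionNetwork,
    Species,
    expand_to_mass_action,
    michaelis_constant,
    mm_validity_ratio,
)
from .simulate import DNARepairSimulator, ExperimentProtocol, NetworkModel, simulate

__all__ = [
    "generate_dataset",
    "choose_largeKM_parameters",
    "mm_reduction_error",
    "single_enzyme_pair",
    "cascade_network",
    "dna_baseline_protocols",
    "dna_expanded_protocols",
    "dna_candidate_grid",
    "default_dna_model",
    "Scenario",
    "build_discrepancy_scenario",
]

SIGMA_FLOOR_REL = 1e-6
NOISE_FRACTION_DEFAULT = 0.10


def _signal_scales(pred, noise_fraction: float, mode: str) -> np.ndarray:
    values = pred.values
    if mode == "per_point":
        return noise_fraction * np.abs(values)
    if mode == "per_observable_max":
        scales = np.empty_like(values)
        groups: dict[tuple[str, str], float] = {}
        for (exp, obs, _t), v in zip(pred.index, values):
            key = (exp, obs)
            groups[key] = max(groups.get(key, 0.0), abs(v))
        for i, (exp, obs, _t) in enumerate(pred.index):
            scales[i] = noise_fraction * groups[(exp, obs)]
        return scales
    if mode == "absolute":
        return np.full(values.shape, noise_fraction)
    raise ValueError(f"unknown sigma mode {mode!r}")


def generate_dataset(model, noise_fraction: float = NOISE_FRACTION_DEFAULT,
                     f_true: float = 0.0, seed: int = 0,
                     log_params=None, sigma_mode: str = "per_observable_max",
                     sigma_floor: bool = True) -> Dataset:
    """Simulate a predictor's protocols and add seeded noise.

    sigma_i = noise_fraction x signal scale; the default scale convention is
    the per-(experiment, observable) maximum of |y| over the trajectory
    ("per_observable_max"); "per_point" uses |y_i| itself and "absolute"
    uses noise_fraction directly.  A floor of 1e-6 x the overall signal scale
    guards silent observables (warned, disable via ``sigma_floor=False``).
    d_i = y_i + sigma_i xi_i + f_true sigma_i xi'_i.
    """
    if noise_fraction <= 0:
        raise ValueError("noise_fraction must be positive")
    if f_true < 0:
        raise ValueError("f_true must be nonnegative")
    pred = model.predict(log_params)
    sigmas = _signal_scales(pred, noise_fraction, sigma_mode)
    overall = np.abs(pred.values).max()
    floor = SIGMA_FLOOR_REL * max(overall, 1.0)
    if sigma_floor and np.any(sigmas < floor):
        import warnings
        if overall == 0.0:
            warnings.warn("all-zero trajectory; sigma floor applied", RuntimeWarning)
        sigmas = np.maximum(sigmas, floor)
    elif not sigma_floor and np.any(sigmas <= 0):
        raise ValueError("zero sigma with the floor disabled")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(pred.values.size)
    xi_prime = rng.standard_normal(pred.values.size)
    d = pred.values + sigmas * xi + f_true * sigmas * xi_prime
    rows = [(exp, obs, t, d[i], sigmas[i])
            for i, (exp, obs, t) in enumerate(pred.index)]
    return Dataset.from_rows(rows)


# ---------------------------------------------------------------------------
# Large-K_M parameter draws and the single-reaction certification
# ---------------------------------------------------------------------------

def _reaction_concentrations(net: ReactionNetwork, rxn: Reaction):
    init = dict(zip(net.species_names, net.initial_state()))
    E = init[rxn.enzyme]
    if rxn.complex_species:
        E += init[rxn.complex_species]
    S = init[rxn.substrates[0][0]]
    return E, S


def choose_largeKM_parameters(
        net: ReactionNetwork, constraint_ratio: float = 0.01, seed: int = 0,
        ranges: dict[str, tuple[float, float]] | None = None,
        max_tries: int = 2000, certify: bool = True) -> np.ndarray:
    """Draw mechanistic-tier rate constants with K_M = (k_r+k_cat)/k_f large.

    Parameters are drawn log-uniformly within ``ranges`` (defaults below),
    rejecting draws until every enzymatic reaction satisfies
    [E]/([S]+K_M) <= constraint_ratio at the network's operating (initial)
    concentrations.  When ``certify`` is set, the accepted draw is checked by
    co-simulating each reaction in isolation and requiring the
    Michaelis-Menten product error to stay below 10%.

    Default log-uniform ranges: k_f in [1e-3, 1e3], k_r in [1e-2, 1e2],
    k_cat in [1e-1, 1e2]; elementary rate constants in [1e-2, 1e2].
    """
    defaults = {"k_f": (1e-3, 1e3), "k_r": (1e-2, 1e2),
                "k_cat": (1e-1, 1e2), "k": (1e-2, 1e2)}
    if ranges:
        defaults.update(ranges)
    rng = np.random.default_rng(seed)
    enz = [r for r in net.reactions if r.kind == MASS_ACTION_ENZYMATIC]
    if any(r.kind == MICHAELIS_MENTEN for r in net.reactions):
        raise ValueError("network is not at the mass-action tier")

    def draw_one(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    slot_of = {}
    for rxn in net.reactions:
        if rxn.kind == MASS_ACTION_ENZYMATIC:
            slot_of[rxn.k_f] = "k_f"
            slot_of[rxn.k_r] = "k_r"
            slot_of[rxn.k_cat] = "k_cat"
        else:
            for pname in rxn.parameter_names():
                slot_of[pname] = "k"

    for _ in range(max_tries):
        values = {p: draw_one(*defaults[slot_of.get(p, "k")])
                  for p in net.parameter_names}
        if not np.isfinite(constraint_ratio):
            violating = []
        else:
            violating = []
            for rxn in enz:
                KM = michaelis_constant(values[rxn.k_f], values[rxn.k_r],
                                        values[rxn.k_cat])
                E, S = _reaction_concentrations(net, rxn)
                if mm_validity_ratio(E, S, KM) > constraint_ratio:
                    violating.append(rxn.name)
        if violating:
            continue
        vec = np.array([values[p] for p in net.parameter_names])
        if certify and np.isfinite(constraint_ratio):
            ok = True
            for rxn in enz:
                E, S = _reaction_concentrations(net, rxn)
                err = mm_reduction_error(values[rxn.k_f], values[rxn.k_r],
                                         values[rxn.k_cat], E, S)
                if err > 0.10:
                    ok = False
                    break
            if not ok:
                continue
        return vec
    raise RuntimeError(
        f"could not satisfy validity ratio <= {constraint_ratio} within "
        f"{max_tries} draws; last violating reactions: {violating}")


def single_enzyme_pair(k_f: float, k_r: float, k_cat: float,
                       E0: float, S0: float):
    """(mass-action network, MM reduction network) for one isolated reaction."""
    KM = michaelis_constant(k_f, k_r, k_cat)
    mech = ReactionNetwork(
        species=[Species("E", E0), Species("S", S0), Species("ES", 0.0),
                 Species("P", 0.0)],
        reactions=[Reaction(
            name="conv", kind=MASS_ACTION_ENZYMATIC,
            substrates=(("S", 1),), products=(("P", 1),),
            enzyme="E", complex_species="ES",
            k_f="k_f", k_r="k_r", k_cat="k_cat")],
        parameters={"k_f": k_f, "k_r": k_r, "k_cat": k_cat},
        observables={"P": {"P": 1.0}},
    )
    approx = ReactionNetwork(
        species=[Species("E", E0), Species("S", S0), Species("P", 0.0)],
        reactions=[Reaction(
            name="conv", kind=MICHAELIS_MENTEN,
            substrates=(("S", 1),), products=(("P", 1),),
            enzyme="E", k_cat="k_cat", K_M="K_M")],
        parameters={"k_cat": k_cat, "K_M": KM},
        observables={"P": {"P": 1.0}},
    )
    return mech, approx


def mm_reduction_error(k_f: float, k_r: float, k_cat: float,
                       E0: float = 1.0, S0: float = 1.0,
                       conversion: float = 0.95, n_times: int = 200) -> float:
    """Max product error of the MM reduction for one isolated reaction.

    Both tiers are co-simulated from identical initial conditions out to the
    time at which the MM reduction reaches the requested substrate
    conversion (from the integrated rate law,
    t = (K_M ln(S0/S) + (S0-S)) / (k_cat E0)).  Returned is
    max_t |P_MM(t) - P_MA(t)| normalized by the final mass-action product
    level, i.e. the error as a fraction of the product scale.
    """
    KM = michaelis_constant(k_f, k_r, k_cat)
    S_end = (1.0 - conversion) * S0
    t_end = (KM * np.log(S0 / S_end) + (S0 - S_end)) / (k_cat * E0)
    times = tuple(np.linspace(t_end / n_times, t_end, n_times))
    mech, approx = single_enzyme_pair(k_f, k_r, k_cat, E0, S0)
    proto = ExperimentProtocol(id="iso", times=times, observables=("P",))
    p_mech = simulate(mech, proto).values
    p_approx = simulate(approx, proto).values
    scale = max(p_mech.max(), 1e-300)
    return float(np.abs(p_approx - p_mech).max() / scale)


# ---------------------------------------------------------------------------
# Shipped scenarios
# ---------------------------------------------------------------------------

def cascade_network(E0: float = 0.01, pool: float = 1.0) -> ReactionNetwork:
    """Approximate-tier (Michaelis-Menten) two-tier phosphorylation cascade.

    Four MM reactions form two coupled covalent-modification cycles: a
    kinase K phosphorylates S -> Sp (r1), phosphatase P1 reverts it (r2);
    Sp itself is the kinase of the downstream cycle T -> Tp (r3), reverted
    by phosphatase P2 (r4).  Substrate pools start unmodified at ``pool``;
    the dedicated enzymes sit at ``E0``.  With the defaults every reaction
    satisfies the Michaelis-Menten validity ratio [E]/([S]+K_M) <= 0.01 at
    operating concentrations (for r3 the operating enzyme level is the Sp
    pool bound, hence its large K_M), so the approximate tier is certified
    accurate under the baseline conditions — the designed perturbations are
    what push it out of that regime.
    """
    species = [Species("S", pool), Species("Sp", 0.0),
               Species("T", pool), Species("Tp", 0.0),
               Species("K", E0), Species("P1", E0), Species("P2", E0)]
    params = {"k_cat1": 50.0, "K_M1": 1.0,
              "k_cat2": 50.0, "K_M2": 1.0,
              "k_cat3": 100.0, "K_M3": 100.0,
              "k_cat4": 50.0, "K_M4": 1.0}
    reactions = [
        Reaction(name="phos_S", kind=MICHAELIS_MENTEN, enzyme="K",
                 substrates=(("S", 1),), products=(("Sp", 1),),
                 k_cat="k_cat1", K_M="K_M1"),
        Reaction(name="dephos_S", kind=MICHAELIS_MENTEN, enzyme="P1",
                 substrates=(("Sp", 1),), products=(("S", 1),),
                 k_cat="k_cat2", K_M="K_M2"),
        Reaction(name="phos_T", kind=MICHAELIS_MENTEN, enzyme="Sp",
                 substrates=(("T", 1),), products=(("Tp", 1),),
                 k_cat="k_cat3", K_M="K_M3"),
        Reaction(name="dephos_T", kind=MICHAELIS_MENTEN, enzyme="P2",
                 substrates=(("Tp", 1),), products=(("T", 1),),
                 k_cat="k_cat4", K_M="K_M4"),
    ]
    observables = {s: {s: 1.0} for s in ("S", "Sp", "T", "Tp")}
    return ReactionNetwork(species=species, reactions=reactions,
                           parameters=params, observables=observables)


def default_dna_model() -> DNARepairModel:
    """Reference composite lesion-kinetics parameters for the DNA scenario.

    Chosen so that (i) a single 14 Gy dose at 1.84 Gy/min leaves a few lethal
    lesions per clonogen (survival of order 1e-3..1e-2, the regime of the
    microcolony assay), (ii) the repair halftime ln2/lambda1 is ~40 min, and
    (iii) binary misrepair competes with first-order repair at high lesion
    loads (lambda3 u ~ lambda1 for u of a few), so the quadratic channel the
    RS reduction lacks shapes high-dose and short-interval responses.  The
    reference point was selected by inspecting the noiseless RS-reduction
    misfit: negligible over the baseline split-dose set, structural over the
    expanded set (see docs/methods.md).
    """
    return DNARepairModel(delta1=0.5, delta2=0.05, lambda1=1.0,
                          lambda2=0.05, lambda3=1.0, epsilon=0.05)


def dna_baseline_protocols(total_dose: float = 14.0, rest: float = 4.0,
                           dose_rate: float = 1.84) -> list[ExperimentProtocol]:
    """The 19 baseline split-dose conditions of the DNA scenario.

    Seven single fractions (2..14 Gy) plus twelve unequal splits of the total
    dose with a fixed rest interval.
    """
    protocols = []
    for D in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0):
        protocols.append(ExperimentProtocol(
            id=f"single_{D:g}Gy", doses=(D,), dose_rate=dose_rate, rest=rest))
    for d1 in (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0):
        protocols.append(ExperimentProtocol(
            id=f"split_{d1:g}+{total_dose - d1:g}Gy",
            doses=(d1, total_dose - d1), dose_rate=dose_rate, rest=rest))
    return protocols


def dna_expanded_protocols(base: list[ExperimentProtocol] | None = None
                           ) -> list[ExperimentProtocol]:
    """Baseline plus nine added conditions plus seven repeats (35 in all).

    The added conditions exercise the mechanisms the RS reduction lacks:
    high acute doses and short-interval high-dose splits (where the
    quadratic misrepair term dominates the lesion budget), a three-fraction
    schedule, and protracted low-dose-rate exposures (where the direct
    lethal-lesion channel sets the response).  Seven of the new conditions
    are repeated with independent noise, as confirmation experiments.
    """
    if base is None:
        base = dna_baseline_protocols()
    new9 = [
        ExperimentProtocol(id="single_18Gy", doses=(18.0,)),
        ExperimentProtocol(id="single_20Gy", doses=(20.0,)),
        ExperimentProtocol(id="split_9+9_r0.5", doses=(9.0, 9.0), rest=0.5),
        ExperimentProtocol(id="split_10+10_r0.5", doses=(10.0, 10.0), rest=0.5),
        ExperimentProtocol(id="frac_3x6_r2", doses=(6.0, 6.0, 6.0), rest=2.0),
        ExperimentProtocol(id="protracted_14Gy", doses=(14.0,), dose_rate=0.005),
        ExperimentProtocol(id="protracted_20Gy", doses=(20.0,), dose_rate=0.005),
        ExperimentProtocol(id="lowrate_20Gy", doses=(20.0,), dose_rate=0.05),
        ExperimentProtocol(id="split_7+7_r24", doses=(7.0, 7.0), rest=24.0),
    ]
    repeated = [new9[i] for i in (0, 1, 2, 3, 4, 6, 8)]
    reps = [ExperimentProtocol(id=p.id + "_rep", doses=p.doses,
                               dose_rate=p.dose_rate, rest=p.rest)
            for p in repeated]
    return base + new9 + reps


def dna_candidate_grid(first_fractions=(2.0, 7.0, 12.0),
                       rests=(0.5, 2.0, 8.0, 24.0),
                       dose_rates=(0.1, 1.84),
                       total_doses=(10.0, 14.0, 18.0)) -> list[ExperimentProtocol]:
    """Factorial candidate pool for DNA experimental design.

    Factors: first-fraction size, rest interval, dose rate and total dose
    (the four factors varied in the design scan); infeasible combinations
    (first fraction >= total dose) collapse to single-fraction protocols.
    """
    from .design import enumerate_candidates

    def build(i, first, rest, rate, total):
        if first >= total:
            doses = (total,)
        else:
            doses = (first, total - first)
        return ExperimentProtocol(
            id=f"cand{i:04d}_f{first:g}_r{rest:g}_dr{rate:g}_T{total:g}",
            doses=doses, dose_rate=rate, rest=rest)

    return enumerate_candidates(
        {"first": list(first_fractions), "rest": list(rests),
         "rate": list(dose_rates), "total": list(total_doses)}, build)


@dataclass
class Scenario:
    """A truth-vs-approximation experiment at full provenance.

    ``truth_model`` and ``fitting_model`` are predictor factories over a
    protocol list (NetworkModel / DNARepairSimulator); the truth tier
    generates the data, the fitting (approximate) tier is estimated on it.
    """

    name: str
    truth_factory: object        # callable(protocols) -> predictor
    fitting_factory: object      # callable(protocols) -> predictor
    baseline_protocols: list[ExperimentProtocol]
    candidate_protocols: list[ExperimentProtocol]
    noise_fraction: float = NOISE_FRACTION_DEFAULT
    sigma_mode: str = "per_observable_max"
    seed: int = 0
    baseline_data: Dataset | None = None
    manifest: dict = field(default_factory=dict)

    def truth(self, protocols):
        return self.truth_factory(protocols)

    def fitting(self, protocols):
        return self.fitting_factory(protocols)

    def generate(self, protocols, seed_offset: int = 0, f_true: float = 0.0) -> Dataset:
        return generate_dataset(
            self.truth(protocols), noise_fraction=self.noise_fraction,
            f_true=f_true, seed=self.seed + seed_offset,
            sigma_mode=self.sigma_mode)


def build_discrepancy_scenario(kind: str = "cascade", seed: int = 0,
                               noise_fraction: float = NOISE_FRACTION_DEFAULT,
                               **kwargs) -> Scenario:
    """Construct one of the shipped truth-vs-approximation scenarios.

    "cascade": the approximate tier is the two-tier phosphorylation cascade
    (four MM reactions); the truth tier is its mass-action expansion
    (parameters via the exact K_M-preserving back-mapping, so the large-K_M
    validity constraint holds by construction).  In the mechanistic tier the
    enzyme-substrate complexes couple the cycles (a phosphoprotein bound to
    its downstream substrate is shielded from its phosphatase), mechanisms
    the MM tier omits.  Baseline observes only the terminal phosphoprotein
    under two mild kinase levels; candidates vary the kinase stimulus,
    jointly over-express both phosphatases (high cycle flux keeps a
    substantial pool fraction enzyme-bound — the regime where the MM
    reduction degrades) and rescale the substrate pools, observing every
    pool species.

    "dna": the truth tier is the six-parameter composite lesion model; the
    fitting tier its RS reduction (delta2 = lambda3 = 0).  Baseline is the
    19-condition split-dose set; candidates come from the factorial dose
    grid.  Survival noise uses the per-point convention (constant
    coefficient of variation, as for count-derived surviving fractions).
    """
    if kind == "cascade":
        approx = cascade_network(**kwargs)
        mech, _mapping = expand_to_mass_action(approx)
        E0 = dict(zip(approx.species_names, approx.initial_state()))["K"]
        times = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 32.0)
        baseline = [
            ExperimentProtocol(id="baseline_lo", times=times,
                               initial={"K": 0.5 * E0}, observables=("Sp", "Tp")),
            ExperimentProtocol(id="baseline_hi", times=times,
                               observables=("Sp", "Tp")),
        ]
        all_obs = ("S", "Sp", "T", "Tp")
        dense = tuple(float(t) for t in (0.5, 1, 2, 4, 6, 8, 12, 16, 24, 32))
        candidates = []
        idx = 0
        for k_level in (E0, 10 * E0, 100 * E0):
            for pf in (1.0, 10.0, 100.0):
                over = {} if pf == 1.0 else {"P1": pf, "P2": pf}
                candidates.append(ExperimentProtocol(
                    id=f"cand{idx:02d}_K={k_level:g}"
                       + (f"_Px{pf:g}" if pf > 1 else ""),
                    times=dense, initial={"K": k_level},
                    overexpress=over, observables=all_obs))
                idx += 1
        for k_level in (E0, 100 * E0):
            for pool in (0.3, 3.0):
                candidates.append(ExperimentProtocol(
                    id=f"cand{idx:02d}_K={k_level:g}_pool{pool:g}",
                    times=dense, initial={"K": k_level, "S": pool, "T": pool},
                    observables=all_obs))
                idx += 1
        return Scenario(
            name="cascade",
            truth_factory=lambda protos, net=mech: NetworkModel(net, protos),
            fitting_factory=lambda protos, net=approx: NetworkModel(net, protos),
            baseline_protocols=baseline,
            candidate_protocols=candidates,
            noise_fraction=noise_fraction,
            sigma_mode="per_observable_max",
            seed=seed,
            manifest={"kind": "cascade", "seed": seed,
                      "noise_fraction": noise_fraction},
        )
    if kind == "dna":
        truth = kwargs.pop("truth_model", default_dna_model())
        rs_free = ("delta1", "lambda1", "lambda2", "epsilon")
        fit_base = truth.reduce("rs")
        # truth tier at tight solver tolerances; fitting tier at fitting-grade
        # tolerances (errors well below the 10% noise floor, several-fold faster)
        return Scenario(
            name="dna",
            truth_factory=lambda protos, m=truth: DNARepairSimulator(m, protos),
            fitting_factory=lambda protos, m=fit_base, fr=rs_free:
                DNARepairSimulator(m, protos, free=fr, rtol=1e-6, atol=1e-9),
            baseline_protocols=dna_baseline_protocols(**kwargs),
            candidate_protocols=dna_candidate_grid(),
            noise_fraction=noise_fraction,
            sigma_mode="per_point",
            seed=seed,
            manifest={"kind": "dna", "seed": seed,
                      "noise_fraction": noise_fraction},
        )
    raise ValueError(f"unknown scenario kind {kind!r}")
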