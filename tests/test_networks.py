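"""Reaction networks: validation, mass-action expansion, DNA-repair kinetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sloppysys.networks import (
    DNARepairModel,
    NetworkStructureError,
    Reaction,
    ReactionNetwork,
    Species,
    dna_repair_rhs,
    expand_to_mass_action,
    load_network,
    lpl_rhs,
    michaelis_constant,
    mm_validity_ratio,
    rs_rhs,
)
from sloppysys.synthgen import mm_reduction_error

from conftest import rk4_integrate


class TestValidityRatio:
    @pytest.mark.parametrize("E,S,KM,expected", [
        (1.0, 1.0, 99.0, 0.01),
        (0.0, 5.0, 2.0, 0.0),
        (0.5, 0.0, 1.0, 0.5),
    ])
    def test_direct_arithmetic(self, E, S, KM, expected):
        assert mm_validity_ratio(E, S, KM) == pytest.approx(expected)

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            mm_validity_ratio(1.0, 0.0, 0.0)

    def test_negative_enzyme_rejected(self):
        with pytest.raises(ValueError):
            mm_validity_ratio(-1.0, 1.0, 1.0)


class TestStructure:
    def test_mm_reaction_requires_enzyme(self):
        with pytest.raises(NetworkStructureError, match="no enzyme"):
            Reaction(name="bad", kind="michaelis_menten",
                     substrates=(("S", 1),), products=(("P", 1),),
                     k_cat="kc", K_M="km")

    def test_undeclared_species_rejected(self):
        with pytest.raises(NetworkStructureError, match="undeclared species"):
            ReactionNetwork(
                species=[Species("S", 1.0)],
                reactions=[Reaction(name="r", kind="mass_action_elementary",
                                    substrates=(("S", 1),),
                                    products=(("Ghost", 1),), k="k")],
                parameters={"k": 1.0})

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(NetworkStructureError, match="positive"):
            ReactionNetwork(species=[Species("S", 1.0)], reactions=[],
                            parameters={"k": 0.0})

    def test_yaml_roundtrip(self, tmp_path):
        cfg = """
species: {E: 0.05, S: 1.0, P: 0.0}
parameters: {kc: 2.0, km: 5.0}
reactions:
  - {name: conv, kind: michaelis_menten, enzyme: E,
     substrates: [[S, 1]], products: [[P, 1]], k_cat: kc, K_M: km}
observables: {P: {P: 1.0}}
"""
        path = tmp_path / "net.yaml"
        path.write_text(cfg)
        net = load_network(str(path))
        assert net.species_names == ["E", "S", "P"]
        assert net.parameters == {"kc": 2.0, "km": 5.0}
        assert net.reactions[0].kind == "michaelis_menten"


class TestExpansion:
    def test_identity_on_pure_mass_action(self, decay_network):
        expanded, mapping = expand_to_mass_action(decay_network)
        assert mapping == {}
        assert expanded.species_names == decay_network.species_names
        assert expanded.parameters == decay_network.parameters

    def test_single_reaction_structure(self, single_mm_network):
        expanded, mapping = expand_to_mass_action(single_mm_network)
        assert set(expanded.species_names) == {"E", "S", "P", "E_S_complex"}
        # one extra parameter: (k_cat, K_M) -> (k_f, k_r, k_cat)
        assert expanded.n_parameters == single_mm_network.n_parameters + 1
        rec = mapping["conv"]
        p = expanded.parameters
        km = michaelis_constant(p[rec["k_f"]], p[rec["k_r"]], p[rec["k_cat"]])
        assert km == pytest.approx(single_mm_network.parameters["K_M"], rel=1e-12)
        # complex starts empty
        es = [s for s in expanded.species if s.name == "E_S_complex"][0]
        assert es.initial == 0.0

    def test_parameter_and_species_counts(self):
        from sloppysys.synthgen import cascade_network
        approx = cascade_network()
        n_mm = sum(r.kind == "michaelis_menten" for r in approx.reactions)
        expanded, _ = expand_to_mass_action(approx)
        assert expanded.n_parameters == approx.n_parameters + n_mm
        assert len(expanded.species) == len(approx.species) + n_mm

    def test_enzyme_conservation_against_rk4(self, single_mm_network):
        expanded, _ = expand_to_mass_action(single_mm_network)
        rhs, _, _ = expanded.compile()
        p = expanded.parameter_vector()
        grid = np.linspace(0.0, 5.0, 4001)
        traj = rk4_integrate(lambda t, y: rhs(t, y, p),
                             expanded.initial_state(), grid)
        names = expanded.species_names
        total = traj[:, names.index("E")] + traj[:, names.index("E_S_complex")]
        assert np.abs(total - 0.05).max() < 1e-9

    def test_qss_convergence_is_monotone(self):
        # tightening the validity ratio by 10x reduces the MM product error
        errors = [mm_reduction_error(k_f=100.0, k_r=50.0, k_cat=50.0,
                                     E0=E0, S0=1.0)
                  for E0 in (0.2, 0.02, 0.002)]  # ratios 0.1, 0.01, 0.001
        assert errors[0] > errors[1] > errors[2]
        assert errors[1] < 0.01


class TestDNARepair:
    def test_absorbing_zero_state(self):
        m = DNARepairModel(0.5, 0.05, 1.0, 0.05, 1.0, 0.05)
        assert dna_repair_rhs((0.0, 0.0), 0.0, 0.0, m) == (0.0, 0.0)

    def test_lpl_substitution(self):
        m = DNARepairModel(delta1=0.3, delta2=0.0, lambda1=0.8,
                           lambda2=0.0, lambda3=0.1, epsilon=0.0)
        r = 2.0
        du, dv = dna_repair_rhs((2.0, 0.5), 0.0, r, m)
        assert du == pytest.approx(0.3 * r - 0.8 * 2 - 0.1 * 4)
        assert dv == pytest.approx(0.1 * 4)

    @given(u=st.floats(0.0, 50.0), v=st.floats(0.0, 50.0),
           r=st.floats(0.0, 100.0))
    def test_lpl_reduction_bit_identical(self, u, v, r):
        m = DNARepairModel(0.4, 0.2, 0.7, 0.3, 0.2, 0.5).reduce("lpl")
        assert dna_repair_rhs((u, v), 0.0, r, m) == lpl_rhs(
            (u, v), 0.0, r, m.delta1, m.lambda1, m.lambda3)

    @given(u=st.floats(0.0, 50.0), v=st.floats(0.0, 50.0),
           r=st.floats(0.0, 100.0))
    def test_rs_reduction_bit_identical(self, u, v, r):
        m = DNARepairModel(0.4, 0.2, 0.7, 0.3, 0.2, 0.5).reduce("rs")
        assert dna_repair_rhs((u, v), 0.0, r, m) == rs_rhs(
            (u, v), 0.0, r, m.delta1, m.lambda1, m.lambda2, m.epsilon)

    def test_rs_small_u_decay_against_rk4(self):
        # at r=0 and small u the linearized decay rate is lambda1 + lambda2
        m = DNARepairModel(delta1=0.5, delta2=0.0, lambda1=0.6,
                           lambda2=0.3, lambda3=0.0, epsilon=0.2)
        u0 = 1e-7  # small enough that the saturation correction eps*u is negligible
        du0, _ = dna_repair_rhs((u0, 0.0), 0.0, 0.0, m)
        assert du0 == pytest.approx(-(0.6 + 0.3) * u0, rel=1e-4)
        grid = np.linspace(0.0, 1.0, 20001)
        traj = rk4_integrate(
            lambda t, y: dna_repair_rhs(y, t, 0.0, m), (u0, 0.0), grid)
        expected = u0 * np.exp(-(0.6 + 0.3) * grid)
        assert np.abs(traj[:, 0] - expected).max() / u0 < 1e-6

    def test_negative_state_rejected(self):
        m = DNARepairModel(0.5, 0.0, 1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            dna_repair_rhs((-1.0, 0.0), 0.0, 0.0, m)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            DNARepairModel(-0.1, 0.0, 1.0, 0.0, 0.0, 0.0)
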