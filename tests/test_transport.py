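"""Transport solver: fluxes, conservation, analytic steady states."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuritesim import (
    TransportParameters,
    advective_flux,
    build_cable,
    build_y_tree,
    diffusive_flux,
    set_uniform_concentration,
    steady_state_profile,
    total_tubulin,
    transport_step,
)
from neuritesim.morphology import CompartmentTree, GROWTH_CONE, SHAFT, SOMA, YTreeSpec
from neuritesim.simulate import Simulator

UM = 1e-6
AREA_1UM = np.pi / 4 * (1e-6) ** 2  # cross-section of a 1 um cylinder


class TestFluxLaws:
    def test_diffusive_flux_hand_value(self):
        # D*A*dC/d with a 5.5 uM drop over 1 um through a 1 um cylinder
        flux = diffusive_flux(5.5e-3, 0.0, AREA_1UM, 1e-6, 1e-11)
        assert flux == pytest.approx(-4.32e-20, rel=1e-2)

    def test_diffusive_flux_zero_at_equal_conc(self):
        assert diffusive_flux(3e-3, 3e-3, AREA_1UM, 1e-6, 1e-11) == 0.0

    @given(
        ci=st.floats(0, 1e-2),
        cj=st.floats(0, 1e-2),
        a=st.floats(1e-14, 1e-11),
        d=st.floats(1e-7, 1e-5),
    )
    def test_diffusive_flux_antisymmetric(self, ci, cj, a, d):
        assert diffusive_flux(ci, cj, a, d, 1e-11) == pytest.approx(
            -diffusive_flux(cj, ci, a, d, 1e-11), abs=1e-30
        )

    def test_diffusive_flux_degenerate_distance(self):
        with pytest.raises(ValueError):
            diffusive_flux(1e-3, 2e-3, AREA_1UM, 0.0, 1e-11)

    def test_advective_flux_hand_value(self):
        flux = advective_flux(5.5e-3, AREA_1UM, 6e-3, 4.4e-7)
        assert flux == pytest.approx(1.14e-23, rel=1e-2)

    def test_advective_flux_zero_when_off(self):
        assert advective_flux(5.5e-3, AREA_1UM, 6e-3, 0.0) == 0.0
        assert advective_flux(5.5e-3, AREA_1UM, 0.0, 4.4e-7) == 0.0

    def test_advective_flux_linear_in_fraction(self):
        one = advective_flux(5.5e-3, AREA_1UM, 6e-3, 4.4e-7)
        two = advective_flux(5.5e-3, AREA_1UM, 12e-3, 4.4e-7)
        assert two == pytest.approx(2 * one, rel=1e-12)


def _sealed_params(**kw):
    base = dict(decay=0.0, active_speed=0.0, soma_clamp=False)
    base.update(kw)
    return TransportParameters(**base)


class TestTransportStep:
    def test_two_compartment_equilibration(self):
        tree = CompartmentTree()
        soma = tree.add(SOMA, 10 * UM, 10 * UM)
        s1 = tree.add(SHAFT, 2 * UM, 1 * UM, parent_id=soma.id, tubulin_quantity=0.0)
        tree.add(
            GROWTH_CONE, 2 * UM, 1 * UM, parent_id=s1.id, tubulin_quantity=1e-18
        )
        params = _sealed_params()
        q0 = total_tubulin(tree)
        for _ in range(3000):
            transport_step(tree, params, dt=10.0)
        assert total_tubulin(tree) == pytest.approx(q0, rel=1e-12)
        concs = [
            c.concentration for c in tree.compartments.values() if c.kind != SOMA
        ]
        assert max(concs) == pytest.approx(min(concs), rel=1e-6)

    def test_sealed_mass_conservation_1e5_steps(self):
        """Relative drift below 1e-10 over 1e5 implicit steps."""
        tree = build_cable(10e-6, max_comp_length=2.5e-6)
        set_uniform_concentration(tree, 5.5e-3)
        tree.compartments[tree.growth_cone_ids[0]].tubulin_quantity *= 2.0
        sim = Simulator(tree, _sealed_params())
        q0 = sim.total_tubulin()
        for _ in range(100_000):
            sim.transport_step(1.0)
        assert abs(sim.total_tubulin() - q0) / q0 < 1e-10

    def test_steady_state_matches_cosh_profile(self):
        """Sealed 100 um cable with strong decay (lambda = 50 um): the
        relaxed profile matches the analytic cosh solution within 1%."""
        params = TransportParameters(decay=4e-3, active_speed=0.0)
        tree = build_cable(
            100e-6, soma_diameter=1e-6, max_comp_length=1e-6, tip_growth_cone=False
        )
        set_uniform_concentration(tree, params.c_soma)
        sim = Simulator(tree, params)
        for _ in range(300):
            sim.transport_step(100.0)
        conc = sim.concentrations()
        x = np.empty(len(sim.ids))
        for k, cid in enumerate(sim.ids):
            comp = tree.compartments[cid]
            if comp.kind == SOMA:
                x[k] = 0.0
            else:
                x[k] = (
                    tree.depth(cid) - comp.length / 2 + tree.soma.half_length
                )
        total_len = 100e-6 + tree.soma.half_length
        expected = steady_state_profile(x, total_len, params)
        assert np.max(np.abs(conc - expected) / expected) < 0.01

    def test_near_flat_profile_with_default_decay(self):
        """With the default decay the space constant is ~4.2 mm, so a
        100 um cable is nearly isopotential."""
        params = TransportParameters(active_speed=0.0)
        lam = np.sqrt(params.diffusion / params.decay)
        assert lam == pytest.approx(4.2e-3, rel=0.01)
        tree = build_cable(100e-6, tip_growth_cone=False)
        set_uniform_concentration(tree, params.c_soma)
        sim = Simulator(tree, params)
        for _ in range(200):
            sim.transport_step(500.0)
        conc = sim.concentrations()
        assert np.max(np.abs(conc - params.c_soma) / params.c_soma) < 0.01

    def test_advection_accumulates_tubulin_distally(self):
        """Sealed chain with active transport and no decay: at steady
        state the tip holds more tubulin than the soma-adjacent shaft."""
        tree = build_cable(6e-6, max_comp_length=2e-6)
        set_uniform_concentration(tree, 5.5e-3)
        params = _sealed_params(active_speed=4.4e-7)
        sim = Simulator(tree, params)
        q0 = sim.total_tubulin()
        for _ in range(5000):
            sim.transport_step(10.0)
        conc = {cid: c for cid, c in zip(sim.ids, sim.concentrations())}
        gc = tree.growth_cone_ids[0]
        first_shaft = tree.soma.child_ids[0]
        assert conc[gc] > conc[first_shaft]
        assert sim.total_tubulin() == pytest.approx(q0, rel=1e-10)

    def test_grid_refinement_tip_concentration(self):
        """Halving the mesh changes the steady-state tip concentration
        by < 0.5%."""
        tips = []
        for h in (2.0e-6, 1.0e-6):
            params = TransportParameters(decay=4e-3, active_speed=0.0)
            tree = build_cable(
                100e-6, soma_diameter=1e-6, max_comp_length=h, tip_growth_cone=False
            )
            set_uniform_concentration(tree, params.c_soma)
            sim = Simulator(tree, params)
            for _ in range(300):
                sim.transport_step(100.0)
            conc = sim.concentrations()
            gc = tree.growth_cone_ids[0]
            tips.append(conc[sim.idx[gc]])
        assert abs(tips[1] - tips[0]) / tips[0] < 0.005

    def test_explicit_and_implicit_agree(self):
        results = []
        for integrator in ("implicit", "explicit"):
            params = TransportParameters(
                active_speed=0.0, integrator=integrator
            )
            tree = build_cable(20e-6)
            set_uniform_concentration(tree, 1e-3)
            sim = Simulator(tree, params)
            for _ in range(2000):
                sim.transport_step(0.005)
            results.append(sim.concentrations())
        np.testing.assert_allclose(results[0], results[1], rtol=1e-3)

    def test_explicit_instability_detected(self):
        from neuritesim.simulate import NumericalError

        params = TransportParameters(active_speed=0.0, integrator="explicit")
        tree = build_cable(20e-6)
        set_uniform_concentration(tree, 1e-3)
        sim = Simulator(tree, params)
        with pytest.raises(NumericalError, match="reduce dt"):
            for _ in range(50):
                sim.transport_step(10.0)  # far beyond the diffusive limit

    def test_mirror_symmetry_of_y_tree(self):
        """Identical growth cones on a symmetric tree stay symmetric to
        machine precision (control case: both branches behave alike)."""
        spec = YTreeSpec(d_a=20e-6, d_b=10e-6)
        tree = build_y_tree(spec)
        set_uniform_concentration(tree, 5.5e-3)
        params = TransportParameters()
        sim = Simulator(tree, params)
        gc1, gc2 = tree.growth_cone_ids
        for _ in range(500):
            sim.transport_step(5.0)
        c = {cid: v for cid, v in zip(sim.ids, sim.concentrations())}
        path1 = [i for i in tree.path_to_soma(gc1) if tree.depth(i) > 20e-6]
        path2 = [i for i in tree.path_to_soma(gc2) if tree.depth(i) > 20e-6]
        for a, b in zip(path1, path2):
            assert c[a] == pytest.approx(c[b], rel=1e-12)

    def test_soma_clamp_holds_and_production_booked(self, default_params):
        tree = build_cable(20e-6)
        set_uniform_concentration(tree, 0.0)  # empty neurite
        tree.soma.tubulin_quantity = default_params.c_soma * tree.soma.volume
        sim = Simulator(tree, default_params)
        for _ in range(100):
            sim.transport_step(1.0)
        assert sim.quantity[sim.soma_idx] == pytest.approx(
            default_params.c_soma * tree.soma.volume
        )
        assert sim.ledger.produced > 0  # mass flowed out into the neurite
        assert sim.ledger.expected_total() == pytest.approx(
            sim.total_tubulin(), rel=1e-12
        )


class TestParameters:
    def test_defaults_are_standard_table(self, default_params):
        p = default_params
        assert (p.diffusion, p.active_fraction, p.active_speed) == (
            1e-11,
            6e-3,
            440e-9,
        )
        assert (p.decay, p.x_per_length) == (5.67e-7, 4e-14)
        assert (p.poly_rate, p.depoly_rate, p.c_soma) == (1.83e-6, 9.17e-9, 5.5e-3)

    @pytest.mark.parametrize(
        "field,value",
        [("diffusion", -1e-11), ("active_fraction", 1.5), ("dt", -1.0)],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            TransportParameters(**{field: value})
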