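"""Necrosis observables: live fraction, barycentres, onsets, thresholds."""

import numpy as np
import pandas as pd
import pytest

from mcelsim.metrics import (find_da_onset_fem, gamma_profile, live_fraction,
                             necrotic_metrics, threshold_search)
from mcelsim.radial1d import rn_maximal
from mcelsim.transport import TransportMode, TransportProblem, solve_transport


def maximal(Da, mesh):
    return solve_transport(
        TransportProblem(TransportMode.maximal_supply, Da=Da), mesh)


def synthetic_field(mesh, values):
    """Wrap a nodal array as a concentration field for metric tests."""
    from mcelsim.transport import ConcentrationField
    pb = TransportProblem(TransportMode.maximal_supply, Da=1.0)
    return ConcentrationField(mesh=mesh, c=np.asarray(values, float),
                              problem=pb, converged=True, newton_iters=0,
                              residual=0.0)


class TestLiveFraction:
    def test_uniform_fields(self, construct_mesh_unconfined):
        mesh = construct_mesh_unconfined
        n = len(mesh.nodes)
        assert live_fraction(synthetic_field(mesh, 0.5 * np.ones(n))) == 1.0
        assert live_fraction(synthetic_field(mesh, np.zeros(n))) \
            == pytest.approx(0.0, abs=1e-12)

    def test_halfplane_split(self, construct_mesh_unconfined):
        """A field crossing the threshold exactly at x = 0 leaves half the
        (symmetric) construct dead."""
        mesh = construct_mesh_unconfined
        t = 1e-3
        c = t * (1.0 + np.sign(mesh.nodes[:, 0])
                 + 0.5 * mesh.nodes[:, 0])
        phi = live_fraction(synthetic_field(mesh, c))
        assert phi == pytest.approx(0.5, abs=0.01)

    def test_phi_plus_necrotic_fraction_is_one(self,
                                               construct_mesh_unconfined):
        f = maximal(10.0, construct_mesh_unconfined)
        m = necrotic_metrics(f)
        area2 = f.mesh.region_area(2)
        assert m.phi_live + m.necrotic_area / area2 == pytest.approx(
            1.0, abs=1e-10)


class TestAgainstAnalytic:
    @pytest.mark.parametrize("Da", [5.0, 10.0, 30.0, 50.0])
    def test_live_fraction_tracks_radial_root(self, Da,
                                              construct_mesh_unconfined_fine):
        """FEM live fraction vs 1 - rn*^2 from the radial model: within 2%
        (fine construct resolution, which resolves the necrotic rim up to
        Da = 50)."""
        f = maximal(Da, construct_mesh_unconfined_fine)
        phi_fem = live_fraction(f)
        phi_an = rn_maximal(Da).phi_live
        assert abs(phi_fem - phi_an) / phi_an < 0.02


class TestBarycentre:
    def test_radially_symmetric_core_centred_in_x(self,
                                                  construct_mesh_unconfined):
        f = maximal(10.0, construct_mesh_unconfined)
        m = necrotic_metrics(f)
        assert abs(m.barycentre[0]) < 1e-2
        assert m.asymmetry == m.barycentre[0]

    def test_confined_core_on_contact_bisector_below_centre(
            self, construct_mesh_confined):
        """Just above the confined onset the core sits on the contact
        normal through x = 0, below the circle centre."""
        f = maximal(3.6, construct_mesh_confined)
        m = necrotic_metrics(f)
        assert m.phi_live < 1.0
        assert abs(m.barycentre[0]) < 5e-2
        assert m.barycentre[1] < f.mesh.spec.centre_y

    def test_downstream_shift_at_moderate_convection(
            self, full_mesh_unconfined, flow_unconfined):
        pb = TransportProblem(TransportMode.microfluidic, Da=5.0, Rd=0.5,
                              Pe1=10.0, flow=flow_unconfined)
        f = solve_transport(pb, full_mesh_unconfined)
        m = necrotic_metrics(f)
        assert m.asymmetry > 0.05

    def test_empty_core_flagged(self, construct_mesh_unconfined):
        f = maximal(1.0, construct_mesh_unconfined)
        m = necrotic_metrics(f)
        assert m.phi_live == 1.0
        assert m.barycentre is None
        assert len(m.boundary_segments) == 0

    def test_printed_normalization_scales_by_necrotic_fraction(
            self, construct_mesh_unconfined):
        f = maximal(10.0, construct_mesh_unconfined)
        m = necrotic_metrics(f)
        area2 = f.mesh.region_area(2)
        frac = m.necrotic_area / area2
        assert m.barycentre_printed[1] == pytest.approx(
            m.barycentre[1] * frac, rel=1e-10)


class TestOnsetSearch:
    def test_unconfined_onset_near_analytic(self, spec_unconfined,
                                            construct_mesh_unconfined):
        da = find_da_onset_fem(spec_unconfined,
                               mesh=construct_mesh_unconfined)
        assert da == pytest.approx(4.0, abs=0.1)

    def test_confinement_lowers_the_onset(self, spec_confined,
                                          construct_mesh_confined,
                                          spec_unconfined,
                                          construct_mesh_unconfined):
        da_c = find_da_onset_fem(spec_confined, mesh=construct_mesh_confined)
        da_u = find_da_onset_fem(spec_unconfined,
                                 mesh=construct_mesh_unconfined)
        assert da_c < da_u


class TestGammaProfile:
    def test_maximal_supply_interface_is_saturated(
            self, construct_mesh_unconfined):
        f = maximal(10.0, construct_mesh_unconfined)
        prof = gamma_profile(f)
        assert np.allclose(prof["gamma"], 1.0)
        assert prof["theta"].is_monotonic_increasing


class TestThresholdSearch:
    def test_static_margin_recovers_planted_threshold(self):
        """On synthetic data where min_c decays exponentially below a known
        margin M0 = 1.3, the search recovers M0."""
        rows = []
        for da in [2.0, 3.0]:
            for margin in np.geomspace(0.1, 10, 12):
                sd = margin / (1 - da / 4.0)
                min_c = min(1e-2, 1e-3 * np.exp(8 * (margin - 1.3)))
                rows.append(dict(Da=da, Sd=sd, min_c=min_c))
        res = threshold_search(pd.DataFrame(rows), "static_margin",
                               da_onset=4.0)
        assert res.reached
        assert res.value == pytest.approx(1.3, rel=0.15)

    def test_unreachable_criterion_reported(self):
        df = pd.DataFrame([dict(Da=2.0, Sd=1.0, min_c=1e-9),
                           dict(Da=2.0, Sd=2.0, min_c=1e-8)])
        res = threshold_search(df, "static_margin")
        assert not res.reached
        assert res.value is None

    def test_asymmetry_peak_located(self):
        pe1 = np.geomspace(0.1, 1e3, 15)
        da = 5.0
        sc = 2 * 0.5 * pe1 / da
        pred = np.sqrt(da) * sc
        shift = 0.2 * np.exp(-0.5 * (np.log(pred / 3.0)) ** 2)
        df = pd.DataFrame(dict(Da=da, Pe1=pe1, Sc=sc, asymmetry=shift))
        res = threshold_search(df, "asymmetry_peak")
        assert res.value == pytest.approx(3.0, rel=0.1)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            threshold_search(pd.DataFrame({"Da": [1.0]}), "bogus")
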