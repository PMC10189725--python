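"""Dimensional scaling, fit behaviour and derived partition/pathway numbers."""

import numpy as np
import pandas as pd
import pytest

from cuticle_uptake import (
    AssaySchemaError,
    DimlessCurve,
    DomainError,
    Geometry,
    InsufficientDataError,
    TransportParams,
    compute_Zmax,
    csat_to_Kcw,
    dimensionalize,
    fit_uptake,
    pathway_criterion_G,
    reference_scales,
    validate_assay,
)
from cuticle_uptake.synth import SynthConfig, gen_assay

from conftest import PAPER_C_SAT_CUT, PAPER_D_CUT


class TestZmax:
    def test_maize_assay_value(self, geom_paper):
        """50 nm cuticle under a 450 um deposit gives Z_max = 1.1e-4 (2 s.f.)."""
        assert compute_Zmax(geom_paper) == pytest.approx(1.1e-4, rel=0.02)

    def test_unit_ratio(self):
        assert compute_Zmax(Geometry(r_dep_m=1e-4, z_max_m=1e-4)) == 1.0

    def test_half_thickness(self):
        g = Geometry(r_dep_m=450e-6, z_max_m=25e-9)
        assert compute_Zmax(g) == pytest.approx(5.556e-5, rel=1e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            Geometry(r_dep_m=-1.0, z_max_m=1.0)


class TestReferenceScales:
    def test_assay_operating_point(self, geom_paper):
        t_ref, m_ref = reference_scales(geom_paper, PAPER_D_CUT, PAPER_C_SAT_CUT)
        assert t_ref == pytest.approx(1.633e11, rel=1e-3)
        assert m_ref == pytest.approx(1.704e-4, rel=1e-3)

    def test_unit_time_scale(self):
        g = Geometry(r_dep_m=2.0, z_max_m=1.0)
        t_ref, _ = reference_scales(g, D_cut=4.0, c_sat_cut=1.0)
        assert t_ref == 1.0

    def test_rejects_nonpositive(self, geom_paper):
        with pytest.raises(DomainError):
            reference_scales(geom_paper, -1.0, 1.0)


def _toy_curve():
    T = np.geomspace(1e-3, 1e3, 200)
    M = 2.0 * np.sqrt(T / np.pi) * np.pi  # Cottrellian cumulative mass
    rate = np.sqrt(np.pi / T)
    return DimlessCurve(T=T, M=M, rate=rate)


class TestDimensionalize:
    def test_identity_scales(self):
        c = _toy_curve()
        tab = dimensionalize(c, t_ref=1.0, m_ref=1.0, n_droplets=1)
        assert np.allclose(tab["time_s"], c.T)
        assert np.allclose(tab["mass_ug"], c.M * 1e6)

    def test_droplet_count_scales_mass_only(self):
        c = _toy_curve()
        one = dimensionalize(c, 10.0, 1e-6, n_droplets=1)
        two = dimensionalize(c, 10.0, 1e-6, n_droplets=2)
        assert np.allclose(two["mass_ug"], 2 * one["mass_ug"])
        assert np.allclose(two["time_s"], one["time_s"])

    def test_round_trip(self):
        """Dimensionalise then scale back: recovers the master to machine precision."""
        c = _toy_curve()
        t_ref, m_ref, n = 3.7e8, 2.2e-5, 20
        tab = dimensionalize(c, t_ref, m_ref, n)
        T_back = tab["time_s"].to_numpy() / t_ref
        M_back = tab["mass_ug"].to_numpy() / 1e6 / (n * m_ref)
        assert np.allclose(T_back, c.T, rtol=1e-14)
        assert np.allclose(M_back, c.M, rtol=1e-14)

    def test_transition_maps_to_minutes(self, geom_paper):
        """At the fitted scales the saturation transition lands at ~17 min,
        the same order as the observed fast-uptake window."""
        t_ref, _ = reference_scales(geom_paper, PAPER_D_CUT, PAPER_C_SAT_CUT)
        T_tr = 0.5 * compute_Zmax(geom_paper) ** 2
        t_min = T_tr * t_ref / 60.0
        assert 5.0 < t_min < 60.0


class TestFit:
    def test_noiseless_recovery(self, geom_paper, master_paper):
        """Self-consistency: exact forward data return the true parameters."""
        cfg = SynthConfig(
            geometry=geom_paper, D_cut=PAPER_D_CUT, c_sat_cut=PAPER_C_SAT_CUT,
            cv=0.0, seed=0,
        )
        fit = fit_uptake(gen_assay(cfg, master_paper), master_paper, geom_paper)
        assert fit.D_cut_hat == pytest.approx(PAPER_D_CUT, rel=0.01)
        assert fit.c_sat_cut_hat == pytest.approx(PAPER_C_SAT_CUT, rel=0.01)
        assert fit.r_squared > 0.9999

    def test_mass_rescaling_moves_only_m_ref(self, geom_paper, master_paper):
        cfg = SynthConfig(
            geometry=geom_paper, D_cut=PAPER_D_CUT, c_sat_cut=PAPER_C_SAT_CUT,
            cv=0.05, seed=3,
        )
        data = gen_assay(cfg, master_paper)
        base = fit_uptake(data, master_paper, geom_paper)
        scaled = data.copy()
        k = 2.5
        scaled["mass_TL_ug"] *= k
        res = fit_uptake(scaled, master_paper, geom_paper)
        assert res.m_ref_hat == pytest.approx(k * base.m_ref_hat, rel=1e-6)
        assert res.t_ref_hat == pytest.approx(base.t_ref_hat, rel=1e-6)
        assert res.D_cut_hat == pytest.approx(base.D_cut_hat, rel=1e-6)

    def test_row_order_invariance(self, geom_paper, master_paper):
        cfg = SynthConfig(
            geometry=geom_paper, D_cut=PAPER_D_CUT, c_sat_cut=PAPER_C_SAT_CUT,
            cv=0.05, seed=4,
        )
        data = gen_assay(cfg, master_paper)
        shuffled = data.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = fit_uptake(data, master_paper, geom_paper)
        b = fit_uptake(shuffled, master_paper, geom_paper)
        assert a.D_cut_hat == pytest.approx(b.D_cut_hat, rel=1e-9)

    def test_too_few_time_points(self, geom_paper, master_paper):
        df = pd.DataFrame(
            {
                "time_min": [10.0, 10.0],
                "mass_LW_ug": [1.0, 1.0],
                "mass_TL_ug": [0.5, 0.5],
                "batch": [1, 1],
                "replicate": [1, 2],
            }
        )
        with pytest.raises(InsufficientDataError):
            fit_uptake(df, master_paper, geom_paper)

    def test_narrow_time_span_warns(self, geom_paper, master_paper):
        cfg = SynthConfig(
            geometry=geom_paper, D_cut=PAPER_D_CUT, c_sat_cut=PAPER_C_SAT_CUT,
            cv=0.0, seed=0, times_min=(10.0, 20.0, 40.0),
        )
        data = gen_assay(cfg, master_paper)
        with pytest.warns(UserWarning, match="decade"):
            fit_uptake(data, master_paper, geom_paper)


class TestAssaySchema:
    def test_missing_column_is_named(self):
        df = pd.DataFrame({"time_min": [1.0], "mass_TL_ug": [0.1]})
        with pytest.raises(AssaySchemaError, match="mass_LW_ug"):
            validate_assay(df)

    def test_negative_mass_rejected(self):
        df = pd.DataFrame(
            {
                "time_min": [1.0],
                "mass_LW_ug": [-0.1],
                "mass_TL_ug": [0.1],
                "batch": [1],
                "replicate": [1],
            }
        )
        with pytest.raises(AssaySchemaError, match="mass_LW_ug"):
            validate_assay(df)


class TestPartitionAndPathway:
    def test_Kcw_unit_ratio(self):
        K, logK = csat_to_Kcw(1.87, 1.87)
        assert K == 1.0 and logK == 0.0

    def test_Kcw_log_form(self):
        K, logK = csat_to_Kcw(1.87e6, 1.87)
        assert K == pytest.approx(1e6)
        assert logK == pytest.approx(6.0)

    def test_Kcw_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            csat_to_Kcw(0.0, 1.0)

    def test_G_boundary_case(self):
        p = TransportParams(D_cut=1e-10, c_sat_cut=5.0, D_aq=1e-10, c_sat_aq=5.0)
        G, label = pathway_criterion_G(p)
        assert G == pytest.approx(1.0)

    def test_G_indirect_dominant_for_fungicide(self):
        p = TransportParams(
            D_cut=PAPER_D_CUT, c_sat_cut=PAPER_C_SAT_CUT, D_aq=1e-10, c_sat_aq=1.0
        )
        G, label = pathway_criterion_G(p)
        assert G == pytest.approx(2.32e-2, rel=1e-2)
        assert label == "indirect-dominant"

    def test_G_monotone_in_D_cut(self):
        Gs = [
            pathway_criterion_G(
                TransportParams(D_cut=d, c_sat_cut=1.0, D_aq=1e-10, c_sat_aq=1.0)
            )[0]
            for d in (1e-18, 1e-16, 1e-14)
        ]
        assert Gs[0] < Gs[1] < Gs[2]

    def test_G_needs_aqueous_solubility(self):
        p = TransportParams(D_cut=1e-18, c_sat_cut=1e6)
        with pytest.raises(InsufficientDataError):
            pathway_criterion_G(p)
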