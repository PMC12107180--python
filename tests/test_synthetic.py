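"""Generators: mass-action RNA sequestration, binodal records, phase split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from llpskit import synthetic as syn, thermo


class TestFreeRna:
    def test_no_binder_returns_total(self):
        assert syn.free_rna(10.0, 0.0, 5.0, 2) == pytest.approx(10.0)

    def test_tight_binding_excess_sites(self):
        assert syn.free_rna(10.0, 100.0, 0.0, 2) == 0.0

    def test_quadratic_root_against_bisection_oracle(self):
        # r + S r / (kd + r) = r_tot with S = 10, kd = 10, r_tot = 10
        oracle = bisect(lambda r: r + 10 * r / (10 + r) - 10, 0, 10, xtol=1e-12)
        assert syn.free_rna(10.0, 5.0, 10.0, 2) == pytest.approx(oracle, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            syn.free_rna(-1.0, 1.0, 1.0)

    @given(
        st.floats(min_value=0.01, max_value=1e3),
        st.floats(min_value=0.0, max_value=1e3),
        st.floats(min_value=0.01, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds_and_monotonicity(self, r_tot, mex5, kd):
        r = syn.free_rna(r_tot, mex5, kd, 2)
        assert 0.0 <= r <= r_tot + 1e-12
        # decreasing in MEX-5, increasing in total RNA
        assert syn.free_rna(r_tot, mex5 + 1.0, kd, 2) <= r + 1e-9
        assert syn.free_rna(r_tot * 1.1, mex5, kd, 2) >= r - 1e-9


class TestBinodalModel:
    def test_csat_strictly_decreasing(self, default_model):
        r = np.linspace(0, 200, 50)
        assert np.all(np.diff(default_model.c_sat(r)) < 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            syn.BinodalModel(w=0.0)
        with pytest.raises(ValueError):
            syn.BinodalModel(k_tie=-0.1)
        with pytest.raises(ValueError):
            syn.BinodalModel(n_sites_m=0)


class TestGenPhaseDiagram:
    def test_same_seed_identical_records(self, default_model):
        a, _ = syn.gen_phase_diagram(default_model, 200, seed=5)
        b, _ = syn.gen_phase_diagram(default_model, 200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_boundary_without_mex5(self):
        """With a vanishing classification width, demixing is p >= c_sat."""
        m = syn.BinodalModel(w=1e-6, k_tie=0.0)
        df, _ = syn.gen_phase_diagram(
            m, 500,
            {"pgl3_uM": (0.05, 2.5), "rna_ng_per_uL": (1, 150),
             "mex5_uM": (0.0, 0.0)},
            seed=3,
        )
        demixed = df["p_demix"] >= 0.5
        expected = df["pgl3_uM"] >= m.c_sat(df["rna_ng_per_uL"])
        assert (demixed == expected).all()

    def test_homogeneous_records_report_total(self, phase_records):
        df, _ = phase_records
        mixed = df[df["p_demix"] < 0.5]
        assert np.allclose(mixed["pgl3_dilute_uM"], mixed["pgl3_uM"])

    def test_dilute_never_exceeds_total(self, phase_records):
        df, _ = phase_records
        assert (df["pgl3_dilute_uM"] <= df["pgl3_uM"] + 1e-9).all()

    def test_zero_tieline_gives_zero_contour_slope(self):
        m = syn.BinodalModel(k_tie=0.0)
        df, _ = syn.gen_phase_diagram(
            m, 5000,
            {"pgl3_uM": (0.05, 2.5), "rna_ng_per_uL": (1, 150),
             "mex5_uM": (0.0, 0.0)},
            seed=2,
        )
        K, _ = thermo.contour_slope_K(df)
        assert abs(K) < 2e-3

    def test_pipeline_csat_matches_model_within_w(self, default_model):
        """At zero MEX-5 the fitted boundary sits on the model binodal."""
        for rna in [5.0, 20.0, 50.0, 100.0, 140.0]:
            df, _ = syn.gen_phase_diagram(
                default_model, 2500,
                {"pgl3_uM": (0.05, 3.0), "rna_ng_per_uL": (rna - 3, rna + 3),
                 "mex5_uM": (0.0, 0.0)},
                seed=int(rna),
            )
            got = thermo.csat_dose_response(df, rna, 0.5)["csat_uM"].iloc[0]
            assert got == pytest.approx(float(default_model.c_sat(rna)),
                                        abs=default_model.w)

    def test_weaker_mex5_approaches_reference_boundary(self):
        """Raising kd_m (weaker binding) shifts the boundary monotonically
        back toward the MEX-5-free boundary."""
        ranges = {"pgl3_uM": (0.05, 2.5), "rna_ng_per_uL": (25, 35),
                  "mex5_uM": (1.0, 1.0)}
        csats = []
        for kd in [100.0, 520.0, 5000.0, 50000.0]:
            m = syn.BinodalModel(k_tie=0.02, kd_m=kd)
            df, _ = syn.gen_phase_diagram(m, 2500, ranges, seed=5)
            csats.append(
                thermo.csat_dose_response(df, 30, 0.2)["csat_uM"].iloc[0]
            )
        ref = syn.BinodalModel(k_tie=0.02).c_sat(30)
        assert np.all(np.diff(csats) < 0)
        assert csats[-1] == pytest.approx(float(ref), abs=0.05)

    def test_empty_range_rejected(self, default_model):
        with pytest.raises(ValueError):
            syn.gen_phase_diagram(
                default_model, 10,
                {"pgl3_uM": (2.0, 1.0), "rna_ng_per_uL": (1, 2),
                 "mex5_uM": (0, 0)},
            )


class TestBinaryPhaseSplit:
    def test_subcritical_chi_no_demixing(self):
        assert syn.binary_phase_split(syn.FreeEnergyBinary(chi=1.5)) is None

    def test_symmetric_compositions_sum_to_one(self):
        s = syn.binary_phase_split(syn.FreeEnergyBinary(chi=2.5), 0.5)
        assert s.psi_dil + s.psi_dense == pytest.approx(1.0, abs=1e-9)
        assert s.nu == pytest.approx(0.5, abs=1e-9)

    def test_against_grid_search_common_tangent_oracle(self):
        """Common tangent vs brute-force search on a 1e5-point grid."""
        m = syn.FreeEnergyBinary(chi=3.0)
        s = syn.binary_phase_split(m, 0.3)

        phi = np.linspace(1e-6, 1 - 1e-6, 100_001)
        f = m.f(phi)
        # brute force: for each pair of grid points on opposite flanks,
        # the common tangent minimizes the mixed free energy at phi=0.5
        left = phi < 0.5
        best = None
        for i in np.nonzero(left)[0][::200]:
            j = np.nonzero(~left)[0]
            lam = (0.5 - phi[i]) / (phi[j] - phi[i])
            mixed = (1 - lam) * f[i] + lam * f[j]
            k = int(np.argmin(mixed))
            if best is None or mixed[k] < best[0]:
                best = (mixed[k], phi[i], phi[j][k])
        # refine around the coarse winner with a dense local pass
        _, pd0, pdn0 = best
        ii = (phi > pd0 - 0.01) & (phi < pd0 + 0.01)
        jj = (phi > pdn0 - 0.01) & (phi < pdn0 + 0.01)
        pi, pj = phi[ii], phi[jj]
        lam = (0.5 - pi[:, None]) / (pj[None, :] - pi[:, None])
        mixed = (1 - lam) * f[ii][:, None] + lam * f[jj][None, :]
        a, b = np.unravel_index(np.argmin(mixed), mixed.shape)
        assert s.psi_dil == pytest.approx(pi[a], abs=1e-4)
        assert s.psi_dense == pytest.approx(pj[b], abs=1e-4)

    def test_split_lowers_free_energy(self):
        """Lever-rule mixture of the split phases never exceeds f(phi)."""
        m = syn.FreeEnergyBinary(chi=2.8, n_poly=2.0)
        s = syn.binary_phase_split(m)
        for phi_tot in np.linspace(s.psi_dil + 1e-3, s.psi_dense - 1e-3, 9):
            sp = syn.binary_phase_split(m, float(phi_tot))
            mixed = (1 - sp.nu) * m.f(sp.psi_dil) + sp.nu * m.f(sp.psi_dense)
            assert mixed <= m.f(phi_tot) + 1e-12

    def test_phi_tot_domain_error(self):
        with pytest.raises(ValueError):
            syn.binary_phase_split(syn.FreeEnergyBinary(chi=2.5), 1.5)


class TestGenPhaseImage:
    def test_flat_image_when_dn_zero(self):
        from llpskit import qpi

        f = qpi.DropletFit(dn=0.0, radius_um=2.0, xc_um=5.0, yc_um=5.0,
                           zeq_um=1.0)
        img = syn.gen_phase_image([f], shape=(64, 64), phi0=0.2)
        assert np.allclose(img.data, 0.2)

    def test_overlapping_droplets_rejected(self):
        from llpskit import qpi

        a = qpi.DropletFit(dn=0.01, radius_um=2.0, xc_um=5.0, yc_um=5.0,
                           zeq_um=1.0)
        b = qpi.DropletFit(dn=0.01, radius_um=2.0, xc_um=7.0, yc_um=5.0,
                           zeq_um=1.0)
        with pytest.raises(ValueError, match="overlap"):
            syn.gen_phase_image([a, b])

    def test_determinism(self, sessile_cap):
        a = syn.gen_phase_image([sessile_cap], noise_sd=0.01, seed=9)
        b = syn.gen_phase_image([sessile_cap], noise_sd=0.01, seed=9)
        assert np.array_equal(a.data, b.data)


class TestGenFrapSeries:
    def test_static_limit(self):
        t = np.linspace(0, 60, 7)
        ser, _ = syn.gen_frap_series(D=1e-12, L=4.0, t_grid=t)
        assert np.allclose(ser.profiles[-1], ser.profiles[0], atol=1e-6)

    def test_sine_mode_decay_closed_form(self):
        D, L = 0.056, 4.0
        t = np.linspace(0, 40, 9)
        ser, _ = syn.gen_frap_series(
            D=D, L=L, t_grid=t,
            boundary_traces=(np.zeros_like(t), np.zeros_like(t)),
            init_profile=lambda x: np.sin(np.pi * x / L),
            n_x=81,
        )
        mid = ser.profiles[:, ser.x.size // 2]
        expected = np.exp(-D * np.pi**2 * t / L**2)
        assert np.allclose(mid / mid[0], expected, rtol=2e-3)

    def test_short_boundary_traces_rejected(self):
        t = np.linspace(0, 10, 6)
        with pytest.raises(ValueError, match="boundary traces"):
            syn.gen_frap_series(D=0.05, L=4.0, t_grid=t,
                                boundary_traces=(np.zeros(3), np.zeros(3)))

    def test_determinism(self):
        t = np.linspace(0, 30, 5)
        a, _ = syn.gen_frap_series(D=0.05, L=4.0, t_grid=t, noise_sd=0.01,
                                   seed=4)
        b, _ = syn.gen_frap_series(D=0.05, L=4.0, t_grid=t, noise_sd=0.01,
                                   seed=4)
        assert np.array_equal(a.profiles, b.profiles)


class TestGenBindingCurve:
    def test_midpoint_at_kd(self):
        x = np.logspace(-2, 2, 15)
        df, _ = syn.gen_binding_curve(1.0, 2.0, 10.0, x)
        y_at_kd = np.interp(1.0, df["x"], df["y"])
        assert y_at_kd == pytest.approx(6.0, rel=1e-6)

    def test_saturation_plateau(self):
        x = np.logspace(-2, 4, 20)
        df, _ = syn.gen_binding_curve(1.0, 2.0, 10.0, x)
        assert df["y"].iloc[-1] == pytest.approx(10.0, rel=1e-3)

    def test_warns_when_grid_misses_kd(self):
        with pytest.warns(UserWarning, match="poorly identifiable"):
            syn.gen_binding_curve(100.0, 0.0, 1.0, np.logspace(-2, 0, 8))


class TestGenFluorStack:
    def test_droplet_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            syn.gen_fluor_stack([2.0], [(0.5, 5.0)], shape=(11, 64, 64))

    def test_single_sphere_geometry(self):
        stack, truth = syn.gen_fluor_stack(
            [1.0], [(6.0, 6.0)], enrichment=3.0, bulk_level=100.0,
            dark_count=50.0, shape=(15, 64, 64), pixel_size_um=0.2,
        )
        assert stack.max() == pytest.approx(350.0)
        assert stack.min() == pytest.approx(150.0)
        assert truth["bulk_volume_um3"] == pytest.approx(
            (64 * 0.2) ** 2 * 15 * 0.7
        )
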