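"""Transmission-line solver: constitutive relations, recursion, aneurysm geometry."""

import math

import numpy as np
import pytest

from aaapulse import hemodynamics as hd


BLOOD = hd.BloodProperties()


def make_segment(length=0.1, radius=5e-3, thickness=0.5e-3, emod=0.4e6,
                 terminal=False, seg_id=1, parent=None):
    return hd.ArterialSegmentSpec(
        id=seg_id, name=f"seg{seg_id}", length=length, radius=radius,
        thickness=thickness, youngs_modulus=emod, parent_id=parent,
        terminal=terminal,
    )


# ---------------------------------------------------------------------------
# aneurysm geometry
# ---------------------------------------------------------------------------


class TestAneurysmGeometry:
    def test_radius_profile_closed_form(self):
        # centre of the bump at maximal area parameter: area factor 6.25
        assert hd.aaa_radius_profile(0.0, 1.0, 5.25) == pytest.approx(2.5)
        # numerical max over the profile agrees
        x = np.linspace(-0.5, 0.5, 10001)
        assert np.max(hd.aaa_radius_profile(x, 1.0, 5.25)) == pytest.approx(2.5, rel=1e-6)

    @pytest.mark.parametrize("a_sl", [0.0, 1.0, 5.25])
    def test_radius_profile_endpoints_and_identity(self, a_sl):
        assert hd.aaa_radius_profile(-0.5, 2.0, a_sl) == pytest.approx(2.0)
        assert hd.aaa_radius_profile(0.5, 2.0, a_sl) == pytest.approx(2.0)
        if a_sl == 0.0:
            x = np.linspace(-0.5, 0.5, 101)
            np.testing.assert_allclose(hd.aaa_radius_profile(x, 2.0, 0.0), 2.0)

    def test_radius_profile_domain(self):
        with pytest.raises(ValueError):
            hd.aaa_radius_profile(0.6, 1.0, 1.0)

    def test_vsi_closed_form_matches_quadrature(self):
        # V/V0 - 1 integrates to l_aaa * a_sl / 2
        for l_aaa, a_sl in [(1.0, 5.25), (1.0, 1.575), (0.6, 2.0)]:
            x = np.linspace(-0.5, 0.5, 200001)
            area = hd.aaa_radius_profile(x, 1.0, a_sl) ** 2
            excess = l_aaa * (np.trapezoid(area, x) - 1.0)
            expected = 100.0 * excess / 2.625
            assert hd.vsi_from_geometry(l_aaa, a_sl) == pytest.approx(expected, abs=1e-6)

    def test_vsi_reference_points(self):
        assert hd.vsi_from_geometry(1.0, 5.25) == pytest.approx(100.0)
        assert hd.vsi_from_geometry(0.77, 0.0) == 0.0
        assert hd.vsi_from_geometry(1.0, 1.575) == pytest.approx(30.0)

    def test_solve_asl_roundtrip(self):
        assert hd.solve_asl(100.0, 1.0) == pytest.approx(5.25)
        assert hd.solve_asl(0.0, 0.5) == 0.0
        assert hd.solve_asl(30.0, 0.6) == pytest.approx(2.625)
        rng = np.random.default_rng(0)
        for _ in range(50):
            vsi = rng.uniform(0, 100)
            l_aaa = rng.uniform(max(0.4, vsi / 100), 1.0)
            a_sl = hd.solve_asl(vsi, l_aaa)
            assert hd.vsi_from_geometry(l_aaa, a_sl) == pytest.approx(vsi, abs=1e-10)

    def test_solve_asl_infeasible(self):
        with pytest.raises(hd.FeasibilityError):
            hd.solve_asl(90.0, 0.5)


# ---------------------------------------------------------------------------
# constitutive relations
# ---------------------------------------------------------------------------


def womersley_series(alpha: float, terms: int = 60) -> complex:
    """Independent series evaluation of F10 from the Bessel power series."""
    z = alpha * np.exp(3j * np.pi / 4)
    # J0 and J1 power series
    j0 = sum((-1) ** m * (z / 2) ** (2 * m) / math.factorial(m) ** 2
             for m in range(terms))
    j1 = sum((-1) ** m * (z / 2) ** (2 * m + 1)
             / (math.factorial(m) * math.factorial(m + 1)) for m in range(terms))
    return 2 * j1 / (z * j0)


class TestConstitutive:
    def test_poiseuille_limit(self):
        seg = make_segment()
        # alpha = 0.05 at a suitably small omega
        omega = (0.05 / seg.radius) ** 2 * BLOOD.viscosity / BLOOD.density
        z = hd.longitudinal_impedance(seg, BLOOD, omega)
        poise = 8 * BLOOD.viscosity / (np.pi * seg.radius**4)
        assert abs(z - poise) / poise < 1e-3

    def test_inertial_limit(self):
        seg = make_segment()
        omega = (60.0 / seg.radius) ** 2 * BLOOD.viscosity / BLOOD.density
        z = hd.longitudinal_impedance(seg, BLOOD, omega)
        assert abs(np.angle(z, deg=True) - 90.0) < 2.0

    @pytest.mark.parametrize("alpha", [0.5, 3.0, 10.0])
    def test_womersley_series_oracle(self, alpha):
        f10 = hd.womersley_f10(alpha)
        ref = womersley_series(alpha)
        assert abs(f10 - ref) / abs(ref) < 1e-6

    def test_wall_compliance_scaling_and_wave_speed(self):
        seg = make_segment()
        c1 = hd.wall_compliance_per_length(seg)
        seg2 = make_segment(emod=0.8e6, seg_id=2)
        assert hd.wall_compliance_per_length(seg2) == pytest.approx(c1 / 2)
        # lossless local wave speed sqrt(2 E h / (3 rho r))
        c = math.sqrt(seg.area / (BLOOD.density * c1))
        assert c == pytest.approx(
            math.sqrt(2 * 0.4e6 * 0.5e-3 / (3 * 1050 * 5e-3)), rel=1e-12
        )
        assert c == pytest.approx(5.04, abs=0.01)

    def test_wave_speed_scaling_law(self):
        # c proportional to sqrt(E / r) at fixed h
        base = make_segment()
        c0 = math.sqrt(base.area / (BLOOD.density * hd.wall_compliance_per_length(base)))
        mod = make_segment(radius=2 * base.radius, emod=2 * base.youngs_modulus, seg_id=3)
        c1 = math.sqrt(mod.area / (BLOOD.density * hd.wall_compliance_per_length(mod)))
        assert c1 / c0 == pytest.approx(1.0, rel=1e-12)

    def test_characteristic_impedance_lossless_limit(self):
        seg = make_segment()
        omega = (100.0 / seg.radius) ** 2 * BLOOD.viscosity / BLOOD.density
        zc = hd.characteristic_impedance(seg, BLOOD, omega)
        assert abs(zc.imag) / abs(zc) < 0.02
        cp = hd.wall_compliance_per_length(seg)
        c = math.sqrt(seg.area / (BLOOD.density * cp))
        assert abs(zc - BLOOD.density * c / seg.area) / abs(zc) < 0.02

    def test_propagation_phase_delay(self):
        # lossless-ish: gamma*l phase ~ omega l / c
        seg = make_segment(length=0.1)
        cp = hd.wall_compliance_per_length(seg)
        c = math.sqrt(seg.area / (BLOOD.density * cp))
        inviscid = hd.BloodProperties(density=1050.0, viscosity=1e-9)
        omega = 2 * np.pi * 1.0
        gl = hd.propagation_constant(seg, inviscid, omega) * seg.length
        assert gl.imag == pytest.approx(omega * seg.length / c, rel=1e-3)

    def test_windkessel_limits(self):
        load = hd.TerminalLoad(r_total=1e9, compliance=1e-10, proximal_fraction=0.2)
        assert hd.windkessel_impedance(load, 0.0) == pytest.approx(1e9)
        assert hd.windkessel_impedance(load, 1e9).real == pytest.approx(load.r1, rel=1e-4)
        # pole frequency: Z = R1 + R2 (1 - j)/2
        w = 1.0 / (load.r2 * load.compliance)
        z = hd.windkessel_impedance(load, w)
        assert z == pytest.approx(load.r1 + load.r2 * (1 - 1j) / 2)


# ---------------------------------------------------------------------------
# input impedance and the tree solve
# ---------------------------------------------------------------------------


def abcd_input_impedance(segs, z_load, blood, omega):
    """Independent ABCD (transfer-matrix) cascade for a chain of segments."""
    m = np.eye(2, dtype=complex)
    for seg in segs:
        zc = hd.characteristic_impedance(seg, blood, omega)
        gl = hd.propagation_constant(seg, blood, omega) * seg.length
        a = np.array([[np.cosh(gl), zc * np.sinh(gl)],
                      [np.sinh(gl) / zc, np.cosh(gl)]])
        m = m @ a
    return (m[0, 0] * z_load + m[0, 1]) / (m[1, 0] * z_load + m[1, 1])


class TestInputImpedance:
    def test_matched_line_returns_zc(self):
        seg = make_segment()
        for f in (1.0, 5.0, 20.0):
            omega = 2 * np.pi * f
            zc = hd.characteristic_impedance(seg, BLOOD, omega)
            zin = hd.input_impedance(seg, zc, BLOOD, omega)
            assert abs(zin - zc) / abs(zc) < 1e-12

    def test_quarter_wave_open_circuit(self):
        seg = make_segment(length=0.1)
        inviscid = hd.BloodProperties(density=1050.0, viscosity=1e-16)
        cp = hd.wall_compliance_per_length(seg)
        c = math.sqrt(seg.area / (BLOOD.density * cp))
        f = c / (4 * seg.length)
        omega = 2 * np.pi * f
        zc = hd.characteristic_impedance(seg, inviscid, omega)
        zin = hd.input_impedance(seg, np.inf, inviscid, omega)
        assert abs(zin) < 1e-6 * abs(zc)

    def test_two_segment_cascade_matches_abcd(self):
        s1 = make_segment(length=0.12, radius=6e-3)
        s2 = make_segment(length=0.08, radius=4e-3, seg_id=2)
        load = 5e8 + 0j
        for f in (1.0, 3.0, 10.0):
            omega = 2 * np.pi * f
            z2 = hd.input_impedance(s2, load, BLOOD, omega)
            z1 = hd.input_impedance(s1, z2, BLOOD, omega)
            ref = abcd_input_impedance([s1, s2], load, BLOOD, omega)
            assert abs(z1 - ref) / abs(ref) < 1e-10


def three_segment_tree():
    """Root bifurcating into two terminal daughters."""
    segs = {
        1: make_segment(length=0.1, radius=8e-3, thickness=0.8e-3, seg_id=1),
        2: make_segment(length=0.15, radius=5e-3, seg_id=2, parent=1, terminal=True),
        3: make_segment(length=0.12, radius=4e-3, thickness=0.4e-3, seg_id=3,
                        parent=1, terminal=True),
    }
    loads = {
        2: hd.TerminalLoad(r_total=2.5e8, compliance=5e-9),
        3: hd.TerminalLoad(r_total=4.0e8, compliance=3e-9),
    }
    sites = {"root": (1, 0.0), "d1": (2, 1.0), "d2": (3, 1.0)}
    return hd.ArterialTree(segments=segs, loads=loads, sites=sites)


class TestTreeSolve:
    def test_toy_tree_matches_abcd_oracle(self):
        tree = three_segment_tree()
        inflow = hd.aortic_inflow(75.0, 70e-6)
        sol = hd.solve_tree(tree, inflow)
        omega = inflow.periodic.omega
        c = sol.compiled
        for k in (0, 4, 14):
            w = omega[k]
            z2 = abcd_input_impedance(
                [tree.segments[2]], hd.windkessel_impedance(tree.loads[2], w), BLOOD, w)
            z3 = abcd_input_impedance(
                [tree.segments[3]], hd.windkessel_impedance(tree.loads[3], w), BLOOD, w)
            zroot = abcd_input_impedance(
                [tree.segments[1]], 1 / (1 / z2 + 1 / z3), BLOOD, w)
            assert abs(sol.z_in[c.index[1], k] - zroot) / abs(zroot) < 1e-10

    def test_bifurcation_flow_conservation(self):
        tree = three_segment_tree()
        inflow = hd.aortic_inflow(70.0, 65e-6)
        sol = hd.solve_tree(tree, inflow)
        c = sol.compiled
        q_parent = sol.flow_harmonics_at(c.index[1], 1.0).coeffs
        q_children = (sol.flow_harmonics_at(c.index[2], 0.0).coeffs
                      + sol.flow_harmonics_at(c.index[3], 0.0).coeffs)
        np.testing.assert_allclose(q_parent, q_children, rtol=1e-8)

    def test_matched_single_tube_is_delay_line(self):
        # a long tube terminated by (real) Zc behaves as a pure delay
        seg = make_segment(length=0.5, radius=6e-3, thickness=0.6e-3, terminal=True)
        inviscid = hd.BloodProperties(density=1050.0, viscosity=1e-10)
        cp = hd.wall_compliance_per_length(seg)
        c = math.sqrt(seg.area / (inviscid.density * cp))
        zc0 = inviscid.density * c / seg.area
        tree = hd.ArterialTree(
            segments={1: seg},
            loads={1: hd.TerminalLoad(r_total=zc0, compliance=1e-22,
                                      proximal_fraction=1.0 - 1e-9)},
            sites={"in": (1, 0.0), "out": (1, 1.0)},
        )
        inflow = hd.aortic_inflow(75.0, 70e-6)
        sol = hd.solve_tree(tree, inflow, inviscid)
        settings = hd.SimulationSettings()
        t = np.arange(settings.n_samples) / settings.fs
        p_in = sol.site_pressure("in").sample(t)
        p_out = sol.site_pressure("out").sample(t)
        delay = seg.length / c
        p_in_delayed = sol.site_pressure("in").sample(t - delay)
        err = np.sqrt(np.mean((p_out - p_in_delayed) ** 2)) / np.sqrt(np.mean(
            (p_in - p_in.mean()) ** 2))
        assert err < 0.01

    def test_dc_conservation(self):
        tree = three_segment_tree()
        inflow = hd.aortic_inflow(75.0, 70e-6)
        sol = hd.solve_tree(tree, inflow)
        c = sol.compiled
        mean_root = sol.site_pressure("root").mean
        r_total = sol.r_in_dc[c.index[1]]
        assert mean_root == pytest.approx(inflow.periodic.mean * r_total, rel=0.005)

    def test_nominal_subject_pressures_physiologic(self):
        tree = hd.nominal_tree()
        inflow = hd.aortic_inflow(75.0, 70e-6)
        waves = hd.simulate_pressures(tree, inflow, sites=["carotid"])
        sys = waves["carotid"].samples.max()
        assert 100.0 < sys < 180.0

    def test_non_periodic_inflow_rejected(self):
        tree = three_segment_tree()
        bad = hd.Waveform(site="ascending_aorta", kind="flow",
                          samples=np.random.default_rng(0).random(256), fs=128.0)
        with pytest.raises(ValueError):
            hd.solve_tree(tree, bad)


# ---------------------------------------------------------------------------
# aneurysm insertion into the full tree
# ---------------------------------------------------------------------------


class TestInsertAneurysm:
    def test_identity_case(self):
        tree = hd.nominal_tree()
        spec = hd.AneurysmSpec(l_aaa=1.0, a_sl=0.0, k_e=1.0, vsi=0.0)
        mod = hd.insert_aneurysm(tree, spec)
        inflow = hd.aortic_inflow(75.0, 70e-6)
        w0 = hd.simulate_pressures(tree, inflow, sites=["carotid"])["carotid"].samples
        w1 = hd.simulate_pressures(mod, inflow, sites=["carotid"])["carotid"].samples
        assert np.sqrt(np.mean((w0 - w1) ** 2)) < 1e-9

    def test_total_length_and_max_radius(self):
        tree = hd.nominal_tree()
        host = tree.segments[31]
        spec = hd.AneurysmSpec.from_vsi(100.0, 1.0, 1.5, n_subsegments=64)
        mod = hd.insert_aneurysm(tree, spec)
        new = [s for s in mod.segments.values() if s.name.startswith(host.name)]
        assert sum(s.length for s in new) == pytest.approx(host.length, rel=1e-12)
        ratio = max(s.radius for s in new) / host.radius
        # half-cell discretisation error bound at the bump centre
        assert ratio == pytest.approx(2.5, abs=2.5 - float(
            hd.aaa_radius_profile(0.5 / 64, 1.0, 5.25)))

    def test_stiffness_scaling_applied(self):
        tree = hd.nominal_tree()
        spec = hd.AneurysmSpec.from_vsi(50.0, 0.8, 2.0)
        mod = hd.insert_aneurysm(tree, spec)
        host_e = tree.segments[31].youngs_modulus
        bump = [s for s in mod.segments.values() if "_aaa" in s.name]
        assert len(bump) == spec.n_subsegments
        assert all(s.youngs_modulus == pytest.approx(2.0 * host_e) for s in bump)

    def test_discretization_convergence(self):
        tree = hd.nominal_tree()
        inflow = hd.aortic_inflow(75.0, 70e-6)
        waves = {}
        for n in (16, 32):
            spec = hd.AneurysmSpec.from_vsi(80.0, 0.9, 1.8, n_subsegments=n)
            mod = hd.insert_aneurysm(tree, spec)
            waves[n] = hd.simulate_pressures(mod, inflow, sites=["carotid"])["carotid"].samples
        rel = np.sqrt(np.mean((waves[16] - waves[32]) ** 2)) / np.sqrt(
            np.mean((waves[32] - waves[32].mean()) ** 2))
        assert rel < 0.005

    def test_missing_host_site(self):
        tree = three_segment_tree()
        spec = hd.AneurysmSpec.from_vsi(50.0, 0.8, 2.0)
        with pytest.raises(hd.ConfigurationError):
            hd.insert_aneurysm(tree, spec)


class TestInflow:
    def test_per_beat_integral_and_peak(self):
        fine = hd.SimulationSettings(fs=2048.0, duration=2.0, n_harmonics=40)
        for hr, sv in [(60.0, 80e-6), (75.0, 70e-6), (90.0, 55e-6)]:
            w = hd.aortic_inflow(hr, sv, fine)
            period = 60.0 / hr
            assert w.periodic.mean * period == pytest.approx(sv, rel=1e-10)
            t_sys = 0.3 * math.sqrt(60.0 / hr)
            assert w.samples.max() == pytest.approx(sv * np.pi / (2 * t_sys), rel=1e-5)

    def test_diastolic_samples_zero(self):
        w = hd.aortic_inflow(60.0, 70e-6)
        t_sys = 0.3 * math.sqrt(60.0 / 60.0)
        t = w.t % 1.0
        assert np.all(w.samples[t > t_sys + 1e-9] == 0.0)

    def test_stiffer_tree_has_faster_waves(self):
        # physical plausibility gate: global stiffness raises cf-PWV
        from aaapulse.features import carotid_femoral_path_length, cf_pwv

        inflow = hd.aortic_inflow(75.0, 70e-6)
        pwvs = []
        for k in (0.7, 1.0, 1.3, 1.6):
            tree = hd.nominal_tree()
            for s in tree.segments.values():
                s.youngs_modulus *= k
            waves = hd.simulate_pressures(tree, inflow, sites=["carotid", "femoral"])
            pwvs.append(cf_pwv(waves["carotid"], waves["femoral"],
                               carotid_femoral_path_length(tree), hr_hint=75.0))
        assert all(b > a for a, b in zip(pwvs, pwvs[1:]))


class TestTreeStructure:
    def test_validation_rejects_cycles_and_orphans(self):
        segs = {
            1: make_segment(seg_id=1),
            2: make_segment(seg_id=2, parent=1, terminal=True),
        }
        loads = {2: hd.TerminalLoad(r_total=1e8, compliance=1e-9)}
        hd.ArterialTree(segments=segs, loads=loads)  # valid
        bad = {1: make_segment(seg_id=1, parent=2),
               2: make_segment(seg_id=2, parent=1, terminal=True)}
        with pytest.raises(hd.ConfigurationError):
            hd.ArterialTree(segments=bad, loads=loads)

    def test_yaml_roundtrip(self, tmp_path):
        tree = hd.nominal_tree()
        path = tmp_path / "anatomy.yaml"
        tree.to_yaml(path)
        back = hd.load_anatomy(path)
        assert set(back.segments) == set(tree.segments)
        assert back.sites == tree.sites
        s0, s1 = tree.segments[31], back.segments[31]
        assert s0.radius == s1.radius and s0.length == s1.length

    def test_55_segments_with_infrarenal_host(self):
        tree = hd.nominal_tree()
        assert len(tree.segments) == 55
        sid, _ = tree.sites["TL_31"]
        assert sid == 31
        assert "abdominal" in tree.segments[31].name
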