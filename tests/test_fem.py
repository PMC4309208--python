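"""Forward-solver physics: analytic benchmark, conservation, limits.

The key verification is Terzaghi's 1-D consolidation problem: the solver
in column mode (radial displacement fixed, drainage at the top surface
only) must reproduce the closed-form pore-pressure series solution.  The
oracle below is coded independently of the solver from the textbook
series.
"""

import numpy as np
import pytest

import porodisc as pdc
from porodisc.fem import effective_stress_zz, run_protocol
from porodisc.protocol import Hold, LoadProtocol, Ramp, Sinusoid


def terzaghi_pressure(z_over_h: np.ndarray, tv: float, n_terms: int = 500) -> np.ndarray:
    """Closed-form pore pressure p/p0 for 1-D consolidation.

    Column of height h, instantaneous load at t=0, drained at the top
    (z = h), impermeable at the bottom; tv = cv t / h^2.
    """
    zeta = 1.0 - np.asarray(z_over_h)  # distance from drained boundary / h
    s = np.zeros_like(zeta, dtype=float)
    for m in range(n_terms):
        mm = 0.5 * np.pi * (2 * m + 1)
        s += 2.0 / mm * np.sin(mm * zeta) * np.exp(-mm * mm * tv)
    return s


@pytest.fixture(scope="module")
def column_setup():
    e, nu, k = 1.5, 0.3, 2.0e-16
    material = pdc.DiskMaterial(e_np=e, e_af=e, k_np=k, k_af=k, poisson=nu)
    geometry = pdc.DiskGeometry(radius=5.0, height=4.0)
    mesh = pdc.build_mesh(geometry, nr=4, nz=24)
    m_oed = e * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    cv = k * 1e12 * m_oed  # mm^2/s
    return mesh, material, cv


@pytest.mark.parametrize("tv", [0.1, 0.5, 1.0])
def test_terzaghi_consolidation_profile(column_setup, tv):
    """Pore-pressure profile matches the analytic series within 1% L2."""
    mesh, material, cv = column_setup
    h = mesh.geometry.height
    p0 = 0.1
    t_end = tv * h * h / cv
    protocol = LoadProtocol((Hold(p0, t_end, t_end / 800),))
    sol = run_protocol(mesh, material, protocol, p_boundary=0.0, mode="column")
    axis = np.flatnonzero(mesh.coords_p[:, 0] < 1e-9)
    z = mesh.coords_p[axis, 1] / h
    p_num = sol.stored_p[-1][axis]
    p_ana = p0 * terzaghi_pressure(z, tv)
    l2 = np.sqrt(np.mean((p_num - p_ana) ** 2)) / p0
    assert l2 < 0.01


@pytest.fixture(scope="module")
def sweep_solution(intact_mean):
    """Full preload + 6-frequency sweep on the mean intact disk."""
    settings = pdc.SweepSettings()
    mesh = pdc.build_mesh(
        intact_mean.geometry, nr=settings.nr, nz=settings.nz,
        radial_grading=settings.radial_grading,
    )
    sol = run_protocol(
        mesh, intact_mean.true_material, settings.protocol(),
        p_boundary=settings.p_boundary,
    )
    return mesh, sol


def test_fluid_mass_conservation(sweep_solution):
    """Interior fluid-continuity imbalance stays below 1e-6 of the disk
    fluid volume at every time step."""
    _, sol = sweep_solution
    assert sol.mass_balance_error < 1e-6


def test_peak_to_peak_non_increasing_with_frequency(sweep_solution):
    """Apparent stiffness grows with loading rate: the last-cycle
    peak-to-peak deformation never increases along the ascending sweep."""
    mesh, sol = sweep_solution
    out = pdc.extract_scalars(sol, mesh)
    assert np.all(np.diff(out.peak_to_peak) <= 1e-8 * out.peak_to_peak[0])


def test_creep_during_preload_hold(sweep_solution):
    """Consolidation creep: compression keeps growing during the hold."""
    _, sol = sweep_solution
    hold = sol.segment_index == 1
    disp = sol.platen_displacement[hold]
    assert np.all(np.diff(disp) <= 0)  # monotone further compression
    assert disp[-1] < disp[0]
    loss = sol.cumulative_fluid_loss
    assert loss[0] == 0.0
    assert loss[-1] > 0.0


def test_drained_equilibrium_uniform_stress():
    """With fast drainage and a long hold, excess pressure vanishes and
    the effective axial stress is uniform at the applied level."""
    e, k = 2.0, 1.0e-13  # high permeability -> minutes-scale drainage
    material = pdc.DiskMaterial(e_np=e, e_af=e, k_np=k, k_af=k, poisson=0.3)
    geometry = pdc.DiskGeometry(radius=5.0, height=4.0)
    mesh = pdc.build_mesh(geometry, nr=6, nz=4)
    p_apply = 0.1
    protocol = LoadProtocol(
        (Ramp(0.0, p_apply, 10.0, 1.0), Hold(p_apply, 990.0, 5.0))
    )
    sol = run_protocol(mesh, material, protocol, p_boundary=0.3)
    assert sol.idp[-1] == pytest.approx(0.3, abs=1e-6)  # back to boundary value
    szz = effective_stress_zz(mesh, material, sol.stored_u[-1])
    assert np.allclose(szz, -p_apply, atol=1e-4)


def test_undrained_limit_matches_incompressible_stiffness():
    """As k -> 0 the instantaneous response is undrained: the platen
    displacement matches the incompressible elastic solution
    -P h / E_u with E_u = 3E / (2(1 + nu)), and the fluid expelled is a
    vanishing boundary artefact (clamped-pressure nodes) that shrinks
    under mesh refinement."""
    e, nu, p, k = 1.5, 0.3, 0.1, 1.0e-22
    material = pdc.DiskMaterial(e_np=e, e_af=e, k_np=k, k_af=k, poisson=nu)
    geometry = pdc.DiskGeometry(radius=5.0, height=4.0)
    protocol = LoadProtocol((Ramp(0.0, p, 1.0, 0.5),))
    e_undrained = 3 * e / (2 * (1 + nu))
    expected = -p * geometry.height / e_undrained

    losses = []
    for nr, nz in ((6, 4), (12, 8)):
        mesh = pdc.build_mesh(geometry, nr=nr, nz=nz)
        sol = run_protocol(mesh, material, protocol, p_boundary=0.3)
        assert sol.platen_displacement[-1] == pytest.approx(expected, rel=0.02)
        losses.append(sol.cumulative_fluid_loss[-1] / mesh.fluid_volume())
    assert losses[0] < 5e-3
    assert losses[1] < 0.6 * losses[0]


def test_small_strain_linearity_of_peak_to_peak(intact_mean):
    """Doubling the cyclic amplitude doubles the last-cycle peak-to-peak
    deformation (linear kinematics), within 5%."""
    g, m = intact_mean.geometry, intact_mean.true_material
    mesh = pdc.build_mesh(g, nr=8, nz=4, radial_grading=0.8)

    def p2p(p_max):
        prot = LoadProtocol(
            (Sinusoid(0.1, p_max, 1.0, 30.0, 0.05),)
        )
        sol = run_protocol(mesh, m, prot)
        return pdc.extract_scalars(sol, mesh).peak_to_peak_final

    a = p2p(0.8)   # amplitude 0.35 MPa
    b = p2p(1.5)   # amplitude 0.70 MPa
    assert b / a == pytest.approx(2.0, rel=0.05)


def test_refinement_changes_scalars_below_two_percent(convergence_runs):
    """Doubling nr, nz and the time resolution changes every reported
    scalar by less than 2%."""
    base, refined = convergence_runs
    for name in ("peak_to_peak_final", "idp", "total_fluid_loss", "max_axial_stress"):
        b = float(getattr(base, name))
        r = float(getattr(refined, name))
        assert abs(r - b) / abs(b) < 0.02, name


class TestExtractScalars:
    def test_hold_only_protocol_has_zero_peak_to_peak(self, small_geometry):
        material = pdc.DiskMaterial.from_identified(1.5, 2.0e-16)
        mesh = pdc.build_mesh(small_geometry, nr=4, nz=2)
        protocol = LoadProtocol((Hold(0.1, 50.0, 5.0),))
        sol = run_protocol(mesh, material, protocol)
        out = pdc.extract_scalars(sol, mesh)
        assert out.peak_to_peak.size == 0
        assert out.peak_to_peak_final == 0.0
        assert out.idp > 0.0

    def test_incomplete_cycle_rejected(self, small_geometry):
        material = pdc.DiskMaterial.from_identified(1.5, 2.0e-16)
        mesh = pdc.build_mesh(small_geometry, nr=4, nz=2)
        protocol = LoadProtocol((Sinusoid(0.1, 0.8, 0.01, 50.0, 5.0),))
        sol = run_protocol(mesh, material, protocol)
        with pytest.raises(ValueError, match="cycle"):
            pdc.extract_scalars(sol, mesh)
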