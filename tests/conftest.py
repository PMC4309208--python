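"""Shared fixtures.

The expensive session fixtures (frequency study, refinement convergence,
parameter-recovery study) are computed once and shared between the
module tests and the acceptance tests.
"""

from __future__ import annotations

import pytest

import porodisc as pdc


@pytest.fixture(scope="session")
def intact_mean():
    """Representative intact disk (group means)."""
    return pdc.mean_specimen("intact")


@pytest.fixture(scope="session")
def degen_mean():
    """Representative enzyme-degenerated disk (group means)."""
    return pdc.mean_specimen("degenerated")


@pytest.fixture(scope="session")
def small_geometry():
    return pdc.DiskGeometry(radius=5.0, height=4.0)


@pytest.fixture(scope="session")
def freq_study_result(intact_mean, degen_mean):
    """Frequency parametric study on the two representative disks
    (0.01/0.1/1/10 Hz, 300 s cyclic phase)."""
    return pdc.run_frequency_study(
        (intact_mean.geometry, intact_mean.true_material),
        (degen_mean.geometry, degen_mean.true_material),
    )


def _cyclic_scalars(geometry, material, frequency, duration, **kw):
    mesh = pdc.build_mesh(
        geometry,
        nr=kw.get("nr", 24),
        nz=kw.get("nz", 6),
        radial_grading=kw.get("radial_grading", 0.8),
    )
    protocol = pdc.cyclic_protocol(
        frequency, duration, steps_per_cycle=kw.get("steps_per_cycle", 20)
    )
    sol = pdc.run_protocol(mesh, material, protocol)
    return pdc.extract_scalars(sol, mesh), sol


@pytest.fixture(scope="session")
def convergence_runs(intact_mean):
    """Baseline vs (2x nr, 2x nz, 2x time resolution) cyclic run at 0.1 Hz."""
    g, m = intact_mean.geometry, intact_mean.true_material
    base, _ = _cyclic_scalars(g, m, 0.1, 300.0)
    refined, _ = _cyclic_scalars(
        g, m, 0.1, 300.0, nr=48, nz=12, steps_per_cycle=40
    )
    return base, refined


@pytest.fixture(scope="session")
def recovery_study():
    """End-to-end parameter recovery: synthetic specimens at 2% noise,
    5 per group, identified with the DOE + response-surface loop."""
    out = []
    for group in ("intact", "degenerated"):
        cohort = pdc.make_cohort(group, n=5, seed=0, noise_cv=0.02)
        for sp in cohort:
            fwd = pdc.sweep_forward_fn(sp.geometry)
            res = pdc.backward_identify(
                sp.observed, fwd, pdc.default_window(group)
            )
            out.append(
                {
                    "specimen": sp.specimen_id,
                    "group": group,
                    "e_true": sp.true_e_np,
                    "k_true": sp.true_k,
                    "e_hat": res.e_np_opt,
                    "k_hat": res.k_opt,
                    "rms_pct": res.rms_pct_final,
                    "converged": res.converged,
                }
            )
    return out


@pytest.fixture(scope="session")
def quick_sweep_settings():
    """Coarse, fast sweep settings for plumbing tests (two frequencies,
    short segments, small mesh)."""
    return pdc.SweepSettings(
        frequencies=(0.1, 1.0),
        segment_duration=100.0,
        steps_per_cycle=10,
        nr=4,
        nz=2,
        radial_grading=1.0,
    )
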