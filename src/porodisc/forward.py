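"""Convenience drivers around the FE solver.

These wrap mesh construction, the standard preload + frequency-sweep
protocol and scalar extraction into single calls, and provide the
forward function consumed by the inverse identification.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .disk import DiskGeometry, DiskMaterial
from .fem import run_protocol
from .mesh import build_mesh
from .outputs import ScalarOutputs, extract_scalars
from .protocol import SWEEP_FREQUENCIES_HZ, sweep_protocol

__all__ = ["simulate_sweep", "sweep_forward_fn", "SweepSettings"]


class SweepSettings:
    """Resolved settings for a peak-to-peak frequency sweep simulation.

    Parameters
    ----------
    frequencies : sweep frequencies in Hz, run consecutively ascending.
    segment_duration : s per frequency segment (default 300).
    steps_per_cycle : time steps resolving one period (default 20,
        matching increments of 5/0.5/0.05/0.005 s at 0.01/0.1/1/10 Hz).
    nr, nz : mesh resolution (default 24 x 6 = 144 elements).
    radial_grading : radial width ratio (default 0.8, finer toward the
        draining outer surface to resolve the pressure boundary layer).
    p_boundary : imposed boundary pore pressure, MPa (default 0.3).
    """

    def __init__(
        self,
        frequencies: Sequence[float] = SWEEP_FREQUENCIES_HZ,
        segment_duration: float = 300.0,
        steps_per_cycle: int = 20,
        nr: int = 24,
        nz: int = 6,
        radial_grading: float = 0.8,
        p_boundary: float = 0.3,
        p_min: float = 0.1,
        p_max: float = 0.8,
        include_preload: bool = True,
    ):
        self.frequencies = tuple(sorted(frequencies))
        self.segment_duration = segment_duration
        self.steps_per_cycle = steps_per_cycle
        self.nr = nr
        self.nz = nz
        self.radial_grading = radial_grading
        self.p_boundary = p_boundary
        self.p_min = p_min
        self.p_max = p_max
        self.include_preload = include_preload

    def protocol(self):
        return sweep_protocol(
            frequencies=self.frequencies,
            segment_duration=self.segment_duration,
            p_min=self.p_min,
            p_max=self.p_max,
            steps_per_cycle=self.steps_per_cycle,
            include_preload=self.include_preload,
        )


def simulate_sweep(
    geometry: DiskGeometry,
    material: DiskMaterial,
    settings: SweepSettings | None = None,
) -> ScalarOutputs:
    """Run the preload + frequency sweep and return scalar outputs.

    ``outputs.peak_to_peak`` holds one value per frequency (ascending),
    from the final full cycle of each segment.
    """
    settings = settings or SweepSettings()
    mesh = build_mesh(geometry, nr=settings.nr, nz=settings.nz,
                      radial_grading=settings.radial_grading)
    sol = run_protocol(
        mesh, material, settings.protocol(), p_boundary=settings.p_boundary
    )
    return extract_scalars(sol, mesh)


def sweep_forward_fn(
    geometry: DiskGeometry,
    settings: SweepSettings | None = None,
    poisson: float = 0.3,
) -> Callable[[float, float], np.ndarray]:
    """Build the forward function (e_np, k) -> peak-to-peak per frequency.

    The returned callable applies the constrained material builder
    (E_AF = 1.67 E_NP, k_AF = k_NP) and runs the sweep; it is the
    simulator the DOE and inverse identification drive.
    """
    settings = settings or SweepSettings()
    mesh = build_mesh(geometry, nr=settings.nr, nz=settings.nz,
                      radial_grading=settings.radial_grading)
    protocol = settings.protocol()

    def forward(e_np: float, k: float) -> np.ndarray:
        material = DiskMaterial.from_identified(e_np, k, poisson=poisson)
        sol = run_protocol(mesh, material, protocol, p_boundary=settings.p_boundary)
        return extract_scalars(sol, mesh).peak_to_peak

    return forward
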