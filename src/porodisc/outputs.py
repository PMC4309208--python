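"""Field solutions and derived scalar outputs of a forward run."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .protocol import LoadProtocol, Sinusoid

if TYPE_CHECKING:  # pragma: no cover
    from .disk import DiskMaterial
    from .mesh import Mesh

__all__ = ["FieldSolution", "ScalarOutputs", "extract_scalars"]


@dataclass
class FieldSolution:
    """Time history of a forward simulation.

    Per-step scalars are stored for every step (index 0 is the initial
    state at t = 0); full displacement/pressure fields only for
    ``stored_steps`` (the final full cycle of each sinusoid segment and
    the last step).

    Attributes
    ----------
    times : (N+1,) s, strictly increasing, times[0] = 0.
    applied_pressure : (N+1,) MPa nominal platen pressure.
    platen_displacement : (N+1,) mm axial displacement of the rigid top
        platen (negative in compression).
    idp : (N+1,) MPa absolute pore pressure at the nucleus centre.
    cumulative_fluid_loss : (N+1,) mm^3 net fluid expelled through the
        draining boundary since the protocol start.
    stored_u : (n_stored, n_unodes, 2) mm nodal displacements.
    stored_p : (n_stored, n_pnodes) MPa absolute pore pressure.
    mass_balance_error : worst per-step interior fluid-continuity
        imbalance, relative to the disk fluid volume.
    """

    times: np.ndarray
    applied_pressure: np.ndarray
    segment_index: np.ndarray
    platen_displacement: np.ndarray
    idp: np.ndarray
    cumulative_fluid_loss: np.ndarray
    stored_steps: np.ndarray
    stored_u: np.ndarray
    stored_p: np.ndarray
    mass_balance_error: float
    p_boundary: float
    protocol: LoadProtocol
    mesh: "Mesh"
    material: "DiskMaterial"

    def final_cycle_mask(self, segment: int) -> np.ndarray:
        """Boolean mask over times selecting the final full cycle of a
        sinusoid segment (by protocol segment index)."""
        seg = self.protocol.segments[segment]
        if not isinstance(seg, Sinusoid):
            raise ValueError(f"segment {segment} is not a sinusoid")
        if seg.n_cycles < 1.0 - 1e-9:
            raise ValueError(
                f"segment {segment} contains no complete cycle "
                f"({seg.n_cycles:.3g} cycles)"
            )
        t_end = sum(s.duration for s in self.protocol.segments[: segment + 1])
        return (self.segment_index == segment) & (
            self.times > t_end - seg.period - 1e-9
        )


@dataclass(frozen=True)
class ScalarOutputs:
    """Scalar summary of a cyclic run.

    ``peak_to_peak`` is ordered as the sinusoid segments in the protocol
    (one value per segment, over its final full cycle).
    """

    frequencies: np.ndarray      # Hz, one per sinusoid segment
    peak_to_peak: np.ndarray     # mm
    idp: float                   # MPa, peak nucleus-centre pressure, final cycle
    total_fluid_loss: float      # mm^3 at protocol end
    max_axial_stress: float      # MPa, peak compressive |sigma'_zz|, final cycle

    @property
    def peak_to_peak_final(self) -> float:
        return float(self.peak_to_peak[-1]) if self.peak_to_peak.size else 0.0


def extract_scalars(solution: FieldSolution, mesh: "Mesh | None" = None) -> ScalarOutputs:
    """Reduce a FieldSolution to the reported scalar outputs.

    peak-to-peak deformation per sinusoid segment (max - min of platen
    displacement over the segment's final full cycle); intradiscal
    pressure (peak nucleus-centre pore pressure over the final cycle of
    the last sinusoid segment); total fluid loss at protocol end; and the
    maximum compressive effective axial stress over that final cycle.
    For a protocol without any sinusoid segment the final time step
    stands in for the "final cycle" and peak-to-peak is empty.
    """
    from .fem import effective_stress_zz

    mesh = mesh if mesh is not None else solution.mesh
    sin_idx = [
        i for i, s in enumerate(solution.protocol.segments) if isinstance(s, Sinusoid)
    ]
    freqs, p2p = [], []
    for i in sin_idx:
        mask = solution.final_cycle_mask(i)
        if not mask.any():
            raise ValueError(f"no stored steps in final cycle of segment {i}")
        disp = solution.platen_displacement[mask]
        freqs.append(solution.protocol.segments[i].frequency)
        p2p.append(float(disp.max() - disp.min()))

    if sin_idx:
        last_mask = solution.final_cycle_mask(sin_idx[-1])
    else:
        last_mask = np.zeros_like(solution.times, dtype=bool)
        last_mask[-1] = True
    idp = float(solution.idp[last_mask].max())

    # stress over the stored fields that fall inside the final cycle
    stored_in_cycle = np.flatnonzero(last_mask[solution.stored_steps])
    if stored_in_cycle.size == 0:
        stored_in_cycle = np.array([len(solution.stored_steps) - 1])
    max_stress = 0.0
    for j in stored_in_cycle:
        szz = effective_stress_zz(mesh, solution.material, solution.stored_u[j])
        max_stress = max(max_stress, float(-szz.min()))

    return ScalarOutputs(
        frequencies=np.asarray(freqs),
        peak_to_peak=np.asarray(p2p),
        idp=idp,
        total_fluid_loss=float(solution.cumulative_fluid_loss[-1]),
        max_axial_stress=max_stress,
    )
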