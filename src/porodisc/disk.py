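"""Disk geometry and material definitions.

The disk is modelled as an axisymmetric two-region cylinder: an inner
nucleus pulposus (NP) core surrounded by an anulus fibrosus (AF) ring.
Each region is a linear poroelastic (Biot) material characterised by a
drained elastic modulus E (MPa), Poisson's ratio nu, and a constant
isotropic hydraulic permeability k.

Units
-----
The package works internally in an mm-N-s-MPa system.  Hydraulic
permeability is conventionally quoted in m^4/(N s); the conversion to the
internal mm^4/(N s) is a factor of 1e12 (``K_M4_NS_TO_MM4_NS``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "DiskGeometry",
    "DiskMaterial",
    "K_M4_NS_TO_MM4_NS",
    "AF_TO_NP_MODULUS_RATIO",
]

#: multiply a permeability in m^4/(N s) by this to get mm^4/(N s)
K_M4_NS_TO_MM4_NS = 1.0e12

#: fixed ratio E_AF / E_NP used by the constrained two-parameter material
AF_TO_NP_MODULUS_RATIO = 1.67


@dataclass(frozen=True)
class DiskGeometry:
    """Axisymmetric two-region disk geometry.

    Parameters
    ----------
    radius : float
        Outer disk radius in mm (geometric mean of long/short axes for a
        real, slightly elliptical disk).
    height : float
        Disk height in mm.
    np_radius_fraction : float
        Radial extent of the nucleus region as a fraction of ``radius``.
    porosity_af, porosity_np : float
        Fluid volume fractions of the anulus and nucleus, in (0, 1).
    """

    radius: float
    height: float
    np_radius_fraction: float = 0.55
    porosity_af: float = 0.80
    porosity_np: float = 0.92

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if not 0.0 < self.np_radius_fraction < 1.0:
            raise ValueError(
                f"np_radius_fraction must be in (0, 1), got {self.np_radius_fraction}"
            )
        for name in ("porosity_af", "porosity_np"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @property
    def face_area(self) -> float:
        """Disk cross-sectional (platen) area in mm^2."""
        import math

        return math.pi * self.radius**2

    @property
    def volume(self) -> float:
        """Disk volume in mm^3."""
        return self.face_area * self.height

    @property
    def fluid_volume(self) -> float:
        """Total interstitial fluid volume in mm^3 (porosity-weighted)."""
        import math

        r_np = self.np_radius_fraction * self.radius
        v_np = math.pi * r_np**2 * self.height
        v_af = self.volume - v_np
        return self.porosity_np * v_np + self.porosity_af * v_af


@dataclass(frozen=True)
class DiskMaterial:
    """Poroelastic material parameters for the two disk regions.

    Moduli in MPa, permeabilities in m^4/(N s) (converted internally).
    """

    e_np: float
    e_af: float
    k_np: float
    k_af: float
    poisson: float = 0.3

    def __post_init__(self) -> None:
        for name in ("e_np", "e_af", "k_np", "k_af"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError(f"poisson must be in [0, 0.5), got {self.poisson}")

    @classmethod
    def from_identified(
        cls, e_np: float, k: float, poisson: float = 0.3
    ) -> "DiskMaterial":
        """Build the constrained two-parameter material.

        The inverse analysis identifies only (E_NP, k); the anulus modulus
        follows the fixed ratio E_AF = 1.67 E_NP and both regions share the
        same permeability (k_AF = k_NP = k).
        """
        return cls(
            e_np=e_np,
            e_af=AF_TO_NP_MODULUS_RATIO * e_np,
            k_np=k,
            k_af=k,
            poisson=poisson,
        )

    def with_poisson(self, poisson: float) -> "DiskMaterial":
        return replace(self, poisson=poisson)

    @property
    def k_np_mm(self) -> float:
        """NP permeability in internal units, mm^4/(N s)."""
        return self.k_np * K_M4_NS_TO_MM4_NS

    @property
    def k_af_mm(self) -> float:
        """AF permeability in internal units, mm^4/(N s)."""
        return self.k_af * K_M4_NS_TO_MM4_NS
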