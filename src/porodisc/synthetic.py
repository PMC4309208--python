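"""Synthetic cohorts emulating the porcine cyclic-loading study.

Disk geometry and ground-truth material parameters are drawn from
truncated Gaussian distributions with the measured group means and SDs
(intact vs. enzyme-degenerated, nine specimens per group).  Observed
peak-to-peak deformations are forward-simulated at the sweep frequencies
and corrupted with multiplicative Gaussian measurement noise, so that
every downstream stage — identification, cohort statistics, the
frequency study — can be exercised without any external data.

Cohort parameter defaults (mean, SD):

===============  ============  =============
quantity         intact        degenerated
===============  ============  =============
radius (mm)      13.18 (0.32)  13.29 (0.27)
height (mm)      4.21 (0.34)   2.95 (0.28)
porosity AF      0.80 (0.03)   0.78 (0.04)
porosity NP      0.92 (0.04)   0.86 (0.05)
E_NP (MPa)       1.41 (0.17)   1.30 (0.14)
k (m^4/(N s))    2.17 (0.36)   1.39 (0.29)  [x 1e-16]
===============  ============  =============
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .disk import DiskGeometry, DiskMaterial
from .forward import SweepSettings, simulate_sweep

__all__ = [
    "CohortSpec",
    "SyntheticSpecimen",
    "default_cohort_spec",
    "sample_cohort",
    "simulate_observations",
    "make_cohort",
    "mean_specimen",
]

_GROUPS = ("intact", "degenerated")

_GEOMETRY_STATS = {
    "intact": {
        "radius": (13.18, 0.32),
        "height": (4.21, 0.34),
        "porosity_af": (0.80, 0.03),
        "porosity_np": (0.92, 0.04),
    },
    "degenerated": {
        "radius": (13.29, 0.27),
        "height": (2.95, 0.28),
        "porosity_af": (0.78, 0.04),
        "porosity_np": (0.86, 0.05),
    },
}

_MATERIAL_STATS = {
    "intact": {"e_np": (1.41, 0.17), "k": (2.17e-16, 0.36e-16)},
    "degenerated": {"e_np": (1.30, 0.14), "k": (1.39e-16, 0.29e-16)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for one study group.

    Each field distribution is (mean, sd); draws are truncated to the
    physical range (positive lengths and moduli, porosities in (0, 1)).
    ``noise_cv`` is the coefficient of variation of the multiplicative
    measurement noise applied to simulated observations.
    """

    group: str
    n: int = 9
    radius: tuple[float, float] = (13.18, 0.32)
    height: tuple[float, float] = (4.21, 0.34)
    porosity_af: tuple[float, float] = (0.80, 0.03)
    porosity_np: tuple[float, float] = (0.92, 0.04)
    e_np: tuple[float, float] = (1.41, 0.17)
    k: tuple[float, float] = (2.17e-16, 0.36e-16)
    noise_cv: float = 0.02
    seed: int = 0
    np_radius_fraction: float = 0.55
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {_GROUPS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name in ("radius", "height", "porosity_af", "porosity_np", "e_np", "k"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")
            if mean <= 0:
                raise ValueError(f"{name}: mean must be > 0")


@dataclass
class SyntheticSpecimen:
    """One synthetic disk: geometry, hidden truth, observed sweep."""

    specimen_id: str
    group: str
    geometry: DiskGeometry
    true_material: DiskMaterial
    frequencies: np.ndarray | None = None    # Hz
    observed: np.ndarray | None = None       # peak-to-peak, mm
    simulated: np.ndarray | None = None      # noise-free forward output, mm

    @property
    def true_e_np(self) -> float:
        return self.true_material.e_np

    @property
    def true_k(self) -> float:
        return self.true_material.k_np


def default_cohort_spec(group: str, n: int = 9, noise_cv: float = 0.02, seed: int = 0) -> CohortSpec:
    """CohortSpec populated with the measured group statistics."""
    if group not in _GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {_GROUPS}")
    g = _GEOMETRY_STATS[group]
    m = _MATERIAL_STATS[group]
    return CohortSpec(
        group=group,
        n=n,
        radius=g["radius"],
        height=g["height"],
        porosity_af=g["porosity_af"],
        porosity_np=g["porosity_np"],
        e_np=m["e_np"],
        k=m["k"],
        noise_cv=noise_cv,
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled Gaussian draw truncated to (lo, hi)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError(
        f"truncated sampling failed for N({mean}, {sd}) on ({lo}, {hi})"
    )


def sample_cohort(spec: CohortSpec) -> list[SyntheticSpecimen]:
    """Draw n specimens (geometry + hidden truth, no observations yet).

    Reproducible from ``spec.seed``; fields are drawn independently
    (no reported covariances to honour).
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n):
        geometry = DiskGeometry(
            radius=_truncated_normal(rng, *spec.radius, 0.0, np.inf),
            height=_truncated_normal(rng, *spec.height, 0.0, np.inf),
            np_radius_fraction=spec.np_radius_fraction,
            porosity_af=_truncated_normal(rng, *spec.porosity_af, 0.0, 1.0),
            porosity_np=_truncated_normal(rng, *spec.porosity_np, 0.0, 1.0),
        )
        material = DiskMaterial.from_identified(
            e_np=_truncated_normal(rng, *spec.e_np, 0.0, np.inf),
            k=_truncated_normal(rng, *spec.k, 0.0, np.inf),
            poisson=spec.poisson,
        )
        out.append(
            SyntheticSpecimen(
                specimen_id=f"{spec.group}-{i + 1:02d}",
                group=spec.group,
                geometry=geometry,
                true_material=material,
            )
        )
    return out


def simulate_observations(
    specimen: SyntheticSpecimen,
    settings: SweepSettings | None = None,
    noise_cv: float = 0.02,
    seed: int = 0,
) -> SyntheticSpecimen:
    """Forward-simulate the sweep and attach noisy observations.

    observed(f) = simulated(f) * (1 + eps_f) with eps_f ~ N(0, noise_cv^2)
    i.i.d. across frequencies, seeded.
    """
    settings = settings or SweepSettings()
    outputs = simulate_sweep(specimen.geometry, specimen.true_material, settings)
    sim = outputs.peak_to_peak
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_cv, size=sim.shape) if noise_cv > 0 else np.zeros_like(sim)
    return replace(
        specimen,
        frequencies=np.asarray(settings.frequencies, dtype=float),
        simulated=sim,
        observed=sim * (1.0 + eps),
    )


def make_cohort(
    group: str,
    n: int = 9,
    seed: int = 0,
    noise_cv: float = 0.02,
    settings: SweepSettings | None = None,
    with_observations: bool = True,
) -> list[SyntheticSpecimen]:
    """Sample a cohort and (optionally) simulate its observations.

    Per-specimen observation seeds are derived from the cohort seed.
    """
    spec = default_cohort_spec(group, n=n, noise_cv=noise_cv, seed=seed)
    cohort = sample_cohort(spec)
    if with_observations:
        ss = np.random.SeedSequence([seed, _GROUPS.index(group)])
        child_seeds = ss.generate_state(n)
        cohort = [
            simulate_observations(
                sp, settings=settings, noise_cv=noise_cv, seed=int(child_seeds[i] % 2**31)
            )
            for i, sp in enumerate(cohort)
        ]
    return cohort


def mean_specimen(group: str) -> SyntheticSpecimen:
    """The group-representative disk: all fields at their group means."""
    g = _GEOMETRY_STATS[group]
    m = _MATERIAL_STATS[group]
    geometry = DiskGeometry(
        radius=g["radius"][0],
        height=g["height"][0],
        porosity_af=g["porosity_af"][0],
        porosity_np=g["porosity_np"][0],
    )
    material = DiskMaterial.from_identified(m["e_np"][0], m["k"][0])
    return SyntheticSpecimen(
        specimen_id=f"{group}-mean",
        group=group,
        geometry=geometry,
        true_material=material,
    )
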