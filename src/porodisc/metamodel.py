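"""Inverse identification of (E_NP, k) by DOE + quadratic response surface.

The identification matches simulated peak-to-peak deformations at the
sweep frequencies to observed ones.  One round:

1. full-factorial design over the current search window (5 levels per
   factor, 25 forward simulations),
2. normalized RMS error (%) of each simulated sweep against the data,
3. ordinary least squares fit of a six-term quadratic response surface
   (QRS) to RMS over the factors scaled to [-1, 1],
4. deterministic minimization of the quadratic over the closed box,
5. re-simulation at the surrogate optimum; the reported RMS is always
   this re-simulated value, never the surrogate prediction.

The identification is accepted when the re-simulated RMS error is below
5%; otherwise the window is recentred on the incumbent optimum, widened
by 50% per factor (clipped to positive values), and the round repeats.
The incumbent after each round is the best of the surrogate optimum and
all DOE points, so the final RMS never exceeds the best DOE sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .disk import AF_TO_NP_MODULUS_RATIO, DiskGeometry

__all__ = [
    "SearchWindow",
    "DoeRecord",
    "IdentificationResult",
    "QuadraticResponseSurface",
    "full_factorial",
    "rms_error",
    "minimize_qrs",
    "backward_identify",
    "DiskParameterIdentifier",
    "default_window",
]

RMS_THRESHOLD_PCT = 5.0

#: initial search windows: E_NP in MPa, k in m^4/(N s)
_INITIAL_WINDOWS = {
    "intact": ((1.2, 1.8), (1.56e-16, 2.34e-16)),
    "degenerated": ((1.2, 1.8), (1.18e-16, 1.76e-16)),
}


@dataclass(frozen=True)
class SearchWindow:
    """Box over the two identified factors with a factorial level count."""

    e_np_range: tuple[float, float]
    k_range: tuple[float, float]
    levels: int = 5

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("e_np_range", self.e_np_range), ("k_range", self.k_range)):
            if not lo < hi:
                raise ValueError(f"{name}: need lo < hi, got ({lo}, {hi})")
            if not lo > 0:
                raise ValueError(f"{name}: need positive range, got lo={lo}")
        if self.levels < 3:
            raise ValueError(f"levels must be >= 3, got {self.levels}")

    def scale(self, pts: np.ndarray) -> np.ndarray:
        """Map raw (e_np, k) points to the [-1, 1]^2 box."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty_like(pts)
        for j, (lo, hi) in enumerate((self.e_np_range, self.k_range)):
            out[:, j] = 2.0 * (pts[:, j] - lo) / (hi - lo) - 1.0
        return out

    def unscale(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty_like(pts)
        for j, (lo, hi) in enumerate((self.e_np_range, self.k_range)):
            out[:, j] = lo + 0.5 * (pts[:, j] + 1.0) * (hi - lo)
        return out

    def contains(self, e_np: float, k: float) -> bool:
        return (
            self.e_np_range[0] <= e_np <= self.e_np_range[1]
            and self.k_range[0] <= k <= self.k_range[1]
        )

    def expanded_around(self, e_np: float, k: float, widen: float = 1.5) -> "SearchWindow":
        """Recentre on (e_np, k) and widen each range by ``widen``.

        Lower bounds are clipped to stay strictly positive (at 1e-3 of
        the new upper bound), keeping moduli and permeabilities physical.
        """
        ranges = []
        for (lo, hi), c in ((self.e_np_range, e_np), (self.k_range, k)):
            half = 0.5 * widen * (hi - lo)
            new_lo, new_hi = c - half, c + half
            new_lo = max(new_lo, 1e-3 * new_hi)
            ranges.append((new_lo, new_hi))
        return SearchWindow(tuple(ranges[0]), tuple(ranges[1]), self.levels)


def full_factorial(window: SearchWindow) -> np.ndarray:
    """levels^2 factorial points, E outer loop, k inner, each factor on
    ``levels`` equally spaced values spanning its range inclusive."""
    e_vals = np.linspace(*window.e_np_range, window.levels)
    k_vals = np.linspace(*window.k_range, window.levels)
    return np.array(list(itertools.product(e_vals, k_vals)))


def rms_error(simulated: Sequence[float], observed: Sequence[float]) -> float:
    """Normalized RMS error in percent.

    100 * sqrt(mean((sim - obs)^2)) / mean(obs): root-mean-square
    deviation over the sweep frequencies, normalized by the mean observed
    peak-to-peak deformation.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"length mismatch: {sim.shape} vs {obs.shape}")
    mean_obs = obs.mean()
    if not mean_obs > 0:
        raise ValueError("mean of observed deformations must be > 0")
    return float(100.0 * np.sqrt(np.mean((sim - obs) ** 2)) / mean_obs)


@dataclass(frozen=True)
class DoeRecord:
    """One factorial point: factors, simulated sweep and its RMS error."""

    round: int
    e_np: float
    k: float
    peak_to_peak: np.ndarray
    rms_pct: float


class QuadraticResponseSurface(RegressorMixin, BaseEstimator):
    """Six-term quadratic surrogate of RMS error over (E_NP, k).

    rms ~ b0 + b1 E~ + b2 k~ + b3 E~^2 + b4 k~^2 + b5 E~ k~ on factors
    scaled to [-1, 1] by the search window (conditioning: k is of
    magnitude 1e-16).  Fitted by ordinary least squares.

    Parameters
    ----------
    window : SearchWindow
        Defines the factor scaling (and the minimization box).
    """

    def __init__(self, window: SearchWindow | None = None):
        self.window = window

    @staticmethod
    def _design(xs: np.ndarray) -> np.ndarray:
        x1, x2 = xs[:, 0], xs[:, 1]
        return np.column_stack(
            [np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2]
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QuadraticResponseSurface":
        """Fit on raw factor points X (n, 2) and responses y (n,)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 6:
            raise ValueError("need at least 6 design points")
        if self.window is None:
            self.window_ = SearchWindow(
                (X[:, 0].min(), X[:, 0].max()), (X[:, 1].min(), X[:, 1].max())
            )
        else:
            self.window_ = self.window
        A = self._design(self.window_.scale(X))
        if np.linalg.matrix_rank(A) < 6:
            raise ValueError("rank-deficient quadratic design (collinear factor points)")
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coef_ = coef
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = max(len(y) - 6, 1)
        self.resid_sd_ = float(np.sqrt(ss_res / dof))
        self.n_features_in_ = 2
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._design(self.window_.scale(X)) @ self.coef_

    def predict_scaled(self, xs: np.ndarray) -> np.ndarray:
        return self._design(np.atleast_2d(xs)) @ self.coef_


def minimize_qrs(
    model: QuadraticResponseSurface, window: SearchWindow | None = None
) -> tuple[float, float]:
    """Global minimum of the fitted quadratic over the closed box.

    Enumerates the interior stationary point (if the Hessian is positive
    definite and the point is inside), the four edge minimizers and the
    four corners; deterministic lexicographic tie-break.
    Returns raw (e_np, k).
    """
    window = window if window is not None else model.window_
    b = model.coef_
    H = np.array([[2 * b[3], b[5]], [b[5], 2 * b[4]]])
    g = np.array([b[1], b[2]])
    cands: list[tuple[float, float]] = []
    # interior stationary point of a strictly convex quadratic
    det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
    if H[0, 0] > 0 and det > 0:
        s = np.linalg.solve(H, -g)
        if np.all(np.abs(s) <= 1.0):
            cands.append((float(s[0]), float(s[1])))
    # edge minimizers: fix one scaled factor at +-1
    for fixed_axis in (0, 1):
        free_axis = 1 - fixed_axis
        a_quad = b[3] if free_axis == 0 else b[4]
        for v in (-1.0, 1.0):
            lin = b[1 + free_axis] + b[5] * v
            if a_quad > 0:
                t = -lin / (2 * a_quad)
                if abs(t) <= 1.0:
                    pt = [0.0, 0.0]
                    pt[fixed_axis] = v
                    pt[free_axis] = t
                    cands.append(tuple(pt))
    cands.extend([(sx, sy) for sx in (-1.0, 1.0) for sy in (-1.0, 1.0)])

    xs = np.array(cands)
    vals = model.predict_scaled(xs)
    order = np.lexsort((xs[:, 1], xs[:, 0], np.round(vals, 12)))
    best = xs[order[0]]
    e_np, k = window.unscale(best[None, :])[0]
    return float(e_np), float(k)


@dataclass
class IdentificationResult:
    """Outcome of the backward identification."""

    e_np_opt: float
    e_af_opt: float
    k_opt: float
    rms_pct_final: float
    converged: bool
    windows_visited: list[SearchWindow] = field(default_factory=list)
    doe_records: list[DoeRecord] = field(default_factory=list)
    qrs_models: list[QuadraticResponseSurface] = field(default_factory=list)
    rounds: int = 0

    def doe_table(self):
        """DOE records as a pandas DataFrame (round, e_np, k, rms_pct)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {"round": r.round, "e_np": r.e_np, "k": r.k, "rms_pct": r.rms_pct}
                for r in self.doe_records
            ]
        )

    def to_dict(self) -> dict:
        return {
            "e_np_opt": self.e_np_opt,
            "e_af_opt": self.e_af_opt,
            "k_opt": self.k_opt,
            "rms_pct_final": self.rms_pct_final,
            "converged": self.converged,
            "rounds": self.rounds,
            "windows_visited": [
                {"e_np_range": list(w.e_np_range), "k_range": list(w.k_range), "levels": w.levels}
                for w in self.windows_visited
            ],
        }


def backward_identify(
    observed: Sequence[float],
    forward: Callable[[float, float], np.ndarray],
    initial_window: SearchWindow,
    max_rounds: int = 5,
    rms_threshold: float = RMS_THRESHOLD_PCT,
) -> IdentificationResult:
    """Identify (E_NP, k) matching observed peak-to-peak deformations.

    Parameters
    ----------
    observed : peak-to-peak deformation per sweep frequency, mm, in the
        same (ascending-frequency) order the forward function returns.
    forward : callable (e_np MPa, k m^4/(N s)) -> simulated sweep (mm).
    initial_window : starting search box.
    max_rounds : window-expansion rounds before giving up.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    observed = np.asarray(observed, dtype=float)

    window = initial_window
    result = IdentificationResult(
        e_np_opt=np.nan, e_af_opt=np.nan, k_opt=np.nan,
        rms_pct_final=np.inf, converged=False,
    )
    for rnd in range(1, max_rounds + 1):
        result.windows_visited.append(window)
        pts = full_factorial(window)
        rms = np.empty(len(pts))
        for i, (e_np, k) in enumerate(pts):
            sim = forward(e_np, k)
            rms[i] = rms_error(sim, observed)
            result.doe_records.append(
                DoeRecord(round=rnd, e_np=e_np, k=k, peak_to_peak=sim, rms_pct=rms[i])
            )
        qrs = QuadraticResponseSurface(window=window).fit(pts, rms)
        result.qrs_models.append(qrs)
        e_opt, k_opt = minimize_qrs(qrs, window)
        rms_opt = rms_error(forward(e_opt, k_opt), observed)

        # incumbent: best of surrogate optimum and all DOE points of this
        # round (guarantees final RMS <= best DOE sample)
        i_best = int(np.argmin(rms))
        if rms[i_best] < rms_opt:
            e_inc, k_inc, rms_inc = pts[i_best, 0], pts[i_best, 1], rms[i_best]
        else:
            e_inc, k_inc, rms_inc = e_opt, k_opt, rms_opt

        result.rounds = rnd
        if rms_inc < result.rms_pct_final:
            result.e_np_opt = float(e_inc)
            result.e_af_opt = float(AF_TO_NP_MODULUS_RATIO * e_inc)
            result.k_opt = float(k_inc)
            result.rms_pct_final = float(rms_inc)
        if result.rms_pct_final < rms_threshold:
            result.converged = True
            break
        window = window.expanded_around(float(e_inc), float(k_inc))
    return result


def default_window(group: str = "intact", levels: int = 5) -> SearchWindow:
    """The standard initial search window for a disk group."""
    if group not in _INITIAL_WINDOWS:
        raise ValueError(f"unknown group {group!r}; expected intact|degenerated")
    e_rng, k_rng = _INITIAL_WINDOWS[group]
    return SearchWindow(e_rng, k_rng, levels=levels)


class DiskParameterIdentifier(BaseEstimator):
    """Scikit-learn style estimator wrapping the backward identification.

    ``fit(X, y)`` takes the sweep frequencies (Hz) as ``X`` (shape (n,)
    or (n, 1)) and the observed peak-to-peak deformations (mm) as ``y``,
    and identifies the nucleus modulus and hydraulic permeability of the
    disk whose geometry is given.  ``predict(X)`` returns the fitted
    model's peak-to-peak deformation at the requested frequencies.

    Parameters
    ----------
    geometry : DiskGeometry of the specimen.
    window : initial SearchWindow (default: the intact-group window).
    segment_duration, steps_per_cycle, nr, nz, p_boundary, poisson :
        forward-simulation settings (see SweepSettings).
    max_rounds, rms_threshold : identification loop controls.
    forward : optional override callable (e_np, k) -> sweep; when given,
        the FE solver is bypassed (useful for fast surrogate testing).

    Attributes
    ----------
    e_np_, e_af_, k_ : identified parameters (MPa, MPa, m^4/(N s)).
    rms_pct_final_ : re-simulated normalized RMS error, %.
    converged_ : True when rms_pct_final_ < rms_threshold.
    result_ : full IdentificationResult.
    """

    def __init__(
        self,
        geometry: DiskGeometry | None = None,
        window: SearchWindow | None = None,
        segment_duration: float = 300.0,
        steps_per_cycle: int = 20,
        nr: int = 24,
        nz: int = 6,
        radial_grading: float = 0.8,
        p_boundary: float = 0.3,
        poisson: float = 0.3,
        max_rounds: int = 5,
        rms_threshold: float = RMS_THRESHOLD_PCT,
        forward: Callable[[float, float], np.ndarray] | None = None,
    ):
        self.geometry = geometry
        self.window = window
        self.segment_duration = segment_duration
        self.steps_per_cycle = steps_per_cycle
        self.nr = nr
        self.nz = nz
        self.radial_grading = radial_grading
        self.p_boundary = p_boundary
        self.poisson = poisson
        self.max_rounds = max_rounds
        self.rms_threshold = rms_threshold
        self.forward = forward

    def _frequencies(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a 1-column array of frequencies")
            X = X[:, 0]
        if np.any(X <= 0):
            raise ValueError("frequencies must be positive")
        return X

    def _make_forward(self, freqs: np.ndarray):
        if self.forward is not None:
            return self.forward
        if self.geometry is None:
            raise ValueError("geometry is required unless a forward override is given")
        from .forward import SweepSettings, sweep_forward_fn

        settings = SweepSettings(
            frequencies=freqs,
            segment_duration=self.segment_duration,
            steps_per_cycle=self.steps_per_cycle,
            nr=self.nr,
            nz=self.nz,
            radial_grading=self.radial_grading,
            p_boundary=self.p_boundary,
        )
        return sweep_forward_fn(self.geometry, settings, poisson=self.poisson)

    def fit(self, X, y) -> "DiskParameterIdentifier":
        freqs = self._frequencies(X)
        y = np.asarray(y, dtype=float)
        if freqs.shape != y.shape:
            raise ValueError("X and y must have the same length")
        order = np.argsort(freqs)
        freqs, y = freqs[order], y[order]
        window = self.window if self.window is not None else default_window("intact")
        result = backward_identify(
            y,
            self._make_forward(freqs),
            window,
            max_rounds=self.max_rounds,
            rms_threshold=self.rms_threshold,
        )
        self.result_ = result
        self.e_np_ = result.e_np_opt
        self.e_af_ = result.e_af_opt
        self.k_ = result.k_opt
        self.rms_pct_final_ = result.rms_pct_final
        self.converged_ = result.converged
        self.frequencies_ = freqs
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "e_np_")
        freqs = self._frequencies(X)
        order = np.argsort(freqs)
        fwd = self._make_forward(freqs[order])
        out = np.empty_like(freqs)
        out[order] = fwd(self.e_np_, self.k_)
        return out
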