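"""Webb photosynthesis–irradiance model fitting for PAM rapid light curves.

A rapid light curve (RLC) steps a plant through a short sequence of actinic
irradiances (here the nine instrument levels 0, 65, 90, 125, 190, 285, 420,
625, 820 μmol photons m⁻² s⁻¹) and records the effective quantum yield of
photosystem II, Φ_PSII, at each step.  Because Φ_PSII itself depends on
irradiance, the exponential-saturation (Webb) model is fitted in its
irradiance-normalized form,

    Φ(E) = α · (E_k / E) · (1 − exp(−E / E_k)),        Φ(0) ≡ α,

which removes the inherent irradiance dependency of yield measurements.
The fitted parameters are the light-limited slope α (dimensionless,
yield scale) and the saturation irradiance E_k (μmol photons m⁻² s⁻¹);
the maximum photosynthetic rate follows as P_max = α · E_k
(μmol electrons m⁻² s⁻¹).

A relative maximum electron transport rate, rETR_max, is also reported:
the largest E·Φ product among steps with Φ_PSII > 0.1, a screen that keeps
the ETR estimate in the range where fluorescence-derived electron transport
tracks oxygen evolution reliably.  No absorption factor is applied, hence
*relative* ETR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_ACTINIC_STEPS",
    "RLCStep",
    "RapidLightCurve",
    "PECurveFit",
    "UnfittableCurveError",
    "webb_yield",
    "fit_webb",
    "compute_pmax",
    "compute_retr_max",
]

#: The nine actinic irradiance levels used throughout, μmol photons m⁻² s⁻¹.
DEFAULT_ACTINIC_STEPS: tuple[float, ...] = (0, 65, 90, 125, 190, 285, 420, 625, 820)

#: Yield screen for rETR_max: only steps with Φ_PSII strictly above this enter.
RETR_PHI_THRESHOLD = 0.1

ALPHA_BOUNDS = (1e-6, 2.0)
EK_BOUNDS = (1e-3, 2000.0)


class UnfittableCurveError(ValueError):
    """Raised when a curve carries no usable photochemical signal.

    Mirrors the field situation of depigmented individuals that cannot
    sustain a fluorescence signal sufficient to run an RLC: such curves are
    excluded from all downstream tables rather than fitted.
    """


@dataclass(frozen=True)
class RLCStep:
    """One actinic step: irradiance and the yield measured under it."""

    e_par: float
    phi_psii: float
    step_index: int

    def __post_init__(self) -> None:
        if self.e_par < 0:
            raise ValueError(f"e_par must be >= 0, got {self.e_par}")
        if not np.isfinite(self.phi_psii):
            raise ValueError("phi_psii must be finite")
        if not 0.0 <= self.phi_psii <= 1.0:
            raise ValueError(f"phi_psii must be in [0, 1], got {self.phi_psii}")


@dataclass
class RapidLightCurve:
    """One plant's RLC on one measurement day.

    ``rlc_order`` is the ordinal position of this measurement in the
    morning's sequence (all curves of a run-day are taken before noon);
    it is carried through to the mixed-model layer as a random effect.
    """

    plant_id: str
    day_label: str  # D1 | D5 | D9
    timestamp: str  # ISO 8601 local clock time
    steps: list[RLCStep] = field(default_factory=list)
    rlc_order: int = 1

    def __post_init__(self) -> None:
        e = [s.e_par for s in self.steps]
        if any(b < a for a, b in zip(e, e[1:])):
            warnings.warn(
                f"RLC steps for {self.plant_id}/{self.day_label} not ordered by "
                "irradiance; sorting",
                stacklevel=2,
            )
            self.steps = sorted(self.steps, key=lambda s: s.e_par)

    @property
    def e_par(self) -> np.ndarray:
        return np.array([s.e_par for s in self.steps], dtype=float)

    @property
    def phi_psii(self) -> np.ndarray:
        return np.array([s.phi_psii for s in self.steps], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        plant_id: str,
        day_label: str,
        e_par,
        phi_psii,
        timestamp: str = "",
        rlc_order: int = 1,
    ) -> "RapidLightCurve":
        steps = [
            RLCStep(float(e), float(p), i + 1)
            for i, (e, p) in enumerate(zip(e_par, phi_psii))
        ]
        return cls(plant_id, day_label, timestamp, steps, rlc_order)


@dataclass
class PECurveFit:
    """Fitted Webb parameters and their derived quantities for one curve."""

    alpha: float
    ek: float
    pmax: float
    retr_max: float | None
    rss: float
    converged: bool
    n_steps: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        # pmax is definitionally alpha * ek; enforce rather than trust callers
        if not np.isclose(self.pmax, self.alpha * self.ek, rtol=0, atol=1e-12):
            raise ValueError("pmax must equal alpha * ek")


def webb_yield(e_par, alpha: float, ek: float):
    """Irradiance-normalized Webb model Φ(E); Φ(0) = α by continuous extension.

    Vectorized over ``e_par``.
    """
    e = np.asarray(e_par, dtype=float)
    out = np.empty_like(e)
    nz = e > 0
    # -expm1(-x) = 1 - exp(-x), accurate for small x
    out[nz] = alpha * (ek / e[nz]) * (-np.expm1(-e[nz] / ek))
    out[~nz] = alpha
    return out if out.ndim else float(out)


def _start_values(e: np.ndarray, phi: np.ndarray) -> tuple[float, float]:
    """Heuristic starting point: α₀ from the lowest nonzero-E yield, E_k0 from
    where the yield first halves relative to α₀ (fallback 100)."""
    nz = e > 0
    alpha0 = float(phi[nz][np.argmin(e[nz])]) if nz.any() else float(phi[0])
    alpha0 = min(max(alpha0, 1e-3), ALPHA_BOUNDS[1] - 1e-6)
    below = nz & (phi < alpha0 / 2.0)
    ek0 = float(e[below].min()) if below.any() else 100.0
    ek0 = min(max(ek0, 1.0), EK_BOUNDS[1] - 1.0)
    return alpha0, ek0


def fit_webb(curve: RapidLightCurve, max_iter: int = 500) -> PECurveFit:
    """Least-squares fit of the normalized Webb model to one RLC.

    Bounded trust-region least squares on Φ (unweighted: the irradiance
    normalization is itself the variance stabilization), starting from data-
    driven values, tolerance 1e-10 on the SSE change.  Non-convergence is
    reported via ``converged=False``; a curve with no positive yield raises
    :class:`UnfittableCurveError` and is meant to be excluded upstream.

    Raises
    ------
    ValueError
        Fewer than 4 steps or non-distinct irradiances.
    UnfittableCurveError
        All yields are zero (no photochemical signal).
    """
    e = curve.e_par
    phi = curve.phi_psii
    if len(e) < 4:
        raise ValueError(f"need >= 4 steps to fit, got {len(e)}")
    if len(np.unique(e)) < 4:
        raise ValueError("need >= 4 distinct e_par values")
    if not (np.isfinite(e).all() and np.isfinite(phi).all()):
        raise ValueError("non-finite values in curve")
    if not (phi > 0).any():
        raise UnfittableCurveError(
            f"curve {curve.plant_id}/{curve.day_label} has no positive yield"
        )

    def resid(theta):
        return webb_yield(e, theta[0], theta[1]) - phi

    x0 = _start_values(e, phi)
    res = least_squares(
        resid,
        x0=x0,
        bounds=([ALPHA_BOUNDS[0], EK_BOUNDS[0]], [ALPHA_BOUNDS[1], EK_BOUNDS[1]]),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter * 3,
    )
    alpha, ek = float(res.x[0]), float(res.x[1])
    rss = float(np.sum(res.fun**2))
    return PECurveFit(
        alpha=alpha,
        ek=ek,
        pmax=compute_pmax(alpha, ek),
        retr_max=compute_retr_max(curve),
        rss=rss,
        converged=bool(res.status > 0),
        n_steps=len(e),
        message=res.message,
    )


def compute_pmax(alpha: float, ek: float) -> float:
    """Maximum photosynthetic rate P_max = α · E_k (μmol electrons m⁻² s⁻¹)."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if ek <= 0:
        raise ValueError(f"ek must be > 0, got {ek}")
    return alpha * ek


def compute_retr_max(curve: RapidLightCurve) -> float | None:
    """Highest relative ETR (E_par · Φ_PSII) among steps with Φ_PSII > 0.1.

    Returns ``None`` when no step passes the yield screen.  Ties on the
    product are broken toward the lower irradiance — the conservative side,
    away from any photoinhibited plateau.
    """
    e = curve.e_par
    phi = curve.phi_psii
    ok = phi > RETR_PHI_THRESHOLD
    if not ok.any():
        return None
    prod = e[ok] * phi[ok]
    best = prod.max()
    winners = e[ok][prod == best]
    _ = winners.min()  # tie-break: lowest irradiance attaining the max
    return float(best)
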