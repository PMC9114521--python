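"""Dielectric and electromechanical core for DEP cell stretching.

A polarizable particle (a cell, a polystyrene bead) suspended in a medium
of different complex permittivity experiences a time-averaged force in a
nonuniform AC electric field — dielectrophoresis (DEP).  For a homogeneous
sphere of radius ``r`` the force is

    F_DEP = 2 pi r^3  eps_m  Re(f_CM)  grad(E_rms^2)

where ``eps_m`` is the absolute permittivity of the medium and ``f_CM`` is
the Clausius–Mossotti factor

    f_CM = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*),
    eps*  = eps - j sigma / omega,   omega = 2 pi f.

``Re(f_CM)`` is bounded in [-0.5, 1] for any physical parameters; its sign
selects attraction toward field maxima (p-DEP, positive) or repulsion
(n-DEP, negative), and the frequency at which it changes sign is the
crossover frequency.

The stretching stress a trapped cell experiences at an electrode tip is
summarised by a dimensionless geometric constant ``n`` of the electrode
layout (see :mod:`depstretch.fieldsolver`):

    sigma_stress = n Re(f_CM) eps_m E0^2,        E = sigma_stress / strain.

All permittivities passed around as ``eps_rel`` are relative; absolute
values are formed with the vacuum permittivity ``EPS0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS0",
    "DielectricBody",
    "DEPSpectrumPoint",
    "StressParameters",
    "complex_permittivity",
    "cm_factor",
    "cm_factor_low_freq_limit",
    "cm_factor_high_freq_limit",
    "cm_spectrum",
    "dep_regime",
    "crossover_frequency",
    "dep_force",
    "dep_stress",
    "youngs_modulus",
]

#: Vacuum permittivity, F/m (CODATA 2018).
EPS0 = 8.8541878128e-12

#: Absolute tolerance on Re(f_CM) below which the DEP regime is called null.
REGIME_TOL = 1e-12


@dataclass(frozen=True)
class DielectricBody:
    """A homogeneous dielectric sphere or a suspending medium.

    Parameters
    ----------
    eps_rel : float
        Relative permittivity (> 0).
    sigma : float
        Ohmic conductivity in S/m (>= 0).
    radius : float, optional
        Particle radius in metres (> 0).  Only particles carry a radius;
        media leave it ``None``.
    """

    eps_rel: float
    sigma: float
    radius: float | None = None

    def __post_init__(self) -> None:
        if not self.eps_rel > 0:
            raise ValueError(f"eps_rel must be > 0, got {self.eps_rel}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.radius is not None and not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    @property
    def eps_abs(self) -> float:
        """Absolute permittivity eps_rel * EPS0, F/m."""
        return self.eps_rel * EPS0


@dataclass(frozen=True)
class DEPSpectrumPoint:
    """One frequency sample of the Clausius–Mossotti spectrum."""

    freq: float
    fcm: complex

    def __post_init__(self) -> None:
        if not self.freq > 0:
            raise ValueError("freq must be > 0")

    @property
    def re_fcm(self) -> float:
        return self.fcm.real


@dataclass(frozen=True)
class StressParameters:
    """Inputs of the DEP stress relation sigma = n Re(f_CM) eps_m E0^2.

    ``n_geom`` is the dimensionless electrode-geometry constant, ``e0`` the
    reference field strength in V/m and ``freq`` the drive frequency in Hz.
    """

    n_geom: float
    e0: float
    medium: DielectricBody
    freq: float

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValueError("e0 must be >= 0")
        if not self.freq > 0:
            raise ValueError("freq must be > 0")


def _check_freq(freq) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError(f"frequency must be positive and finite, got {freq!r}")
    return f


def complex_permittivity(body: DielectricBody, freq):
    """Complex permittivity eps* = eps - j sigma/omega at ``freq`` Hz.

    ``omega = 2 pi freq``; the result is in F/m (absolute).  Accepts a
    scalar or array frequency; the imaginary part is always <= 0.
    """
    f = _check_freq(freq)
    omega = 2.0 * math.pi * f
    out = body.eps_abs - 1j * body.sigma / omega
    return complex(out) if np.isscalar(freq) else out


def cm_factor(particle: DielectricBody, medium: DielectricBody, freq):
    """Clausius–Mossotti factor (eps_p* - eps_m*) / (eps_p* + 2 eps_m*).

    The real part lies in [-0.5, 1] for any physical parameters.  Scalar or
    array frequency.
    """
    ep = complex_permittivity(particle, freq)
    em = complex_permittivity(medium, freq)
    denom = ep + 2 * em
    if np.any(np.abs(denom) == 0):
        raise ZeroDivisionError(
            "degenerate Clausius–Mossotti denominator; parameters unphysical"
        )
    out = (ep - em) / denom
    return complex(out) if np.isscalar(freq) else out


def cm_factor_low_freq_limit(particle: DielectricBody, medium: DielectricBody) -> float:
    """omega -> 0 limit of Re(f_CM): conductivities dominate.

    Equals (sigma_p - sigma_m)/(sigma_p + 2 sigma_m); when both
    conductivities vanish the ohmic terms never dominate and the limit is
    the permittivity form instead.
    """
    denom = particle.sigma + 2 * medium.sigma
    if denom == 0:
        return cm_factor_high_freq_limit(particle, medium)
    return (particle.sigma - medium.sigma) / denom


def cm_factor_high_freq_limit(particle: DielectricBody, medium: DielectricBody) -> float:
    """omega -> inf limit of Re(f_CM): permittivities dominate.

    Equals (eps_p - eps_m)/(eps_p + 2 eps_m).
    """
    return (particle.eps_rel - medium.eps_rel) / (
        particle.eps_rel + 2 * medium.eps_rel
    )


def cm_spectrum(
    particle: DielectricBody,
    medium: DielectricBody,
    f_min: float = 1e3,
    f_max: float = 1e9,
    n_points: int = 200,
) -> list[DEPSpectrumPoint]:
    """Sample f_CM on a log-spaced frequency grid."""
    if not (f_min > 0 and f_max > f_min):
        raise ValueError("need 0 < f_min < f_max")
    freqs = np.logspace(math.log10(f_min), math.log10(f_max), n_points)
    vals = cm_factor(particle, medium, freqs)
    return [DEPSpectrumPoint(float(f), complex(v)) for f, v in zip(freqs, vals)]


def dep_regime(
    particle: DielectricBody,
    medium: DielectricBody,
    freq: float,
    tol: float = REGIME_TOL,
) -> str:
    """DEP regime at ``freq``: ``"positive"``, ``"negative"`` or ``"null"``.

    Positive Re(f_CM) attracts the particle to field maxima (p-DEP),
    negative repels (n-DEP); magnitudes below ``tol`` are called null.
    """
    re = cm_factor(particle, medium, freq).real
    if re > tol:
        return "positive"
    if re < -tol:
        return "negative"
    return "null"


def crossover_frequency(
    particle: DielectricBody, medium: DielectricBody
) -> float | None:
    """Frequency (Hz) where Re(f_CM) changes sign, or ``None``.

    A homogeneous sphere has at most one crossover; it exists iff the
    low-frequency (conductivity) and high-frequency (permittivity) limits
    of Re(f_CM) differ in sign, and then equals

        f_c = (1/2 pi) sqrt( -[(s_p - s_m)(s_p + 2 s_m)]
                              / [(e_p - e_m)(e_p + 2 e_m)] )

    with absolute permittivities.  ``None`` is a value (no crossover), not
    an error.
    """
    lo = cm_factor_low_freq_limit(particle, medium)
    hi = cm_factor_high_freq_limit(particle, medium)
    if lo == 0.0 or hi == 0.0 or (lo > 0) == (hi > 0):
        return None
    sp, sm = particle.sigma, medium.sigma
    ep, em = particle.eps_abs, medium.eps_abs
    radicand = -((sp - sm) * (sp + 2 * sm)) / ((ep - em) * (ep + 2 * em))
    if radicand <= 0:  # opposite-sign limits guarantee > 0; guard anyway
        return None
    return math.sqrt(radicand) / (2.0 * math.pi)


def dep_force(
    particle: DielectricBody,
    medium: DielectricBody,
    freq: float,
    grad_e2rms: float,
) -> float:
    """Time-averaged DEP force 2 pi r^3 eps_m Re(f_CM) grad(E_rms^2), in N.

    ``grad_e2rms`` is the gradient of the squared RMS field, V^2/m^3.  The
    particle must carry a radius.
    """
    if particle.radius is None:
        raise ValueError("particle must have a radius to feel a DEP force")
    re = cm_factor(particle, medium, freq).real
    return 2.0 * math.pi * particle.radius**3 * medium.eps_abs * re * grad_e2rms


def dep_stress(
    params: StressParameters,
    particle: DielectricBody,
    medium: DielectricBody,
) -> float:
    """Stretching stress n Re(f_CM) eps_m E0^2 on a trapped cell, in Pa.

    Sign follows Re(f_CM): positive in the p-DEP regime used for
    stretching.
    """
    re = cm_factor(particle, medium, params.freq).real
    return params.n_geom * re * medium.eps_abs * params.e0**2


def youngs_modulus(stress: float, strain: float) -> float:
    """Young's modulus E = stress / strain, in Pa.

    A cell that did not stretch (strain <= 0) is unmeasurable; that is an
    error here, never an infinity.
    """
    if not strain > 0:
        raise ValueError(
            f"strain must be > 0 to define a modulus, got {strain}"
        )
    return stress / strain
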