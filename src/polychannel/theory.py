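"""Closed-form limiting results used as sanity anchors.

These are the textbook expressions the simulation results are discussed
against: the Debye screening length of the electrolyte, the free-draining
electrophoretic velocity (mobility of a polyion equals the mobility of a
segment), and the Hermans-Fujita porous-sphere velocity in the compact
(Henry) limit.  They are reference formulas only and are never fitted to
simulation output.

All quantities are in reduced LJ units; the Henry-limit velocity is exposed
per unit applied field (the field dependence is a multiplicative prefactor).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "debye_length",
    "free_draining_velocity",
    "henry_limit_velocity",
    "gamma_factor",
]


def debye_length(lB: float, densities, valences=None) -> float:
    """Debye screening length ``1 / sqrt(4 pi lB sum_i c_i z_i^2)`` in sigma.

    ``densities`` are the number densities of the charged species in
    sigma^-3; ``valences`` default to 1 for every species.
    """
    c = np.atleast_1d(np.asarray(densities, dtype=float))
    if c.size == 0:
        raise ValueError("at least one charged species is required")
    if np.any(c <= 0):
        raise ValueError("densities must be positive")
    z = (
        np.ones_like(c)
        if valences is None
        else np.atleast_1d(np.asarray(valences, dtype=float))
    )
    ionic = float(np.sum(c * z**2))
    if ionic <= 0:
        raise ValueError("no charged species")
    return 1.0 / math.sqrt(4.0 * math.pi * lB * ionic)


def free_draining_velocity(rho_f: float, E: float, nu_m: float, gamma: float) -> float:
    """Electrophoretic velocity ``rho_f E / (nu_m gamma)`` of a fully
    permeable (free-draining) polyion: fixed charge density ``rho_f``,
    segment density ``nu_m``, segment friction ``gamma``."""
    if nu_m <= 0 or gamma <= 0:
        raise ValueError("nu_m and gamma must be positive")
    return rho_f * E / (nu_m * gamma)


def gamma_factor(p: float) -> float:
    """Henry-type screening factor ``p^2 / (3 + p^2)``; 0 at p->0, 1 at p->inf."""
    return p * p / (3.0 + p * p)


def henry_limit_velocity(rho_f: float, Rs: float, eta: float, p: float) -> float:
    """Compact-sphere (Henry-limit) electrophoretic velocity per unit field.

    ``v = 2 rho_f Rs^2 e^{-p} Gamma(p) cosh(p) / (3 eta p^2)`` with
    ``p = kappa Rs`` and ``Gamma(p) = p^2/(3 + p^2)``.  At p -> 0 the
    expression tends to ``2 rho_f Rs^2 / (9 eta)``.
    """
    if p <= 0:
        raise ValueError("p = kappa * Rs must be positive")
    # e^{-p} cosh p = (1 + e^{-2p})/2, stable for large p
    ep = 0.5 * (1.0 + math.exp(-2.0 * p))
    return 2.0 * rho_f * Rs**2 * ep * gamma_factor(p) / (3.0 * eta * p**2)
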