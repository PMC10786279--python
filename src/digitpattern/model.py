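"""Reaction kinetics of the BMP digit-segmentation network.

The network encodes five core assumptions: free GDF5 activates pSMAD; pSMAD
represses *GDF5* transcription; NOG binds GDF5 into an inert complex that
cannot signal; NOG, GDF5 and the complex diffuse; and (in the validated
topology) pSMAD also represses *NOG* transcription. This module defines the
local (reaction-only) dynamics and the homogeneous steady state; diffusion is
added by :mod:`digitpattern.simulate` and the linearization by
:mod:`digitpattern.stability`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters

#: Component order used everywhere a state vector is flattened.
COMPONENTS = ("m_G", "m_N", "G", "N", "C", "S")

#: Components that diffuse (free proteins and the complex).
DIFFUSIBLE = ("G", "N", "C")


class SteadyStateError(RuntimeError):
    """Raised when no non-negative homogeneous steady state can be located."""


@dataclass
class ModelState:
    """Values of the six model components on a 1D grid at one time.

    ``x`` holds grid positions in μm (uniform spacing); each component is a
    same-length array; ``t`` is the time in hours.
    """

    x: np.ndarray
    m_G: np.ndarray
    m_N: np.ndarray
    G: np.ndarray
    N: np.ndarray
    C: np.ndarray
    S: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        n = self.x.size
        for name in COMPONENTS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"component {name} has shape {arr.shape}, expected ({n},)"
                )
            if np.any(arr < 0):
                raise ValueError(f"component {name} has negative entries")
            setattr(self, name, arr)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else np.nan

    def component_matrix(self) -> np.ndarray:
        """(6, n) matrix of component values in canonical order."""
        return np.stack([getattr(self, c) for c in COMPONENTS])

    @classmethod
    def uniform(cls, x, values, t: float = 0.0) -> "ModelState":
        """Spatially homogeneous state from a component->value mapping."""
        x = np.asarray(x, dtype=float)
        comps = {c: np.full(x.size, float(values[c])) for c in COMPONENTS}
        return cls(x=x, t=t, **comps)


# -- regulatory functions ---------------------------------------------------

def hill_activation(value, K: float, h: float):
    """Increasing Hill function value^h / (K^h + value^h)."""
    v = np.asarray(value, dtype=float)
    return v**h / (K**h + v**h)


def hill_repression(value, K: float, h: float):
    """Decreasing Hill function K^h / (K^h + value^h)."""
    v = np.asarray(value, dtype=float)
    return K**h / (K**h + v**h)


def psmad_response(G_value, params: ModelParameters):
    """pSMAD activity produced by a free-GDF5 level.

    Saturating (Hill) activation: ``S_max * G^h_S / (K_S^h_S + G^h_S)``.
    Monotone non-decreasing in ``G_value`` and bounded by ``S_max``. The
    NOG-GDF5 complex never appears here: bound ligand cannot signal.
    """
    G = np.asarray(G_value, dtype=float)
    if np.any(G < 0):
        raise ValueError("free GDF5 concentration must be >= 0")
    return params.S_max * hill_activation(G, params.K_S, params.h_S)


def transcription_rates(S_value, params: ModelParameters):
    """(GDF5, NOG) mRNA production rates at a given pSMAD activity.

    *GDF5* transcription is always repressed by pSMAD. *NOG* transcription
    follows ``params.nog_regulation``: repressed (validated topology),
    constant, or activated.
    """
    S = np.asarray(S_value, dtype=float)
    if np.any(S < 0):
        raise ValueError("pSMAD activity must be >= 0")
    gdf5 = params.alpha_G * hill_repression(S, params.K_G, params.h_G)
    if params.nog_regulation == "repressed":
        nog = params.alpha_N * hill_repression(S, params.K_N, params.h_N)
    elif params.nog_regulation == "constant":
        nog = params.alpha_N * np.ones_like(S)
    else:  # activated
        nog = params.alpha_N * hill_activation(S, params.K_N, params.h_N)
    return gdf5, nog


def reaction_terms(state: ModelState, params: ModelParameters) -> dict:
    """Per-grid-point time derivatives of all components, diffusion excluded.

    Returns a component-name -> array mapping. When ``tau_S == 0`` the pSMAD
    entry is the algebraic residual target, i.e. ``psmad_response(G) - S``
    (callers treating pSMAD as instantaneous should instead overwrite S with
    :func:`psmad_response`).
    """
    tG, tN = transcription_rates(state.S, params)
    bind = params.k_on * state.G * state.N
    unbind = params.k_off * state.C
    d = {
        "m_G": tG - params.delta_mG * state.m_G,
        "m_N": tN - params.delta_mN * state.m_N,
        "G": params.beta_G * state.m_G - bind + unbind - params.delta_G * state.G,
        "N": params.beta_N * state.m_N - bind + unbind - params.delta_N * state.N,
        "C": bind - unbind - params.delta_C * state.C,
    }
    target = psmad_response(state.G, params)
    if params.instantaneous_psmad:
        d["S"] = target - state.S
    else:
        d["S"] = (target - state.S) / params.tau_S
    return d


# -- homogeneous steady state ----------------------------------------------

def _steady_given_G(G: float, params: ModelParameters) -> dict:
    """All other components expressed through free GDF5 at steady state."""
    S = float(psmad_response(G, params))
    tG, tN = transcription_rates(S, params)
    m_G = float(tG) / params.delta_mG
    m_N = float(tN) / params.delta_mN
    # Effective removal of free protein through the complex channel:
    # C* = k_on G N / (k_off + delta_C), so the net binding loss per unit
    # G*N is k_on * delta_C / (k_off + delta_C).
    phi = params.k_on * params.delta_C / (params.k_off + params.delta_C) \
        if (params.k_off + params.delta_C) > 0 else 0.0
    N = params.beta_N * m_N / (phi * G + params.delta_N)
    C = params.k_on * G * N / (params.k_off + params.delta_C) \
        if (params.k_off + params.delta_C) > 0 else 0.0
    return {"m_G": m_G, "m_N": m_N, "G": G, "N": N, "C": C, "S": S}


def _G_residual(G: float, params: ModelParameters) -> float:
    vals = _steady_given_G(G, params)
    phi = params.k_on * params.delta_C / (params.k_off + params.delta_C) \
        if (params.k_off + params.delta_C) > 0 else 0.0
    return (
        params.beta_G * vals["m_G"]
        - phi * G * vals["N"]
        - params.delta_G * G
    )


def homogeneous_steady_state(
    params: ModelParameters, guess: dict | None = None, tol: float = 1e-12
) -> dict:
    """Non-negative homogeneous steady state of the reaction system.

    The fixed point reduces exactly to one scalar equation in free GDF5:
    every other component has a closed form given G (mRNAs from the Hill
    transcription terms, N from its own balance, C from the binding
    quasi-equilibrium with degradation, S from the pSMAD response). The
    scalar equation changes sign on ``[0, G_max]`` where
    ``G_max = beta_G * alpha_G / (delta_mG * delta_G)`` bounds production,
    so Brent's method converges deterministically. ``guess`` (an optional
    component mapping) only tightens the initial bracket.
    """
    if params.alpha_G == 0.0 and params.alpha_N == 0.0:
        return {c: 0.0 for c in COMPONENTS}
    if params.delta_G <= 0 or params.delta_mG <= 0 or params.delta_mN <= 0 \
            or params.delta_N <= 0:
        raise SteadyStateError("degradation rates must be positive for a steady state")
    G_hi = params.beta_G * params.alpha_G / (params.delta_mG * params.delta_G)
    if G_hi == 0.0:
        vals = _steady_given_G(0.0, params)
    else:
        lo, hi = 0.0, G_hi * (1 + 1e-9)
        if guess is not None and "G" in guess:
            g = float(guess["G"])
            if 0 < g < hi and _G_residual(g, params) > 0:
                lo = g
        f_lo, f_hi = _G_residual(lo, params), _G_residual(hi, params)
        if f_lo < 0 or f_hi > 0:  # pragma: no cover - bracket is analytic
            raise SteadyStateError(
                f"could not bracket the steady state: f({lo})={f_lo}, f({hi})={f_hi}"
            )
        G = brentq(_G_residual, lo, hi, args=(params,), xtol=1e-15, rtol=8.9e-16)
        vals = _steady_given_G(float(G), params)
    # Verify the residual on a normalized scale.
    resid = steady_state_residual(vals, params)
    if resid > 1e-10:
        raise SteadyStateError(f"steady-state residual {resid:.3e} exceeds 1e-10")
    return vals


def steady_state_residual(values: dict, params: ModelParameters) -> float:
    """Max |reaction rate| at a homogeneous state, normalized per component."""
    x = np.zeros(3)
    state = ModelState.uniform(x, values)
    rates = reaction_terms(state, params)
    worst = 0.0
    for name in COMPONENTS:
        scale = max(abs(values[name]), 1.0)
        worst = max(worst, float(np.max(np.abs(rates[name]))) / scale)
    return worst
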