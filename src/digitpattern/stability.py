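"""Linear instability analysis of the GDF5/NOG/pSMAD network.

For a homogeneous steady state ``u*`` the growth rate of a spatial
perturbation with wavenumber ``k`` is the largest real part of the
eigenvalues of ``J - k^2 D``, where ``J`` is the reaction Jacobian at ``u*``
and ``D`` the diagonal diffusion matrix (nonzero only for the free proteins
and the complex). A Turing (diffusion-driven) instability requires stability
at ``k = 0`` together with a band of ``k > 0`` with positive growth; the
maximizing wavenumber predicts the pattern wavelength ``2*pi/k_max``.

The Jacobian is built symbolically (sympy) once per network topology and
pSMAD regime and cross-checked against central finite differences of the
numeric reaction terms.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from . import model
from .model import COMPONENTS, ModelState, homogeneous_steady_state
from .params import NOG_REGULATION_MODES, ModelParameters

_PARAM_ORDER = (
    "D_G", "D_N", "D_C", "k_on", "k_off", "alpha_G", "alpha_N", "beta_G",
    "beta_N", "delta_mG", "delta_mN", "delta_G", "delta_N", "delta_C",
    "K_S", "h_S", "S_max", "K_G", "h_G", "K_N", "h_N", "tau_S",
)

#: instability threshold on growth rates (1/h); guards against calling a
#: numerically-zero eigenvalue "unstable".
GROWTH_TOL = 1e-9


@dataclass
class DispersionResult:
    """Per-wavenumber linear growth rates and the Turing verdict."""

    k_values: np.ndarray
    growth_rates: np.ndarray
    k_max: float | None
    lambda_pred: float | None
    turing_unstable: bool
    stable_at_zero: bool
    steady_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=float)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        if self.k_values.shape != self.growth_rates.shape:
            raise ValueError("k_values and growth_rates must have equal length")
        if self.k_values.size and (
            self.k_values[0] != 0.0 or np.any(np.diff(self.k_values) <= 0)
        ):
            raise ValueError("k_values must start at 0 and be strictly increasing")


@functools.lru_cache(maxsize=8)
def _symbolic_jacobian(nog_regulation: str, instantaneous: bool):
    """Lambdified reaction Jacobian for one topology/pSMAD regime.

    Returns (component names, function(state values..., param values...)).
    With an instantaneous pSMAD readout, S is eliminated from the
    linearization (chain rule through S = f(G)), giving a 5-component
    Jacobian; otherwise all six components appear.
    """
    syms = {c: sp.Symbol(c, nonnegative=True) for c in COMPONENTS}
    p = {name: sp.Symbol(name, positive=True) for name in _PARAM_ORDER}
    m_G, m_N, G, N, C, S = (syms[c] for c in COMPONENTS)

    f_S = p["S_max"] * G ** p["h_S"] / (p["K_S"] ** p["h_S"] + G ** p["h_S"])
    t_G = p["alpha_G"] * p["K_G"] ** p["h_G"] / (p["K_G"] ** p["h_G"] + S ** p["h_G"])
    if nog_regulation == "repressed":
        t_N = p["alpha_N"] * p["K_N"] ** p["h_N"] / (p["K_N"] ** p["h_N"] + S ** p["h_N"])
    elif nog_regulation == "constant":
        t_N = p["alpha_N"]
    else:
        t_N = p["alpha_N"] * S ** p["h_N"] / (p["K_N"] ** p["h_N"] + S ** p["h_N"])

    bind = p["k_on"] * G * N
    rhs = {
        "m_G": t_G - p["delta_mG"] * m_G,
        "m_N": t_N - p["delta_mN"] * m_N,
        "G": p["beta_G"] * m_G - bind + p["k_off"] * C - p["delta_G"] * G,
        "N": p["beta_N"] * m_N - bind + p["k_off"] * C - p["delta_N"] * N,
        "C": bind - p["k_off"] * C - p["delta_C"] * C,
        "S": (f_S - S) / p["tau_S"],
    }
    if instantaneous:
        comps = COMPONENTS[:5]
        exprs = [rhs[c].subs(S, f_S) for c in comps]
    else:
        comps = COMPONENTS
        exprs = [rhs[c] for c in comps]
    jac = sp.Matrix(exprs).jacobian(sp.Matrix([syms[c] for c in comps]))
    args = [syms[c] for c in comps] + [p[name] for name in _PARAM_ORDER]
    fn = sp.lambdify(args, jac, modules="numpy")
    return comps, fn


def linearized_components(params: ModelParameters) -> tuple[str, ...]:
    """Components entering the linearization for this parameter set."""
    return COMPONENTS[:5] if params.instantaneous_psmad else COMPONENTS


def reaction_jacobian(
    params: ModelParameters, steady: dict | None = None
) -> np.ndarray:
    """Reaction Jacobian at the homogeneous steady state (symbolic route)."""
    if steady is None:
        steady = homogeneous_steady_state(params)
    comps, fn = _symbolic_jacobian(
        params.nog_regulation, params.instantaneous_psmad
    )
    # the generated Hill-derivative expressions contain negative powers of
    # the state; clamp exact zeros to a tiny positive value (the h >= 1
    # derivatives are continuous there, so the limit is recovered)
    state_vals = [max(steady[c], 1e-10) for c in comps]
    # tau_S enters only the S row; pass a dummy positive value when
    # instantaneous so the lambdified function never divides by zero.
    pvals = []
    for name in _PARAM_ORDER:
        v = getattr(params, name)
        if name == "tau_S" and params.instantaneous_psmad:
            v = 1.0
        pvals.append(v)
    J = np.asarray(fn(*state_vals, *pvals), dtype=float)
    return J


def finite_difference_jacobian(
    params: ModelParameters, steady: dict | None = None, step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of the numeric reaction terms.

    Independent cross-check of :func:`reaction_jacobian`; with an
    instantaneous pSMAD readout the differentiated map first collapses S to
    its algebraic value, matching the reduced linearization.
    """
    if steady is None:
        steady = homogeneous_steady_state(params)
    comps = linearized_components(params)
    x = np.zeros(1)

    def rates(vec):
        vals = dict(zip(comps, vec))
        if params.instantaneous_psmad:
            vals["S"] = float(model.psmad_response(max(vals["G"], 0.0), params))
        state = ModelState.uniform(x, {c: max(vals[c], 0.0) for c in COMPONENTS})
        r = model.reaction_terms(state, params)
        return np.array([r[c][0] for c in comps])

    base = np.array([steady[c] for c in comps])
    n = len(comps)
    J = np.zeros((n, n))
    for j in range(n):
        h = step * max(abs(base[j]), 1.0)
        up, dn = base.copy(), base.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (rates(up) - rates(dn)) / (2 * h)
    return J


def diffusion_matrix(params: ModelParameters) -> np.ndarray:
    """Diagonal diffusion matrix on the linearized components."""
    comps = linearized_components(params)
    diag = {"G": params.D_G, "N": params.D_N, "C": params.D_C}
    return np.diag([diag.get(c, 0.0) for c in comps])


def growth_rates_at(
    k_values: np.ndarray, J: np.ndarray, D: np.ndarray
) -> np.ndarray:
    """Max real eigenvalue part of J - k^2 D for each wavenumber (batched)."""
    k = np.atleast_1d(np.asarray(k_values, dtype=float))
    mats = J[None, :, :] - (k**2)[:, None, None] * D[None, :, :]
    eig = np.linalg.eigvals(mats)
    return eig.real.max(axis=1)


def linearized_growth(params: ModelParameters, k: float, steady: dict | None = None) -> float:
    """Largest real eigenvalue part of the linearization at wavenumber k."""
    J = reaction_jacobian(params, steady)
    D = diffusion_matrix(params)
    return float(growth_rates_at(np.array([k]), J, D)[0])


def _default_k_hi(params: ModelParameters) -> float:
    removal = max(
        params.delta_mG, params.delta_mN, params.delta_G,
        params.delta_N, params.delta_C,
    )
    d_min = min(params.D_G, params.D_N, params.D_C)
    return 6.0 * np.sqrt(removal / d_min)


def dispersion_relation(
    params: ModelParameters,
    k_hi: float | None = None,
    n_k: int = 256,
    steady: dict | None = None,
    _max_extensions: int = 12,
) -> DispersionResult:
    """Dispersion relation on a [0, k_hi] grid with parabolic peak refinement.

    The grid is extended (k_hi doubled) until the growth-rate maximum lies in
    the grid interior, so the predicted wavelength never sits on the grid
    boundary. A steady state that is already unstable to homogeneous
    perturbations yields ``stable_at_zero=False`` and no Turing verdict.
    """
    if n_k < 200:
        raise ValueError("k grid needs at least 200 points")
    if steady is None:
        steady = homogeneous_steady_state(params)
    J = reaction_jacobian(params, steady)
    D = diffusion_matrix(params)
    hi = k_hi if k_hi is not None else _default_k_hi(params)
    for _ in range(_max_extensions):
        k = np.linspace(0.0, hi, n_k)
        sigma = growth_rates_at(k, J, D)
        imax = int(np.argmax(sigma))
        if imax < n_k - 1:
            break
        hi *= 2.0
    stable_at_zero = sigma[0] < -GROWTH_TOL
    interior_max = sigma[1:].max()
    turing = bool(stable_at_zero and interior_max > GROWTH_TOL)
    k_max = lam = None
    if turing:
        if 0 < imax < n_k - 1:
            # three-point parabolic refinement around the grid maximum
            y0, y1, y2 = sigma[imax - 1 : imax + 2]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            k_max = float(k[imax] + shift * (k[1] - k[0]))
        else:
            k_max = float(k[imax])
        lam = 2 * np.pi / k_max
    return DispersionResult(
        k_values=k,
        growth_rates=sigma,
        k_max=k_max,
        lambda_pred=lam,
        turing_unstable=turing,
        stable_at_zero=bool(stable_at_zero),
        steady_state=dict(steady),
    )


# -- parameter-space screen -------------------------------------------------

#: parameters sampled by the screen (regulatory topology and Hill exponents
#: are held fixed; bounds are multiplicative around a center set).
SCREEN_PARAMETERS = (
    "D_G", "D_N", "D_C", "k_on", "k_off", "alpha_G", "alpha_N", "beta_G",
    "beta_N", "delta_mG", "delta_mN", "delta_G", "delta_N", "delta_C",
    "K_S", "S_max", "K_G", "K_N",
)


@dataclass
class SamplerSpec:
    """Log-uniform sampling bounds, per parameter, around a center set."""

    center: ModelParameters
    span: float = 100.0  # upper/lower bound ratio to the center (10**2 = +-2 decades)
    parameters: tuple = SCREEN_PARAMETERS

    def bounds(self) -> dict:
        out = {}
        for name in self.parameters:
            c = getattr(self.center, name)
            out[name] = (c / self.span, c * self.span)
        return out


@dataclass
class ScreenResult:
    n_draws: int
    n_unstable: int
    n_failed: int
    unstable_draws: list
    records: "object"  # pandas.DataFrame

    @property
    def fraction_unstable(self) -> float:
        ok = self.n_draws - self.n_failed
        return self.n_unstable / ok if ok else float("nan")


def sample_parameters(spec: SamplerSpec, rng: np.random.Generator) -> ModelParameters:
    bounds = spec.bounds()
    draws = {
        name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for name, (lo, hi) in bounds.items()
    }
    return spec.center.replace(**draws)


def screen_parameter_space(
    spec: SamplerSpec,
    n_draws: int,
    nog_regulation: str,
    seed: int,
    n_k: int = 200,
) -> ScreenResult:
    """Fraction of log-uniform parameter draws that are Turing-unstable.

    This is the testable shadow of the network's necessary condition: with
    ``nog_regulation`` in {constant, activated} no draw should destabilize,
    whereas the repressed topology patterns on a nonzero fraction of
    parameter space. Steady-state failures are counted separately and
    excluded from the denominator. Deterministic for a fixed seed.
    """
    import pandas as pd

    if nog_regulation not in NOG_REGULATION_MODES:
        raise ValueError(f"unknown nog_regulation {nog_regulation!r}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    unstable = []
    n_fail = 0
    for i in range(n_draws):
        params = sample_parameters(spec, rng).replace(nog_regulation=nog_regulation)
        row = {"draw": i}
        row.update({name: getattr(params, name) for name in spec.parameters})
        try:
            disp = dispersion_relation(params, n_k=n_k)
        except model.SteadyStateError:
            n_fail += 1
            row.update(status="steady_state_failed", turing_unstable=False)
        else:
            row.update(
                status="ok",
                turing_unstable=disp.turing_unstable,
                stable_at_zero=disp.stable_at_zero,
                max_growth=float(disp.growth_rates[1:].max()),
                lambda_pred=disp.lambda_pred if disp.turing_unstable else np.nan,
            )
            if disp.turing_unstable:
                unstable.append(params)
        rows.append(row)
    n_unstable = len(unstable)
    return ScreenResult(
        n_draws=n_draws,
        n_unstable=n_unstable,
        n_failed=n_fail,
        unstable_draws=unstable,
        records=pd.DataFrame(rows),
    )


def equal_diffusivity_witness(
    spec: SamplerSpec,
    seed: int,
    n_draws: int = 2000,
    nog_regulation: str = "repressed",
    min_growth: float = 0.0,
) -> ModelParameters | None:
    """Search for a Turing-unstable set with equal diffusivities.

    Draws from ``spec`` with D_N and D_C tied to D_G; returns the first
    unstable witness whose fastest-growing mode exceeds ``min_growth``
    (1/h; demand e.g. 0.05 so the witness patterns on a developmental
    timescale), or None if the budget is exhausted (a reported outcome,
    not an error).
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_draws):
        params = sample_parameters(spec, rng)
        params = params.replace(
            D_N=params.D_G, D_C=params.D_G, nog_regulation=nog_regulation
        )
        try:
            disp = dispersion_relation(params)
        except model.SteadyStateError:
            continue
        if disp.turing_unstable and disp.growth_rates[1:].max() > min_growth:
            return params
    return None
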