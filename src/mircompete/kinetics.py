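"""Mass-action kinetics of pre-miRNA maturation by Dicer.

The model tracks, for each pre-miRNA species *i*, free pre-miRNA ``P_i``,
the transient pre-miRNA--Dicer complex ``PD_i``, an irreversibly stalled
complex ``S_i`` and mature miRNA ``M_i``, plus a single pool of free Dicer
``D`` (all concentrations in nM, time in seconds)::

    dP_i/dt  = k_b PD_i - (k_a + k_c) P_i D
    dPD_i/dt = k_a P_i D - (k_b + k_d) PD_i
    dS_i/dt  = k_c P_i D
    dM_i/dt  = k_d PD_i
    dD/dt    = sum_i [ (k_b + k_d) PD_i - (k_a + k_c) P_i D ]

Dicer is released on both dissociation (``k_b``) and dicing (``k_d``) but is
permanently sequestered by stalling (``k_c``), which makes free Dicer a shared,
exhaustible resource: species compete for it whenever the total stall demand
approaches the initial pool.

Two conservation laws hold exactly and are the main correctness checks:
``P_i + PD_i + S_i + M_i = P0_i`` per species, and
``D + sum_i (PD_i + S_i) = D0``.

When free Dicer is never exhausted the fate of a single pre-miRNA molecule is
a first-passage problem (P -> PD -> {mature, back to P} or P -> S) whose
absorption probability into the mature state is

    q = k_a k_d / (k_a k_d + k_c (k_b + k_d)),

exposed as :func:`closed_form_diced_fraction` and used throughout as an
independent oracle for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateSet",
    "SpeciesSpec",
    "SystemConfig",
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "WT_RATES",
    "SL_RATES",
    "derivatives",
    "simulate",
    "run_to_steady_state",
    "closed_form_diced_fraction",
    "stall_demand",
]

RATE_NAMES = ("k_a", "k_b", "k_c", "k_d")

#: Hard horizon for steady-state runs: 3000 min.
DEFAULT_T_MAX = 180_000.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces unphysical output."""


@dataclass(frozen=True)
class RateSet:
    """Per-species reaction rates.

    Parameters
    ----------
    k_a : float
        Association rate of pre-miRNA with Dicer, s^-1 nM^-1.
    k_b : float
        Dissociation rate of the transient complex, s^-1.
    k_c : float
        Stalling rate (irreversible sequestration), s^-1 nM^-1.
    k_d : float
        Dicing (maturation) rate, s^-1.
    """

    k_a: float
    k_b: float
    k_c: float
    k_d: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name}={v!r} must be finite and >= 0")

    def scaled(self, rate_name: str, factor: float) -> "RateSet":
        """Return a copy with one rate multiplied by ``factor``."""
        if rate_name not in RATE_NAMES:
            raise ValueError(f"unknown rate {rate_name!r}; expected one of {RATE_NAMES}")
        return replace(self, **{rate_name: getattr(self, rate_name) * factor})

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.k_a, self.k_b, self.k_c, self.k_d)


#: Fitted wild-type (long-loop let-7) rates.
WT_RATES = RateSet(k_a=0.0053, k_b=0.1340, k_c=0.0122, k_d=10439.0)
#: Fitted short-loop mutant rates.
SL_RATES = RateSet(k_a=0.0020, k_b=0.2902, k_c=0.0343, k_d=0.0707)


@dataclass(frozen=True)
class SpeciesSpec:
    """One pre-miRNA species: a label, its initial concentration and rates."""

    label: str
    P0: float
    rates: RateSet

    def __post_init__(self) -> None:
        if not math.isfinite(self.P0) or self.P0 < 0:
            raise ValueError(f"P0={self.P0!r} must be finite and >= 0")


@dataclass(frozen=True)
class SystemConfig:
    """A set of pre-miRNA species plus the Dicer pool.

    ``shared_dicer=True`` couples all species through one free-Dicer pool
    (competition); ``shared_dicer=False`` means each species is simulated in
    its own isolated system with the full ``D0`` (the no-competition control).
    """

    species: tuple[SpeciesSpec, ...]
    D0: float
    shared_dicer: bool = True

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ValueError("need at least one species")
        object.__setattr__(self, "species", tuple(self.species))
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError(f"species labels must be unique, got {labels}")
        if not math.isfinite(self.D0) or self.D0 < 0:
            raise ValueError(f"D0={self.D0!r} must be finite and >= 0")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.species)

    def species_by_label(self, label: str) -> SpeciesSpec:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(f"no species labelled {label!r}")

    def with_P0(self, label: str, P0: float) -> "SystemConfig":
        """Return a config with one species' initial concentration replaced."""
        if label not in self.labels:
            raise KeyError(f"no species labelled {label!r}")
        new = tuple(replace(s, P0=P0) if s.label == label else s for s in self.species)
        return replace(self, species=new)

    def isolated(self, label: str) -> "SystemConfig":
        """Single-species config for ``label`` with the full Dicer pool."""
        return SystemConfig(
            species=(self.species_by_label(label),), D0=self.D0, shared_dicer=True
        )

    def initial_state(self) -> np.ndarray:
        n = self.n_species
        y0 = np.zeros(4 * n + 1)
        y0[:n] = [s.P0 for s in self.species]
        y0[4 * n] = self.D0
        return y0


def _rate_arrays(config: SystemConfig) -> tuple[np.ndarray, ...]:
    ka = np.array([s.rates.k_a for s in config.species])
    kb = np.array([s.rates.k_b for s in config.species])
    kc = np.array([s.rates.k_c for s in config.species])
    kd = np.array([s.rates.k_d for s in config.species])
    return ka, kb, kc, kd


def derivatives(state: np.ndarray, config: SystemConfig) -> np.ndarray:
    """Time derivative of the packed state ``[P_1..n, PD_1..n, S_1..n, M_1..n, D]``.

    The free-Dicer equation sums binding/release over all species so that
    Dicer conservation holds for the coupled (shared-pool) system.
    """
    state = np.asarray(state, dtype=float)
    n = config.n_species
    if state.shape != (4 * n + 1,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({4 * n + 1},) for {n} species"
        )
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    ka, kb, kc, kd = _rate_arrays(config)
    P, PD = state[:n], state[n : 2 * n]
    D = state[4 * n]
    bind = (ka + kc) * P * D
    dP = kb * PD - bind
    dPD = ka * P * D - (kb + kd) * PD
    dS = kc * P * D
    dM = kd * PD
    dD = np.sum((kb + kd) * PD - bind)
    return np.concatenate([dP, dPD, dS, dM, [dD]])


@dataclass
class Trajectory:
    """Time-resolved concentrations of one shared-pool integration.

    Arrays ``P, PD, S, M`` have shape ``(n_times, n_species)``; ``D`` has
    shape ``(n_times,)``.
    """

    times: np.ndarray
    P: np.ndarray
    PD: np.ndarray
    S: np.ndarray
    M: np.ndarray
    D: np.ndarray
    config: SystemConfig

    @property
    def labels(self) -> tuple[str, ...]:
        return self.config.labels

    def species_index(self, label: str) -> int:
        return self.labels.index(label)

    def to_frame(self):
        """Tidy table with columns time_s, species, P, PD, S, M, D."""
        import pandas as pd

        frames = []
        for j, label in enumerate(self.labels):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.times,
                        "species": label,
                        "P": self.P[:, j],
                        "PD": self.PD[:, j],
                        "S": self.S[:, j],
                        "M": self.M[:, j],
                        "D": self.D,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def conservation_errors(self) -> tuple[float, float]:
        """Worst-case violation of per-species mass and Dicer conservation."""
        P0 = np.array([s.P0 for s in self.config.species])
        mass = self.P + self.PD + self.S + self.M - P0
        dicer = self.D + (self.PD + self.S).sum(axis=1) - self.config.D0
        return float(np.abs(mass).max()), float(np.abs(dicer).max())


@dataclass
class SteadyState:
    """Asymptotic concentrations per species plus the free-Dicer pool.

    ``D`` is a scalar for a shared-pool run; for a no-competition run each
    species had its own full pool, so ``D`` is then a per-species array.
    """

    labels: tuple[str, ...]
    P: np.ndarray
    PD: np.ndarray
    S: np.ndarray
    M: np.ndarray
    D: float | np.ndarray
    converged: bool
    t_end: float

    def mature(self, label: str) -> float:
        return float(self.M[self.labels.index(label)])

    def mature_series(self):
        import pandas as pd

        return pd.Series(self.M, index=list(self.labels), name="M")


def _solve_segment(config, y0, t0, t1, t_eval, rtol, atol, method):
    sol = solve_ivp(
        lambda t, y: derivatives(y, config),
        (t0, t1),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        rates = ", ".join(
            f"{s.label}: ka={s.rates.k_a:g} kb={s.rates.k_b:g} "
            f"kc={s.rates.k_c:g} kd={s.rates.k_d:g}"
            for s in config.species
        )
        raise IntegrationError(
            f"ODE solver failed on [{t0:g}, {t1:g}] s ({sol.message}); species: {rates}"
        )
    return sol


def _check_nonnegative(y: np.ndarray, config: SystemConfig, rtol: float, atol: float) -> None:
    # never clip silently: a visibly negative concentration means the solver
    # tolerances are inadequate for this rate set
    scale = max(config.D0, sum(s.P0 for s in config.species), 1.0)
    floor = -10.0 * (atol + rtol * scale)
    if y.min() < floor:
        raise IntegrationError(
            f"negative concentration {y.min():.3e} below tolerance floor {floor:.3e}"
        )


def simulate(
    config: SystemConfig,
    t_end: float,
    *,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the coupled shared-pool system from its initial state to ``t_end`` s.

    The dicing rate can exceed 1e4 s^-1 while binding acts on ~100 s
    timescales, so the system is stiff. The default integrator is implicit
    (BDF): the switching LSODA solver can stall in its non-stiff mode on
    the long quiescent stretch after the transient, where the fast complex
    keeps a ~1e4 s^-1 eigenvalue alive while every derivative is tiny.
    Tight default tolerances keep the conservation laws visibly intact.
    """
    if not config.shared_dicer:
        raise ValueError(
            "simulate integrates the coupled shared-pool system; for the "
            "no-competition control run each species via config.isolated(label)"
        )
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 200)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = _solve_segment(config, config.initial_state(), 0.0, t_end, t_eval, rtol, atol, method)
    _check_nonnegative(sol.y, config, rtol, atol)
    n = config.n_species
    y = sol.y
    return Trajectory(
        times=sol.t,
        P=y[:n].T,
        PD=y[n : 2 * n].T,
        S=y[2 * n : 3 * n].T,
        M=y[3 * n : 4 * n].T,
        D=y[4 * n],
        config=config,
    )


def _steady_state_shared(
    config: SystemConfig,
    steady_tol: float,
    t_max: float,
    n_probes: int,
    rtol: float,
    atol: float,
    method: str,
) -> SteadyState:
    y = config.initial_state()
    t = 0.0
    converged = bool(np.max(np.abs(derivatives(y, config))) < steady_tol)
    probes = np.geomspace(max(1.0, t_max * 1e-5), t_max, n_probes)
    for t_next in probes:
        if converged:
            break
        sol = _solve_segment(config, y, t, t_next, None, rtol, atol, method)
        y = sol.y[:, -1]
        _check_nonnegative(y, config, rtol, atol)
        t = t_next
        converged = bool(np.max(np.abs(derivatives(y, config))) < steady_tol)
    n = config.n_species
    # a species with P0 = 0 is identically zero; scrub solver roundoff so
    # knockouts read exactly 0
    absent = np.array([s.P0 == 0.0 for s in config.species])
    blocks = [y[k * n : (k + 1) * n].copy() for k in range(4)]
    for block in blocks:
        block[absent] = 0.0
    return SteadyState(
        labels=config.labels,
        P=blocks[0],
        PD=blocks[1],
        S=blocks[2],
        M=blocks[3],
        D=float(y[4 * n]),
        converged=converged,
        t_end=t,
    )


def run_to_steady_state(
    config: SystemConfig,
    *,
    steady_tol: float = 1e-9,
    t_max: float = DEFAULT_T_MAX,
    n_probes: int = 25,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> SteadyState:
    """Integrate until all derivatives fall below ``steady_tol`` nM/s.

    Convergence is probed at logarithmically spaced times up to ``t_max``
    (default 3000 min, the horizon used for all steady-state read-outs).
    With ``shared_dicer=False`` each species is run alone against the full
    Dicer pool and the per-species results are assembled; ``D`` is then an
    array (one leftover pool per species).
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if config.shared_dicer:
        return _steady_state_shared(config, steady_tol, t_max, n_probes, rtol, atol, method)
    parts = [
        _steady_state_shared(
            config.isolated(label), steady_tol, t_max, n_probes, rtol, atol, method
        )
        for label in config.labels
    ]
    return SteadyState(
        labels=config.labels,
        P=np.array([p.P[0] for p in parts]),
        PD=np.array([p.PD[0] for p in parts]),
        S=np.array([p.S[0] for p in parts]),
        M=np.array([p.M[0] for p in parts]),
        D=np.array([p.D for p in parts]),
        converged=all(p.converged for p in parts),
        t_end=max(p.t_end for p in parts),
    )


def closed_form_diced_fraction(rates: RateSet) -> float:
    """Absorption probability of a single pre-miRNA into the mature state.

    ``q = k_a k_d / (k_a k_d + k_c (k_b + k_d))`` — the steady-state diced
    fraction M/P0 whenever free Dicer is never exhausted (total stall demand
    below D0), which the caller must check, e.g. via :func:`stall_demand`.
    """
    num = rates.k_a * rates.k_d
    den = num + rates.k_c * (rates.k_b + rates.k_d)
    if den == 0.0:
        raise ValueError(
            "diced fraction undefined: k_a*k_d + k_c*(k_b + k_d) = 0 "
            "(need k_a or k_c positive and k_b + k_d positive)"
        )
    return num / den


def stall_demand(config: SystemConfig) -> float:
    """Total Dicer permanently sequestered if no species is supply-limited.

    ``sum_i (1 - q_i) P0_i``: if this is below ``D0`` the pool is never
    exhausted and every species attains its closed-form diced fraction.
    """
    return float(
        sum((1.0 - closed_form_diced_fraction(s.rates)) * s.P0 for s in config.species)
    )
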