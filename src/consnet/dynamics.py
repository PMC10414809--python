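"""Coupled plant community / environment dynamics.

The community follows generalized Lotka–Volterra growth with an
additive environmental forcing on the per-capita rate,

    dN_i/dt = N_i (r_i + sum_j B_ij N_j) + (sum_k A_ik E_k) N_i

while each environmental factor integrates a baseline drive plus the
species' engineering effects,

    dE_k/dt = K_k + sum_i gamma_ki N_i.

The coupling functions are linear by default — the minimal assumption —
and the chosen form is recorded on the spec so saturating alternatives
can be slotted in without changing the equations' shape.  ``B`` and
``A`` may be obtained from a fitted Markov network via
:func:`rescale_from_mrf`: the statistical associations have no dynamical
units, so the rescaling constants are free modelling parameters.

Integration is fixed-step fourth-order Runge–Kutta for bit-for-bit
reproducibility; species falling below an extinction threshold are
clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mrf import MarkovNetworkParams

__all__ = ["DynamicsSpec", "Trajectory", "simulate", "rescale_from_mrf", "equilibria"]

EXTINCTION_THRESHOLD = 1e-9


@dataclass
class DynamicsSpec:
    """Parameters of the coupled community-environment system.

    r : per-species intrinsic growth rates (1/time)
    B : species x species interaction matrix (effect of j on i per unit
        abundance; diagonal = self-regulation, typically negative)
    A : species x factors environment-effect matrix (rescaled alpha)
    gamma : factors x species engineering matrix (effect of species on
        each factor per unit abundance)
    K_drive : per-factor baseline forcing (factor units / time)
    env_coupling : functional form of the environment coupling
        ("linear" is the only built-in form)
    E_clip : optional (F, 2) per-factor [min, max] bounds for factors
        that are physically bounded (e.g. moisture fraction)
    """

    r: np.ndarray
    B: np.ndarray
    A: np.ndarray
    gamma: np.ndarray
    K_drive: np.ndarray
    env_coupling: str = "linear"
    species_names: list | None = None
    factor_names: list | None = None
    E_clip: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.K_drive = np.atleast_1d(np.asarray(self.K_drive, dtype=float))
        S = self.r.size
        F = self.K_drive.size
        if self.B.shape != (S, S):
            raise ValueError(f"B shape {self.B.shape} != ({S}, {S})")
        if self.A.shape != (S, F):
            raise ValueError(f"A shape {self.A.shape} != ({S}, {F})")
        if self.gamma.shape != (F, S):
            raise ValueError(f"gamma shape {self.gamma.shape} != ({F}, {S})")
        if self.env_coupling != "linear":
            raise ValueError(f"unsupported env_coupling {self.env_coupling!r}")
        if self.E_clip is not None:
            self.E_clip = np.asarray(self.E_clip, dtype=float).reshape(F, 2)

    @property
    def n_species(self) -> int:
        return self.r.size

    @property
    def n_factors(self) -> int:
        return self.K_drive.size

    def to_dict(self) -> dict:
        d = {
            "r": self.r.tolist(), "B": self.B.tolist(), "A": self.A.tolist(),
            "gamma": self.gamma.tolist(), "K_drive": self.K_drive.tolist(),
            "env_coupling": self.env_coupling,
            "species_names": self.species_names, "factor_names": self.factor_names,
        }
        if self.E_clip is not None:
            d["E_clip"] = self.E_clip.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicsSpec":
        return cls(**d)


@dataclass
class Trajectory:
    """Time-indexed state of the coupled system."""

    times: np.ndarray
    N: np.ndarray  # (T, S)
    E: np.ndarray  # (T, F)
    diverged: bool = False
    species_names: list | None = None
    factor_names: list | None = None

    def to_frame(self):
        """Tidy long format: time, variable, type in {species, factor}, value."""
        import pandas as pd

        S, F = self.N.shape[1], self.E.shape[1]
        sp = self.species_names or [f"species_{i}" for i in range(S)]
        fa = self.factor_names or [f"factor_{k}" for k in range(F)]
        frames = []
        for j, name in enumerate(sp):
            frames.append(pd.DataFrame(
                {"time": self.times, "variable": name, "type": "species", "value": self.N[:, j]}
            ))
        for k, name in enumerate(fa):
            frames.append(pd.DataFrame(
                {"time": self.times, "variable": name, "type": "factor", "value": self.E[:, k]}
            ))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _derivatives(spec: DynamicsSpec, N: np.ndarray, E: np.ndarray):
    growth = spec.r + spec.B @ N + spec.A @ E
    dN = N * growth
    dE = spec.K_drive + spec.gamma @ N
    return dN, dE


def simulate(
    spec: DynamicsSpec,
    N0,
    E0,
    t_max: float,
    dt: float = 0.01,
    seed: int | None = None,
) -> Trajectory:
    """Integrate the coupled system with fixed-step RK4.

    Species are clamped to zero once they fall below the extinction
    threshold (1e-9).  A non-finite state stops the integration and
    flags the (truncated) trajectory as diverged instead of raising.
    The default path is fully deterministic; ``seed`` is reserved for
    stochastic forcing extensions.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    N = np.atleast_1d(np.asarray(N0, dtype=float)).copy()
    E = np.atleast_1d(np.asarray(E0, dtype=float)).copy()
    if np.any(N < 0):
        raise ValueError("initial abundances must be non-negative")
    if N.size != spec.n_species or E.size != spec.n_factors:
        raise ValueError("N0/E0 sizes do not match spec")

    n_steps = int(round(t_max / dt))
    times = np.empty(n_steps + 1)
    Ns = np.empty((n_steps + 1, N.size))
    Es = np.empty((n_steps + 1, E.size))
    times[0], Ns[0], Es[0] = 0.0, N, E
    diverged = False
    t_index = 0

    for step in range(1, n_steps + 1):
        k1N, k1E = _derivatives(spec, N, E)
        k2N, k2E = _derivatives(spec, N + 0.5 * dt * k1N, E + 0.5 * dt * k1E)
        k3N, k3E = _derivatives(spec, N + 0.5 * dt * k2N, E + 0.5 * dt * k2E)
        k4N, k4E = _derivatives(spec, N + dt * k3N, E + dt * k3E)
        N = N + (dt / 6.0) * (k1N + 2 * k2N + 2 * k3N + k4N)
        E = E + (dt / 6.0) * (k1E + 2 * k2E + 2 * k3E + k4E)
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(E))):
            diverged = True
            break
        N = np.where(N < EXTINCTION_THRESHOLD, 0.0, N)
        if spec.E_clip is not None:
            E = np.clip(E, spec.E_clip[:, 0], spec.E_clip[:, 1])
        t_index = step
        times[step], Ns[step], Es[step] = step * dt, N, E

    end = t_index + 1
    return Trajectory(
        times=times[:end], N=Ns[:end], E=Es[:end], diverged=diverged,
        species_names=spec.species_names, factor_names=spec.factor_names,
    )


def rescale_from_mrf(
    params: MarkovNetworkParams,
    beta_scale: float = 0.1,
    alpha_scale: float = 0.1,
    self_regulation: float = 1.0,
    r=None,
    gamma=None,
    K_drive=None,
) -> DynamicsSpec:
    """Build a DynamicsSpec from fitted Markov network parameters.

    Off-diagonal interactions are ``B_ij = beta_scale * beta_ij`` (signs
    preserved), the diagonal is ``-self_regulation``, and the
    environment effects are ``A = alpha_scale * alpha``.  The scales are
    free parameters — statistical associations carry no dynamical units.
    ``r`` defaults to 0.1 per species; ``gamma``/``K_drive`` default to
    zero (environment held constant unless the caller couples it).
    """
    if beta_scale <= 0 or alpha_scale <= 0:
        raise ValueError("scales must be positive")
    if self_regulation < 0:
        raise ValueError("self_regulation must be >= 0")
    S, F = params.n_species, params.n_factors
    B = beta_scale * np.nan_to_num(params.beta)
    np.fill_diagonal(B, -self_regulation)
    A = alpha_scale * np.nan_to_num(params.alpha)
    r = np.full(S, 0.1) if r is None else np.asarray(r, dtype=float)
    gamma = np.zeros((F, S)) if gamma is None else np.asarray(gamma, dtype=float)
    K_drive = np.zeros(F) if K_drive is None else np.asarray(K_drive, dtype=float)
    return DynamicsSpec(
        r=r, B=B, A=A, gamma=gamma, K_drive=K_drive,
        species_names=list(params.species_names),
        factor_names=list(params.factor_names),
    )


@dataclass
class EquilibriumResult:
    N_star: np.ndarray | None
    feasible: bool
    stable: bool | None
    eigenvalues: np.ndarray | None
    singular: bool = False


def equilibria(spec: DynamicsSpec, E_fixed) -> EquilibriumResult:
    """Interior equilibrium of the community at fixed environment.

    Solves ``r + A E + B N* = 0``; feasibility requires N* > 0
    everywhere, and local stability is judged from the eigenvalues of
    the community Jacobian ``diag(N*) B`` at the interior point.
    Singular B is flagged and no equilibrium is returned.
    """
    E_fixed = np.atleast_1d(np.asarray(E_fixed, dtype=float))
    rhs = -(spec.r + spec.A @ E_fixed)
    try:
        cond = np.linalg.cond(spec.B)
        if not np.isfinite(cond) or cond > 1e12:
            return EquilibriumResult(None, False, None, None, singular=True)
        N_star = np.linalg.solve(spec.B, rhs)
    except np.linalg.LinAlgError:
        return EquilibriumResult(None, False, None, None, singular=True)
    feasible = bool(np.all(N_star > 0))
    jac = N_star[:, None] * spec.B
    eig = np.linalg.eigvals(jac)
    stable = bool(np.all(eig.real < 0)) if feasible else None
    return EquilibriumResult(N_star, feasible, stable, eig)
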