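"""Open-system ODE models of glycosyltransferase action.

Two model classes are provided.  :class:`OneDimensionalModel` is the
minimal substrate-inhibited system: a single acceptor exchanging with
an external reservoir at rate K([B]0 - [B]) while a buffered donor
drives a non-monotone enzymatic sink,

    db/dt = K(b0 - b) - Vmax a b / (Ka Kb + Kb a + Ka b + (Ka/Ks) b^2 + a b).

:class:`NetworkModel` assembles the full multi-acceptor system on a
glycoform lattice: every species (each acceptor and the donor)
exchanges with the exterior at the same diffusion constant K, and each
lattice edge carries one enzyme velocity evaluated from the shared
competition sums (AE, AE', s_I).  For the diantennary case this is the
five-ODE system

    db_i/dt = K(b0 - b_i) + (production) - (consumption)
    da/dt   = K(a0 - a)   - (sum of all velocities).

Both classes expose a uniform interface for the continuation module: a
``species`` tuple, a ``default_params()`` mapping of named continuation
parameters, and ``rhs_vec(y, params)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import GlycanNetwork
from .rate_laws import (
    CompetitionSums,
    DonorParams,
    ReactionParams,
    SiteConstants,
    competition_sums,
    edge_rate,
    ki_pairs_from_sites,
)

__all__ = [
    "OneDimensionalModel",
    "NetworkModel",
    "TimeCourse",
    "SimulationError",
    "build_1d_model",
    "rhs",
    "simulate",
]


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid state reached."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(message)
        self.t = t
        self.last_state = state


def _merge_params(defaults: Mapping[str, float],
                  params: Mapping[str, float] | None) -> dict[str, float]:
    merged = dict(defaults)
    if params:
        for k, v in params.items():
            if k not in merged:
                raise ValueError(f"unknown parameter {k!r}; have {sorted(merged)}")
            merged[k] = float(v)
    return merged


@dataclass
class OneDimensionalModel:
    """Single-acceptor open system with a buffered donor.

    Parameters are dimensionless: ``a`` the constant donor
    concentration, ``K`` the diffusion (exchange) constant, ``Kb`` the
    acceptor Michaelis constant, ``Ks`` the substrate-inhibition
    constant (the quadratic-term constant), ``Vmax`` the maximal
    velocity, ``Ka`` the donor Michaelis constant, and ``b0`` the
    external acceptor concentration (the natural bifurcation
    parameter).
    """

    a: float = 0.6
    K: float = 0.075
    Kb: float = 0.1
    Ks: float = 0.05
    Vmax: float = 1.0
    Ka: float = 0.6
    b0: float = 2.0

    species: tuple[str, ...] = ("B",)

    def __post_init__(self) -> None:
        for name in ("a", "K", "Kb", "Ks", "Vmax", "Ka"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.b0 < 0:
            raise ValueError("b0 must be non-negative")

    @property
    def n(self) -> int:
        return 1

    def default_params(self) -> dict[str, float]:
        return {"b0": self.b0, "K": self.K, "a": self.a, "Ks": self.Ks}

    def _denominator_coeffs(self, p: Mapping[str, float]) -> tuple[float, float, float]:
        """(c0, c1, c2) of v_enz = Vmax a b / (c0 + c1 b + c2 b^2)."""
        a, Ks = p["a"], p["Ks"]
        return (self.Ka * self.Kb + self.Kb * a, self.Ka + a, self.Ka / Ks)

    def v_enz(self, b: float, params: Mapping[str, float] | None = None) -> float:
        """Enzymatic (substrate-inhibited) velocity at acceptor level b."""
        p = _merge_params(self.default_params(), params)
        c0, c1, c2 = self._denominator_coeffs(p)
        return self.Vmax * p["a"] * b / (c0 + c1 * b + c2 * b * b)

    def dv_enz_db(self, b: float, params: Mapping[str, float] | None = None) -> float:
        """Analytic derivative of v_enz with respect to b."""
        p = _merge_params(self.default_params(), params)
        c0, c1, c2 = self._denominator_coeffs(p)
        den = c0 + c1 * b + c2 * b * b
        return self.Vmax * p["a"] * (c0 - c2 * b * b) / (den * den)

    def rhs_vec(self, y: np.ndarray,
                params: Mapping[str, float] | None = None) -> np.ndarray:
        p = _merge_params(self.default_params(), params)
        b = float(y[0])
        return np.array([p["K"] * (p["b0"] - b) - self.v_enz(b, p)])


@dataclass
class NetworkModel:
    """Open system on a glycoform lattice with a dynamic donor pool.

    State vector order: acceptors in lattice order (B1 ... B_{2^m}),
    then the donor (unless ``constant_donor``).  Named continuation
    parameters: ``a0`` (donor external), ``b0`` (shared acceptor
    external; per-species entries in ``external_overrides`` take
    precedence) and ``K`` (diffusion constant).
    """

    network: GlycanNetwork
    edges: tuple[ReactionParams, ...]          # one per lattice edge
    products: tuple[str, ...]                  # product species per edge
    sites: tuple[SiteConstants, ...]
    donor_name: str
    donor_Ks: float
    K: float
    a0: float
    b0: float
    external_overrides: dict[str, float] = field(default_factory=dict)
    mechanism: str = "inhibited"
    constant_donor: bool = False

    def __post_init__(self) -> None:
        if not self.donor_Ks > 0:
            raise ValueError("donor Ks must be positive")
        if not self.K > 0:
            raise ValueError("diffusion constant K must be positive")
        for name, v in (("a0", self.a0), ("b0", self.b0)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        acceptors = self.network.species_names
        for e, prod in zip(self.edges, self.products):
            if e.substrate not in acceptors or prod not in acceptors:
                raise ValueError(f"edge {e.edge} references unknown species")
        if len(self.edges) != len(self.network.edges):
            raise ValueError(
                f"expected {len(self.network.edges)} parameterised edges, "
                f"got {len(self.edges)}"
            )
        self._ki_pairs = ki_pairs_from_sites(self.sites)
        # stoichiometry: rows = species, cols = edges
        names = list(self.species)
        S = np.zeros((len(names), len(self.edges)))
        for k, (e, prod) in enumerate(zip(self.edges, self.products)):
            S[names.index(e.substrate), k] -= 1.0
            S[names.index(prod), k] += 1.0
            if not self.constant_donor:
                S[names.index(self.donor_name), k] -= 1.0
        self._stoich = S

    @property
    def species(self) -> tuple[str, ...]:
        base = self.network.species_names
        return base if self.constant_donor else base + (self.donor_name,)

    @property
    def n(self) -> int:
        return len(self.species)

    def default_params(self) -> dict[str, float]:
        return {"a0": self.a0, "b0": self.b0, "K": self.K}

    def externals_vector(self, p: Mapping[str, float]) -> np.ndarray:
        """External concentration for each state-vector entry."""
        ext = []
        for s in self.species:
            if s == self.donor_name:
                ext.append(p["a0"])
            else:
                ext.append(self.external_overrides.get(s, p["b0"]))
        return np.array(ext)

    def velocities(self, y: np.ndarray,
                   params: Mapping[str, float] | None = None) -> np.ndarray:
        """Edge velocities at a state, from the shared competition sums."""
        p = _merge_params(self.default_params(), params)
        concs = dict(zip(self.species, np.asarray(y, dtype=float)))
        if self.constant_donor:
            concs[self.donor_name] = p["a0"]
        donor = DonorParams(Ks=self.donor_Ks, conc=max(concs[self.donor_name], 0.0))
        clipped = {k: max(v, 0.0) for k, v in concs.items()}
        cs = competition_sums(clipped, self.sites, ki_pairs=self._ki_pairs)
        out = np.empty(len(self.edges))
        for k, e in enumerate(self.edges):
            km_ax = None
            if self.mechanism == "compulsory":
                site = next(
                    s for s in self.sites
                    if s.species == e.substrate and s.site == e.site
                )
                km_ax = donor.Ks * e.Km / site.Ks
            out[k] = edge_rate(e, donor, clipped[e.substrate], cs,
                               self.mechanism, km_ax=km_ax)
        return out

    def rhs_vec(self, y: np.ndarray,
                params: Mapping[str, float] | None = None) -> np.ndarray:
        p = _merge_params(self.default_params(), params)
        y = np.asarray(y, dtype=float)
        v = self.velocities(y, p)
        return p["K"] * (self.externals_vector(p) - y) + self._stoich @ v


def build_1d_model(a: float, K: float, Kb: float, Ks: float,
                   Vmax: float, Ka: float, b0: float = 2.0) -> OneDimensionalModel:
    """Construct the single-acceptor substrate-inhibited open system."""
    return OneDimensionalModel(a=a, K=K, Kb=Kb, Ks=Ks, Vmax=Vmax, Ka=Ka, b0=b0)


def rhs(model, state: Mapping[str, float],
        params: Mapping[str, float] | None = None) -> dict[str, float]:
    """Right-hand side at a named concentration state, as a dict."""
    try:
        y = np.array([state[s] for s in model.species], dtype=float)
    except KeyError as exc:
        raise ValueError(f"state is missing species {exc.args[0]!r}") from None
    dy = model.rhs_vec(y, params)
    return dict(zip(model.species, dy.tolist()))


@dataclass
class TimeCourse:
    """Integrated trajectory: reporting times and per-species states."""

    times: np.ndarray
    states: np.ndarray          # shape (n_times, n_species)
    species: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "t", self.times)
        return df

    @property
    def final_state(self) -> dict[str, float]:
        return dict(zip(self.species, self.states[-1].tolist()))


def simulate(model, initial: Mapping[str, float] | Sequence[float],
             t_end: float, t_eval: Sequence[float] | None = None,
             params: Mapping[str, float] | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> TimeCourse:
    """Integrate the model with a stiff-capable method (LSODA).

    The sharp curvature introduced by small dissociation constants
    makes the network systems stiff; LSODA switches automatically.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if isinstance(initial, Mapping):
        y0 = np.array([initial[s] for s in model.species], dtype=float)
    else:
        y0 = np.asarray(initial, dtype=float)
        if y0.shape != (model.n,):
            raise ValueError(f"initial state must have length {model.n}")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 200)
    sol = solve_ivp(
        lambda t, y: model.rhs_vec(y, params),
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}",
            t=float(sol.t[-1]) if sol.t.size else 0.0,
            state=sol.y[:, -1] if sol.y.size else y0,
        )
    return TimeCourse(times=sol.t, states=sol.y.T, species=model.species)
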