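"""Initial-rate laws for a glycosyltransferase with n competing acceptors.

A donor Ax transfers the x moiety to one of n acceptor substrates
B_1 ... B_n sharing the same enzyme.  All laws below are initial-rate
expressions (no product terms) in which the competing acceptors enter
through three aggregate sums evaluated at the current concentration
state:

    AE  = sum_i [B_i] / Km_i      (Michaelis-weighted competition)
    AE' = sum_i [B_i] / Ks_i      (free-enzyme binding competition)
    s_I = (sum_k [B_k]/KI_k) * (sum_i [B_i]/Ks_i)
                                  (abortive ternary complexes)

where the sums run over (species, site) pairs carrying the relevant
constant — a multivalent acceptor contributes one term per site.  The
s_I double sum has one summand per (KI site, Ks site) pair and
factorises exactly into the product above.

All quantities are dimensionless (arbitrary concentration and time
units).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _cartesian
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DonorParams",
    "SiteConstants",
    "ReactionParams",
    "CompetitionSums",
    "KineticParams",
    "ki_pairs_from_sites",
    "competition_sums",
    "inhibition_sum_factorized",
    "edge_rate",
    "rate_random_order",
    "rate_compulsory_order",
    "rate_inhibited",
    "rate_single_inhibited",
    "apparent_km",
]


class ConfigurationError(ValueError):
    """A rate-law evaluation referenced a missing kinetic constant."""


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")


def _check_nonnegative(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class DonorParams:
    """Donor-side parameters: Ks (dissociation from E.Ax) and [Ax]."""

    Ks: float
    conc: float

    def __post_init__(self) -> None:
        _check_positive("donor Ks", self.Ks)
        _check_nonnegative("donor concentration", self.conc)


@dataclass(frozen=True)
class SiteConstants:
    """Kinetic constants attached to one recognition site of one species.

    Km is the Michaelis constant of the catalysed transfer at this site
    (dissociation from the productive ternary complex E.Ax.B), Ks the
    dissociation constant of the acceptor from the free enzyme, and KI
    the dissociation constant of the acceptor from an abortive
    E.B.B complex.  At least one must be present.
    """

    species: str
    site: int
    Km: float | None = None
    Ks: float | None = None
    KI: float | None = None

    def __post_init__(self) -> None:
        if self.Km is None and self.Ks is None and self.KI is None:
            raise ValueError(
                f"site ({self.species}, {self.site}) carries no constant"
            )
        for name, value in (("Km", self.Km), ("Ks", self.Ks), ("KI", self.KI)):
            if value is not None:
                _check_positive(f"{name} of ({self.species}, {self.site})", value)


@dataclass(frozen=True)
class ReactionParams:
    """Per-edge parameters of one catalysed transfer.

    The edge is identified by its substrate species and the site it
    fills.  ``Km_Ax`` is the donor Michaelis constant of this edge; when
    the substrate site carries a Ks it is derived from the identity
    Km_Ax = Ks_Ax * Km / Ks and need not be supplied.
    """

    edge: str
    substrate: str
    site: int
    Vmax: float
    Km: float
    Km_Ax: float | None = None

    def __post_init__(self) -> None:
        _check_positive(f"Vmax of edge {self.edge}", self.Vmax)
        _check_positive(f"Km of edge {self.edge}", self.Km)
        if self.Km_Ax is not None:
            _check_positive(f"Km_Ax of edge {self.edge}", self.Km_Ax)


@dataclass(frozen=True)
class CompetitionSums:
    """The aggregate competition terms at one concentration state."""

    AE: float
    AEprime: float
    sI: float


@dataclass(frozen=True)
class KineticParams:
    """Bundle of per-edge parameters and per-site constants."""

    edges: Mapping[str, ReactionParams]
    sites: tuple[SiteConstants, ...]

    def site(self, species: str, site: int) -> SiteConstants | None:
        for s in self.sites:
            if s.species == species and s.site == site:
                return s
        return None

    def km_ax(self, donor: DonorParams, edge: ReactionParams) -> float:
        """Donor Michaelis constant of an edge (derived or explicit)."""
        sc = self.site(edge.substrate, edge.site)
        if sc is not None and sc.Ks is not None:
            derived = donor.Ks * edge.Km / sc.Ks
            if edge.Km_Ax is not None and not np.isclose(edge.Km_Ax, derived):
                raise ConfigurationError(
                    f"edge {edge.edge}: explicit Km_Ax {edge.Km_Ax} is "
                    f"inconsistent with Ks_Ax*Km/Ks = {derived}"
                )
            return derived
        if edge.Km_Ax is None:
            raise ConfigurationError(
                f"edge {edge.edge}: no site Ks and no explicit Km_Ax"
            )
        return edge.Km_Ax


def ki_pairs_from_sites(
    sites: Sequence[SiteConstants],
) -> list[tuple[SiteConstants, SiteConstants]]:
    """All (KI-carrying, Ks-carrying) site pairs — the summands of s_I."""
    ki = [s for s in sites if s.KI is not None]
    ks = [s for s in sites if s.Ks is not None]
    return [(a, b) for a, b in _cartesian(ki, ks)]


def _conc(concs: Mapping[str, float], species: str) -> float:
    try:
        c = concs[species]
    except KeyError:
        raise ConfigurationError(f"no concentration given for species {species}")
    _check_nonnegative(f"[{species}]", c)
    return c


def competition_sums(
    concs: Mapping[str, float],
    sites: Sequence[SiteConstants],
    ki_pairs: Sequence[tuple[SiteConstants, SiteConstants]] | None = None,
) -> CompetitionSums:
    """Evaluate AE, AE' and s_I at a concentration state.

    ``s_I`` is accumulated as the explicit double sum over the supplied
    (KI site, Ks site) pairs; by construction of the Cartesian product
    it equals the factorised form (sum [B]/KI) * (sum [B]/Ks), see
    :func:`inhibition_sum_factorized`.  With ``ki_pairs`` omitted the
    full Cartesian product of the sites list is used.
    """
    ae = sum(_conc(concs, s.species) / s.Km for s in sites if s.Km is not None)
    aep = sum(_conc(concs, s.species) / s.Ks for s in sites if s.Ks is not None)
    if ki_pairs is None:
        ki_pairs = ki_pairs_from_sites(sites)
    si = 0.0
    for ki_site, ks_site in ki_pairs:
        if ki_site.KI is None:
            raise ConfigurationError(
                f"site ({ki_site.species}, {ki_site.site}) has no KI constant"
            )
        if ks_site.Ks is None:
            raise ConfigurationError(
                f"site ({ks_site.species}, {ks_site.site}) has no Ks constant"
            )
        si += (_conc(concs, ki_site.species) / ki_site.KI) * (
            _conc(concs, ks_site.species) / ks_site.Ks
        )
    return CompetitionSums(AE=float(ae), AEprime=float(aep), sI=float(si))


def inhibition_sum_factorized(
    concs: Mapping[str, float], sites: Sequence[SiteConstants]
) -> float:
    """s_I in factorised form: (sum [B]/KI) * (sum [B]/Ks)."""
    ki = sum(_conc(concs, s.species) / s.KI for s in sites if s.KI is not None)
    ks = sum(_conc(concs, s.species) / s.Ks for s in sites if s.Ks is not None)
    return float(ki * ks)


def edge_rate(
    edge: ReactionParams,
    donor: DonorParams,
    b: float,
    cs: CompetitionSums,
    mechanism: str = "inhibited",
    km_ax: float | None = None,
) -> float:
    """Velocity of one edge given precomputed competition sums.

    This is the single evaluation kernel shared by the public rate-law
    functions and by the open-system right-hand sides, so that every
    velocity in the package comes from one expression per mechanism.
    """
    a = donor.conc
    if mechanism == "inhibited":
        den = donor.Ks * edge.Km * (1.0 + cs.AEprime + cs.sI) + edge.Km * a * (
            1.0 + cs.AE
        )
    elif mechanism == "random":
        den = donor.Ks * edge.Km * (1.0 + cs.AEprime) + edge.Km * a * (1.0 + cs.AE)
    elif mechanism == "compulsory":
        if km_ax is None:
            raise ConfigurationError(
                f"edge {edge.edge}: compulsory-order law needs Km_Ax"
            )
        s_bj = cs.AE - b / edge.Km  # remove the own-site Michaelis term
        den = donor.Ks * edge.Km * (1.0 + s_bj) + edge.Km * a + km_ax * b + a * b
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return edge.Vmax * a * b / den


def rate_random_order(
    j: str,
    donor: DonorParams,
    concs: Mapping[str, float],
    params: KineticParams,
) -> float:
    """Initial rate of edge ``j`` for random-order donor/acceptor binding.

    Evaluated in the aggregate representation

        v_j = V_j [Ax][B_j] / (Ks_Ax Km_j (1 + AE') + Km_j [Ax] (1 + AE))

    which, because AE and AE' contain the substrate's own-site terms,
    is identical to the per-competitor form with separate Km_Ax [B_j]
    and [Ax][B_j] denominator terms.
    """
    edge = params.edges[j]
    cs = competition_sums(concs, params.sites, ki_pairs=())
    return edge_rate(edge, donor, _conc(concs, edge.substrate), cs, "random")


def rate_compulsory_order(
    j: str,
    donor: DonorParams,
    concs: Mapping[str, float],
    params: KineticParams,
) -> float:
    """Initial rate of edge ``j`` for compulsory-order binding (donor first).

    Quasi-steady-state law

        v_j = V_j [Ax][B_j] /
              (Ks_Ax Km_j (1 + s_Bj) + Km_j [Ax] + Km_Ax_j [B_j] + [Ax][B_j])

    with s_Bj the Michaelis-weighted competition sum excluding the
    edge's own site term.  Competitive suppression by the other
    substrates therefore vanishes as [Ax] grows large.
    """
    edge = params.edges[j]
    cs = competition_sums(concs, params.sites, ki_pairs=())
    return edge_rate(
        edge,
        donor,
        _conc(concs, edge.substrate),
        cs,
        "compulsory",
        km_ax=params.km_ax(donor, edge),
    )


def rate_inhibited(
    j: str,
    donor: DonorParams,
    concs: Mapping[str, float],
    params: KineticParams,
    ki_pairs: Sequence[tuple[SiteConstants, SiteConstants]] | None = None,
) -> float:
    """Initial rate of edge ``j`` with abortive-complex substrate inhibition.

        v_j = V_j [Ax][B_j] /
              (Ks_Ax Km_j (1 + AE' + s_I) + Km_j [Ax] (1 + AE))

    The same law holds for random- and compulsory-order binding.  With
    no (KI, Ks) pairs this reduces to :func:`rate_random_order`.
    """
    edge = params.edges[j]
    cs = competition_sums(concs, params.sites, ki_pairs=ki_pairs)
    return edge_rate(edge, donor, _conc(concs, edge.substrate), cs, "inhibited")


def rate_single_inhibited(
    a: float,
    b: float,
    Vmax: float,
    Ka: float,
    Kb: float,
    Ks_Ax: float,
    KI: float,
) -> float:
    """Substrate-inhibited rate for a single acceptor (n = 1).

        v = Vmax a b / (Ks_Ax Kb + Kb a + Ka b + (Ka/KI) b^2 + a b)

    ``Ka`` is the donor Michaelis constant Km_Ax and ``Kb`` the acceptor
    Michaelis constant.  The quadratic acceptor term makes v(b)
    non-monotone: it rises to a single interior maximum and decays,
    which is the geometric prerequisite for bistability in an open
    system.
    """
    for name, value in (("Vmax", Vmax), ("Ka", Ka), ("Kb", Kb),
                        ("Ks_Ax", Ks_Ax), ("KI", KI)):
        _check_positive(name, value)
    _check_nonnegative("a", a)
    _check_nonnegative("b", b)
    den = Ks_Ax * Kb + Kb * a + Ka * b + (Ka / KI) * b * b + a * b
    return Vmax * a * b / den


def apparent_km(kms: Sequence[float]) -> float:
    """Apparent Michaelis constant of a multivalent acceptor.

    Under the equal-Vmax assumption the half-saturation concentration
    of the summed per-site Michaelis terms solves

        1 = sum_i Km_app / (Km_i + Km_app).

    For two sites this is the geometric mean sqrt(Km_1 Km_2).  For a
    single site the relation has no finite root and the lone Km is
    returned (half-saturation of a single Michaelis term).
    """
    kms = list(kms)
    if not kms:
        raise ValueError("kms must be a non-empty list")
    for k in kms:
        _check_positive("Km", k)
    if len(kms) == 1:
        return float(kms[0])

    def g(k: float) -> float:
        return sum(k / (km + k) for km in kms) - 1.0

    lo = min(kms) * 1e-12
    hi = max(kms) * 1e12
    return float(brentq(g, lo, hi, xtol=1e-15, rtol=1e-14))
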