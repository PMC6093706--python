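"""Shared fixtures: published parameter sets and random-state helpers."""

from __future__ import annotations

import numpy as np
import pytest

from glycoswitch import (
    DonorParams,
    KineticParams,
    ReactionParams,
    SiteConstants,
    make_fixture,
)


@pytest.fixture
def model_1d():
    """The single-acceptor bistable open system (published constants)."""
    return make_fixture("fig4_1d").build()


@pytest.fixture
def model_galt():
    """The diantennary GalT five-ODE model (published constants)."""
    return make_fixture("table1_galt").build()


@pytest.fixture
def table1_sites():
    """Per-site constants of the diantennary GalT model."""
    return (
        SiteConstants("B1", 0, Km=0.25, Ks=0.05),
        SiteConstants("B1", 1, Km=0.45, Ks=0.05),
        SiteConstants("B2", 0, KI=0.02),
        SiteConstants("B2", 1, Km=0.45, Ks=0.002),
        SiteConstants("B3", 0, Km=0.45, Ks=0.1),
        SiteConstants("B3", 1, KI=20.0),
        SiteConstants("B4", 0, KI=20.0),
        SiteConstants("B4", 1, KI=20.0),
    )


def random_kinetics(rng: np.random.Generator, n: int, with_ki: bool = False):
    """Random n-acceptor single-site kinetics for oracle comparisons.

    Returns (donor, params, species).  Constants drawn log-uniformly in
    [0.01, 10]; every species carries Km and Ks (and KI if requested).
    """
    def draw():
        return float(10 ** rng.uniform(-2, 1))

    species = [f"B{i + 1}" for i in range(n)]
    sites = tuple(
        SiteConstants(sp, 0, Km=draw(), Ks=draw(),
                      KI=draw() if with_ki else None)
        for sp in species
    )
    edges = {
        f"e{i + 1}": ReactionParams(edge=f"e{i + 1}", substrate=sp, site=0,
                                    Vmax=draw(), Km=sites[i].Km)
        for i, sp in enumerate(species)
    }
    donor = DonorParams(Ks=draw(), conc=float(10 ** rng.uniform(-1, 1)))
    return donor, KineticParams(edges=edges, sites=sites), species


def random_concs(rng: np.random.Generator, species) -> dict[str, float]:
    return {sp: float(10 ** rng.uniform(-2, 0.5)) for sp in species}
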