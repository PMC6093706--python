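"""Combinatorial glycoform networks.

A glycan acceptor with ``m`` enzyme-recognition sites gives rise to a
site-occupancy lattice: every subset of filled sites is a distinct
glycoform, and each enzyme-catalysed transfer fills exactly one empty
site.  The full network for an ``m``-site acceptor therefore has
``2**m`` nodes and ``m * 2**(m-1)`` edges, with the number of species
at step ``k`` (k sites filled) following the binomial coefficient
C(m, k).

The lattice also fixes the index sets needed by the inhibition rate
laws: every (species, site) pair that can bind a second acceptor to an
enzyme-acceptor complex (a K_I-carrying site) pairs with every
(species, site) pair that can bind the free enzyme as a substrate
analogue (a K_s-carrying site), one summand of the inhibition sum per
ordered pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GlycoformNode",
    "GlycanEdge",
    "GlycanNetwork",
    "SiteRoles",
    "build_network",
    "network_stats",
    "inhibition_index_sets",
    "MAX_SITES",
]

#: Enumeration cap: path counting is factorial in m, so the full lattice
#: is only constructed for desk-scale m (4096 nodes at the cap).
MAX_SITES = 12


@dataclass(frozen=True, order=True)
class GlycoformNode:
    """One glycoform, identified by which of the m sites are filled."""

    occupancy: tuple[bool, ...]

    @property
    def step(self) -> int:
        """Number of filled sites (the k of the binomial hierarchy)."""
        return sum(self.occupancy)

    @property
    def m(self) -> int:
        return len(self.occupancy)

    def fill(self, site: int) -> "GlycoformNode":
        """Return the product of filling ``site`` (must be empty)."""
        if self.occupancy[site]:
            raise ValueError(f"site {site} is already filled")
        occ = list(self.occupancy)
        occ[site] = True
        return GlycoformNode(tuple(occ))


@dataclass(frozen=True)
class GlycanEdge:
    """A single transfer: substrate -> product, filling ``site``."""

    substrate: GlycoformNode
    product: GlycoformNode
    site: int


@dataclass(frozen=True)
class GlycanNetwork:
    """Full site-occupancy lattice for an m-site acceptor."""

    m: int
    nodes: tuple[GlycoformNode, ...]
    edges: tuple[GlycanEdge, ...]
    _names: dict[GlycoformNode, str] = field(repr=False, hash=False, compare=False, default_factory=dict)

    @property
    def root(self) -> GlycoformNode:
        """The unmodified acceptor (no site filled)."""
        return GlycoformNode((False,) * self.m)

    @property
    def terminal(self) -> GlycoformNode:
        """The fully glycosylated product (every site filled)."""
        return GlycoformNode((True,) * self.m)

    def name(self, node: GlycoformNode) -> str:
        """Display name of a node (B1 ... B_{2^m}).

        Nodes are numbered by increasing step; within a step, the node
        with the lower-indexed filled sites comes first, so that for
        m = 2 the order is B1 = (-,-), B2 = (site 1 filled),
        B3 = (site 2 filled), B4 = (both).
        """
        return self._names[node]

    def node_by_name(self, name: str) -> GlycoformNode:
        for node, n in self._names.items():
            if n == name:
                return node
        raise KeyError(name)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self._names[n] for n in self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node, step=node.step, name=self.name(node))
        for e in self.edges:
            g.add_edge(e.substrate, e.product, site=e.site)
        return g


def _validate_m(m: int) -> None:
    if not isinstance(m, (int,)) or isinstance(m, bool):
        raise ValueError(f"number of sites must be an integer, got {m!r}")
    if m < 0:
        raise ValueError(f"number of sites must be non-negative, got {m}")
    if m > MAX_SITES:
        raise ValueError(
            f"number of sites {m} exceeds the enumeration cap {MAX_SITES}"
        )


def build_network(m: int) -> GlycanNetwork:
    """Build the full 2^m-node glycoform lattice for an m-site acceptor.

    Every node at step k has in-degree k and out-degree m - k; an edge
    exists exactly where the product differs from the substrate by one
    newly filled site.
    """
    _validate_m(m)
    nodes = [GlycoformNode(occ) for occ in product((False, True), repeat=m)]
    # Order: by step, then by position of filled sites (earlier site first).
    nodes.sort(key=lambda n: (n.step, tuple(i for i, f in enumerate(n.occupancy) if f)))
    names = {node: f"B{i + 1}" for i, node in enumerate(nodes)}
    edges = []
    for node in nodes:
        for site, filled in enumerate(node.occupancy):
            if not filled:
                edges.append(GlycanEdge(node, node.fill(site), site))
    edges.sort(key=lambda e: (e.substrate.step, names[e.substrate], e.site))
    return GlycanNetwork(m=m, nodes=tuple(nodes), edges=tuple(edges), _names=names)


def _count_paths(net: GlycanNetwork) -> int:
    """Exhaustively count maximal directed paths root -> terminal."""
    if net.m == 0:
        return 1  # the empty path from the single node to itself
    g = net.to_networkx()
    return sum(1 for _ in nx.all_simple_paths(g, net.root, net.terminal))


def p_formula(m: int) -> int:
    """The closed-form pathway expression P(m) = sum_k C(m,k) * k * (m-k).

    Evaluated exactly as written.  Note that for m >= 3 this differs
    from the exhaustively enumerated number of root-to-terminal paths
    (which is m!); both quantities are reported by :func:`network_stats`
    and the enumerated count is the one used in documentation claims.
    """
    _validate_m(m)
    return sum(math.comb(m, k) * k * (m - k) for k in range(m + 1))


def network_stats(m: int) -> dict:
    """Closed-form and enumerated size statistics of the m-site lattice.

    Returns a record with ``n_nodes`` (= 2^m), ``n_edges``
    (= m * 2^(m-1)), ``p_formula`` (the closed-form pathway expression,
    as written) and ``n_paths_enumerated`` (maximal directed paths from
    the empty to the full glycoform, counted by exhaustive traversal).
    """
    _validate_m(m)
    net = build_network(m)
    n_nodes = sum(math.comb(m, k) for k in range(m + 1))
    n_edges = sum(math.comb(m, k) * (m - k) for k in range(m + 1))
    assert n_nodes == len(net.nodes) and n_edges == len(net.edges)
    return {
        "m": m,
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "p_formula": p_formula(m),
        "n_paths_enumerated": _count_paths(net),
    }


@dataclass(frozen=True)
class SiteRoles:
    """Which sites of one glycoform carry K_s and K_I constants.

    ``ks_sites`` are sites at which the species binds the free enzyme
    as a substrate analogue (substrate role); ``ki_sites`` are sites at
    which it binds an enzyme-acceptor complex to form an abortive
    ternary complex (inhibitor role).
    """

    ks_sites: tuple[int, ...] = ()
    ki_sites: tuple[int, ...] = ()


def inhibition_index_sets(
    net: GlycanNetwork,
    roles: Mapping[GlycoformNode | str, SiteRoles],
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Enumerate the ((K_I species, site), (K_s species, site)) pairs.

    One abortive ternary complex E.B_k.B_i forms for every way of
    combining a K_I-carrying (species, site) with a K_s-carrying
    (species, site); the inhibition sum s_I has one summand per pair,
    so the returned list always has length (#K_I sites) x (#K_s sites).

    ``roles`` may be keyed by node or by display name.
    """
    ki_slots: list[tuple[str, int]] = []
    ks_slots: list[tuple[str, int]] = []
    for key, role in roles.items():
        node = net.node_by_name(key) if isinstance(key, str) else key
        name = net.name(node)
        for s in tuple(role.ks_sites) + tuple(role.ki_sites):
            if not (0 <= s < net.m):
                raise ValueError(
                    f"site index {s} for {name} out of range for m={net.m}"
                )
        ks_slots.extend((name, s) for s in role.ks_sites)
        ki_slots.extend((name, s) for s in role.ki_sites)
    # deterministic order: by species name then site
    ki_slots.sort()
    ks_slots.sort()
    return [(ki, ks) for ki in ki_slots for ks in ks_slots]
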