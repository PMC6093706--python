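"""Model-description files: schema, validation, bundled fixtures.

Models are described in plain YAML (no anchors/aliases).  Two kinds are
supported:

``kind: one_dimensional`` — the single-acceptor open system; keys
``a, K, Kb, Ks, Vmax, Ka, b0``.

``kind: network`` — a glycoform-lattice model; keys::

    sites: 2                      # m, number of recognition sites
    mechanism: compulsory         # binding order (random | compulsory)
    inhibition: true              # abortive-complex term in the law
    donor: {name: Ax, Ks: 0.5, external: 1.5, constant: false}
    diffusion: 0.075
    external_acceptor: 0.15       # shared b0
    externals: {}                 # optional per-species overrides
    edges:                        # one per lattice edge
      - {substrate: B1, site: 0, Vmax: 5.0, Km: 0.25}
      ...
    site_constants:               # per species, full-length-m lists in
      B1: {Ks: [0.05, 0.05]}      # site order; null where absent
      B2: {Km: [null, 0.45], Ks: [null, 0.002], KI: [0.02, null]}

Site-indexed constants are written as length-m lists in site order so
that tabulated pairs like "0.25, 0.45" map unambiguously onto sites.
Three fixtures reproduce the published parameter sets: ``fig4_1d`` (the
1-D bistable system), ``table1_galt`` (the diantennary GalT model) and
``fig5a_galt`` (the same with the acceptor external raised to 0.3).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .network import GlycanNetwork, build_network
from .rate_laws import ReactionParams, SiteConstants
from .system import NetworkModel, OneDimensionalModel, build_1d_model

__all__ = [
    "ModelConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "save_config",
    "dumps_config",
    "make_fixture",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """Schema violation, naming the offending key and constraint."""


_1D_KEYS = {"a", "K", "Kb", "Ks", "Vmax", "Ka", "b0"}


def _require(cond: bool, key: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"config key {key!r}: {constraint}")


def _positive(data: Mapping[str, Any], key: str) -> float:
    _require(key in data, key, "is required")
    v = data[key]
    _require(isinstance(v, (int, float)) and not isinstance(v, bool), key,
             "must be a number")
    _require(v > 0, key, f"must be positive, got {v}")
    return float(v)


def _nonneg(data: Mapping[str, Any], key: str, default=None) -> float:
    if key not in data:
        _require(default is not None, key, "is required")
        return float(default)
    v = data[key]
    _require(isinstance(v, (int, float)) and not isinstance(v, bool), key,
             "must be a number")
    _require(v >= 0, key, f"must be non-negative, got {v}")
    return float(v)


@dataclass
class ModelConfig:
    """A validated model description.

    Holds the raw (canonicalised) mapping and builds the corresponding
    model object on demand.
    """

    data: dict[str, Any]

    @property
    def kind(self) -> str:
        return self.data["kind"]

    @property
    def name(self) -> str:
        return self.data.get("name", "unnamed")

    def build(self) -> OneDimensionalModel | NetworkModel:
        if self.kind == "one_dimensional":
            d = self.data
            return build_1d_model(a=d["a"], K=d["K"], Kb=d["Kb"], Ks=d["Ks"],
                                  Vmax=d["Vmax"], Ka=d["Ka"], b0=d["b0"])
        return _build_network_model(self.data)

    def network(self) -> GlycanNetwork:
        if self.kind != "network":
            raise ConfigError("config key 'kind': no lattice for a "
                              "one-dimensional model")
        return build_network(self.data["sites"])


def _validate_1d(data: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {"kind": "one_dimensional"}
    if "name" in data:
        out["name"] = str(data["name"])
    for key in ("a", "K", "Kb", "Ks", "Vmax", "Ka"):
        out[key] = _positive(data, key)
    out["b0"] = _nonneg(data, "b0", default=2.0)
    unknown = set(data) - _1D_KEYS - {"kind", "name"}
    _require(not unknown, sorted(unknown)[0] if unknown else "",
             "is not a recognised key for kind 'one_dimensional'")
    return out


def _site_list(species: str, m: int, raw: Any, key: str) -> list[float | None]:
    _require(isinstance(raw, list) and len(raw) == m, f"site_constants.{species}.{key}",
             f"must be a length-{m} list in site order (null where absent)")
    out: list[float | None] = []
    for i, v in enumerate(raw):
        if v is None:
            out.append(None)
        else:
            _require(isinstance(v, (int, float)) and not isinstance(v, bool)
                     and v > 0,
                     f"site_constants.{species}.{key}[{i}]",
                     f"must be positive or null, got {v}")
            out.append(float(v))
    return out


def _validate_network(data: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {"kind": "network"}
    if "name" in data:
        out["name"] = str(data["name"])
    _require("sites" in data, "sites", "is required")
    m = data["sites"]
    _require(isinstance(m, int) and not isinstance(m, bool) and m >= 0,
             "sites", f"must be a non-negative integer, got {m!r}")
    out["sites"] = m
    net = build_network(m)
    names = net.species_names

    mech = data.get("mechanism", "compulsory")
    _require(mech in ("random", "compulsory"), "mechanism",
             f"must be 'random' or 'compulsory', got {mech!r}")
    out["mechanism"] = mech
    inh = data.get("inhibition", True)
    _require(isinstance(inh, bool), "inhibition", "must be a boolean")
    out["inhibition"] = inh

    donor = data.get("donor")
    _require(isinstance(donor, Mapping), "donor", "must be a mapping")
    dname = str(donor.get("name", "Ax"))
    _require(dname not in names, "donor.name",
             f"{dname!r} collides with an acceptor name")
    const = donor.get("constant", False)
    _require(isinstance(const, bool), "donor.constant", "must be a boolean")
    out["donor"] = {
        "name": dname,
        "Ks": _positive(donor, "Ks"),
        "external": _nonneg(donor, "external", default=0.0),
        "constant": const,
    }
    out["diffusion"] = _positive(data, "diffusion")
    out["external_acceptor"] = _nonneg(data, "external_acceptor", default=0.0)
    overrides = data.get("externals", {}) or {}
    _require(isinstance(overrides, Mapping), "externals", "must be a mapping")
    for sp, v in overrides.items():
        _require(sp in names, f"externals.{sp}", "is not a species of this lattice")
        _require(isinstance(v, (int, float)) and v >= 0, f"externals.{sp}",
                 "must be a non-negative number")
    out["externals"] = {str(k): float(v) for k, v in sorted(overrides.items())}

    # site constants
    site_raw = data.get("site_constants", {}) or {}
    _require(isinstance(site_raw, Mapping), "site_constants", "must be a mapping")
    canon_sites: dict[str, dict[str, list]] = {}
    for sp, block in sorted(site_raw.items()):
        _require(sp in names, f"site_constants.{sp}",
                 "is not a species of this lattice")
        _require(isinstance(block, Mapping), f"site_constants.{sp}",
                 "must be a mapping with Km/Ks/KI lists")
        entry: dict[str, list] = {}
        for key in ("Km", "Ks", "KI"):
            if key in block:
                entry[key] = _site_list(sp, m, block[key], key)
        unknown = set(block) - {"Km", "Ks", "KI"}
        _require(not unknown, f"site_constants.{sp}.{sorted(unknown)[0] if unknown else ''}",
                 "only Km, Ks and KI are recognised")
        canon_sites[sp] = entry
    out["site_constants"] = canon_sites

    # edges: every lattice edge needs Vmax and Km
    raw_edges = data.get("edges", []) or []
    _require(isinstance(raw_edges, list), "edges", "must be a list")
    seen: dict[tuple[str, int], dict] = {}
    for i, e in enumerate(raw_edges):
        _require(isinstance(e, Mapping), f"edges[{i}]", "must be a mapping")
        sub = e.get("substrate")
        _require(sub in names, f"edges[{i}].substrate",
                 f"{sub!r} is not a species of this lattice")
        site = e.get("site")
        _require(isinstance(site, int) and 0 <= site < m, f"edges[{i}].site",
                 f"must be a site index in [0, {m}), got {site!r}")
        key = (sub, site)
        _require(key not in seen, f"edges[{i}]",
                 f"duplicate edge ({sub}, site {site})")
        seen[key] = {
            "substrate": sub,
            "site": site,
            "Vmax": _positive(e, "Vmax"),
            "Km": _positive(e, "Km"),
        }
    for edge in net.edges:
        sub = net.name(edge.substrate)
        _require((sub, edge.site) in seen, "edges",
                 f"missing Vmax/Km for lattice edge ({sub}, site {edge.site})")
        # substrate site must carry a Ks so the donor Michaelis constant
        # of the edge is defined (Km_Ax = Ks_Ax * Km / Ks)
        ks_list = canon_sites.get(sub, {}).get("Ks", [None] * m)
        _require(ks_list[edge.site] is not None, f"site_constants.{sub}.Ks",
                 f"site {edge.site} needs a Ks (substrate-binding) constant")
    out["edges"] = [seen[k] for k in sorted(seen)]

    unknown = set(data) - {"kind", "name", "sites", "mechanism", "inhibition",
                           "donor", "diffusion", "external_acceptor",
                           "externals", "site_constants", "edges"}
    _require(not unknown, sorted(unknown)[0] if unknown else "",
             "is not a recognised key for kind 'network'")
    return out


def _validate(data: Mapping[str, Any]) -> dict[str, Any]:
    _require(isinstance(data, Mapping), "<root>", "document must be a mapping")
    kind = data.get("kind")
    _require(kind in ("one_dimensional", "network"), "kind",
             f"must be 'one_dimensional' or 'network', got {kind!r}")
    if kind == "one_dimensional":
        return _validate_1d(data)
    return _validate_network(data)


def _build_network_model(data: Mapping[str, Any]) -> NetworkModel:
    net = build_network(data["sites"])
    m = data["sites"]
    sites: list[SiteConstants] = []
    for sp, block in data["site_constants"].items():
        for i in range(m):
            km = block.get("Km", [None] * m)[i]
            ks = block.get("Ks", [None] * m)[i]
            ki = block.get("KI", [None] * m)[i]
            if km is not None or ks is not None or ki is not None:
                sites.append(SiteConstants(species=sp, site=i, Km=km, Ks=ks, KI=ki))
    by_key = {(e["substrate"], e["site"]): e for e in data["edges"]}
    edges, products = [], []
    for edge in net.edges:
        sub = net.name(edge.substrate)
        e = by_key[(sub, edge.site)]
        edges.append(ReactionParams(edge=f"{sub}:site{edge.site}", substrate=sub,
                                    site=edge.site, Vmax=e["Vmax"], Km=e["Km"]))
        products.append(net.name(edge.product))
    mechanism = "inhibited" if data["inhibition"] else (
        "random" if data["mechanism"] == "random" else "compulsory")
    return NetworkModel(
        network=net,
        edges=tuple(edges),
        products=tuple(products),
        sites=tuple(sites),
        donor_name=data["donor"]["name"],
        donor_Ks=data["donor"]["Ks"],
        K=data["diffusion"],
        a0=data["donor"]["external"],
        b0=data["external_acceptor"],
        external_overrides=dict(data["externals"]),
        mechanism=mechanism,
        constant_donor=data["donor"]["constant"],
    )


def loads_config(text: str) -> ModelConfig:
    """Parse and validate a YAML model description from a string."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config key '<root>': not valid YAML ({exc})") from exc
    return ModelConfig(data=_validate(data))


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model-description file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return loads_config(path.read_text(encoding="utf-8"))


def dumps_config(cfg: ModelConfig) -> str:
    """Serialise a config canonically (sorted keys, no anchors)."""
    return yaml.safe_dump(cfg.data, sort_keys=True, default_flow_style=False,
                          allow_unicode=True)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(dumps_config(cfg), encoding="utf-8")


# ---------------------------------------------------------------------------
# bundled fixtures

_FIG4_1D = {
    "kind": "one_dimensional",
    "name": "fig4_1d",
    "a": 0.6,
    "K": 0.075,
    "Kb": 0.1,
    "Ks": 0.05,
    "Vmax": 1.0,
    "Ka": 0.6,
    "b0": 2.0,
}

_TABLE1_GALT = {
    "kind": "network",
    "name": "table1_galt",
    "sites": 2,
    "mechanism": "compulsory",
    "inhibition": True,
    "donor": {"name": "Ax", "Ks": 0.5, "external": 1.5, "constant": False},
    "diffusion": 0.075,
    "external_acceptor": 0.15,
    "externals": {},
    "edges": [
        {"substrate": "B1", "site": 0, "Vmax": 5.0, "Km": 0.25},
        {"substrate": "B1", "site": 1, "Vmax": 5.0, "Km": 0.45},
        {"substrate": "B2", "site": 1, "Vmax": 5.0, "Km": 0.45},
        {"substrate": "B3", "site": 0, "Vmax": 5.0, "Km": 0.45},
    ],
    "site_constants": {
        "B1": {"Km": [0.25, 0.45], "Ks": [0.05, 0.05]},
        "B2": {"Km": [None, 0.45], "Ks": [None, 0.002], "KI": [0.02, None]},
        "B3": {"Km": [0.45, None], "Ks": [0.1, None], "KI": [None, 20.0]},
        "B4": {"KI": [20.0, 20.0]},
    },
}

FIXTURE_NAMES = ("fig4_1d", "table1_galt", "fig5a_galt")


def make_fixture(name: str) -> ModelConfig:
    """One of the bundled published parameter sets.

    ``fig4_1d``: the 1-D bistable open system (a=0.6, K=0.075, Kb=0.1,
    Ks=0.05, Vmax=1, Ka=0.6).  ``table1_galt``: the diantennary GalT
    network (all Vmax 5.0, K 0.075, externals a0=1.5, b0=0.15).
    ``fig5a_galt``: the same with the shared acceptor external raised
    to b0 = 0.3.
    """
    if name == "fig4_1d":
        raw = copy.deepcopy(_FIG4_1D)
    elif name == "table1_galt":
        raw = copy.deepcopy(_TABLE1_GALT)
    elif name == "fig5a_galt":
        raw = copy.deepcopy(_TABLE1_GALT)
        raw["name"] = "fig5a_galt"
        raw["external_acceptor"] = 0.3
    else:
        raise ValueError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    return ModelConfig(data=_validate(raw))
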