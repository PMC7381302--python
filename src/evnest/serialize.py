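"""Lossless structured-text (YAML) serialization of reaction networks."""

from __future__ import annotations

from pathlib import Path

import yaml

from .network import NetworkConfigError, Reaction, ReactionNetwork, Species

FORMAT_VERSION = 1


def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "format": "evnest-network",
        "version": FORMAT_VERSION,
        "species": [
            {"name": s.name, "compartment": s.compartment,
             "initial_copies": float(s.initial_copies)}
            for s in network.species
        ],
        "reactions": [
            {"id": r.id, "reactants": list(r.reactants), "products": list(r.products),
             "rate_class": r.rate_class, "parameter_id": r.parameter_id}
            for r in network.reactions
        ],
        "accumulators": [
            {"name": name, "reactions": list(rids)}
            for name, rids in network.accumulators
        ],
    }


def network_from_dict(data: dict) -> ReactionNetwork:
    if data.get("format") != "evnest-network":
        raise NetworkConfigError("not an evnest network document")
    if data.get("version") != FORMAT_VERSION:
        raise NetworkConfigError(f"unsupported format version {data.get('version')!r}")
    species = tuple(
        Species(d["name"], d.get("compartment", "none"), float(d.get("initial_copies", 0.0)))
        for d in data.get("species", [])
    )
    reactions = tuple(
        Reaction(d["id"], tuple(d["reactants"]), tuple(d["products"]),
                 d["rate_class"], d["parameter_id"])
        for d in data.get("reactions", [])
    )
    accumulators = tuple(
        (d["name"], tuple(d["reactions"])) for d in data.get("accumulators", [])
    )
    return ReactionNetwork(species=species, reactions=reactions, accumulators=accumulators)


def write_network(network: ReactionNetwork, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(network_to_dict(network), sort_keys=False), encoding="utf-8"
    )


def read_network(path: str | Path) -> ReactionNetwork:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise NetworkConfigError(f"{path}: not a network document")
    return network_from_dict(data)
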