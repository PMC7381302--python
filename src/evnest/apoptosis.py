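"""Reduced extrinsic-apoptosis reaction network and its knockout subnetworks.

The full model wires the canonical extrinsic-apoptosis mechanism at the
scale of a reduced EARM (extrinsic apoptosis reaction model): DISC assembly
and Caspase-8 activation; direct Caspase-8 -> Caspase-3 cleavage (the
Type I route); the mitochondrial route through Bid truncation, Bax
activation and oligomerization into a pore, Cytochrome-c/Smac release,
apoptosome formation and apoptosome-mediated Caspase-3 activation
(Type II); Bcl-2 inhibition of tBid and activated Bax with a Bad-like
sensitizer; XIAP sequestration/degradation of Caspase-3, XIAP sequestration
of the apoptosome, and Smac inhibition of XIAP; the Caspase-3 ->
Caspase-6 -> Caspase-8 feed-forward loop; and Caspase-3 cleavage of PARP.

Structure: 50 species, 62 elementary reactions, 62 rate parameters, and 16
species at nonzero initial copy numbers.  Two accumulators record
cumulative Caspase-3 activation by its immediate catalyst: via the direct
Caspase-8 reaction (``C3_activation_caspase``) and via the apoptosome
(``C3_activation_mito``).

Six subnetwork variants, addressable by one-letter code or catalogue name,
implement in-silico knockouts.  Knocked-out content is *removed* (species
deleted, with every reaction touching them), not zeroed: each variant is a
distinct model whose expected values integrate over a correspondingly
reduced parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .network import NetworkConfigError, Reaction, ReactionNetwork, Species

CASPASE_ACC = "C3_activation_caspase"
MITO_ACC = "C3_activation_mito"

#: variant code -> (catalogue name, description)
VARIANTS = {
    "A": ("caspase", "direct caspase pathway only"),
    "B": ("caspase+mito_act", "direct caspase + mitochondrial activation (no Smac arm)"),
    "C": ("caspase+xiap_inh", "direct caspase + mitochondrial inhibition of XIAP (no apoptosome arm)"),
    "D": ("mito_act", "mitochondrial activation only (no direct caspase link, no Smac arm)"),
    "E": ("full", "complete network"),
    "F": ("mito_full", "full mitochondrial subnetwork (no direct caspase link)"),
}

_NAME_TO_CODE = {name: code for code, (name, _) in VARIANTS.items()}


@dataclass(frozen=True)
class SubnetworkVariant:
    """One of the six knockout variants (codes A-F)."""

    code: str

    def __post_init__(self):
        if self.code not in VARIANTS:
            raise NetworkConfigError(
                f"unknown subnetwork variant {self.code!r}; valid codes: {sorted(VARIANTS)}"
            )

    @property
    def name(self) -> str:
        return VARIANTS[self.code][0]

    @property
    def description(self) -> str:
        return VARIANTS[self.code][1]


@dataclass(frozen=True)
class RegulatorSetting:
    """A single initial-copy-number override (e.g. XIAP level in a scan)."""

    species_name: str
    copies: float

    def __post_init__(self):
        if self.copies < 0:
            raise NetworkConfigError(
                f"regulator {self.species_name!r}: copies must be >= 0"
            )


def default_initial_copies() -> dict[str, float]:
    """The 16 nonzero default initial copy numbers (from the package config file)."""
    text = resources.files("evnest").joinpath("data/initial_conditions.yaml").read_text()
    return {str(k): float(v) for k, v in yaml.safe_load(text).items()}


class _Builder:
    """Motif-level network assembly; every elementary reaction gets its own parameter."""

    def __init__(self):
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []

    def add_species(self, name, compartment="cytosol", initial=0.0):
        if name not in self.species:
            self.species[name] = Species(name, compartment, initial)

    def _rxn(self, rid, reactants, products, rate_class):
        self.reactions.append(
            Reaction(rid, tuple(reactants), tuple(products), rate_class, f"k_{rid}")
        )

    def bind(self, a, b, complex_name, compartment="cytosol"):
        """Reversible binding A + B <-> A:B (2 elementary reactions)."""
        self.add_species(complex_name, compartment)
        tag = complex_name.replace(":", "_")
        self._rxn(f"bind_{tag}", (a, b), (complex_name,), "second_order_forward")
        self._rxn(f"unbind_{tag}", (complex_name,), (a, b), "first_order_reverse")

    def catalyze(self, enzyme, substrate, products, compartment="cytosol"):
        """Catalysis E + S <-> E:S -> E + P (3 elementary reactions).

        ``products`` may be empty for catalytic degradation (the substrate
        is consumed).
        """
        complex_name = f"{enzyme}:{substrate}"
        self.add_species(complex_name, compartment)
        for p in products:
            self.add_species(p, compartment)
        tag = f"{enzyme}_{substrate}"
        self._rxn(f"bind_{tag}", (enzyme, substrate), (complex_name,), "second_order_forward")
        self._rxn(f"unbind_{tag}", (complex_name,), (enzyme, substrate), "first_order_reverse")
        cat_id = f"cat_{tag}"
        self._rxn(cat_id, (complex_name,), (enzyme, *products), "catalysis")
        return cat_id

    def translocate(self, src, dst, compartment="mitochondria"):
        """Reversible translocation src <-> dst (2 elementary reactions)."""
        self.add_species(dst, compartment)
        self._rxn(f"to_{dst}", (src,), (dst,), "first_order_forward")
        self._rxn(f"from_{dst}", (dst,), (src,), "first_order_reverse")


def build_full_model(initial_copies: dict[str, float] | None = None) -> ReactionNetwork:
    """Construct the complete reduced extrinsic-apoptosis network.

    Parameters
    ----------
    initial_copies:
        Optional overrides of the default nonzero initial copy numbers
        (species name -> molecules per cell).
    """
    init = default_initial_copies()
    if initial_copies:
        unknown = set(initial_copies) - set(init)
        if unknown:
            raise NetworkConfigError(f"unknown initial-condition species: {sorted(unknown)}")
        init.update(initial_copies)

    b = _Builder()
    compartments = {
        "Receptor": "membrane",
        "CytoC_mito": "mitochondria",
        "Smac_mito": "mitochondria",
        "Bcl2": "mitochondria",
        "Bad": "mitochondria",
    }
    for name, copies in init.items():
        b.add_species(name, compartments.get(name, "cytosol"), copies)

    # -- DISC assembly and Caspase-8 activation ----------------------------
    b.bind("Ligand", "Receptor", "Ligand:Receptor", "membrane")
    b.bind("Ligand:Receptor", "FADD", "DISC", "membrane")
    b.catalyze("DISC", "pC8", ("C8",), "membrane")

    # -- direct caspase cascade (Type I route) ------------------------------
    direct_cat = b.catalyze("C8", "pC3", ("C3",))

    # -- execution: PARP cleavage and XIAP inhibition of Caspase-3 ----------
    b.catalyze("C3", "PARP", ("cPARP",))
    b.catalyze("XIAP", "C3", ())  # sequestration + ubiquitin-mediated degradation

    # -- Caspase-3 -> Caspase-6 -> Caspase-8 feed-forward loop --------------
    b.catalyze("C3", "pC6", ("C6",))
    b.catalyze("C6", "pC8", ("C8",))

    # -- mitochondrial route: Bid truncation, Bax activation, MOMP ----------
    b.catalyze("C8", "Bid", ("tBid",))
    b.translocate("tBid", "tBid_mito")
    b.catalyze("tBid_mito", "Bax", ("aBax",), "mitochondria")
    b.translocate("aBax", "Bax_mito")
    b.bind("Bax_mito", "Bax_mito", "Bax2", "membrane")
    b.bind("Bax2", "Bax2", "Bax4", "membrane")

    # -- Bcl-2 family regulation of MOMP ------------------------------------
    b.bind("Bcl2", "tBid_mito", "Bcl2:tBid", "mitochondria")
    b.bind("Bcl2", "Bax_mito", "Bcl2:Bax", "mitochondria")
    b.bind("Bcl2", "Bax2", "Bcl2:Bax2", "mitochondria")
    b.bind("Bad", "Bcl2", "Bad:Bcl2", "mitochondria")

    # -- pore-mediated release of pro-apoptotic factors ---------------------
    b.catalyze("Bax4", "CytoC_mito", ("CytoC",), "membrane")
    b.catalyze("Bax4", "Smac_mito", ("Smac",), "membrane")

    # -- apoptosome assembly and mitochondrial Caspase-3 activation ---------
    b.catalyze("CytoC", "Apaf", ("aApaf",))
    b.bind("aApaf", "pC9", "Apop")
    mito_cat = b.catalyze("Apop", "pC3", ("C3",))

    # -- XIAP sequestration of the apoptosome; Smac inhibition of XIAP ------
    b.bind("Apop", "XIAP", "Apop:XIAP")
    b.bind("Smac", "XIAP", "Smac:XIAP")

    return ReactionNetwork(
        species=tuple(b.species.values()),
        reactions=tuple(b.reactions),
        accumulators=(
            (CASPASE_ACC, (direct_cat,)),
            (MITO_ACC, (mito_cat,)),
        ),
    )


# Species content removed per variant.  Reactions touching any removed
# species are dropped with it, and accumulators whose contributing
# reactions all disappear are dropped too.
_SMAC_ARM = {"Smac_mito", "Bax4:Smac_mito", "Smac", "Smac:XIAP"}
_APOPTOSOME_ARM = {
    "CytoC_mito", "Bax4:CytoC_mito", "CytoC", "CytoC:Apaf",
    "Apaf", "aApaf", "pC9", "Apop", "Apop:pC3", "Apop:XIAP",
}
_DIRECT_LINK = {"C8:pC3"}
_MOMP_MACHINERY = {
    "Bid", "C8:Bid", "tBid", "tBid_mito", "tBid_mito:Bax", "Bax", "aBax",
    "Bax_mito", "Bax2", "Bax4", "Bcl2", "Bad", "Bcl2:tBid", "Bcl2:Bax",
    "Bcl2:Bax2", "Bad:Bcl2",
}
_MITO_ALL = _MOMP_MACHINERY | _APOPTOSOME_ARM | _SMAC_ARM

_REMOVED_SPECIES: dict[str, set[str]] = {
    "A": set(_MITO_ALL),
    "B": set(_SMAC_ARM),
    "C": set(_APOPTOSOME_ARM),
    "D": _DIRECT_LINK | _SMAC_ARM,
    "E": set(),
    "F": set(_DIRECT_LINK),
}


def build_subnetwork(
    variant: SubnetworkVariant | str,
    initial_copies: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Build one of the six knockout subnetworks (by code ``A``-``F`` or catalogue name).

    Variant ``E`` is the complete network.  Shared reactions keep their
    parameter ids, so prior ranges transfer unchanged between the full
    model and every subnetwork.
    """
    if isinstance(variant, str):
        code = _NAME_TO_CODE.get(variant, variant)
        variant = SubnetworkVariant(code)
    full = build_full_model(initial_copies)
    removed = _REMOVED_SPECIES[variant.code]
    if not removed:
        return full

    species = tuple(s for s in full.species if s.name not in removed)
    reactions = tuple(
        r for r in full.reactions
        if not (set(r.reactants) | set(r.products)) & removed
    )
    kept_rids = {r.id for r in reactions}
    accumulators = []
    for name, rids in full.accumulators:
        kept = tuple(rid for rid in rids if rid in kept_rids)
        if kept:
            accumulators.append((name, kept))
    # prune species stranded by reaction removal (none expected for these
    # variants, but the contract is "unreachable content is removed")
    used = {nm for r in reactions for nm in (*r.reactants, *r.products)}
    species = tuple(s for s in species if s.name in used)
    return ReactionNetwork(species=species, reactions=reactions,
                           accumulators=tuple(accumulators))


def set_initial(network: ReactionNetwork, setting: RegulatorSetting) -> ReactionNetwork:
    """Copy of ``network`` with one initial copy number replaced.

    Raises a configuration error when the species does not exist in the
    target network -- e.g. when attempting to set a regulator that the
    variant knocked out.
    """
    return network.with_initial(setting.species_name, setting.copies)
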