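"""Built-in, versioned knowledge base of urinary steroid analytes.

The registry bundles three immutable lookup structures:

* a metabolite catalogue (abbreviation, trivial name, parent hormones,
  report group),
* a pathway graph of hormones and enzyme-catalysed conversions with
  cofactor annotations, and
* the diagnostic precursor/product ratio panel used for disorder calling.

Registry releases are shipped as YAML files inside the package
(``steromet/data/registry_<tag>.yaml``) and loaded with
:func:`load_registry`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "GROUPS",
    "MetaboliteRecord",
    "Hormone",
    "PathwayReaction",
    "PathwayGraph",
    "RatioDefinition",
    "Registry",
    "RegistryError",
    "canonical_abbr",
    "load_registry",
]

#: Fixed report-group order used by the grouped quantitative report.
GROUPS: tuple[str, ...] = (
    "androgens",
    "androgen_precursors",
    "mineralocorticoids_and_precursors",
    "glucocorticoid_precursors",
    "glucocorticoids",
)


class RegistryError(Exception):
    """Unknown registry version, failed validation, or a bad lookup key."""


# Greek letters appear in the conventional analyte symbols; identifiers are
# ASCII-safe, with both forms accepted on input.
_GREEK = str.maketrans({"α": "a", "β": "b", "Α": "a", "Β": "b"})


def _fold(abbr: str) -> str:
    return abbr.strip().translate(_GREEK).casefold()


@dataclass(frozen=True)
class MetaboliteRecord:
    """One quantified urinary analyte."""

    abbr: str
    trivial_name: str
    parents: frozenset[str]
    group: str
    display: str = ""
    a_ring_note: str = "3alpha,5beta- A-ring configuration unless noted"


@dataclass(frozen=True)
class Hormone:
    id: str
    class_label: str


@dataclass(frozen=True)
class PathwayReaction:
    """An enzyme-catalysed conversion between two hormone nodes.

    ``cofactors`` lists electron-donor / cofactor dependencies (``POR``,
    ``b5``, ``ADR_Adx``, ``H6PDH``).  ``reversible`` marks the
    cortisol/cortisone interconversion pair, which is excluded from flux
    propagation.  ``backdoor`` marks the alternative androgen route.
    """

    substrate: str
    product: str
    enzyme: str
    cofactors: frozenset[str] = frozenset()
    base_rate: float = 1.0
    backdoor: bool = False
    reversible: bool = False

    @property
    def por_dependent(self) -> bool:
        return "POR" in self.cofactors

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.substrate, self.product, self.enzyme)


@dataclass(frozen=True)
class RatioDefinition:
    """A diagnostic ratio: sum(numerator analytes) / sum(denominator analytes).

    Every ratio in the panel is interpreted one-sidedly: it is *elevated*
    in its disorder.
    """

    id: str
    disorder: str
    gene: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    direction: str = "elevated_in_disorder"


@dataclass(frozen=True)
class PathwayGraph:
    """Hormones as nodes, enzymatic conversions as directed weighted edges."""

    hormones: tuple[Hormone, ...]
    reactions: tuple[PathwayReaction, ...]

    def __post_init__(self) -> None:
        ids = [h.id for h in self.hormones]
        if len(ids) != len(set(ids)):
            raise RegistryError("duplicate hormone ids in pathway graph")
        keys = [r.key for r in self.reactions]
        if len(keys) != len(set(keys)):
            raise RegistryError("duplicate (substrate, product, enzyme) reaction")
        nodes = set(ids)
        for r in self.reactions:
            if r.substrate not in nodes or r.product not in nodes:
                raise RegistryError(
                    f"reaction {r.key} references an unknown hormone node"
                )

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(h.id for h in self.hormones)

    def flux_reactions(self) -> tuple[PathwayReaction, ...]:
        """Reactions participating in steady-state flux (reversible pair excluded)."""
        return tuple(r for r in self.reactions if not r.reversible)

    def outgoing(self, hormone_id: str) -> tuple[PathwayReaction, ...]:
        return tuple(r for r in self.flux_reactions() if r.substrate == hormone_id)


@dataclass(frozen=True)
class Registry:
    """Immutable bundle of metabolites, pathway and diagnostic ratios."""

    version: str
    metabolites: tuple[MetaboliteRecord, ...]
    pathway: PathwayGraph
    ratios: tuple[RatioDefinition, ...]
    checksum: str = ""
    _index: Mapping[str, MetaboliteRecord] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        index: dict[str, MetaboliteRecord] = {}
        for m in self.metabolites:
            key = _fold(m.abbr)
            if key in index:
                raise RegistryError(f"duplicate metabolite abbreviation {m.abbr!r}")
            index[key] = m
            if m.group not in GROUPS:
                raise RegistryError(f"metabolite {m.abbr!r} has unknown group {m.group!r}")
            if not m.parents:
                raise RegistryError(f"metabolite {m.abbr!r} has no parent hormones")
            unknown = m.parents - self.pathway.node_ids
            if unknown:
                raise RegistryError(
                    f"metabolite {m.abbr!r} has parents outside the pathway: {sorted(unknown)}"
                )
            if m.display:
                index.setdefault(_fold(m.display), m)
        object.__setattr__(self, "_index", index)
        for rd in self.ratios:
            for abbr in (*rd.numerator, *rd.denominator):
                self.record(abbr)  # raises on dangling reference

    # -- lookups ---------------------------------------------------------

    def record(self, abbr: str) -> MetaboliteRecord:
        """Resolve an analyte abbreviation (case- and Greek-insensitively)."""
        try:
            return self._index[_fold(abbr)]
        except KeyError:
            raise RegistryError(f"unknown analyte abbreviation {abbr!r}") from None

    def canonical(self, abbr: str) -> str:
        return self.record(abbr).abbr

    def parents_of(self, abbr: str) -> frozenset[str]:
        return self.record(abbr).parents

    def group_of(self, abbr: str) -> str:
        return self.record(abbr).group

    @property
    def abbrs(self) -> tuple[str, ...]:
        """Canonical abbreviations in registry (report) order."""
        return tuple(m.abbr for m in self.metabolites)

    def ratios_for(self, disorder: str) -> tuple[RatioDefinition, ...]:
        return tuple(r for r in self.ratios if r.disorder == disorder)

    @property
    def disorders(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.ratios:
            seen.setdefault(r.disorder, None)
        return tuple(seen)

    def serialize(self) -> str:
        """Deterministic textual serialization (used for round-trip checks)."""
        payload = {
            "version": self.version,
            "metabolites": [
                {
                    "abbr": m.abbr,
                    "display": m.display,
                    "trivial_name": m.trivial_name,
                    "parents": sorted(m.parents),
                    "group": m.group,
                    "a_ring_note": m.a_ring_note,
                }
                for m in self.metabolites
            ],
            "hormones": [
                {"id": h.id, "class_label": h.class_label} for h in self.pathway.hormones
            ],
            "reactions": [
                {
                    "substrate": r.substrate,
                    "product": r.product,
                    "enzyme": r.enzyme,
                    "cofactors": sorted(r.cofactors),
                    "base_rate": r.base_rate,
                    "backdoor": r.backdoor,
                    "reversible": r.reversible,
                }
                for r in self.pathway.reactions
            ],
            "ratios": [
                {
                    "id": rd.id,
                    "disorder": rd.disorder,
                    "gene": rd.gene,
                    "numerator": list(rd.numerator),
                    "denominator": list(rd.denominator),
                    "direction": rd.direction,
                }
                for rd in self.ratios
            ],
        }
        return yaml.safe_dump(payload, sort_keys=True)


def canonical_abbr(registry: Registry, abbr: str) -> str:
    """Canonical ASCII form of ``abbr``; raises :class:`RegistryError` if unknown."""
    return registry.canonical(abbr)


def _parse(text: str) -> dict:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise RegistryError("malformed registry file")
    return doc


def load_registry(version_tag: str = "v1") -> Registry:
    """Load a bundled registry release.

    Parameters
    ----------
    version_tag
        Name of a shipped registry release (currently ``"v1"``).

    Returns
    -------
    Registry
        Immutable registry; loading the same tag twice yields identical
        content (the SHA-256 checksum of the data file is recorded on the
        returned object).
    """
    name = f"registry_{version_tag}.yaml"
    pkg = resources.files("steromet.data")
    try:
        text = (pkg / name).read_text(encoding="utf-8")
    except (FileNotFoundError, ModuleNotFoundError):
        raise RegistryError(
            f"unknown registry version {version_tag!r}; no bundled file {name}"
        ) from None
    doc = _parse(text)
    checksum = hashlib.sha256(text.encode("utf-8")).hexdigest()

    hormones = tuple(
        Hormone(id=str(h["id"]), class_label=str(h["class_label"]))
        for h in doc["hormones"]
    )
    reactions = tuple(
        PathwayReaction(
            substrate=str(r["substrate"]),
            product=str(r["product"]),
            enzyme=str(r["enzyme"]),
            cofactors=frozenset(r.get("cofactors", ())),
            base_rate=float(r.get("base_rate", 1.0)),
            backdoor=bool(r.get("backdoor", False)),
            reversible=bool(r.get("reversible", False)),
        )
        for r in doc["reactions"]
    )
    metabolites = tuple(
        MetaboliteRecord(
            abbr=str(m["abbr"]),
            display=str(m.get("display", m["abbr"])),
            trivial_name=str(m["trivial_name"]),
            parents=frozenset(str(p) for p in m["parents"]),
            group=str(m["group"]),
            a_ring_note=str(
                m.get("a_ring_note", "3alpha,5beta- A-ring configuration unless noted")
            ),
        )
        for m in doc["metabolites"]
    )
    ratios = tuple(
        RatioDefinition(
            id=str(r["id"]),
            disorder=str(r["disorder"]),
            gene=str(r["gene"]),
            numerator=tuple(str(a) for a in r["numerator"]),
            denominator=tuple(str(a) for a in r["denominator"]),
        )
        for r in doc["ratios"]
    )
    return Registry(
        version=str(doc["version"]),
        metabolites=metabolites,
        pathway=PathwayGraph(hormones=hormones, reactions=reactions),
        ratios=ratios,
        checksum=checksum,
    )
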