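"""Reading and writing pathway files in the KGML dialect.

KGML (KEGG Markup Language) describes a pathway as a set of *entries*
(genes, compounds, pathway links, groups), *reactions* (substrate/product
conversions catalyzed by gene entries) and *relations* (gene-gene or
gene-compound links such as protein-protein interactions).  This module
parses that XML into small frozen dataclasses, validates every internal
reference, and can serialize the records back to the same dialect so that
parse/serialize round-trips are lossless.

Layout information (``graphics`` coordinates, colours) is irrelevant to
network topology and is discarded, except for the display name which is
kept as the entry label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

logger = logging.getLogger(__name__)

#: closed vocabulary of entry kinds understood by the pipeline
ENTRY_KINDS = frozenset({"gene", "compound", "map", "group", "ortholog"})

#: closed vocabulary of KGML relation types
RELATION_TYPES = frozenset({"ECrel", "PPrel", "GErel", "PCrel", "maplink"})

# attributes we knowingly consume per element; anything else is warned about
_KNOWN_ATTRS = {
    "pathway": {"name", "org", "number", "title", "image", "link"},
    "entry": {"id", "name", "type", "reaction", "link"},
    "reaction": {"id", "name", "type"},
    "relation": {"entry1", "entry2", "type"},
    "substrate": {"id", "name"},
    "product": {"id", "name"},
    "subtype": {"name", "value"},
    "component": {"id"},
}


class KGMLError(ValueError):
    """Base class for KGML reading problems."""


class KGMLParseError(KGMLError):
    """Malformed XML that cannot be parsed at all."""


class KGMLValidationError(KGMLError):
    """Well-formed XML whose content violates a KGML invariant."""


@dataclass(frozen=True)
class KeggEntry:
    """One KGML entry: a gene, compound, pathway link, group or ortholog.

    ``kegg_ids`` holds the namespaced identifiers verbatim (``hsa:1373``,
    ``cpd:C00169``); a single entry may name several genes.  ``reaction_names``
    records which reactions a gene entry catalyzes (the KGML ``reaction``
    attribute), which is how catalysis is linked to :class:`KeggReaction`.
    """

    entry_id: int
    kind: str
    kegg_ids: tuple[str, ...]
    label: str
    component_ids: tuple[int, ...] = ()
    reaction_names: tuple[str, ...] = ()

    @property
    def is_network_material(self) -> bool:
        """Whether this entry can become nodes (genes/compounds only)."""
        return self.kind in ("gene", "compound")


@dataclass(frozen=True)
class KeggReaction:
    """A substrate->product conversion catalyzed by gene entries."""

    reaction_id: int
    names: tuple[str, ...]
    reversible: bool
    substrate_refs: tuple[int, ...]
    product_refs: tuple[int, ...]
    gene_refs: tuple[int, ...]


@dataclass(frozen=True)
class KeggRelation:
    """A typed link between two entries (PPrel, GErel, ECrel, PCrel, maplink)."""

    entry1: int
    entry2: int
    relation_type: str
    subtypes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Pathway:
    """A validated in-memory KGML pathway."""

    pathway_id: str
    title: str
    entries: tuple[KeggEntry, ...]
    reactions: tuple[KeggReaction, ...]
    relations: tuple[KeggRelation, ...]

    def entry_map(self) -> dict[int, KeggEntry]:
        return {e.entry_id: e for e in self.entries}


def _warn_unknown_attrs(elem: etree._Element, tag: str) -> None:
    unknown = set(elem.attrib) - _KNOWN_ATTRS.get(tag, set())
    for name in sorted(unknown):
        logger.warning("ignoring unknown attribute %r on <%s>", name, tag)


def _entry_label(elem: etree._Element, fallback: str) -> str:
    graphics = elem.find("graphics")
    if graphics is not None and graphics.get("name"):
        # a graphics name may list several comma-separated aliases
        return graphics.get("name").split(",")[0].strip().rstrip(".")
    return fallback


def parse_kgml(xml_text: str | bytes) -> Pathway:
    """Parse one KGML document into a validated :class:`Pathway`.

    Raises :class:`KGMLParseError` for malformed XML (the message names the
    line), and :class:`KGMLValidationError` for dangling entry references,
    unknown entry kinds or relation types, and reactions without substrates
    or products.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed KGML at line {exc.lineno}: {exc.msg}") from exc
    if root.tag != "pathway":
        raise KGMLValidationError(f"expected <pathway> root, got <{root.tag}>")
    _warn_unknown_attrs(root, "pathway")

    pathway_id = (root.get("name") or "").removeprefix("path:")
    if not pathway_id:
        raise KGMLValidationError("pathway has no name attribute")
    title = root.get("title") or pathway_id

    entries: list[KeggEntry] = []
    seen_ids: set[int] = set()
    for elem in root.findall("entry"):
        _warn_unknown_attrs(elem, "entry")
        entry_id = int(elem.get("id"))
        if entry_id in seen_ids:
            raise KGMLValidationError(f"duplicate entry id {entry_id}")
        seen_ids.add(entry_id)
        kind = elem.get("type") or ""
        if kind not in ENTRY_KINDS:
            raise KGMLValidationError(
                f"unknown entry kind {kind!r} on entry {entry_id}"
            )
        names = tuple(n for n in (elem.get("name") or "").split() if n != "undefined")
        if kind in ("gene", "compound") and not names:
            raise KGMLValidationError(
                f"{kind} entry {entry_id} has no namespaced identifiers"
            )
        components = tuple(
            int(c.get("id")) for c in elem.findall("component")
        )
        reaction_names = tuple((elem.get("reaction") or "").split())
        entries.append(
            KeggEntry(
                entry_id=entry_id,
                kind=kind,
                kegg_ids=names,
                label=_entry_label(elem, names[0] if names else str(entry_id)),
                component_ids=components,
                reaction_names=reaction_names,
            )
        )
    emap = {e.entry_id: e for e in entries}

    for entry in entries:
        for cid in entry.component_ids:
            if cid not in emap:
                raise KGMLValidationError(
                    f"group entry {entry.entry_id} references missing entry {cid}"
                )

    reactions: list[KeggReaction] = []
    for elem in root.findall("reaction"):
        _warn_unknown_attrs(elem, "reaction")
        reaction_id = int(elem.get("id"))
        names = tuple((elem.get("name") or "").split())
        reversible = (elem.get("type") or "irreversible") == "reversible"
        substrates = tuple(int(s.get("id")) for s in elem.findall("substrate"))
        products = tuple(int(p.get("id")) for p in elem.findall("product"))
        if not substrates or not products:
            raise KGMLValidationError(
                f"reaction {reaction_id} must have at least one substrate and one product"
            )
        for ref in (*substrates, *products):
            target = emap.get(ref)
            if target is None:
                raise KGMLValidationError(
                    f"reaction {reaction_id} references missing entry {ref}"
                )
            if target.kind != "compound":
                raise KGMLValidationError(
                    f"reaction {reaction_id} substrate/product {ref} is not a compound"
                )
        gene_refs = tuple(
            e.entry_id
            for e in entries
            if e.kind in ("gene", "ortholog") and set(e.reaction_names) & set(names)
        )
        reactions.append(
            KeggReaction(
                reaction_id=reaction_id,
                names=names,
                reversible=reversible,
                substrate_refs=substrates,
                product_refs=products,
                gene_refs=gene_refs,
            )
        )

    relations: list[KeggRelation] = []
    for elem in root.findall("relation"):
        _warn_unknown_attrs(elem, "relation")
        e1, e2 = int(elem.get("entry1")), int(elem.get("entry2"))
        rtype = elem.get("type") or ""
        if rtype not in RELATION_TYPES:
            raise KGMLValidationError(f"unknown relation type {rtype!r}")
        for ref in (e1, e2):
            if ref not in emap:
                raise KGMLValidationError(
                    f"relation {rtype} references missing entry {ref}"
                )
        subtypes = tuple(
            s.get("name") or "" for s in elem.findall("subtype")
        )
        relations.append(KeggRelation(e1, e2, rtype, subtypes))

    return Pathway(
        pathway_id=pathway_id,
        title=title,
        entries=tuple(entries),
        reactions=tuple(reactions),
        relations=tuple(relations),
    )


def read_kgml(path: str | Path) -> Pathway:
    """Read one KGML file from disk."""
    return parse_kgml(Path(path).read_bytes())


def serialize_kgml(pathway: Pathway) -> str:
    """Serialize a :class:`Pathway` back to KGML text.

    Output is deterministic and round-trips through :func:`parse_kgml`
    field-for-field.
    """
    root = etree.Element(
        "pathway", name=f"path:{pathway.pathway_id}", title=pathway.title
    )
    for entry in pathway.entries:
        attrs = {
            "id": str(entry.entry_id),
            "name": " ".join(entry.kegg_ids) if entry.kegg_ids else "undefined",
            "type": entry.kind,
        }
        if entry.reaction_names:
            attrs["reaction"] = " ".join(entry.reaction_names)
        elem = etree.SubElement(root, "entry", attrs)
        etree.SubElement(elem, "graphics", name=entry.label)
        for cid in entry.component_ids:
            etree.SubElement(elem, "component", id=str(cid))
    for relation in pathway.relations:
        elem = etree.SubElement(
            root,
            "relation",
            entry1=str(relation.entry1),
            entry2=str(relation.entry2),
            type=relation.relation_type,
        )
        for name in relation.subtypes:
            etree.SubElement(elem, "subtype", name=name, value="")
    for reaction in pathway.reactions:
        elem = etree.SubElement(
            root,
            "reaction",
            id=str(reaction.reaction_id),
            name=" ".join(reaction.names),
            type="reversible" if reaction.reversible else "irreversible",
        )
        emap = pathway.entry_map()
        for ref in reaction.substrate_refs:
            etree.SubElement(
                elem, "substrate", id=str(ref), name=emap[ref].kegg_ids[0]
            )
        for ref in reaction.product_refs:
            etree.SubElement(
                elem, "product", id=str(ref), name=emap[ref].kegg_ids[0]
            )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
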