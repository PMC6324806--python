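"""File formats: four-block substrate XML, FASTA, and annotation tables.

The substrate XML mirrors the layout used by chemically aware metabolite
databases: one file per substrate, with four top-level blocks —

* ``properties`` — protease name ("matrix"), peptidase code, substrate
  accession, peptide range, organism and literature references;
* ``parent`` — the intact substrate: its block sequence plus optional
  opaque structure payload (sdf/mol text), formula and m/z;
* ``metabolized-parent`` — same shape as parent, for the reacted form;
* ``metabolites`` — one entry per product fragment, carrying the fragment
  sequence, the metabolic mechanism and, for hydrolysis, the 0-based index
  of the cleaved parent bond.

Chemical-structure payloads are carried verbatim and never interpreted;
the sequence tokens are authoritative for block identity.  A hydrolysis
event at bond ``i`` produces the two complementary fragments
``blocks[:i+1]`` and ``blocks[i+1:]``, and the reader checks each fragment
against them.  The machine-readable schema ships as ``docs/substrate.dtd``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import etree

from .peptide_core import (
    BlockRegistry,
    CleavageEvent,
    Peptide,
    parse_sequence,
    tokenize,
)

__all__ = [
    "Metabolite",
    "SubstrateRecord",
    "SchemaError",
    "read_substrate_xml",
    "write_substrate_xml",
    "make_substrate_record",
    "filter_substrates",
    "read_fasta",
    "write_fasta",
    "read_events_tsv",
    "write_events_tsv",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """The XML is missing a required block or carries inconsistent content."""


@dataclass(frozen=True)
class Metabolite:
    """One product fragment of a metabolic reaction on the parent peptide."""

    name: str
    sequence: str
    mechanism: str = "hydrolysis"
    cleaved_bond: int | None = None
    count: int = 1
    structure: str | None = None


@dataclass
class SubstrateRecord:
    """A parsed four-block substrate file."""

    properties: dict
    parent: Peptide
    metabolites: list[Metabolite] = field(default_factory=list)
    parent_structure: str | None = None
    parent_formula: str | None = None
    parent_mz: float | None = None
    metabolized_parent: dict = field(default_factory=dict)

    @property
    def protease_id(self) -> str:
        return self.properties.get("matrix", "")

    def events(self) -> list[CleavageEvent]:
        """Cleavage events derived from the hydrolysis metabolites.

        Complementary fragment pairs of one hydrolysis share a bond index
        and collapse into a single event; the event count is the maximum
        count annotated on the contributing fragments.
        """
        by_bond: dict[int, int] = {}
        for m in self.metabolites:
            if m.mechanism == "hydrolysis" and m.cleaved_bond is not None:
                by_bond[m.cleaved_bond] = max(by_bond.get(m.cleaved_bond, 0), m.count)
        return [
            CleavageEvent(self.parent.id, b, self.protease_id, c)
            for b, c in sorted(by_bond.items())
        ]


_PROPERTY_TAGS = ("matrix", "peptidase-code", "uniprot-acc", "peptide-range", "organism")


def _text(el, tag, default=None):
    child = el.find(tag)
    return child.text if child is not None and child.text is not None else default


def read_substrate_xml(path, registry: BlockRegistry) -> SubstrateRecord:
    """Parse one four-block substrate XML file.

    Raises :class:`SchemaError` when one of the four blocks is missing, and
    a consistency error when a metabolite's cleavage annotation does not
    map onto a valid parent bond or its fragment sequence is not one of the
    two complements of that bond.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    for block in ("properties", "parent", "metabolized-parent", "metabolites"):
        if root.find(block) is None:
            raise SchemaError(f"{path}: missing required block <{block}>")

    props_el = root.find("properties")
    properties = {t: _text(props_el, t, "") for t in _PROPERTY_TAGS}
    properties["references"] = [r.text or "" for r in props_el.findall("reference")]

    parent_el = root.find("parent")
    seq = _text(parent_el, "sequence")
    if not seq:
        raise SchemaError(f"{path}: parent block lacks a <sequence>")
    pep_id = root.get("id") or properties.get("uniprot-acc") or Path(str(path)).stem
    parent = parse_sequence(seq, registry, id=pep_id)

    mp_el = root.find("metabolized-parent")
    metabolized = {c.tag: c.text for c in mp_el}

    metabolites = []
    for m_el in root.find("metabolites").findall("metabolite"):
        bond_text = _text(m_el, "cleaved-bond")
        bond = int(bond_text) if bond_text is not None else None
        mech = _text(m_el, "mechanism", "hydrolysis")
        m_seq = _text(m_el, "sequence", "")
        if mech == "hydrolysis":
            if bond is None or not 0 <= bond < parent.n_bonds:
                raise SchemaError(
                    f"{path}: metabolite cleaved-bond {bond} does not map to a "
                    f"parent bond (parent has {parent.n_bonds})"
                )
            n_term = parent.blocks[: bond + 1]
            c_term = parent.blocks[bond + 1 :]
            frag_blocks = tuple(tok for tok, _ in tokenize(m_seq))
            if frag_blocks not in (n_term, c_term):
                raise SchemaError(
                    f"{path}: hydrolysis fragment {m_seq!r} is neither complement "
                    f"of parent bond {bond}"
                )
        metabolites.append(
            Metabolite(
                name=_text(m_el, "name", ""),
                sequence=m_seq,
                mechanism=mech,
                cleaved_bond=bond,
                count=int(_text(m_el, "count", "1")),
                structure=_text(m_el, "structure"),
            )
        )
    # hydrolysis must leave both complementary fragments
    for bond in {m.cleaved_bond for m in metabolites
                 if m.mechanism == "hydrolysis" and m.cleaved_bond is not None}:
        frags = {m.sequence for m in metabolites if m.cleaved_bond == bond}
        if len(frags) < 2:
            raise SchemaError(
                f"{path}: hydrolysis at bond {bond} lists only one fragment; "
                "expected the complementary pair"
            )

    return SubstrateRecord(
        properties=properties,
        parent=parent,
        metabolites=metabolites,
        parent_structure=_text(parent_el, "structure"),
        parent_formula=_text(parent_el, "formula"),
        parent_mz=float(_text(parent_el, "mz")) if _text(parent_el, "mz") else None,
        metabolized_parent=metabolized,
    )


def write_substrate_xml(record: SubstrateRecord, path, registry: BlockRegistry) -> None:
    """Write a record back to the four-block XML layout (round-trip stable)."""
    root = etree.Element("substrate", id=record.parent.id)

    props = etree.SubElement(root, "properties")
    for tag in _PROPERTY_TAGS:
        etree.SubElement(props, tag).text = record.properties.get(tag, "")
    for ref in record.properties.get("references", []):
        etree.SubElement(props, "reference").text = ref

    parent = etree.SubElement(root, "parent")
    etree.SubElement(parent, "sequence").text = record.parent.to_tokens(registry)
    if record.parent_structure is not None:
        etree.SubElement(parent, "structure").text = record.parent_structure
    if record.parent_formula is not None:
        etree.SubElement(parent, "formula").text = record.parent_formula
    if record.parent_mz is not None:
        etree.SubElement(parent, "mz").text = repr(record.parent_mz)

    mp = etree.SubElement(root, "metabolized-parent")
    for tag, text in record.metabolized_parent.items():
        etree.SubElement(mp, tag).text = text

    mets = etree.SubElement(root, "metabolites")
    for m in record.metabolites:
        m_el = etree.SubElement(mets, "metabolite")
        etree.SubElement(m_el, "name").text = m.name
        etree.SubElement(m_el, "sequence").text = m.sequence
        etree.SubElement(m_el, "mechanism").text = m.mechanism
        if m.cleaved_bond is not None:
            etree.SubElement(m_el, "cleaved-bond").text = str(m.cleaved_bond)
        etree.SubElement(m_el, "count").text = str(m.count)
        if m.structure is not None:
            etree.SubElement(m_el, "structure").text = m.structure

    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def make_substrate_record(
    parent: Peptide,
    events: list[CleavageEvent],
    registry: BlockRegistry,
    properties: dict | None = None,
) -> SubstrateRecord:
    """Build a record whose metabolites encode the given hydrolysis events."""
    props = {t: "" for t in _PROPERTY_TAGS}
    props["references"] = []
    if properties:
        props.update(properties)
    metabolites = []
    for ev in events:
        if ev.peptide_id != parent.id:
            raise ValueError(f"event peptide {ev.peptide_id!r} != parent {parent.id!r}")
        for side, blocks in (("N", parent.blocks[: ev.bond_index + 1]),
                             ("C", parent.blocks[ev.bond_index + 1 :])):
            seq = "".join(registry[b].token for b in blocks)
            metabolites.append(
                Metabolite(
                    name=f"{parent.id}-bond{ev.bond_index}-{side}",
                    sequence=seq,
                    mechanism="hydrolysis",
                    cleaved_bond=ev.bond_index,
                    count=ev.count,
                )
            )
    return SubstrateRecord(properties=props, parent=parent, metabolites=metabolites)


def filter_substrates(
    records: list[SubstrateRecord], max_len: int = 200
) -> list[SubstrateRecord]:
    """Keep substrates with parent length strictly below ``max_len`` blocks.

    The pipeline targets peptide substrates rather than whole proteins;
    excluded records are counted in the log.
    """
    kept = [r for r in records if len(r.parent) < max_len]
    if len(kept) < len(records):
        log.info("filter_substrates: excluded %d substrate(s) with >= %d blocks",
                 len(records) - len(kept), max_len)
    return kept


def read_fasta(path, registry: BlockRegistry) -> list[Peptide]:
    """Read plain sequences from FASTA; the record id becomes the peptide id."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            peptides.append(parse_sequence(str(rec.seq), registry, id=rec.id))
        except Exception as e:  # unresolvable tokens: skip with a logged reason
            log.warning("skipping FASTA record %s: %s", rec.id, e)
    return peptides


def write_fasta(peptides: list[Peptide], path, registry: BlockRegistry) -> None:
    records = [
        SeqRecord(Seq(p.to_tokens(registry)), id=p.id, description="")
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_events_tsv(path) -> list[CleavageEvent]:
    """Read a cleavage annotation table: peptide_id, bond_index, protease_id, count."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protease_id": str})
    required = {"peptide_id", "bond_index", "protease_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if "count" not in df.columns:
        df["count"] = 1
    return [
        CleavageEvent(r.peptide_id, int(r.bond_index), r.protease_id, int(r.count))
        for r in df.itertuples()
    ]


def write_events_tsv(events: list[CleavageEvent], path) -> None:
    pd.DataFrame(
        {
            "peptide_id": [e.peptide_id for e in events],
            "bond_index": [e.bond_index for e in events],
            "protease_id": [e.protease_id for e in events],
            "count": [e.count for e in events],
        }
    ).to_csv(path, sep="\t", index=False)
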