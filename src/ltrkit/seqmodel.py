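"""Core domain types for plant LTR retrotransposon libraries.

Plant LTR retrotransposons (LTR-RTs) split into the Copia (RLC) and Gypsy
(RLG) superfamilies, each subdivided into lineages (also called families)
defined by coding-region phylogeny.  This module carries the canonical
13-lineage angiosperm vocabulary (with alias merging such as Tork+Tar ->
TORK/TAR and Ogre/Retand -> TAT), the dash-separated FASTA header codec

    >Superfamily-Lineage-plant_family-specie-source-length-ID

and FASTA reading/writing for element libraries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"

#: Canonical angiosperm lineage vocabulary (merged groups), keyed by lineage
#: with its superfamily code (RLC = Copia, RLG = Gypsy).
CANONICAL_SUPERFAMILY: dict[str, str] = {
    # Copia
    "ALE/RETROFIT": "RLC",
    "ANGELA": "RLC",
    "BIANCA": "RLC",
    "IKEROS": "RLC",
    "IVANA/ORYCO": "RLC",
    "TORK/TAR": "RLC",
    "SIRE": "RLC",
    # Gypsy
    "ATHILA": "RLG",
    "CRM": "RLG",
    "DEL/TEKAY": "RLG",
    "GALADRIEL": "RLG",
    "REINA": "RLG",
    "TAT": "RLG",
}

CANONICAL_LINEAGES: tuple[str, ...] = tuple(CANONICAL_SUPERFAMILY)

COPIA_LINEAGES = frozenset(k for k, v in CANONICAL_SUPERFAMILY.items() if v == "RLC")
GYPSY_LINEAGES = frozenset(k for k, v in CANONICAL_SUPERFAMILY.items() if v == "RLG")

#: Raw lineage names folded into the canonical merged groups.
LINEAGE_ALIASES: dict[str, str] = {
    "ALE": "ALE/RETROFIT",
    "RETROFIT": "ALE/RETROFIT",
    "ALE/RETROFIT": "ALE/RETROFIT",
    "RETROFIT/ALE": "ALE/RETROFIT",
    "IVANA": "IVANA/ORYCO",
    "ORYCO": "IVANA/ORYCO",
    "IVANA/ORYCO": "IVANA/ORYCO",
    "ORYCO/IVANA": "IVANA/ORYCO",
    "TAR": "TORK/TAR",
    "TORK": "TORK/TAR",
    "TORK/TAR": "TORK/TAR",
    "TAR/TORK": "TORK/TAR",
    "TEKAY": "DEL/TEKAY",
    "DEL": "DEL/TEKAY",
    "DEL/TEKAY": "DEL/TEKAY",
    "TEKAY/DEL": "DEL/TEKAY",
    "OGRE": "TAT",
    "RETAND": "TAT",
    "TAT": "TAT",
}
for _name in CANONICAL_SUPERFAMILY:
    LINEAGE_ALIASES.setdefault(_name, _name)

#: Lineages restricted to non-angiosperm taxa; rejected by canonical_lineage.
NON_ANGIOSPERM_LINEAGES = frozenset(
    {
        "CHLAMYVIR",
        "TCN1",
        "PHYGY",
        "SELGY",
        "TATI",
        "TATII",
        "TATIII",
        "OSSER",
        "BRYCO",
        "LYCO",
        "GYMCOI",
        "GYMCOII",
        "GYMCOIII",
        "GYMCOIV",
    }
)

VALID_SUPERFAMILIES = ("RLC", "RLG", UNKNOWN)


class HeaderError(ValueError):
    """Raised for malformed library headers."""


class NonAngiospermLineageError(ValueError):
    """Raised when a lineage known only outside angiosperms is requested."""


class UnknownLineageError(ValueError):
    """Raised for lineage names outside the vocabulary and its aliases."""


def canonical_lineage(raw: str) -> str:
    """Map a raw lineage name onto the canonical 13-label vocabulary.

    Case-insensitive and idempotent; merged groups (e.g. ``Tork`` and ``Tar``)
    collapse onto one canonical label.  ``UNKNOWN`` passes through.

    Raises
    ------
    NonAngiospermLineageError
        for lineages absent from angiosperms (Chlamyvir, Tcn1, Gymco ...).
    UnknownLineageError
        for names outside the vocabulary.
    """
    key = raw.strip().upper()
    if key == UNKNOWN:
        return UNKNOWN
    if key in NON_ANGIOSPERM_LINEAGES:
        raise NonAngiospermLineageError(
            f"{raw!r} is a non-angiosperm lineage and is excluded from the vocabulary"
        )
    try:
        return LINEAGE_ALIASES[key]
    except KeyError:
        raise UnknownLineageError(f"unknown lineage name {raw!r}") from None


def lineage_superfamily(lineage: str) -> str:
    """Superfamily code (RLC/RLG) of a canonical lineage; UNKNOWN maps to UNKNOWN."""
    if lineage == UNKNOWN:
        return UNKNOWN
    return CANONICAL_SUPERFAMILY[canonical_lineage(lineage)]


class HeaderFields(NamedTuple):
    """The seven dash-separated fields of a library FASTA header."""

    superfamily: str
    lineage: str
    plant_family: str
    species: str
    source: str
    length: int
    id: str


_FIELD_NAMES = ("Superfamily", "Lineage", "plant_family", "specie", "source", "length", "ID")


def parse_header(header: str) -> HeaderFields:
    """Parse ``>Superfamily-Lineage-plant_family-specie-source-length-ID``.

    Fields are dash-separated; composed names (species) use underscores.
    The lineage is passed through :func:`canonical_lineage`.
    """
    text = header.strip()
    if text.startswith(">"):
        text = text[1:]
    parts = text.split("-")
    if len(parts) != 7:
        raise HeaderError(
            f"header {header!r} has {len(parts)} dash-separated fields; "
            f"7 required ({'-'.join(_FIELD_NAMES)})"
        )
    superfamily, lineage, plant_family, species, source, length_s, elem_id = parts
    superfamily = superfamily.upper()
    if superfamily not in VALID_SUPERFAMILIES:
        raise HeaderError(
            f"header {header!r}: superfamily {superfamily!r} not one of {VALID_SUPERFAMILIES}"
        )
    try:
        length = int(length_s)
    except ValueError:
        raise HeaderError(f"header {header!r}: length field {length_s!r} is not an integer") from None
    return HeaderFields(
        superfamily=superfamily,
        lineage=canonical_lineage(lineage),
        plant_family=plant_family,
        species=species,
        source=source,
        length=length,
        id=elem_id,
    )


def format_header(meta: "HeaderFields | LtrElement") -> str:
    """Emit the dash-separated header for element metadata.

    Spaces inside fields are normalized to underscores; a literal dash inside
    a field would break the codec and raises :class:`HeaderError`.
    """
    if isinstance(meta, LtrElement):
        fields = meta.header_fields()
    else:
        fields = meta
    values = [
        str(fields.superfamily),
        str(fields.lineage),
        str(fields.plant_family),
        str(fields.species),
        str(fields.source),
        str(int(fields.length)),
        str(fields.id),
    ]
    values = [v.replace(" ", "_") for v in values]
    for name, value in zip(_FIELD_NAMES, values):
        if "-" in value:
            raise HeaderError(f"field {name}={value!r} contains a dash; cannot encode")
        if not value:
            raise HeaderError(f"field {name} is empty; cannot encode")
    return ">" + "-".join(values)


@dataclass
class LtrElement:
    """One LTR retrotransposon element with its library metadata."""

    id: str
    sequence: str
    superfamily: str = UNKNOWN
    lineage: str = UNKNOWN
    plant_family: str = "NA"
    species: str = "NA"
    source: str = "NA"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"element {self.id!r} has an empty sequence")
        if self.superfamily not in VALID_SUPERFAMILIES:
            raise ValueError(f"element {self.id!r}: invalid superfamily {self.superfamily!r}")
        if self.lineage != UNKNOWN:
            self.lineage = canonical_lineage(self.lineage)
            expected = CANONICAL_SUPERFAMILY[self.lineage]
            if self.superfamily != UNKNOWN and self.superfamily != expected:
                raise ValueError(
                    f"element {self.id!r}: superfamily {self.superfamily} inconsistent "
                    f"with lineage {self.lineage} ({expected})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def header_fields(self) -> HeaderFields:
        return HeaderFields(
            superfamily=self.superfamily,
            lineage=self.lineage,
            plant_family=self.plant_family,
            species=self.species,
            source=self.source,
            length=self.length,
            id=self.id,
        )

    @property
    def header(self) -> str:
        return format_header(self)

    def with_classification(self, superfamily: str, lineage: str) -> "LtrElement":
        """Copy of the element carrying an assigned superfamily/lineage."""
        new = replace(self, superfamily=UNKNOWN, lineage=UNKNOWN)
        new.lineage = canonical_lineage(lineage) if lineage != UNKNOWN else UNKNOWN
        new.superfamily = superfamily
        new.__post_init__()
        return new


_NON_ACGTN = re.compile(r"[^ACGTN]")


def _clean_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper()
    if _NON_ACGTN.search(seq):
        n_bad = len(_NON_ACGTN.findall(seq))
        logger.warning(
            "record %s: %d non-ACGTN characters mapped to N", record_id, n_bad
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def read_library(path) -> list[LtrElement]:
    """Read a nucleotide FASTA library into :class:`LtrElement` records.

    Headers in the seven-field dash layout populate the metadata; any other
    header is treated as a bare id with UNKNOWN classification.  Sequences
    are upper-cased and non-ACGTN characters are mapped to N with a warning.
    """
    elements: list[LtrElement] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        description = record.description
        try:
            fields = parse_header(description)
            meta = dict(
                id=fields.id,
                superfamily=fields.superfamily,
                lineage=fields.lineage,
                plant_family=fields.plant_family,
                species=fields.species,
                source=fields.source,
            )
        except (HeaderError, UnknownLineageError, NonAngiospermLineageError):
            meta = dict(id=record.id)
        seq = _clean_sequence(str(record.seq), meta["id"])
        element = LtrElement(sequence=seq, **meta)
        if element.id in seen:
            raise ValueError(f"duplicate element id {element.id!r} in {path}")
        seen.add(element.id)
        elements.append(element)
    if not elements:
        raise ValueError(f"FASTA library {path} contains no records")
    return elements


def write_library(elements: Iterable[LtrElement], path) -> None:
    """Write elements as FASTA with seven-field dash headers."""
    records = []
    for el in elements:
        header = format_header(el)[1:]
        records.append(SeqRecord(Seq(el.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")
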