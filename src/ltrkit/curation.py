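"""Homology-based classification and intact-element filtering.

Each candidate element is scanned in all six reading frames against a
reference peptide library of the five canonical LTR-RT coding domains
(GAG, AP, INT, RT, RNaseH), each reference labeled with its lineage and
superfamily.  The element's superfamily and lineage are assigned by a
vote over its best domain hits, then five filters retain only intact
elements:

F1  domains from both superfamilies (potential chimera)
F2  ambiguous lineage vote (top two lineages tied, e.g. 2 DEL + 2 REINA)
F3  length outside the per-lineage reference length +- tolerance (20%)
F4  fewer than three distinct coding domains identified
F5  nested insertion of a class II (DNA) transposon

Filters are evaluated in that fixed order and the first failure is
reported.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqmodel import UNKNOWN, LtrElement, canonical_lineage

logger = logging.getLogger(__name__)

DOMAIN_CLASSES = ("GAG", "AP", "INT", "RT", "RNASEH")


class ConfigurationError(ValueError):
    """Missing or inconsistent curation configuration."""


@dataclass(frozen=True)
class DomainRef:
    """One reference coding-domain peptide."""

    domain_class: str
    lineage: str
    superfamily: str
    peptide: str
    id: str = ""


def read_domain_library(path) -> list[DomainRef]:
    """Read a peptide FASTA with ``>DomainClass-Lineage-Superfamily-id`` headers."""
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.description.split("-")
        if len(parts) != 4:
            raise ConfigurationError(
                f"domain reference header {record.description!r}: expected "
                ">DomainClass-Lineage-Superfamily-id"
            )
        domain_class, lineage, superfamily, ref_id = parts
        domain_class = domain_class.upper()
        if domain_class not in DOMAIN_CLASSES:
            raise ConfigurationError(f"unknown domain class {domain_class!r}")
        refs.append(
            DomainRef(
                domain_class=domain_class,
                lineage=canonical_lineage(lineage),
                superfamily=superfamily.upper(),
                peptide=str(record.seq).upper(),
                id=ref_id,
            )
        )
    if not refs:
        raise ConfigurationError(f"domain library {path} is empty")
    return refs


def write_domain_library(refs: Iterable[DomainRef], path) -> None:
    with open(path, "w") as fh:
        for i, ref in enumerate(refs):
            rid = ref.id or str(i)
            lineage = ref.lineage.replace("-", "/")
            fh.write(f">{ref.domain_class}-{lineage}-{ref.superfamily}-{rid}\n")
            fh.write(ref.peptide + "\n")


@dataclass(frozen=True)
class DomainHit:
    """Best local match of one domain class on one element."""

    element_id: str
    domain_class: str
    ref_lineage: str
    ref_superfamily: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    identity: float  # percent over aligned (non-gap) columns
    aligned_length: int  # aligned aa columns excluding gaps
    start: int  # nt, half-open on the element's forward strand
    end: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad coordinates [{self.start}, {self.end})")


@dataclass(frozen=True)
class ScanParams:
    min_identity: float = 50.0  # percent
    min_aa_length: int = 30


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames +1..+3 and -1..-3; partial codons trimmed."""
    out = []
    rc = str(Seq(seq).reverse_complement())
    for offset in range(3):
        for strand_seq, sign in ((seq, 1), (rc, -1)):
            sub = strand_seq[offset : offset + ((len(strand_seq) - offset) // 3) * 3]
            if not sub:
                continue
            pep = str(Seq(sub).translate())
            out.append((sign * (offset + 1), pep))
    return out


def _frame_to_element_coords(frame: int, aa_start: int, aa_end: int, elem_len: int) -> tuple[int, int]:
    offset = abs(frame) - 1
    nt_start = offset + 3 * aa_start
    nt_end = offset + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end
    return elem_len - nt_end, elem_len - nt_start


def scan_domains(
    element: LtrElement,
    domain_library: Sequence[DomainRef],
    params: ScanParams = ScanParams(),
) -> list[DomainHit]:
    """Best hit per domain class from six-frame local peptide alignment.

    Elements too short to encode a minimal domain (< 3 * min_aa_length nt)
    return an empty list.  Per domain class, the highest-scoring
    (frame, reference) pair is realigned with traceback and kept if it
    clears the identity and aligned-length thresholds.
    """
    if not domain_library:
        raise ConfigurationError("domain library is empty")
    if element.length < 3 * params.min_aa_length:
        return []
    aligner = _make_aligner()
    frames = six_frame_translations(element.sequence)
    by_class: dict[str, list[DomainRef]] = {}
    for ref in domain_library:
        by_class.setdefault(ref.domain_class, []).append(ref)

    hits: list[DomainHit] = []
    for domain_class, refs in by_class.items():
        best: tuple[float, int, DomainRef, str] | None = None
        for frame, pep in frames:
            for ref in refs:
                score = aligner.score(pep, ref.peptide)
                if best is None or score > best[0]:
                    best = (score, frame, ref, pep)
        if best is None or best[0] <= 0:
            continue
        score, frame, ref, pep = best
        alignment = aligner.align(pep, ref.peptide)[0]
        counts = alignment.counts()
        aligned = counts.identities + counts.mismatches
        if aligned == 0:
            continue
        identity = 100.0 * counts.identities / aligned
        if identity < params.min_identity or aligned < params.min_aa_length:
            continue
        target_blocks = alignment.aligned[0]
        aa_start = int(target_blocks[0][0])
        aa_end = int(target_blocks[-1][1])
        start, end = _frame_to_element_coords(frame, aa_start, aa_end, element.length)
        hits.append(
            DomainHit(
                element_id=element.id,
                domain_class=domain_class,
                ref_lineage=ref.lineage,
                ref_superfamily=ref.superfamily,
                frame=frame,
                identity=identity,
                aligned_length=int(aligned),
                start=start,
                end=end,
            )
        )
    return hits


@dataclass(frozen=True)
class Classification:
    """Domain-vote result for one element."""

    superfamily: str
    lineage: str
    tally: tuple[tuple[str, int], ...]  # lineage -> hit count, sorted
    chimeric: bool = False
    ambiguous: bool = False
    mixed_lineage: bool = False


def assign_classification(hits: Sequence[DomainHit]) -> Classification:
    """Superfamily by majority of hits; lineage by strict majority.

    Flags: ``chimeric`` when hits come from both superfamilies; ``ambiguous``
    when the two most frequent lineages tie; ``mixed_lineage`` when more than
    one lineage appears but a strict majority exists (kept, but logged).
    """
    if not hits:
        return Classification(UNKNOWN, UNKNOWN, ())
    sf_counts = Counter(h.ref_superfamily for h in hits)
    chimeric = len([s for s in sf_counts if s in ("RLC", "RLG")]) > 1
    superfamily = min(sf_counts, key=lambda s: (-sf_counts[s], s))
    lin_counts = Counter(h.ref_lineage for h in hits)
    ranked = sorted(lin_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ambiguous = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
    mixed = len(ranked) > 1 and not ambiguous
    if mixed:
        logger.info(
            "element %s: minority lineage dissent in domain vote: %s",
            hits[0].element_id,
            dict(ranked),
        )
    return Classification(
        superfamily=superfamily,
        lineage=ranked[0][0],
        tally=tuple(ranked),
        chimeric=chimeric,
        ambiguous=ambiguous,
        mixed_lineage=mixed,
    )


class FilterReason(str, Enum):
    PASS = "PASS"
    F1_CHIMERIC_SUPERFAMILY = "F1_CHIMERIC_SUPERFAMILY"
    F2_MULTI_LINEAGE = "F2_MULTI_LINEAGE"
    F3_LENGTH = "F3_LENGTH"
    F4_FEW_DOMAINS = "F4_FEW_DOMAINS"
    F5_CLASS2_INSERTION = "F5_CLASS2_INSERTION"


@dataclass(frozen=True)
class FilterDecision:
    element_id: str
    kept: bool
    reason: FilterReason
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kept != (self.reason == FilterReason.PASS):
            raise ValueError("kept flag inconsistent with reason code")


@dataclass
class ReferenceLengths:
    """Expected full-element length per lineage, with a relative tolerance."""

    lengths: dict[str, int]
    tolerance: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError(f"tolerance {self.tolerance} outside (0, 1)")
        self.lengths = {canonical_lineage(k): int(v) for k, v in self.lengths.items()}
        for lineage, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive reference length for {lineage}")

    def expected(self, lineage: str) -> int:
        key = canonical_lineage(lineage)
        if key not in self.lengths:
            raise ConfigurationError(
                f"no reference length configured for lineage {key!r}"
            )
        return self.lengths[key]

    def within(self, lineage: str, length: int) -> bool:
        ref = self.expected(lineage)
        return abs(length - ref) <= self.tolerance * ref

    @classmethod
    def from_tsv(cls, path, tolerance: float = 0.20) -> "ReferenceLengths":
        lengths: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("lineage"):
                continue
            lineage, value = line.split("\t")[:2]
            lengths[lineage] = int(value)
        if not lengths:
            raise ConfigurationError(f"reference length table {path} is empty")
        return cls(lengths=lengths, tolerance=tolerance)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lineage\tlength_nt\n")
            for lineage, length in self.lengths.items():
                fh.write(f"{lineage}\t{length}\n")


@dataclass(frozen=True)
class Class2Params:
    """Thresholds for nested class II (DNA transposon) detection."""

    min_identity: float = 80.0  # percent
    min_length: int = 80  # aligned bp


def find_class2_insertion(
    element: LtrElement,
    class2_library: Sequence[tuple[str, str]],
    params: Class2Params = Class2Params(),
) -> str | None:
    """Id of the first class II reference nested in the element, else None.

    Each reference is aligned as an infix of the element (semi-global);
    a hit needs >= min_identity percent over >= min_length aligned columns.
    """
    for ref_id, ref_seq in class2_library:
        if len(ref_seq) < params.min_length:
            continue
        result = edlib.align(ref_seq, element.sequence, task="path", mode="HW")
        if result["editDistance"] < 0 or not result.get("cigar"):
            continue
        columns = matches = 0
        import re as _re

        for count, op in _re.findall(r"(\d+)([=XIDM])", result["cigar"]):
            n = int(count)
            columns += n
            if op == "=":
                matches += n
        if columns >= params.min_length and 100.0 * matches / columns >= params.min_identity:
            return ref_id
    return None


def apply_filters(
    element: LtrElement,
    classification: Classification,
    hits: Sequence[DomainHit],
    ref_lengths: ReferenceLengths,
    class2_library: Sequence[tuple[str, str]] | None = None,
    class2_params: Class2Params = Class2Params(),
) -> FilterDecision:
    """Evaluate filters F1..F5 in order; report the first failure."""
    if classification.chimeric:
        return FilterDecision(
            element.id, False, FilterReason.F1_CHIMERIC_SUPERFAMILY,
            f"domains from both superfamilies: {dict(classification.tally)}",
        )
    if classification.ambiguous:
        return FilterDecision(
            element.id, False, FilterReason.F2_MULTI_LINEAGE,
            f"tied lineage vote: {dict(classification.tally)}",
        )
    if classification.lineage != UNKNOWN:
        ref = ref_lengths.expected(classification.lineage)
        if not ref_lengths.within(classification.lineage, element.length):
            return FilterDecision(
                element.id, False, FilterReason.F3_LENGTH,
                f"length {element.length} vs reference {ref} "
                f"(tolerance {ref_lengths.tolerance:.0%})",
            )
    n_domains = len({h.domain_class for h in hits})
    if n_domains < 3:
        return FilterDecision(
            element.id, False, FilterReason.F4_FEW_DOMAINS,
            f"only {n_domains} distinct coding domains identified",
        )
    if class2_library:
        nested = find_class2_insertion(element, class2_library, class2_params)
        if nested is not None:
            return FilterDecision(
                element.id, False, FilterReason.F5_CLASS2_INSERTION,
                f"nested class II insertion matching {nested}",
            )
    return FilterDecision(element.id, True, FilterReason.PASS)


@dataclass
class CurationReport:
    """One filter decision per input element, plus vote summaries."""

    decisions: list[FilterDecision] = field(default_factory=list)
    classifications: dict[str, Classification] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(d.reason.value for d in self.decisions)
        return {reason.value: c.get(reason.value, 0) for reason in FilterReason}

    @property
    def kept_ids(self) -> list[str]:
        return [d.element_id for d in self.decisions if d.kept]

    def to_tsv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write("element_id\tkept\treason\tdetail\n")
            for d in self.decisions:
                fh.write(f"{d.element_id}\t{int(d.kept)}\t{d.reason.value}\t{d.detail}\n")


def curate_library(
    elements: Sequence[LtrElement],
    domain_library: Sequence[DomainRef],
    ref_lengths: ReferenceLengths,
    class2_library: Sequence[tuple[str, str]] | None = None,
    scan_params: ScanParams = ScanParams(),
    class2_params: Class2Params = Class2Params(),
) -> tuple[list[LtrElement], CurationReport]:
    """Classify and filter a library; kept elements carry assigned labels."""
    report = CurationReport()
    kept: list[LtrElement] = []
    if not elements:
        logger.warning("curate_library called on an empty library")
        return kept, report
    for element in elements:
        hits = scan_domains(element, domain_library, scan_params)
        classification = assign_classification(hits)
        report.classifications[element.id] = classification
        decision = apply_filters(
            element, classification, hits, ref_lengths, class2_library, class2_params
        )
        report.decisions.append(decision)
        if decision.kept:
            kept.append(
                element.with_classification(
                    classification.superfamily, classification.lineage
                )
            )
    logger.info("curation: %d/%d elements kept (%s)", len(kept), len(elements),
                report.counts)
    return kept, report
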