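"""Labeled synthetic LTR retrotransposon libraries.

Each lineage gets a profile: a target element length, a flanking LTR, one
reference peptide per coding domain (GAG, AP, INT, RT, RNaseH) carrying a
lineage-identifying random motif, and a set of enriched hexamers that bias
the composition of the internal spacer regions.  Elements are assembled as

    LTR + spacer + GAG + spacer + AP + spacer + INT + spacer + RT
        + spacer + RNaseH + spacer + LTR(near-identical)

with point substitutions applied at a configurable rate.  The hexamer bias
injects exactly the kind of signal a k<=6 k-mer classifier can use, with
controllable strength; it does not emulate phylogenetically realistic
evolution.  Controlled defect classes (chimeric, multi-lineage, short/long,
few-domains, class-II-nested) each violate exactly one curation filter by
construction, and a ground-truth manifest records every element's lineage,
family of origin and injected defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import DOMAIN_CLASSES, DomainRef, ReferenceLengths, write_domain_library
from .seqmodel import (
    CANONICAL_SUPERFAMILY,
    LtrElement,
    canonical_lineage,
    write_library,
)

BASES = "ACGT"
HEXAMERS = ["".join(p) for p in product(BASES, repeat=6)]
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed sense codon per amino acid (no stops) so back-translation is
#: deterministic and re-translation recovers the peptide exactly.
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

DEFECT_TYPES = ("CHIMERIC", "MULTI_LINEAGE", "SHORT", "LONG", "FEW_DOMAINS", "CLASS2_NESTED")
NO_DEFECT = "NONE"


def back_translate(peptide: str) -> str:
    return "".join(CODON_OF[aa] for aa in peptide)


@dataclass
class LineageProfile:
    """Everything needed to emit elements of one synthetic lineage."""

    lineage: str
    superfamily: str
    target_length: int
    ltr_length: int
    ltr_seq: str
    biased_kmers: dict[str, float]  # hexamer -> enrichment weight (> 1)
    domain_peptides: dict[str, str]  # domain class -> peptide
    hexamer_probs: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.target_length <= 2 * self.ltr_length:
            raise ValueError(
                f"{self.lineage}: target length {self.target_length} must exceed "
                f"twice the LTR length {self.ltr_length}"
            )
        if any(w <= 1.0 for w in self.biased_kmers.values()):
            raise ValueError("enrichment weights must be > 1")
        if self.hexamer_probs is None:
            weights = np.ones(len(HEXAMERS))
            for hexamer, w in self.biased_kmers.items():
                weights[HEXAMERS.index(hexamer)] = w
            self.hexamer_probs = weights / weights.sum()


@dataclass
class DefectSpec:
    """A defect to inject; each type violates exactly one curation filter."""

    defect: str
    length_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.defect not in DEFECT_TYPES:
            raise ValueError(f"unknown defect {self.defect!r}; known: {DEFECT_TYPES}")


def make_profiles(
    lineages: Sequence[str],
    seed: int = 0,
    bias_weight: float = 8.0,
    n_biased: int = 40,
    ltr_length: int = 300,
    length_range: tuple[int, int] = (5000, 15000),
    peptide_length: int = 80,
) -> tuple[list[LineageProfile], list[DomainRef]]:
    """Profiles with pairwise-disjoint biased hexamer sets, plus the matching
    reference peptide library (five domains per lineage)."""
    canon = [canonical_lineage(l) for l in lineages]
    if len(set(canon)) != len(canon):
        raise ValueError(f"duplicate lineage in request: {lineages}")
    n = len(canon)
    if n * n_biased > len(HEXAMERS):
        raise ValueError("too many biased hexamers requested for disjoint sets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(HEXAMERS))
    lo, hi = length_range
    targets = np.linspace(lo, hi, n).round().astype(int) if n > 1 else np.array([(lo + hi) // 2])
    profiles: list[LineageProfile] = []
    refs: list[DomainRef] = []
    for i, lineage in enumerate(canon):
        superfamily = CANONICAL_SUPERFAMILY[lineage]
        biased = {
            HEXAMERS[j]: float(bias_weight)
            for j in perm[i * n_biased : (i + 1) * n_biased]
        }
        peptides = {
            dc: "".join(rng.choice(list(AA_ALPHABET), size=peptide_length))
            for dc in DOMAIN_CLASSES
        }
        profiles.append(
            LineageProfile(
                lineage=lineage,
                superfamily=superfamily,
                target_length=int(targets[i]),
                ltr_length=ltr_length,
                ltr_seq="".join(rng.choice(list(BASES), size=ltr_length)),
                biased_kmers=biased,
                domain_peptides=peptides,
            )
        )
        for dc in DOMAIN_CLASSES:
            refs.append(
                DomainRef(
                    domain_class=dc,
                    lineage=lineage,
                    superfamily=superfamily,
                    peptide=peptides[dc],
                    id=f"{dc}_{lineage.replace('/', '_')}",
                )
            )
    return profiles, refs


def _sample_spacer(profile: LineageProfile, n_nt: int, rng: np.random.Generator) -> str:
    if n_nt <= 0:
        return ""
    m, rem = divmod(n_nt, 6)
    codes = rng.choice(len(HEXAMERS), size=m, p=profile.hexamer_probs)
    tail = "".join(rng.choice(list(BASES), size=rem)) if rem else ""
    return "".join(HEXAMERS[c] for c in codes) + tail


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        code[ord(b)] = i
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        new = (code[arr[hit]] + shift) % 4
        arr[hit] = np.frombuffer(BASES.encode(), dtype=np.uint8)[new]
    return arr.tobytes().decode("ascii")


def _assemble(
    profile: LineageProfile,
    domain_peptides: Sequence[tuple[str, str]],
    rng: np.random.Generator,
    length_multiplier: float = 1.0,
    insert: str = "",
) -> str:
    """Build LTR + interleaved domains/spacers + LTR at the requested length."""
    target = int(round(profile.target_length * length_multiplier))
    domains_nt = [back_translate(pep) for _, pep in domain_peptides]
    budget = target - 2 * profile.ltr_length - sum(map(len, domains_nt)) - len(insert)
    n_gaps = len(domains_nt) + 1
    if budget < n_gaps:
        raise ValueError(
            f"{profile.lineage}: target length {target} cannot accommodate "
            f"LTRs, domains and insert"
        )
    per_gap, extra = divmod(budget, n_gaps)
    gap_sizes = [per_gap + (1 if i < extra else 0) for i in range(n_gaps)]
    insert_gap = n_gaps // 2
    parts = [profile.ltr_seq]
    for i in range(n_gaps):
        spacer = _sample_spacer(profile, gap_sizes[i], rng)
        if i == insert_gap and insert:
            half = len(spacer) // 2
            spacer = spacer[:half] + insert + spacer[half:]
        parts.append(spacer)
        if i < len(domains_nt):
            parts.append(domains_nt[i])
    parts.append(profile.ltr_seq)
    return "".join(parts)


def generate_element(
    profile: LineageProfile,
    mutation_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    element_id: str = "0",
    domain_subset: Sequence[str] | None = None,
    length_multiplier: float = 1.0,
    insert: str = "",
) -> LtrElement:
    """One element from a profile; 0 <= mutation_rate < 0.5 (substitutions)."""
    if not (0.0 <= mutation_rate < 0.5):
        raise ValueError(f"mutation_rate {mutation_rate} outside [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = list(domain_subset) if domain_subset is not None else list(DOMAIN_CLASSES)
    peptides = [(dc, profile.domain_peptides[dc]) for dc in classes]
    seq = _assemble(profile, peptides, rng, length_multiplier, insert)
    seq = _mutate(seq, mutation_rate, rng)
    return LtrElement(
        id=element_id,
        sequence=seq,
        superfamily=profile.superfamily,
        lineage=profile.lineage,
        plant_family="Simulatae",
        species="Synthetica_exemplaris",
        source="SIM",
    )


def make_class2_decoys(
    n: int = 3, length: int = 600, seed: int = 0
) -> list[tuple[str, str]]:
    """Random decoy DNA-transposon sequences for the nested-insertion defect."""
    rng = np.random.default_rng(seed)
    return [
        (f"DTX_{i}", "".join(rng.choice(list(BASES), size=length)))
        for i in range(n)
    ]


def _partner(
    profile: LineageProfile, profiles: Sequence[LineageProfile], same_superfamily: bool
) -> LineageProfile:
    for other in profiles:
        if other.lineage == profile.lineage:
            continue
        if (other.superfamily == profile.superfamily) == same_superfamily:
            return other
    kind = "same" if same_superfamily else "other"
    raise ValueError(
        f"no {kind}-superfamily partner available for {profile.lineage}; "
        "defect construction needs a larger profile set"
    )


def generate_defect_element(
    defect: str,
    profile: LineageProfile,
    profiles: Sequence[LineageProfile],
    class2_library: Sequence[tuple[str, str]],
    mutation_rate: float,
    rng: np.random.Generator,
    element_id: str,
) -> LtrElement:
    """An element violating exactly the curation filter its defect targets."""
    if defect == "CHIMERIC":
        partner = _partner(profile, profiles, same_superfamily=False)
        peptides = [(dc, profile.domain_peptides[dc]) for dc in ("GAG", "AP", "INT")]
        peptides += [(dc, partner.domain_peptides[dc]) for dc in ("RT", "RNASEH")]
        seq = _assemble(profile, peptides, rng)
    elif defect == "MULTI_LINEAGE":
        partner = _partner(profile, profiles, same_superfamily=True)
        peptides = [(dc, profile.domain_peptides[dc]) for dc in ("AP", "INT")]
        peptides += [(dc, partner.domain_peptides[dc]) for dc in ("RT", "RNASEH")]
        seq = _assemble(profile, peptides, rng)
    elif defect in ("SHORT", "LONG"):
        mult = 0.7 if defect == "SHORT" else 1.3
        peptides = [(dc, profile.domain_peptides[dc]) for dc in DOMAIN_CLASSES]
        seq = _assemble(profile, peptides, rng, length_multiplier=mult)
    elif defect == "FEW_DOMAINS":
        peptides = [(dc, profile.domain_peptides[dc]) for dc in ("GAG", "RT")]
        seq = _assemble(profile, peptides, rng)
    elif defect == "CLASS2_NESTED":
        if not class2_library:
            raise ValueError("CLASS2_NESTED defect needs a class II decoy library")
        decoy = class2_library[int(rng.integers(len(class2_library)))][1]
        peptides = [(dc, profile.domain_peptides[dc]) for dc in DOMAIN_CLASSES]
        seq = _assemble(profile, peptides, rng, insert=decoy)
    else:
        raise ValueError(f"unknown defect {defect!r}")
    seq = _mutate(seq, mutation_rate, rng)
    return LtrElement(
        id=element_id,
        sequence=seq,
        superfamily=profile.superfamily,
        lineage=profile.lineage,
        plant_family="Simulatae",
        species="Synthetica_exemplaris",
        source="SIM",
    )


@dataclass
class SyntheticLibrary:
    """A generated library plus its ground truth and companion inputs."""

    elements: list[LtrElement]
    manifest: pd.DataFrame  # element_id, lineage, superfamily, family_id, defect
    profiles: list[LineageProfile]
    domain_refs: list[DomainRef]
    class2_library: list[tuple[str, str]]

    @property
    def reference_lengths(self) -> ReferenceLengths:
        return ReferenceLengths(
            lengths={p.lineage: p.target_length for p in self.profiles}
        )

    def labels(self) -> np.ndarray:
        return self.manifest["lineage"].to_numpy()

    def write_bundle(self, outdir) -> dict[str, Path]:
        """FASTA library + domain peptides + class II decoys + reference lengths
        + manifest: a complete self-consistent input set for the pipeline."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "library": outdir / "library.fasta",
            "domains": outdir / "domains.fasta",
            "class2": outdir / "class2.fasta",
            "ref_lengths": outdir / "ref_lengths.tsv",
            "manifest": outdir / "manifest.tsv",
        }
        write_library(self.elements, paths["library"])
        write_domain_library(self.domain_refs, paths["domains"])
        with open(paths["class2"], "w") as fh:
            for rid, seq in self.class2_library:
                fh.write(f">{rid}\n{seq}\n")
        self.reference_lengths.to_tsv(paths["ref_lengths"])
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        return paths


def generate_library(
    profiles: Sequence[LineageProfile],
    domain_refs: Sequence[DomainRef],
    n_per_lineage: int = 200,
    mutation_rate: float = 0.03,
    copies_per_family: int = 1,
    defect_fractions: dict[str, float] | None = None,
    seed: int = 0,
    class2_library: Sequence[tuple[str, str]] | None = None,
) -> SyntheticLibrary:
    """A labeled multi-lineage library with optional copies and defects.

    Per lineage, intact elements are organized into families: one founder
    plus ``copies_per_family - 1`` mutated copies each (all copies mutate
    at ``mutation_rate`` from the founder, so any two copies of one family
    stay clusterable).  Defect counts are ``round(fraction * total)`` per
    type, spread round-robin over lineages and recorded in the manifest.
    """
    if n_per_lineage < 1 or copies_per_family < 1:
        raise ValueError("n_per_lineage and copies_per_family must be >= 1")
    defect_fractions = defect_fractions or {}
    unknown = set(defect_fractions) - set(DEFECT_TYPES)
    if unknown:
        raise ValueError(f"unknown defect types {sorted(unknown)}")
    if sum(defect_fractions.values()) > 1.0 + 1e-9:
        raise ValueError("defect fractions sum to more than 1")
    rng = np.random.default_rng(seed)
    if class2_library is None:
        class2_library = make_class2_decoys(seed=seed + 1)

    n_lineages = len(profiles)
    total = n_per_lineage * n_lineages
    defect_counts = {d: int(round(f * total)) for d, f in defect_fractions.items()}

    # round-robin defect slots over lineages
    defect_slots: dict[int, list[str]] = {i: [] for i in range(n_lineages)}
    cursor = 0
    for defect in DEFECT_TYPES:
        for _ in range(defect_counts.get(defect, 0)):
            defect_slots[cursor % n_lineages].append(defect)
            cursor += 1

    elements: list[LtrElement] = []
    rows = []
    eid = 0
    for li, profile in enumerate(profiles):
        slots_defect = defect_slots[li]
        if len(slots_defect) > n_per_lineage:
            raise ValueError("more defect slots than elements for a lineage")
        n_intact = n_per_lineage - len(slots_defect)
        n_families = -(-n_intact // copies_per_family)  # ceil
        made = 0
        for fam in range(n_families):
            family_id = f"{profile.lineage}:fam{fam}"
            founder = generate_element(
                profile, mutation_rate=0.0, seed=rng, element_id="founder"
            ).sequence
            for _ in range(min(copies_per_family, n_intact - made)):
                seq = _mutate(founder, mutation_rate, rng)
                el = LtrElement(
                    id=f"E{eid:06d}",
                    sequence=seq,
                    superfamily=profile.superfamily,
                    lineage=profile.lineage,
                    plant_family="Simulatae",
                    species="Synthetica_exemplaris",
                    source="SIM",
                )
                elements.append(el)
                rows.append((el.id, profile.lineage, profile.superfamily,
                             family_id, NO_DEFECT))
                eid += 1
                made += 1
        for k, defect in enumerate(slots_defect):
            el = generate_defect_element(
                defect, profile, profiles, class2_library,
                mutation_rate, rng, f"E{eid:06d}",
            )
            elements.append(el)
            rows.append((el.id, profile.lineage, profile.superfamily,
                         f"{profile.lineage}:defect{k}", defect))
            eid += 1

    manifest = pd.DataFrame(
        rows, columns=["element_id", "lineage", "superfamily", "family_id", "defect"]
    )
    return SyntheticLibrary(
        elements=elements,
        manifest=manifest,
        profiles=list(profiles),
        domain_refs=list(domain_refs),
        class2_library=list(class2_library),
    )


def generate_null_library(
    lineages: Sequence[str],
    n_total: int,
    seed: int = 0,
    target_length: int = 8000,
) -> tuple[list[LtrElement], np.ndarray]:
    """A label-signal-free control: every sequence drawn from one profile,
    lineage labels assigned round-robin.  Any classifier's macro F1 on this
    library converges to chance (1 / n_lineages)."""
    canon = [canonical_lineage(l) for l in lineages]
    profiles, _ = make_profiles(
        [canon[0]], seed=seed, bias_weight=8.0,
        length_range=(target_length, target_length),
    )
    profile = profiles[0]
    rng = np.random.default_rng(seed + 1)
    elements = [
        generate_element(profile, mutation_rate=0.0, seed=rng, element_id=f"N{i:06d}")
        for i in range(n_total)
    ]
    labels = np.array([canon[i % len(canon)] for i in range(n_total)])
    return elements, labels


def make_filter_fixture(
    seed: int = 0, mutation_rate: float = 0.02
) -> SyntheticLibrary:
    """The 12-element curation fixture: 7 intact + one element per defect
    class (CHIMERIC, MULTI_LINEAGE, SHORT, FEW_DOMAINS, CLASS2_NESTED)."""
    lineages = ["ATHILA", "REINA", "SIRE", "TORK/TAR"]
    profiles, refs = make_profiles(
        lineages, seed=seed, length_range=(5000, 8000)
    )
    class2 = make_class2_decoys(seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    elements: list[LtrElement] = []
    rows = []
    for i in range(7):
        profile = profiles[i % len(profiles)]
        el = generate_element(
            profile, mutation_rate, seed=rng, element_id=f"INTACT{i}"
        )
        elements.append(el)
        rows.append((el.id, profile.lineage, profile.superfamily,
                     f"{profile.lineage}:fix{i}", NO_DEFECT))
    for j, defect in enumerate(
        ("CHIMERIC", "MULTI_LINEAGE", "SHORT", "FEW_DOMAINS", "CLASS2_NESTED")
    ):
        profile = profiles[j % len(profiles)]
        el = generate_defect_element(
            defect, profile, profiles, class2, mutation_rate, rng, f"DEFECT{j}"
        )
        elements.append(el)
        rows.append((el.id, profile.lineage, profile.superfamily,
                     f"{profile.lineage}:defect{j}", defect))
    manifest = pd.DataFrame(
        rows, columns=["element_id", "lineage", "superfamily", "family_id", "defect"]
    )
    return SyntheticLibrary(
        elements=elements, manifest=manifest, profiles=profiles,
        domain_refs=refs, class2_library=class2,
    )
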