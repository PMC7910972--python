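"""Non-redundant library construction.

Near-identical element copies are grouped by single-linkage clustering on a
pairwise identity/coverage graph (edges at >= 90% identity and >= 95%
coverage of the shorter sequence by default), each cluster is aligned
center-star against its longest member, columns gapped in all rows but one
are trimmed, and a majority-rule consensus represents the cluster.

Pairwise alignment uses banded bit-parallel global alignment (edlib) with
an exact extended-CIGAR traceback; candidate pairs are prefiltered by
shared 12-mers so unrelated sequences are rarely aligned at all.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .seqmodel import LtrElement

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ClusteringParams:
    min_identity: float = 90.0  # percent, over non-terminal aligned columns
    min_coverage: float = 95.0  # percent of the shorter sequence
    prefilter_kmer: int = 12
    prefilter_min_shared: int = 20  # distinct shared k-mers to become a candidate pair

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ValueError(f"{name}={v} outside (0, 100]")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def pairwise_identity(
    a: str, b: str, params: ClusteringParams = ClusteringParams()
) -> tuple[float, float]:
    """(identity %, coverage %) from exact global alignment of two sequences.

    Identity counts matched columns over all aligned columns excluding
    terminal gap runs; coverage is the non-terminal aligned span as a
    fraction of the shorter sequence.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    # fix argument order so the result is exactly symmetric
    if (len(a), a) > (len(b), b):
        a, b = b, a
    result = edlib.align(a, b, task="path", mode="NW")
    ops = _cigar_ops(result["cigar"])
    # strip terminal gap runs (I = gap in target/b, D = gap in query/a)
    start, end = 0, len(ops)
    while start < end and ops[start][1] in "ID":
        start += 1
    while end > start and ops[end - 1][1] in "ID":
        end -= 1
    inner = ops[start:end]
    columns = sum(n for n, _ in inner)
    matches = sum(n for n, op in inner if op == "=")
    if columns == 0:
        return 0.0, 0.0
    identity = 100.0 * matches / columns
    coverage = 100.0 * columns / min(len(a), len(b))
    return identity, min(coverage, 100.0)


@dataclass
class Cluster:
    """A single-linkage cluster of near-identical elements."""

    members: list[str]
    representative: str  # longest member's id

    @property
    def size(self) -> int:
        return len(self.members)


def _candidate_pairs(
    elements: Sequence[LtrElement], params: ClusteringParams
) -> Iterable[tuple[int, int]]:
    """Index pairs sharing enough distinct k-mers to be worth aligning."""
    k = params.prefilter_kmer
    kmer_owners: dict[str, list[int]] = defaultdict(list)
    n_distinct = []
    for i, el in enumerate(elements):
        seq = el.sequence
        kmers = {seq[j : j + k] for j in range(0, max(len(seq) - k + 1, 1))}
        n_distinct.append(len(kmers))
        for kmer in kmers:
            kmer_owners[kmer].append(i)
    shared: Counter[tuple[int, int]] = Counter()
    for owners in kmer_owners.values():
        if len(owners) < 2:
            continue
        for x in range(len(owners)):
            for y in range(x + 1, len(owners)):
                shared[(owners[x], owners[y])] += 1
    out = []
    for (i, j), n in shared.items():
        # repetitive or short sequences have few distinct k-mers; scale the
        # threshold down so they are still considered
        need = min(params.prefilter_min_shared,
                   max(1, min(n_distinct[i], n_distinct[j]) // 2))
        if n >= need:
            out.append((i, j))
    return out


def cluster_library(
    elements: Sequence[LtrElement], params: ClusteringParams = ClusteringParams()
) -> list[Cluster]:
    """Connected components of the identity/coverage threshold graph.

    Deterministic: clusters are ordered by representative id, members
    sorted within each cluster.  The output partitions the input.
    """
    if not elements:
        raise ValueError("cluster_library requires at least one element")
    n = len(elements)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, j in _candidate_pairs(elements, params):
        if find(i) == find(j):
            continue
        identity, coverage = pairwise_identity(
            elements[i].sequence, elements[j].sequence, params
        )
        if identity >= params.min_identity and coverage >= params.min_coverage:
            union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    clusters = []
    for idxs in groups.values():
        rep = max(idxs, key=lambda i: (len(elements[i].sequence), elements[i].id))
        clusters.append(
            Cluster(
                members=sorted(elements[i].id for i in idxs),
                representative=elements[rep].id,
            )
        )
    clusters.sort(key=lambda c: c.representative)
    return clusters


def align_cluster(sequences: Sequence[str]) -> list[str]:
    """Center-star multiple alignment against the longest sequence.

    Each sequence is globally aligned to the star (the longest member);
    the pairwise gap patterns are merged into one set of columns.  Exact
    for the near-identical copies clustering produces; not a general MSA.
    """
    if not sequences:
        raise ValueError("align_cluster requires a non-empty cluster")
    if len(sequences) == 1:
        return [sequences[0]]
    star_idx = max(range(len(sequences)), key=lambda i: (len(sequences[i]), -i))
    star = sequences[star_idx]
    S = len(star)

    # For each non-star row: col_chars[p] = char aligned to star position p
    # (or '-'), ins_chunks[p] = string inserted before star position p.
    parsed: dict[int, tuple[list[str], list[str]]] = {}
    max_insert = [0] * (S + 1)
    for i, seq in enumerate(sequences):
        if i == star_idx:
            continue
        result = edlib.align(seq, star, task="path", mode="NW")
        col_chars = ["-"] * S
        ins_chunks = [""] * (S + 1)
        pos_s = pos_q = 0
        for n, op in _cigar_ops(result["cigar"]):
            if op in ("=", "X", "M"):
                col_chars[pos_s : pos_s + n] = seq[pos_q : pos_q + n]
                pos_s += n
                pos_q += n
            elif op == "D":  # gap in query: star advances alone
                pos_s += n
            elif op == "I":  # query chars inserted relative to the star
                ins_chunks[pos_s] += seq[pos_q : pos_q + n]
                pos_q += n
        parsed[i] = (col_chars, ins_chunks)
        for p in range(S + 1):
            max_insert[p] = max(max_insert[p], len(ins_chunks[p]))

    def build_row(col_chars: list[str], ins_chunks: list[str]) -> str:
        parts: list[str] = []
        for p in range(S + 1):
            chunk = ins_chunks[p]
            parts.append(chunk + "-" * (max_insert[p] - len(chunk)))
            if p < S:
                parts.append(col_chars[p])
        return "".join(parts)

    msa: list[str] = []
    for i in range(len(sequences)):
        if i == star_idx:
            msa.append(build_row(list(star), [""] * (S + 1)))
        else:
            msa.append(build_row(*parsed[i]))
    width = len(msa[0])
    assert all(len(r) == width for r in msa), "center-star rows disagree in width"
    return msa


def trim_alignment(msa: Sequence[str]) -> list[str]:
    """Drop columns where all rows but one (or all) are gaps."""
    if not msa:
        return []
    n = len(msa)
    if n == 1:
        return [msa[0].replace("-", "")] if "-" in msa[0] else [msa[0]]
    arr = np.array([list(row) for row in msa])
    gap_counts = (arr == "-").sum(axis=0)
    keep = gap_counts < n - 1
    return ["".join(row) for row in arr[:, keep]]


def majority_consensus(msa: Sequence[str]) -> str:
    """Plurality non-gap base per column; columns won by a gap are omitted.

    Ties among bases break by fixed order A < C < G < T < N.
    """
    if not msa:
        raise ValueError("majority_consensus requires a non-empty alignment")
    if len(msa) == 1:
        return msa[0].replace("-", "")
    order = {b: i for i, b in enumerate("ACGTN")}
    out = []
    for col in zip(*msa):
        counts = Counter(col)
        gap_count = counts.pop("-", 0)
        if not counts:
            continue
        best_base, best_count = min(
            counts.items(), key=lambda kv: (-kv[1], order.get(kv[0], 99))
        )
        if gap_count > best_count:
            continue
        out.append(best_base)
    return "".join(out)


@dataclass
class ConsensusRecord:
    """Majority-rule representative of one cluster."""

    consensus: LtrElement
    member_count: int
    cluster_representative: str


def build_nonredundant(
    elements: Sequence[LtrElement],
    params: ClusteringParams = ClusteringParams(),
) -> tuple[list[ConsensusRecord], list[Cluster]]:
    """Cluster a curated library and emit one consensus per cluster.

    Singleton clusters pass their member through unchanged.  The consensus
    carries the representative's metadata; with mixed lineages in a cluster
    (warned), the plurality lineage among members labels the consensus.
    """
    clusters = cluster_library(elements, params)
    by_id = {el.id: el for el in elements}
    records: list[ConsensusRecord] = []
    for cluster in clusters:
        members = [by_id[mid] for mid in cluster.members]
        rep = by_id[cluster.representative]
        if cluster.size == 1:
            consensus_seq = rep.sequence
        else:
            msa = align_cluster([m.sequence for m in members])
            consensus_seq = majority_consensus(trim_alignment(msa))
        lineages = Counter(m.lineage for m in members)
        if len(lineages) > 1:
            logger.warning(
                "cluster %s mixes lineages %s; labeling consensus by plurality",
                cluster.representative, dict(lineages),
            )
        lineage = min(lineages, key=lambda l: (-lineages[l], l))
        superfamily = rep.superfamily
        if lineage != rep.lineage:
            superfamily = Counter(
                m.superfamily for m in members if m.lineage == lineage
            ).most_common(1)[0][0]
        consensus = LtrElement(
            id=rep.id,
            sequence=consensus_seq,
            superfamily=superfamily,
            lineage=lineage,
            plant_family=rep.plant_family,
            species=rep.species,
            source=rep.source,
        )
        records.append(
            ConsensusRecord(
                consensus=consensus,
                member_count=cluster.size,
                cluster_representative=cluster.representative,
            )
        )
    logger.info(
        "redundancy removal: %d elements -> %d consensus records",
        len(elements), len(records),
    )
    return records, clusters


def clusters_to_tsv(clusters: Sequence[Cluster], path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("cluster_id\telement_id\trepresentative\n")
        for i, cluster in enumerate(clusters):
            for member in cluster.members:
                fh.write(f"{i}\t{member}\t{int(member == cluster.representative)}\n")
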