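import numpy as np
import pytest
from Bio.Align import PairwiseAligner

from ltrkit.redundancy import (
    Cluster,
    ClusteringParams,
    align_cluster,
    build_nonredundant,
    cluster_library,
    clusters_to_tsv,
    majority_consensus,
    pairwise_identity,
    trim_alignment,
)
from ltrkit.seqmodel import LtrElement
from ltrkit.synthetic_data import generate_library, make_profiles


def _mutate_subs(seq, n_subs, rng):
    """Introduce exactly n distinct substitutions."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def nw_oracle(a: str, b: str) -> tuple[float, float]:
    """Exact global alignment with unit edit costs (independent of edlib)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    # epsilon-worse gaps: substitution-only optima become unique while the
    # edit-distance ordering is preserved for the pairs this oracle checks
    aligner.open_gap_score = -1.0001
    aligner.extend_gap_score = -1.0001
    alignment = aligner.align(a, b)[0]
    cols_a, cols_b = alignment[0], alignment[1]
    # strip terminal gap columns
    start, end = 0, len(cols_a)
    while start < end and (cols_a[start] == "-" or cols_b[start] == "-"):
        start += 1
    while end > start and (cols_a[end - 1] == "-" or cols_b[end - 1] == "-"):
        end -= 1
    columns = end - start
    matches = sum(
        1 for i in range(start, end) if cols_a[i] == cols_b[i] and cols_a[i] != "-"
    )
    return 100.0 * matches / columns, 100.0 * columns / min(len(a), len(b))


class TestPairwiseIdentity:
    def test_identical(self):
        seq = "ACGT" * 50
        assert pairwise_identity(seq, seq) == (100.0, 100.0)

    def test_five_substitutions_in_100(self, rng):
        seq = _random_dna(rng, 100)
        mut = _mutate_subs(seq, 5, rng)
        identity, coverage = pairwise_identity(seq, mut)
        assert identity == pytest.approx(95.0)
        assert coverage == pytest.approx(100.0)

    def test_symmetric(self, rng):
        a, b = _random_dna(rng, 300), _random_dna(rng, 250)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_random_pairs_low_identity(self, rng):
        below_70 = 0
        for _ in range(20):
            a, b = _random_dna(rng, 500), _random_dna(rng, 500)
            identity, _ = pairwise_identity(a, b)
            below_70 += identity < 70
        assert below_70 == 20

    def test_agrees_with_global_alignment_oracle(self, rng):
        """Agreement with an independent dynamic-programming oracle.

        Optimal global alignments are not always unique (two adjacent
        substitutions can be co-optimally explained as an indel pair), so
        identity may differ between valid optima by a fraction of a point;
        agreement is asserted to half a percentage point.
        """
        for _ in range(30):
            n = int(rng.integers(100, 1000))
            a = _random_dna(rng, n)
            b = _mutate_subs(a, int(rng.integers(0, n // 10)), rng)
            identity, coverage = pairwise_identity(a, b)
            o_identity, o_coverage = nw_oracle(a, b)
            assert identity == pytest.approx(o_identity, abs=0.5)
            assert min(coverage, 100.0) == pytest.approx(min(o_coverage, 100.0), abs=1.0)

    def test_indel_pair_against_oracle(self, rng):
        a = _random_dna(rng, 400)
        b = a[:150] + a[170:]  # 20 nt internal deletion
        identity, coverage = pairwise_identity(a, b)
        # internal gap columns count against identity: 380 matches / 400 columns
        assert identity == pytest.approx(100.0 * 380 / 400)
        assert coverage == pytest.approx(100.0)  # span exceeds shorter; capped

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


def _elements(seqs):
    return [LtrElement(id=f"s{i}", sequence=s) for i, s in enumerate(seqs)]


class TestClusterLibrary:
    def test_copies_plus_unrelated(self, rng):
        base = _random_dna(rng, 600)
        copies = [_mutate_subs(base, 30, rng) for _ in range(5)]  # ~95% identity
        unrelated = [_random_dna(rng, 600) for _ in range(3)]
        clusters = cluster_library(_elements(copies + unrelated))
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 1, 1, 5]

    def test_all_identical_single_cluster(self):
        clusters = cluster_library(_elements(["ACGT" * 100] * 4))
        assert len(clusters) == 1 and clusters[0].size == 4

    def test_pair_below_cutoff_stays_split(self, rng):
        seq = _random_dna(rng, 100)
        mut = _mutate_subs(seq, 11, rng)  # ~89% < 90% threshold
        assert pairwise_identity(seq, mut)[0] < 90.0
        assert pairwise_identity(seq, mut)[0] == pytest.approx(89.0, abs=0.5)
        clusters = cluster_library(
            _elements([seq, mut]), ClusteringParams(prefilter_min_shared=1)
        )
        assert len(clusters) == 2

    def test_partition_invariant(self, rng):
        seqs = [_random_dna(rng, 300) for _ in range(6)]
        base = _random_dna(rng, 300)
        seqs += [_mutate_subs(base, 9, rng) for _ in range(4)]
        elements = _elements(seqs)
        clusters = cluster_library(elements)
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(e.id for e in elements)

    def test_single_linkage_bridging(self, rng):
        """An identical twin of a member never splits its cluster."""
        base = _random_dna(rng, 500)
        copies = [_mutate_subs(base, 25, rng) for _ in range(3)]
        before = cluster_library(_elements(copies))
        after = cluster_library(_elements(copies + [copies[0]]))
        assert len(after) == len(before) == 1

    def test_representative_is_longest(self, rng):
        base = _random_dna(rng, 500)
        longer = base + _random_dna(rng, 10)
        clusters = cluster_library(_elements([base, longer]))
        assert len(clusters) == 1
        assert clusters[0].representative == "s1"


class TestConsensus:
    def test_two_vs_one_majority_recovers_original(self, rng):
        original = _random_dna(rng, 200)
        rows = [original, original, _mutate_subs(original, 20, rng)]
        msa = align_cluster(rows)
        assert majority_consensus(trim_alignment(msa)) == original

    def test_all_but_one_gap_column_trimmed(self):
        msa = ["AC-GT", "AC-GT", "ACAGT"]
        assert trim_alignment(msa) == ["ACGT", "ACGT", "ACGT"]

    def test_all_gap_column_trimmed(self):
        msa = ["AC-T", "AC-T", "AC-T"]
        assert trim_alignment(msa) == ["ACT", "ACT", "ACT"]

    def test_singleton_passthrough(self):
        assert align_cluster(["ACGT"]) == ["ACGT"]
        assert majority_consensus(["ACGT"]) == "ACGT"

    def test_consensus_of_identical_is_identity(self):
        seq = "ACGTTGCA" * 10
        msa = align_cluster([seq] * 5)
        assert majority_consensus(trim_alignment(msa)) == seq

    def test_gap_plurality_column_omitted(self):
        msa = ["A-CT", "A-CT", "AGCT"]
        assert majority_consensus(msa) == "ACT"

    def test_tie_breaks_by_base_order(self):
        msa = ["AC", "AG"]
        # C vs G tie in column 2: C wins by fixed order
        assert majority_consensus(msa) == "AC"

    def test_center_star_handles_indels(self, rng):
        original = _random_dna(rng, 300)
        with_ins = original[:100] + "TTTTT" + original[100:]
        with_del = original[:200] + original[210:]
        msa = align_cluster([original, with_ins, with_del])
        assert len({len(r) for r in msa}) == 1
        assert msa[0].replace("-", "") == original


class TestBuildNonredundant:
    def test_ten_families_three_copies(self, rng):
        originals = [_random_dna(rng, 500) for _ in range(10)]
        seqs = [
            _mutate_subs(orig, 15, rng) for orig in originals for _ in range(3)
        ]
        records, clusters = build_nonredundant(_elements(seqs))
        assert len(records) == 10
        assert all(r.member_count == 3 for r in records)

    def test_no_pair_above_threshold_output_equals_input(self, rng):
        seqs = [_random_dna(rng, 400) for _ in range(5)]
        elements = _elements(seqs)
        records, _ = build_nonredundant(elements)
        assert len(records) == len(elements)
        assert {r.consensus.sequence for r in records} == set(seqs)

    def test_sixfold_inflation_recovers_family_count(self, small_profiles):
        profiles, refs = small_profiles
        lib = generate_library(
            profiles, refs, n_per_lineage=12, mutation_rate=0.03,
            copies_per_family=6, seed=21,
        )
        records, clusters = build_nonredundant(lib.elements)
        n_families = lib.manifest.family_id.nunique()
        assert len(records) == n_families
        assert len(lib.elements) / len(records) == pytest.approx(6.0)

    def test_consensus_metadata_and_tsv(self, small_profiles, tmp_path):
        profiles, refs = small_profiles
        lib = generate_library(
            profiles, refs, n_per_lineage=6, mutation_rate=0.02,
            copies_per_family=3, seed=22,
        )
        records, clusters = build_nonredundant(lib.elements)
        truth = dict(zip(lib.manifest.element_id, lib.manifest.lineage))
        for rec in records:
            assert rec.consensus.lineage == truth[rec.cluster_representative]
        path = tmp_path / "clusters.tsv"
        clusters_to_tsv(clusters, path, provenance="p")
        body = path.read_text().splitlines()
        assert len(body) == 2 + len(lib.elements)
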