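import numpy as np
import pytest
from Bio.Seq import Seq

from ltrkit.curation import (
    Classification,
    ConfigurationError,
    DomainHit,
    FilterReason,
    ReferenceLengths,
    assign_classification,
    apply_filters,
    curate_library,
    read_domain_library,
    scan_domains,
    write_domain_library,
)
from ltrkit.seqmodel import LtrElement
from ltrkit.synthetic_data import back_translate, generate_element


def _hit(domain, lineage, superfamily, eid="e"):
    return DomainHit(
        element_id=eid, domain_class=domain, ref_lineage=lineage,
        ref_superfamily=superfamily, frame=1, identity=90.0,
        aligned_length=60, start=0, end=180,
    )


class TestScanDomains:
    def test_backtranslated_domain_found_forward(self, small_profiles, rng):
        profiles, refs = small_profiles
        rt = next(r for r in refs if r.domain_class == "RT" and r.lineage == "ATHILA")
        pad = "".join(rng.choice(list("ACGT"), size=120))
        el = LtrElement(id="x", sequence=pad + back_translate(rt.peptide) + pad)
        hits = scan_domains(el, refs)
        (hit,) = [h for h in hits if h.domain_class == "RT"]
        assert hit.identity == pytest.approx(100.0)
        assert hit.ref_lineage == "ATHILA"
        assert hit.frame == 1
        assert el.sequence[hit.start : hit.end] == back_translate(rt.peptide)

    def test_reverse_strand_domain_found(self, small_profiles, rng):
        profiles, refs = small_profiles
        rt = next(r for r in refs if r.domain_class == "RT" and r.lineage == "ATHILA")
        pad = "".join(rng.choice(list("ACGT"), size=121))
        forward = pad + back_translate(rt.peptide) + pad
        el = LtrElement(id="x", sequence=str(Seq(forward).reverse_complement()))
        hits = scan_domains(el, refs)
        (hit,) = [h for h in hits if h.domain_class == "RT"]
        assert hit.frame < 0
        assert hit.identity == pytest.approx(100.0)
        # coordinates map back to the insert on the element's forward strand
        rc_domain = str(Seq(back_translate(rt.peptide)).reverse_complement())
        assert el.sequence[hit.start : hit.end] == rc_domain

    def test_random_sequence_no_hits(self, small_profiles, rng):
        _, refs = small_profiles
        el = LtrElement(id="x", sequence="".join(rng.choice(list("ACGT"), size=2000)))
        assert scan_domains(el, refs) == []

    def test_too_short_element_empty_not_error(self, small_profiles):
        _, refs = small_profiles
        el = LtrElement(id="x", sequence="ACGTACGT")
        assert scan_domains(el, refs) == []

    def test_empty_library_rejected(self):
        el = LtrElement(id="x", sequence="ACGT" * 100)
        with pytest.raises(ConfigurationError):
            scan_domains(el, [])

    def test_domain_library_roundtrip(self, small_profiles, tmp_path):
        _, refs = small_profiles
        path = tmp_path / "domains.fasta"
        write_domain_library(refs, path)
        back = read_domain_library(path)
        assert len(back) == len(refs) == 20
        assert {(r.domain_class, r.lineage) for r in back} == {
            (r.domain_class, r.lineage) for r in refs
        }


class TestAssignClassification:
    def test_unanimous(self):
        hits = [_hit(d, "ATHILA", "RLG") for d in ("RT", "INT", "GAG")]
        cls = assign_classification(hits)
        assert (cls.superfamily, cls.lineage) == ("RLG", "ATHILA")
        assert not (cls.chimeric or cls.ambiguous)

    def test_chimeric_flag(self):
        hits = [
            _hit("RT", "ATHILA", "RLG"),
            _hit("INT", "SIRE", "RLC"),
            _hit("GAG", "ATHILA", "RLG"),
        ]
        cls = assign_classification(hits)
        assert cls.chimeric
        assert cls.superfamily == "RLG" and cls.lineage == "ATHILA"

    def test_two_two_tie_is_ambiguous(self):
        hits = [
            _hit("RT", "DEL/TEKAY", "RLG"),
            _hit("RNASEH", "DEL/TEKAY", "RLG"),
            _hit("AP", "REINA", "RLG"),
            _hit("INT", "REINA", "RLG"),
        ]
        cls = assign_classification(hits)
        assert cls.ambiguous and not cls.chimeric

    def test_strict_majority_with_dissent_not_ambiguous(self):
        hits = [
            _hit("RT", "ATHILA", "RLG"),
            _hit("INT", "ATHILA", "RLG"),
            _hit("GAG", "ATHILA", "RLG"),
            _hit("AP", "REINA", "RLG"),
        ]
        cls = assign_classification(hits)
        assert not cls.ambiguous and cls.mixed_lineage
        assert cls.lineage == "ATHILA"

    def test_empty_hits_unknown(self):
        cls = assign_classification([])
        assert cls.superfamily == "UNKNOWN" and cls.lineage == "UNKNOWN"


class TestApplyFilters:
    @pytest.fixture
    def ref_lengths(self):
        return ReferenceLengths(lengths={"ATHILA": 8000, "SIRE": 10000})

    def _element(self, length=8000):
        return LtrElement(id="x", sequence="ACGT" * (length // 4))

    def _classification(self, lineage="ATHILA", superfamily="RLG", **flags):
        return Classification(superfamily, lineage, ((lineage, 3),), **flags)

    def test_two_domains_fails_f4(self, ref_lengths):
        hits = [_hit("RT", "ATHILA", "RLG"), _hit("GAG", "ATHILA", "RLG")]
        decision = apply_filters(
            self._element(), self._classification(), hits, ref_lengths
        )
        assert decision.reason == FilterReason.F4_FEW_DOMAINS

    @pytest.mark.parametrize(
        "factor,expected",
        [(1.25, FilterReason.F3_LENGTH), (1.19, FilterReason.PASS),
         (0.79, FilterReason.F3_LENGTH), (0.81, FilterReason.PASS)],
    )
    def test_length_tolerance_boundary(self, ref_lengths, factor, expected):
        hits = [_hit(d, "ATHILA", "RLG") for d in ("RT", "INT", "GAG")]
        el = self._element(length=int(8000 * factor))
        decision = apply_filters(el, self._classification(), hits, ref_lengths)
        assert decision.reason == expected

    def test_filter_order_chimeric_wins(self, ref_lengths):
        # chimeric AND too short AND too few domains: F1 reported
        hits = [_hit("RT", "ATHILA", "RLG"), _hit("INT", "SIRE", "RLC")]
        cls = self._classification(chimeric=True)
        decision = apply_filters(self._element(400), cls, hits, ref_lengths)
        assert decision.reason == FilterReason.F1_CHIMERIC_SUPERFAMILY

    def test_missing_reference_length_is_config_error(self, ref_lengths):
        hits = [_hit(d, "REINA", "RLG") for d in ("RT", "INT", "GAG")]
        with pytest.raises(ConfigurationError, match="REINA"):
            apply_filters(
                self._element(), self._classification("REINA"), hits, ref_lengths
            )

    def test_kept_iff_pass(self):
        from ltrkit.curation import FilterDecision

        with pytest.raises(ValueError):
            FilterDecision("x", True, FilterReason.F3_LENGTH)


class TestReferenceLengths:
    def test_tolerance_bounds(self):
        with pytest.raises(ValueError):
            ReferenceLengths(lengths={"ATHILA": 100}, tolerance=1.5)

    def test_tsv_roundtrip(self, tmp_path):
        rl = ReferenceLengths(lengths={"ATHILA": 8000, "SIRE": 10000})
        path = tmp_path / "ref.tsv"
        rl.to_tsv(path)
        back = ReferenceLengths.from_tsv(path)
        assert back.lengths == rl.lengths


class TestCurateLibrary:
    def test_filter_fixture_exact_pass_count(self, filter_fixture):
        lib = filter_fixture
        kept, report = curate_library(
            lib.elements, lib.domain_refs, lib.reference_lengths, lib.class2_library
        )
        assert len(kept) == 7
        expected_reason = {
            "CHIMERIC": FilterReason.F1_CHIMERIC_SUPERFAMILY,
            "MULTI_LINEAGE": FilterReason.F2_MULTI_LINEAGE,
            "SHORT": FilterReason.F3_LENGTH,
            "LONG": FilterReason.F3_LENGTH,
            "FEW_DOMAINS": FilterReason.F4_FEW_DOMAINS,
            "CLASS2_NESTED": FilterReason.F5_CLASS2_INSERTION,
        }
        truth = dict(zip(lib.manifest.element_id, lib.manifest.defect))
        for decision in report.decisions:
            defect = truth[decision.element_id]
            if defect == "NONE":
                assert decision.kept
            else:
                assert decision.reason == expected_reason[defect]

    def test_kept_elements_carry_true_labels(self, filter_fixture):
        lib = filter_fixture
        kept, _ = curate_library(
            lib.elements, lib.domain_refs, lib.reference_lengths, lib.class2_library
        )
        truth = dict(zip(lib.manifest.element_id, lib.manifest.lineage))
        for el in kept:
            assert el.lineage == truth[el.id]
            assert el.superfamily in ("RLC", "RLG")

    def test_empty_library_warns_and_returns_empty(self, small_profiles, caplog):
        _, refs = small_profiles
        kept, report = curate_library(
            [], refs, ReferenceLengths(lengths={"ATHILA": 8000})
        )
        assert kept == [] and report.decisions == []

    def test_idempotent_on_kept_set(self, filter_fixture):
        lib = filter_fixture
        kept, _ = curate_library(
            lib.elements, lib.domain_refs, lib.reference_lengths, lib.class2_library
        )
        kept2, report2 = curate_library(
            kept, lib.domain_refs, lib.reference_lengths, lib.class2_library
        )
        assert [e.id for e in kept2] == [e.id for e in kept]
        assert all(d.kept for d in report2.decisions)

    def test_report_tsv(self, filter_fixture, tmp_path):
        lib = filter_fixture
        _, report = curate_library(
            lib.elements, lib.domain_refs, lib.reference_lengths, lib.class2_library
        )
        path = tmp_path / "report.tsv"
        report.to_tsv(path, provenance="test run")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#") and len(lines) == 2 + len(lib.elements)
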