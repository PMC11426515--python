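"""De novo SNM candidate identification, filter criteria, callable-genome
accounting and the pedigree-aware rate correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import musema as m
from musema.pedigree import FEMALE, MALE, IndividualRecord, Pedigree
from musema.snm import CandidateVariant, SampleEvidence


def _candidate(qual=100.0, depths=None, carrier_gt="het", carrier_alt=None,
               impurities=(0, 0, 0, 0), chrom="chr1", n_alleles=2,
               in_phase=False, xc=0):
    line = [f"line{i}" for i in range(1, 6)]
    founders = ("founder_m", "founder_f")
    depths = depths or {}
    samples = {}
    for s in (*founders, *line):
        d = depths.get(s, 30)
        samples[s] = SampleEvidence(depth=d, genotype="hom_ref", alt_reads=0)
    carrier = "line1"
    d = depths.get(carrier, 30)
    alt = carrier_alt if carrier_alt is not None else d // 2
    samples[carrier] = SampleEvidence(depth=d, genotype=carrier_gt,
                                      alt_reads=alt)
    for s, imp in zip(line[1:], impurities):
        samples[s] = SampleEvidence(depth=depths.get(s, 30),
                                    genotype="hom_ref", alt_reads=imp)
    return CandidateVariant(
        chrom=chrom, pos=1000, ref="A", alt="T", qual=qual, carrier=carrier,
        samples=samples, line_samples=tuple(line), founder_samples=founders,
        n_alleles=n_alleles, in_phase=in_phase, cross_chrom_mate_reads=xc)


def test_quality_threshold_strict():
    c = _candidate(qual=29.9)
    assert m.apply_site_filters(c) == [1]
    c = _candidate(qual=30.0)
    assert m.apply_site_filters(c) == []


def test_depth_window_closed_open():
    assert m.apply_site_filters(_candidate(depths={"line3": 9})) == [2]
    assert m.apply_site_filters(_candidate(depths={"line3": 10})) == []
    assert m.apply_site_filters(_candidate(depths={"founder_m": 60})) == [3]
    c = _candidate(depths={"founder_m": 59})
    assert m.apply_site_filters(c) == []


def test_allele_balance_inclusive_bounds():
    c = _candidate(depths={"line1": 20}, carrier_alt=5)   # 0.25 exactly
    assert m.apply_site_filters(c) == []
    c = _candidate(depths={"line1": 20}, carrier_alt=15)  # 0.75 exactly
    assert m.apply_site_filters(c) == []
    c = _candidate(depths={"line1": 20}, carrier_alt=4)
    assert m.apply_site_filters(c) == [4]
    # homozygous calls are exempt
    c = _candidate(carrier_gt="hom_alt", carrier_alt=30)
    assert m.apply_site_filters(c) == []


def test_impurity_threshold():
    c = _candidate(impurities=(10, 10, 6, 0))   # 26 > 25
    assert m.apply_site_filters(c) == [5]
    c = _candidate(impurities=(10, 10, 5, 0))   # 25 allowed
    assert m.apply_site_filters(c) == []


def test_all_failed_criteria_recorded_not_just_first():
    c = _candidate(qual=10.0, depths={"line2": 5}, impurities=(30, 0, 0, 0))
    failed = m.apply_site_filters(c)
    assert set(failed) == {1, 2, 5}
    assert set(c.failed_criteria) == {1, 2, 5}


def test_missing_evidence_flags_incomplete():
    c = _candidate()
    c.samples["line4"].depth = None
    m.apply_site_filters(c)
    assert c.incomplete_evidence and not c.passed


def test_paralog_criteria():
    assert m.apply_paralog_filters(_candidate(in_phase=True)) == [6]
    assert m.apply_paralog_filters(_candidate(chrom="X")) == [7]
    hom = _candidate(chrom="X", carrier_gt="hom_alt", carrier_alt=30)
    assert m.apply_paralog_filters(hom) == []
    assert m.apply_paralog_filters(_candidate(n_alleles=3)) == [8]
    assert m.apply_paralog_filters(_candidate(xc=2)) == [9]
    assert m.apply_paralog_filters(_candidate(xc=1)) == []


def test_filters_order_independent():
    c1 = _candidate(qual=10.0, in_phase=True, xc=5)
    m.apply_site_filters(c1)
    m.apply_paralog_filters(c1)
    c2 = _candidate(qual=10.0, in_phase=True, xc=5)
    m.apply_paralog_filters(c2)
    m.apply_site_filters(c2)
    assert set(c1.failed_criteria) == set(c2.failed_criteria)


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------

def test_impurity_search_all_clean_true_positives():
    assert m.impurity_threshold_search([(0, True), (0, True),
                                        (50, False)]) == 0


def test_impurity_search_brute_force_case():
    cands = [(0, True), (3, True), (12, True), (25, True),
             (40, False), (44, False), (60, False)]
    got = m.impurity_threshold_search(cands)
    # brute force: smallest threshold including every true positive
    tps = sorted(i for i, t in cands if t)
    brute = min(t for t in range(0, 61)
                if sum(1 for i in tps if i <= t) == len(tps))
    assert got == brute == 25


@given(st.lists(st.tuples(st.integers(0, 80), st.booleans()), min_size=1,
                max_size=30),
       st.integers(0, 80))
@settings(derandomize=True, max_examples=50)
def test_impurity_search_properties(cands, extra_tp):
    """The returned threshold admits every true positive, is minimal, and
    never decreases when a higher-impurity true positive is added."""
    t = m.impurity_threshold_search(cands)
    tps = [i for i, truth in cands if truth]
    assert all(i <= t for i in tps)
    assert t == (max(tps) if tps else 0)
    t2 = m.impurity_threshold_search(cands + [(extra_tp, True)])
    assert t2 >= t


def test_impurity_search_empty_errors():
    with pytest.raises(ValueError):
        m.impurity_threshold_search([])


# ---------------------------------------------------------------------------
# VCF stream, verdicts against planted truth, callable genome
# ---------------------------------------------------------------------------

def test_candidates_match_planted_truth(vcf_fixture):
    path, sequenced, truth = vcf_fixture
    counters = {}
    cands = {(c.chrom, c.pos): c
             for c in m.identify_candidates(path, ["founder_m", "founder_f"],
                                            sequenced, counters)}
    expected = truth[truth["is_candidate"]]
    assert set(cands) == set(zip(expected["chrom"], expected["pos"]))
    # shared and founder variants never surface
    for row in truth[~truth["is_candidate"]].itertuples():
        assert (row.chrom, row.pos) not in cands


def test_verdicts_match_planted_truth(vcf_fixture):
    path, sequenced, truth = vcf_fixture
    cands = list(m.identify_candidates(path, ["founder_m", "founder_f"],
                                       sequenced))
    tmap = {(r.chrom, r.pos): r for r in truth.itertuples()}
    for c in cands:
        m.apply_site_filters(c)
        m.apply_paralog_filters(c)
        t = tmap[(c.chrom, c.pos)]
        if t.is_true_mutation:
            assert c.passed, (t, c.failed_criteria)
        else:
            assert t.expected_criterion in c.failed_criteria


def test_missing_sample_errors(vcf_fixture):
    path, sequenced, _ = vcf_fixture
    with pytest.raises(KeyError):
        list(m.identify_candidates(path, ["founder_m", "nope"], sequenced))


def test_callable_counts_and_y_exclusion(vcf_fixture):
    path, sequenced, truth = vcf_fixture
    mask = m.callable_sites(path)
    assert "Y" not in mask.per_chrom and "chrY" not in mask.per_chrom
    only1 = m.callable_sites(path, included_chroms={"chr1"})
    # hand count: 80 passing invariant records plus the chr1 variant
    # records whose QUAL and depths meet criteria 1-3
    from cyvcf2 import VCF
    n = 0
    for v in VCF(path):
        if v.CHROM != "chr1":
            continue
        if v.QUAL is None or v.QUAL < 30:
            continue
        d = v.gt_depths
        if (d < 10).any() or (d >= 60).any():
            continue
        n += 1
    assert only1.total == n
    assert mask.total >= only1.total


def test_empty_stream_counts_zero(tmp_path):
    p = tmp_path / "empty.vcf"
    p.write_text("##fileformat=VCFv4.2\n"
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n")
    assert m.callable_sites(str(p)).total == 0


# ---------------------------------------------------------------------------
# Gene-dropping correction
# ---------------------------------------------------------------------------

def _toy_lines(n_lines=5, depth=2):
    recs = [IndividualRecord("fm", sex=MALE, generation=0),
            IndividualRecord("ff", sex=FEMALE, generation=0)]
    seq = []
    for k in range(1, n_lines + 1):
        prev = ("fm", "ff")
        for g in range(1, depth + 1):
            mrec = IndividualRecord(f"m{k}g{g}", prev[0], prev[1], MALE,
                                    line_id=f"L{k}", generation=g)
            frec = IndividualRecord(f"f{k}g{g}", prev[0], prev[1], FEMALE,
                                    line_id=f"L{k}", generation=g)
            recs.extend([mrec, frec])
            prev = (mrec.id, frec.id)
        seq.append(prev[0])
    return Pedigree(recs), seq


def test_self_sequenced_origin_always_detected():
    ped = Pedigree([IndividualRecord("only", sex=MALE, generation=0)])
    est = m.gene_drop_correction(ped, ["only"], n_iter=1000, seed=1)
    assert est.correction_factor == 1.0
    ex = m.enumerate_correction(ped, ["only"])
    assert ex.correction_factor == 1.0


def test_shared_ancestor_mutations_count_undetected():
    """Founder-origin mutations reaching two sequenced lines are shared,
    hence undetected under the uniqueness rule."""
    ped, seq = _toy_lines(3, 1)
    ex = m.enumerate_correction(ped, seq, eligible=["fm"])
    assert ex.p_shared > 0
    assert ex.p_detected + ex.p_lost + ex.p_shared == pytest.approx(1.0)


def test_monte_carlo_matches_enumeration_within_one_percent():
    ped, seq = _toy_lines(5, 2)
    ex = m.enumerate_correction(ped, seq)
    mc = m.gene_drop_correction(ped, seq, n_iter=300_000, seed=7)
    assert mc.correction_factor == pytest.approx(ex.correction_factor,
                                                 rel=0.01)


def test_correction_requires_sequenced():
    ped, _ = _toy_lines(2, 1)
    with pytest.raises(ValueError):
        m.gene_drop_correction(ped, [], n_iter=10, seed=0)


# ---------------------------------------------------------------------------
# Rate arithmetic
# ---------------------------------------------------------------------------

def test_rate_worked_example():
    r = m.mutation_rate(10, 10**6, 5, 2)
    assert r.raw_rate == pytest.approx(5e-7, rel=1e-12)
    assert r.corrected_rate == r.raw_rate


def test_rate_homogeneity():
    base = m.mutation_rate(10, 10**6, 5, 2).raw_rate
    assert m.mutation_rate(10, 2 * 10**6, 5, 2).raw_rate == \
        pytest.approx(base / 2)
    assert m.mutation_rate(10, 10**6, 10, 2).raw_rate == \
        pytest.approx(base / 2)
    assert m.mutation_rate(10, 10**6, 5, 4).raw_rate == \
        pytest.approx(base / 2)


def test_rate_correction_applies():
    r = m.mutation_rate(10, 10**6, 5, 2, correction_factor=1.5)
    assert r.corrected_rate == pytest.approx(1.5 * r.raw_rate)


def test_rate_input_validation():
    with pytest.raises(ValueError):
        m.mutation_rate(10, 0, 5, 2)
    with pytest.raises(ValueError):
        m.mutation_rate(10, 100, 5, 2, correction_factor=0.5)
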