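import numpy as np
import pytest
from scipy import stats

from _oracles import oracle_p_more_than_two_distinct
from ampliclone.errors import ConfigurationError, SimulationError
from ampliclone.simulate import (
    HDR,
    NHEJ,
    WT,
    CloneTruth,
    EditModel,
    ErrorModel,
    GrowthModel,
    allele_sequence,
    child_rng,
    draw_allele_outcome,
    make_barcodes,
    parse_provenance,
    simulate_clone,
    simulate_dataset,
    simulate_exports,
    simulate_pens,
    simulate_reads,
)
from ampliclone.references import revcomp

DEL2 = {-2: 1.0}
ZERO_ERR = ErrorModel(sub_rate=0.0, seq_indel_rate=0.0, depth=50)


class TestEditModelValidation:
    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            EditModel(p_hdr=1.2)
        with pytest.raises(ConfigurationError):
            EditModel(p_hdr=0.7, p_nhej=0.5)

    def test_indel_dist_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            EditModel(indel_length_dist={-2: 0.5})

    def test_indel_dist_no_zero_mass(self):
        with pytest.raises(ConfigurationError):
            EditModel(indel_length_dist={0: 0.5, -2: 0.5})

    def test_default_dist_is_valid(self):
        model = EditModel()
        assert abs(sum(model.indel_length_dist.values()) - 1.0) < 1e-12
        assert 0 not in model.indel_length_dist


class TestDrawAlleleOutcome:
    def test_forced_hdr(self, refs):
        model = EditModel(p_hdr=1.0, p_nhej=0.0)
        for seed in range(20):
            allele = draw_allele_outcome(model, refs, seed)
            assert allele.class_ == HDR
            assert allele.signature == ""

    def test_forced_wt(self, refs):
        model = EditModel(p_hdr=0.0, p_nhej=0.0)
        for seed in range(20):
            allele = draw_allele_outcome(model, refs, seed)
            assert allele.class_ == WT
            assert allele.signature == ""

    def test_forced_two_bp_deletion(self, refs):
        # point mass at -2: always a 2-bp deletion at the cut site
        model = EditModel(p_hdr=0.0, p_nhej=1.0, indel_length_dist=DEL2, p_point_nhej=0.0)
        for seed in range(20):
            allele = draw_allele_outcome(model, refs, seed)
            assert allele.class_ == NHEJ
            (v,) = allele.variants
            assert v.kind == "DEL" and len(v.ref_allele) == 2
            # left-normalized placement never sits right of the cut site
            assert v.ref_pos <= refs.cut_site

    def test_hdr_frequency_matches_probability(self, refs):
        # >= 10,000 draws within 3 SE of p_hdr
        p = 0.3
        model = EditModel(p_hdr=p, p_nhej=0.4)
        rng = np.random.default_rng(123)
        n = 10_000
        hits = sum(draw_allele_outcome(model, refs, rng).class_ == HDR for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestSimulateClone:
    def test_forced_biallelic_hdr_merges(self, refs):
        model = EditModel(p_hdr=1.0, p_nhej=0.0, p_late_edit=0.0)
        truth = simulate_clone(model, refs, 5, "c1")
        assert len(truth.alleles) == 1
        assert truth.alleles[0].class_ == HDR
        assert truth.alleles[0].fraction == 1.0

    def test_no_late_edit_fractions(self, refs):
        model = EditModel(p_hdr=0.4, p_nhej=0.4, p_late_edit=0.0)
        for seed in range(50):
            truth = simulate_clone(model, refs, seed)
            assert all(a.fraction in (0.5, 1.0) for a in truth.alleles)
            assert abs(sum(a.fraction for a in truth.alleles) - 1.0) < 1e-12

    def test_late_edit_quarter_fractions(self, refs):
        model = EditModel(p_hdr=0.4, p_nhej=0.4, p_late_edit=1.0)
        for seed in range(50):
            truth = simulate_clone(model, refs, seed)
            for a in truth.alleles:
                assert abs(a.fraction / 0.25 - round(a.fraction / 0.25)) < 1e-12

    def test_multiallelic_rate_matches_enumeration(self, refs):
        # deletion-only NHEJ so the outcome space is finite and enumerable
        model = EditModel(
            p_hdr=0.3,
            p_nhej=0.5,
            indel_length_dist={-2: 0.5, -3: 0.5},
            p_point_nhej=0.0,
            p_late_edit=1.0,
        )
        outcomes = {"WT": 0.2, "HDR": 0.3, "DEL2": 0.25, "DEL3": 0.25}
        expected = oracle_p_more_than_two_distinct(outcomes, n_draws=4)
        n = 10_000
        rng = np.random.default_rng(2024)
        hits = sum(len(simulate_clone(model, refs, rng).alleles) > 2 for _ in range(n))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se


class TestSimulateReads:
    def test_zero_error_wt_reads_are_substrings(self, refs):
        truth = CloneTruth("c", simulate_clone(EditModel(p_hdr=0, p_nhej=0), refs, 0).alleles)
        pairs = simulate_reads(truth, refs, ZERO_ERR, "ACGTACGT", 1)
        assert len(pairs) == ZERO_ERR.depth
        for p in pairs:
            assert p.r1.seq.startswith("ACGTACGT")
            assert p.r1.seq[8:] in refs.wt_seq
            assert revcomp(p.r2.seq) in refs.wt_seq

    def test_hdr_wt_mixture_binomial(self, refs):
        from ampliclone.simulate import AlleleLineage

        mixed = CloneTruth(
            "mix",
            (
                AlleleLineage(HDR, "", (), 0.5),
                AlleleLineage(WT, "", (), 0.5),
            ),
        )
        err = ErrorModel(sub_rate=0.0, seq_indel_rate=0.0, depth=100)
        total = 0
        hdr_reads = 0
        for seed in range(50):
            pairs = simulate_reads(mixed, refs, err, "ACGTACGT", seed)
            total += len(pairs)
            hdr_reads += sum(p.allele_class == HDR for p in pairs)
        lo, hi = stats.binom.interval(0.99, total, 0.5)
        assert lo <= hdr_reads <= hi

    def test_no_contamination_provenance(self, refs):
        truth = simulate_clone(EditModel(), refs, 9, "c9")
        pairs = simulate_reads(truth, refs, ZERO_ERR, "ACGTACGT", 2)
        assert all(not p.is_contaminant and p.source_clone == "c9" for p in pairs)

    def test_contaminant_reads_tagged(self, refs):
        t1 = simulate_clone(EditModel(p_hdr=1, p_nhej=0), refs, 1, "own")
        t2 = simulate_clone(EditModel(p_hdr=0, p_nhej=0), refs, 2, "other")
        pairs = simulate_reads(
            t1, refs, ZERO_ERR, "ACGTACGT", 3, contaminant=t2, contaminant_fraction=0.3
        )
        contams = [p for p in pairs if p.is_contaminant]
        assert 0 < len(contams) < len(pairs)
        assert all(p.source_clone == "other" for p in contams)
        prov = parse_provenance(pairs[0].r1.description)
        assert set(prov) == {"src", "allele", "class", "contam"}

    def test_short_barcode_rejected(self, refs):
        truth = simulate_clone(EditModel(), refs, 0)
        with pytest.raises(SimulationError):
            simulate_reads(truth, refs, ZERO_ERR, "ACGT", 0)

    def test_deterministic_given_seed(self, refs):
        truth = simulate_clone(EditModel(p_late_edit=0.5), refs, 4, "d")
        err = ErrorModel(sub_rate=0.01, seq_indel_rate=0.001, depth=30)
        a = simulate_reads(truth, refs, err, "ACGTACGT", 77)
        b = simulate_reads(truth, refs, err, "ACGTACGT", 77)
        assert a == b

    def test_errored_bases_get_low_quality(self, refs):
        truth = simulate_clone(EditModel(p_hdr=0, p_nhej=0), refs, 0, "c")
        err = ErrorModel(sub_rate=0.05, seq_indel_rate=0.0, depth=20)
        pairs = simulate_reads(truth, refs, err, "ACGTACGT", 5)
        mismatch_quals = []
        for p in pairs:
            frag = p.r1.seq[8:]
            quals = p.r1.quals[8:]
            for i, (got, exp) in enumerate(zip(frag, refs.wt_seq)):
                if got != exp:
                    mismatch_quals.append(quals[i])
        assert mismatch_quals and all(q == err.q_error for q in mismatch_quals)


class TestSimulatePens:
    def test_exponential_doubling_counts(self):
        growth = GrowthModel(doubling_time_h=24.0, p_no_growth=0.0, p_contam_pen=0.0)
        pens = simulate_pens(growth, 10, 1.0, 0)
        for p in pens:
            assert [p.counts[t] for t in (0, 24, 48, 72)] == [1, 2, 4, 8]

    def test_no_growth_means_zero_occe(self):
        from ampliclone.chip import occe

        growth = GrowthModel(p_no_growth=1.0)
        pens = simulate_pens(growth, 50, 1.0, 1)
        assert occe(pens) == 0.0

    def test_empty_pen_contamination_binomial(self):
        from ampliclone.chip import contamination_rate

        growth = GrowthModel(p_contam_pen=0.02)
        pens = simulate_pens(growth, 10_000, 0.0, 3)
        gained = round(contamination_rate(pens) * 10_000)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.02)
        assert lo <= gained <= hi


class TestDatasetAssembly:
    def test_barcodes_well_separated(self):
        bcs = make_barcodes(30, 0, length=8, min_dist=3)
        assert len(set(bcs)) == 30
        for i, a in enumerate(bcs):
            for b in bcs[i + 1:]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_dataset_deterministic(self, refs):
        edit = EditModel(p_late_edit=0.2, contamination_rate=0.3)
        err = ErrorModel(sub_rate=0.002, depth=10)
        d1 = simulate_dataset(refs, edit, err, 5, master_seed=11)
        d2 = simulate_dataset(refs, edit, err, 5, master_seed=11)
        assert d1 == d2

    def test_contaminated_clones_flagged(self, refs):
        edit = EditModel(contamination_rate=1.0, contaminant_fraction=0.2)
        err = ErrorModel(sub_rate=0.0, seq_indel_rate=0.0, depth=20)
        data = simulate_dataset(refs, edit, err, 4, master_seed=5)
        assert all(t.contaminated for t in data.truths)
        for truth in data.truths:
            own = [p for p in data.pairs if p.r1.id.startswith(truth.clone_id + "_")]
            assert any(p.is_contaminant for p in own)

    def test_child_rng_stable(self):
        a = child_rng(42, "clone:3").random(4)
        b = child_rng(42, "clone:3").random(4)
        assert np.allclose(a, b)
        c = child_rng(42, "clone:4").random(4)
        assert not np.allclose(a, c)


class TestSimulateExports:
    def test_flat_survival_calibration(self):
        recs = simulate_exports(2000, 0, p_export_fail=0.0, survival_prob=0.6)
        ok = [r for r in recs if r.exported_ok]
        surv = sum(r.survived for r in ok)
        lo, hi = stats.binom.interval(0.99, len(ok), 0.6)
        assert lo <= surv <= hi

    def test_survived_implies_exported_ok(self):
        recs = simulate_exports(500, 1)
        assert all(r.exported_ok or not r.survived for r in recs)
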