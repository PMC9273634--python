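import numpy as np
import pytest
from Bio.Seq import Seq

from cleftdnm.dnm_discovery import (
    FUNNEL_STAGES,
    Annotation,
    FilterConfig,
    FilterFunnel,
    annotate_variant,
    call_consequence,
    discover_dnms,
    impact_class,
    is_denovo,
    max_panel_maf,
    passes_quality,
    _translate_codon,
)
from cleftdnm.errors import ValidationError
from cleftdnm.models import FrequencyPanel, GenotypeCall, TranscriptModel, VariantSite


def G(code, gq=99, dp=30):
    return GenotypeCall.from_code(code, gq, dp)


class TestPassesQuality:
    def test_high_quality_true(self):
        assert passes_quality(G(0, 99, 30), G(0, 99, 30), G(1, 99, 30))

    def test_child_gq_19_fails(self):
        assert not passes_quality(G(0), G(0), G(1, gq=19))

    def test_dp_10_inclusive(self):
        assert passes_quality(G(0, dp=10), G(0), G(1))

    def test_gq_20_inclusive(self):
        assert passes_quality(G(0, gq=20), G(0), G(1))

    def test_missing_member_fails(self):
        assert not passes_quality(G(-1), G(0), G(1))


class TestIsDenovo:
    def test_canonical_config(self):
        assert is_denovo(G(0), G(0), G(1))

    def test_inherited_false(self):
        assert not is_denovo(G(1), G(0), G(1))

    def test_autosomal_double_hit_rejected_by_default(self):
        assert not is_denovo(G(0), G(0), G(2), chrom="1")
        assert is_denovo(G(0), G(0), G(2), chrom="1", config=FilterConfig(require_child_het=False))

    def test_male_x_hemizygous_alt_accepted(self):
        assert is_denovo(G(0), G(0), G(2), child_sex="male", chrom="X")
        assert not is_denovo(G(0), G(0), G(1), child_sex="male", chrom="X")

    def test_female_x_het_accepted(self):
        assert is_denovo(G(0), G(0), G(1), child_sex="female", chrom="X")


class TestMaxPanelMaf:
    def make_panels(self, freqs):
        panels = []
        for i, f in enumerate(freqs):
            p = FrequencyPanel(f"p{i}")
            if f is not None:
                p.add(VariantSite("1", 100, "A", "G"), f)
            panels.append(p)
        return panels

    def test_absent_everywhere_is_zero(self):
        site = VariantSite("1", 100, "A", "G")
        assert max_panel_maf(site, self.make_panels([None, None])) == 0.0

    def test_max_across_panels(self):
        site = VariantSite("1", 100, "A", "G")
        assert max_panel_maf(site, self.make_panels([0.005, 0.02])) == 0.02

    def test_exactly_one_percent_passes_inclusive(self):
        site = VariantSite("1", 100, "A", "G")
        maf = max_panel_maf(site, self.make_panels([0.01]))
        assert not maf > FilterConfig().max_maf

    def test_no_panels_is_error(self):
        with pytest.raises(ValidationError):
            max_panel_maf(VariantSite("1", 100, "A", "G"), [])


class TestImpactClass:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("stop_gained", "protein_truncating"),
            ("start_lost", "protein_truncating"),
            ("splice_donor_variant", "protein_truncating"),
            ("splice_acceptor_variant", "protein_truncating"),
            ("frameshift_variant", "protein_truncating"),
            ("missense_variant", "missense"),
            ("synonymous_variant", "other"),
            ("intron_variant", "other"),
            ("other", "other"),
        ],
    )
    def test_mapping(self, term, expected):
        assert impact_class(term) == expected

    def test_unknown_term_errors(self):
        with pytest.raises(ValidationError):
            impact_class("upstream_gene_variant")


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------


class TestCallConsequence:
    def test_stop_gained_deep_exon_fixture(self, resources, transcripts_by_gene):
        # CGA -> TGA at codon 4738 of the 50-exon transcript
        tx = transcripts_by_gene["TTN"]
        assert len(tx.exons) >= 40
        gpos = tx.transcript_to_genomic(tx.cds_start + 3 * 4737)
        site = VariantSite(tx.chrom, gpos, resources.reference[tx.chrom][gpos - 1], "T")
        ann = call_consequence(site, tx, resources.reference)
        assert ann.consequence == "stop_gained"
        assert ann.protein_change == "p.Arg4738Ter"
        assert impact_class(ann.consequence) == "protein_truncating"

    def test_missense_ser37leu_reverse_strand(self, resources, transcripts_by_gene):
        # TCG -> TTG at codon 37; the transcript is on the minus strand so the
        # genomic alternate allele is the complement of the coding T
        tx = transcripts_by_gene["DHRS3"]
        assert tx.strand == "-"
        gpos = tx.transcript_to_genomic(tx.cds_start + 3 * 36 + 1)
        site = VariantSite(tx.chrom, gpos, resources.reference[tx.chrom][gpos - 1], "A")
        ann = call_consequence(site, tx, resources.reference)
        assert ann.consequence == "missense_variant"
        assert ann.protein_change == "p.Ser37Leu"

    def test_canonical_splice_donor(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        donor_pos = tx.exons[0][1] + 1  # +1 intronic base after the first exon
        ref = resources.reference[tx.chrom][donor_pos - 1]
        alt = "A" if ref != "A" else "C"
        ann = call_consequence(VariantSite(tx.chrom, donor_pos, ref, alt), tx, resources.reference)
        assert ann.consequence == "splice_donor_variant"

    def test_deep_intron_is_intron_variant(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        pos = tx.exons[0][1] + 50
        ref = resources.reference[tx.chrom][pos - 1]
        alt = "A" if ref != "A" else "C"
        ann = call_consequence(VariantSite(tx.chrom, pos, ref, alt), tx, resources.reference)
        assert ann.consequence == "intron_variant"

    def test_start_lost(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        gpos = tx.transcript_to_genomic(tx.cds_start)  # the A of ATG
        ref = resources.reference[tx.chrom][gpos - 1]
        assert ref == "A"  # plus strand
        ann = call_consequence(VariantSite(tx.chrom, gpos, ref, "G"), tx, resources.reference)
        assert ann.consequence == "start_lost"
        assert impact_class("start_lost") == "protein_truncating"

    def test_synonymous(self, resources, transcripts_by_gene):
        # find a codon where a third-position change is silent
        tx = transcripts_by_gene["TTN"]
        cds = tx.cds_sequence(resources.reference)
        for ci in range(1, 200):
            codon = cds[3 * ci : 3 * ci + 3]
            for base in "ACGT":
                if base == codon[2]:
                    continue
                if _translate_codon(codon[:2] + base) == _translate_codon(codon):
                    gpos = tx.transcript_to_genomic(tx.cds_start + 3 * ci + 2)
                    site = VariantSite(tx.chrom, gpos, resources.reference[tx.chrom][gpos - 1], base)
                    ann = call_consequence(site, tx, resources.reference)
                    assert ann.consequence == "synonymous_variant"
                    return
        pytest.fail("no synonymous change found in 200 codons")

    def test_intergenic_is_other_never_raises(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        pos = 55_000
        ref = resources.reference[tx.chrom][pos - 1]
        alt = "A" if ref != "A" else "C"
        ann = call_consequence(VariantSite(tx.chrom, pos, ref, alt), tx, resources.reference)
        assert ann.consequence == "other" and ann.gene is None

    def test_frameshift_deletion(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        # middle of exon 2, safely inside CDS
        start, end = tx.exons[1]
        gpos = (start + end) // 2
        ref2 = resources.reference[tx.chrom][gpos - 1 : gpos + 1]
        ann = call_consequence(VariantSite(tx.chrom, gpos, ref2, ref2[0]), tx, resources.reference)
        assert ann.consequence == "frameshift_variant"
        assert ann.protein_change.endswith("fs")

    def test_inframe_deletion_is_other(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        start, end = tx.exons[1]
        gpos = (start + end) // 2
        ref4 = resources.reference[tx.chrom][gpos - 1 : gpos + 3]
        ann = call_consequence(VariantSite(tx.chrom, gpos, ref4, ref4[0]), tx, resources.reference)
        assert ann.consequence == "other"

    def test_reference_mismatch_raises(self, resources, transcripts_by_gene):
        tx = transcripts_by_gene["TTN"]
        gpos = tx.transcript_to_genomic(tx.cds_start + 30)
        ref = resources.reference[tx.chrom][gpos - 1]
        wrong = "A" if ref != "A" else "C"
        other = next(b for b in "ACGT" if b not in (ref, wrong))
        with pytest.raises(ValidationError, match="mismatch"):
            call_consequence(VariantSite(tx.chrom, gpos, wrong, other), tx, resources.reference)


class TestTranslationRoundTrip:
    def test_cds_translation_matches_biopython(self, resources):
        # dual route: the caller's per-codon table vs Bio.Seq full translation
        for tx in resources.transcripts:
            cds = tx.cds_sequence(resources.reference)
            ours = "".join(_translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))
            theirs = str(Seq(cds).translate())
            assert ours == theirs
            assert ours.startswith("M")

    def test_strand_symmetry(self):
        # a transcript and its mirror image on the reverse-complemented contig
        # must yield identical consequences and protein changes
        rng = np.random.default_rng(17)
        utr5, utr3 = 12, 9
        cds = "ATG" + "".join(
            rng.choice(["GCT", "TCG", "CGA", "AAA", "CTT", "GGA"], size=30)
        ) + "TAA"
        tx_seq = (
            "".join(rng.choice(list("ACGT"), size=utr5))
            + cds
            + "".join(rng.choice(list("ACGT"), size=utr3))
        )
        # forward layout: two exons with a 100 bp intron
        L = len(tx_seq)
        exon1_len = 40
        contig_len = 400
        e1 = (51, 50 + exon1_len)
        e2 = (e1[1] + 101, e1[1] + 100 + (L - exon1_len))
        fwd = list(rng.choice(list("ACGT"), size=contig_len))
        fwd[e1[0] - 1 : e1[1]] = list(tx_seq[:exon1_len])
        fwd[e2[0] - 1 : e2[1]] = list(tx_seq[exon1_len:])
        fwd = "".join(fwd)
        tx_fwd = TranscriptModel(
            "GENE", "TX_F", "1", "+", (e1, e2), utr5 + 1, utr5 + len(cds)
        )
        rev_contig = str(Seq(fwd).reverse_complement())
        mirror = lambda iv: (contig_len - iv[1] + 1, contig_len - iv[0] + 1)
        tx_rev = TranscriptModel(
            "GENE", "TX_R", "1", "-", tuple(sorted([mirror(e1), mirror(e2)])), utr5 + 1, utr5 + len(cds)
        )
        ref_fwd = {"1": fwd}
        ref_rev = {"1": rev_contig}
        comp = str.maketrans("ACGT", "TGCA")
        for gpos in range(e1[0], e2[1] + 1):
            ref_base = fwd[gpos - 1]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                ann_f = call_consequence(VariantSite("1", gpos, ref_base, alt), tx_fwd, ref_fwd)
                mpos = contig_len - gpos + 1
                ann_r = call_consequence(
                    VariantSite("1", mpos, ref_base.translate(comp), alt.translate(comp)),
                    tx_rev,
                    ref_rev,
                )
                assert ann_f.consequence == ann_r.consequence, (gpos, alt)
                assert ann_f.protein_change == ann_r.protein_change, (gpos, alt)


class TestAnnotateVariant:
    def test_most_severe_consequence_wins(self, resources):
        # a variant outside every transcript: falls through to "other"
        ann = annotate_variant(VariantSite("1", 59_999, "A", "G") if resources.reference["1"][59_998] == "A" else VariantSite("1", 59_999, resources.reference["1"][59_998], "A"), resources.transcripts, resources.reference)
        assert ann.consequence == "other"

    def test_empty_transcript_list(self, resources):
        ann = annotate_variant(VariantSite("1", 100, resources.reference["1"][99], "A" if resources.reference["1"][99] != "A" else "C"), [], resources.reference)
        assert ann == Annotation("other")


# ---------------------------------------------------------------------------
# funnel / discovery
# ---------------------------------------------------------------------------


class TestFunnel:
    def test_monotone_on_planted_cohorts(self, small_discovery):
        counts = small_discovery.funnel.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        small_discovery.funnel.validate()

    def test_monotone_on_random_seeds(self):
        from cleftdnm.synthetic_cohort import CohortSpec, generate_cohort

        for seed in (21, 22):
            cohort = generate_cohort(
                CohortSpec(
                    n_trios=6, qc_failures={}, n_background_autosomal=200,
                    n_background_x=200, seed=seed,
                )
            )
            res = discover_dnms(cohort.pedigrees, cohort.trios, cohort.resources)
            assert all(a >= b for a, b in zip(res.funnel.counts, res.funnel.counts[1:]))

    def test_validate_rejects_increase(self):
        funnel = FilterFunnel(counts=[5, 6, 0, 0, 0])
        with pytest.raises(ValidationError):
            funnel.validate()

    def test_stage_vocabulary_stable(self):
        assert FUNNEL_STAGES == ("raw", "quality_pass", "denovo_config", "protein_altering", "rare")


class TestDiscovery:
    def test_noise_free_recovery_is_exact(self, small_cohort, small_qc, small_discovery):
        found = {(d.trio_id, d.site.key()) for d in small_discovery.candidates}
        truth = small_cohort.truth.true_dnm_keys()
        assert found == truth  # precision = recall = 1

    def test_each_decoy_rejected_at_its_stage(self, small_cohort, small_discovery):
        expected_stage = {
            "decoy_low_gq": "quality_pass",
            "decoy_low_dp": "quality_pass",
            "decoy_parent_missing": "quality_pass",
            "decoy_inherited": "denovo_config",
            "decoy_double_hit": "denovo_config",
            "decoy_noncoding": "protein_altering",
            "decoy_common_maf": "rare",
        }
        attribution = small_discovery.stage_attribution
        for v in small_cohort.truth.variants:
            if v.vclass.startswith("decoy_"):
                assert attribution[(v.trio_id, v.site.key())] == expected_stage[v.vclass], v.vclass

    def test_double_hit_flag_count_matches_planted(self, small_cohort, small_discovery):
        planted = len(small_cohort.truth.by_class("decoy_double_hit"))
        assert len(small_discovery.double_hit_flags) == planted == 1

    def test_no_dnm_from_qc_excluded_trio(self, small_cohort, small_qc, small_discovery):
        excluded = set(small_cohort.truth.qc_failures)
        assert all(d.trio_id not in excluded for d in small_discovery.candidates)

    def test_protein_altering_and_rare_commute(self, small_cohort, small_discovery):
        # recompute the two last filters in either order on post-denovo survivors
        resources = small_cohort.resources
        tx_by_chrom = resources.transcripts_by_chrom()
        survivors = [
            v for v in small_cohort.truth.variants
            if v.vclass in ("true_dnm", "decoy_noncoding", "decoy_common_maf")
        ]

        def protein_altering(v):
            from cleftdnm.models import normalize_chrom

            ann = annotate_variant(
                v.site, tx_by_chrom.get(normalize_chrom(v.site.chrom), []), resources.reference
            )
            return impact_class(ann.consequence) != "other"

        def rare(v):
            return not max_panel_maf(v.site, resources.panels) > 0.01

        order_a = {id(v) for v in survivors if protein_altering(v) and rare(v)}
        order_b = {id(v) for v in survivors if rare(v) and protein_altering(v)}
        assert order_a == order_b

    def test_empty_cohort_zero_funnel(self, small_cohort):
        res = discover_dnms([], {}, small_cohort.resources)
        assert res.candidates == [] and res.funnel.counts == [0] * 5

    def test_candidate_invariants(self, small_discovery):
        for d in small_discovery.candidates:
            assert d.max_maf <= 0.01
            assert d.impact in ("protein_truncating", "missense")
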