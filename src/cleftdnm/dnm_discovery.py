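"""The de novo mutation filtration funnel.

Stages, in order: raw -> quality_pass (GQ/DP in all three members) ->
denovo_config (parents hom-ref, child carries the alternate) ->
protein_altering (truncating or missense consequence) -> rare (max panel
MAF <= threshold, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .errors import ValidationError
from .models import (
    FrequencyPanel,
    GenotypeCall,
    ResourceBundle,
    TranscriptModel,
    TrioGenotypeMatrix,
    TrioPedigree,
    VariantSite,
    normalize_chrom,
)

FUNNEL_STAGES = ("raw", "quality_pass", "denovo_config", "protein_altering", "rare")

CONSEQUENCE_SEVERITY = (
    "stop_gained",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "start_lost",
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "other",
)
_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY)}

PROTEIN_TRUNCATING = frozenset(
    {"stop_gained", "start_lost", "splice_donor_variant", "splice_acceptor_variant", "frameshift_variant"}
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _translate_codon(codon: str) -> str:
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


@dataclass(frozen=True)
class FilterConfig:
    min_gq: int = 20
    min_dp: int = 10
    max_maf: float = 0.01
    maf_inclusive: bool = True  # paper's Methods state "MAF <= 1% (0.01)"
    require_child_het: bool = True  # autosomal double-hit diverted to diagnostics


@dataclass
class FilterFunnel:
    """Ordered per-stage retained-variant counts; monotonically non-increasing."""

    counts: list[int] = field(default_factory=lambda: [0] * len(FUNNEL_STAGES))

    stage_names = FUNNEL_STAGES

    def count(self, stage: str) -> int:
        return self.counts[FUNNEL_STAGES.index(stage)]

    def record_pass(self, reached_index: int) -> None:
        for i in range(reached_index + 1):
            self.counts[i] += 1

    def validate(self) -> None:
        for earlier, later in zip(self.counts, self.counts[1:]):
            if later > earlier:
                raise ValidationError("funnel counts must be non-increasing")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(FUNNEL_STAGES, self.counts))


@dataclass(frozen=True)
class Annotation:
    consequence: str
    gene: Optional[str] = None
    transcript_id: Optional[str] = None
    protein_change: Optional[str] = None


@dataclass
class DNMCandidate:
    trio_id: str
    site: VariantSite
    gene: Optional[str]
    transcript_id: Optional[str]
    consequence: str
    impact: str
    protein_change: Optional[str]
    max_maf: float
    cadd_phred: Optional[float] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self):
        if self.impact == "protein_truncating" and self.consequence not in PROTEIN_TRUNCATING:
            raise ValidationError(f"impact/consequence mismatch: {self.consequence}")
        if self.impact == "missense" and self.consequence != "missense_variant":
            raise ValidationError(f"impact/consequence mismatch: {self.consequence}")


# ---------------------------------------------------------------------------
# per-site predicates
# ---------------------------------------------------------------------------


def passes_quality(
    g_father: GenotypeCall,
    g_mother: GenotypeCall,
    g_child: GenotypeCall,
    config: FilterConfig = FilterConfig(),
) -> bool:
    """True iff all three members have non-missing genotypes with GQ and DP
    at or above the thresholds (bounds inclusive)."""
    for g in (g_father, g_mother, g_child):
        if g.is_missing or g.gq < config.min_gq or g.dp < config.min_dp:
            return False
    return True


def is_denovo(
    g_father: GenotypeCall,
    g_mother: GenotypeCall,
    g_child: GenotypeCall,
    child_sex: str = "female",
    chrom: str = "1",
    config: FilterConfig = FilterConfig(),
) -> bool:
    """De novo configuration: both parents hom-ref, child carries the alternate.

    On autosomes the child is expected heterozygous; a hom-alt child is
    rejected by default (double hit, diverted to diagnostics by the caller).
    A hemizygous (hom-alt-coded) male child is accepted on X.
    """
    if any(g.is_missing for g in (g_father, g_mother, g_child)):
        return False
    if g_father.code != 0 or g_mother.code != 0:
        return False
    c = g_child.code
    if c <= 0:
        return False
    if normalize_chrom(chrom) == "X" and child_sex == "male":
        return c == 2  # hemizygous alt emitted as homozygous diploid
    if c == 2 and config.require_child_het:
        return False
    return True


def max_panel_maf(site: VariantSite, panels: list[FrequencyPanel]) -> float:
    """Maximum allele frequency across panels; 0 when absent from all."""
    if not panels:
        raise ValidationError("at least one frequency panel is required")
    return max(panel.lookup(site) for panel in panels)


def impact_class(consequence: str) -> str:
    if consequence in PROTEIN_TRUNCATING:
        return "protein_truncating"
    if consequence == "missense_variant":
        return "missense"
    if consequence in _SEVERITY_RANK:
        return "other"
    raise ValidationError(f"unknown consequence term {consequence!r}")


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------


def _coding_allele(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMPLEMENT)


def call_consequence(
    site: VariantSite, transcript: TranscriptModel, reference: dict[str, str]
) -> Annotation:
    """Classify one variant against one transcript model.

    Variants outside the transcript (beyond +-8 bp of its span) come back as
    ``other``; this function never raises for position, only for reference
    mismatches.
    """
    chrom = normalize_chrom(site.chrom)
    if chrom != normalize_chrom(transcript.chrom):
        return Annotation("other")
    span_start, span_end = transcript.span
    contig = reference[chrom]

    if site.is_snv:
        if not (span_start - 8 <= site.pos <= span_end + 8):
            return Annotation("other")
        ref_base = contig[site.pos - 1]
        if ref_base != site.ref:
            raise ValidationError(
                f"reference mismatch at {chrom}:{site.pos}: expected {ref_base}, VCF says {site.ref}"
            )
        tpos = transcript.genomic_to_transcript(site.pos)
        if tpos is None:
            donors, acceptors = transcript.splice_positions()
            if site.pos in donors:
                return _annot(transcript, "splice_donor_variant")
            if site.pos in acceptors:
                return _annot(transcript, "splice_acceptor_variant")
            if span_start <= site.pos <= span_end:
                return _annot(transcript, "intron_variant")
            return Annotation("other")
        if not transcript.cds_start <= tpos <= transcript.cds_end:
            return _annot(transcript, "other")  # UTR
        cds = transcript.cds_sequence(reference)
        cds_pos = tpos - transcript.cds_start  # 0-based within CDS
        codon_index = cds_pos // 3
        within = cds_pos % 3
        ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
        coding_ref = _coding_allele(site.ref, transcript.strand)
        coding_alt = _coding_allele(site.alt, transcript.strand)
        if ref_codon[within] != coding_ref:
            raise ValidationError(
                f"CDS/reference inconsistency in {transcript.transcript_id} at {chrom}:{site.pos}"
            )
        alt_codon = ref_codon[:within] + coding_alt + ref_codon[within + 1 :]
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        pchange = f"p.{_aa3(ref_aa)}{codon_index + 1}{_aa3(alt_aa)}"
        if codon_index == 0 and ref_codon == "ATG" and alt_codon != "ATG":
            return _annot(transcript, "start_lost", pchange)
        if alt_aa == "*" and ref_aa != "*":
            return _annot(transcript, "stop_gained", pchange)
        if ref_aa == alt_aa:
            return _annot(transcript, "synonymous_variant", pchange)
        if ref_aa == "*":
            return _annot(transcript, "other", pchange)  # stop_lost, outside vocabulary
        return _annot(transcript, "missense_variant", pchange)

    # indel: affected genomic range is the bases after the anchor for both
    # insertions and deletions (alleles share their first base in VCF style)
    del_len = max(len(site.ref) - 1, 0)
    affect_start = site.pos + 1 if del_len else site.pos
    affect_end = site.pos + del_len if del_len else site.pos + 1
    if affect_end < span_start - 8 or affect_start > span_end + 8:
        return Annotation("other")
    length_change = len(site.alt) - len(site.ref)
    cds_positions = []
    for gpos in range(max(affect_start, span_start), min(affect_end, span_end) + 1):
        tpos = transcript.genomic_to_transcript(gpos)
        if tpos is not None and transcript.cds_start <= tpos <= transcript.cds_end:
            cds_positions.append(tpos)
    if cds_positions:
        if length_change % 3 != 0:
            cds = transcript.cds_sequence(reference)
            codon_index = (min(cds_positions) - transcript.cds_start) // 3
            ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
            pchange = f"p.{_aa3(_translate_codon(ref_codon))}{codon_index + 1}fs"
            return _annot(transcript, "frameshift_variant", pchange)
        return _annot(transcript, "other")  # in-frame indel
    donors, acceptors = transcript.splice_positions()
    affected = set(range(affect_start, affect_end + 1))
    if affected & donors:
        return _annot(transcript, "splice_donor_variant")
    if affected & acceptors:
        return _annot(transcript, "splice_acceptor_variant")
    if affect_start >= span_start and affect_end <= span_end:
        return _annot(transcript, "intron_variant")
    return Annotation("other")


def _annot(transcript: TranscriptModel, consequence: str, pchange: Optional[str] = None) -> Annotation:
    return Annotation(
        consequence=consequence,
        gene=transcript.gene,
        transcript_id=transcript.transcript_id,
        protein_change=pchange,
    )


def annotate_variant(
    site: VariantSite,
    transcripts: list[TranscriptModel],
    reference: dict[str, str],
) -> Annotation:
    """Most severe consequence across transcripts; ties break on transcript id."""
    best: Optional[Annotation] = None
    best_key = (len(CONSEQUENCE_SEVERITY), "")
    for t in transcripts:
        ann = call_consequence(site, t, reference)
        key = (_SEVERITY_RANK[ann.consequence], ann.transcript_id or "~")
        if key < best_key:
            best, best_key = ann, key
    return best if best is not None else Annotation("other")


# ---------------------------------------------------------------------------
# cohort-level discovery
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    candidates: list[DNMCandidate]
    funnel: FilterFunnel
    per_trio_counts: dict[str, int]
    double_hit_flags: list[tuple[str, VariantSite]]
    stage_attribution: Optional[dict] = None  # (trio, site key) -> failed stage or "retained"


def discover_dnms(
    pedigrees: list[TrioPedigree],
    cohort: dict[str, TrioGenotypeMatrix],
    resources: ResourceBundle,
    config: FilterConfig = FilterConfig(),
    excluded_sites: Optional[set] = None,
    track_attribution: bool = False,
) -> DiscoveryResult:
    """Run the filtration funnel over QC-retained trios."""
    excluded_sites = excluded_sites or set()
    tx_by_chrom = resources.transcripts_by_chrom()
    funnel = FilterFunnel()
    candidates: list[DNMCandidate] = []
    per_trio: dict[str, int] = {}
    double_hits: list[tuple[str, VariantSite]] = []
    attribution: Optional[dict] = {} if track_attribution else None
    maf_limit = config.max_maf if config.maf_inclusive else config.max_maf * (1 - 1e-12)

    for ped in pedigrees:
        trio = cohort[ped.trio_id]
        per_trio[ped.trio_id] = 0
        gt, gq, dp = trio.gt, trio.gq, trio.dp
        quality_ok = (
            (gt != -1).all(axis=1)
            & (gq >= config.min_gq).all(axis=1)
            & (dp >= config.min_dp).all(axis=1)
        )
        is_x = trio.x_mask
        for i, site in enumerate(trio.sites):
            key = site.key()
            if key in excluded_sites:
                continue
            stage_reached = 0  # raw
            f, m, c = int(gt[i, 0]), int(gt[i, 1]), int(gt[i, 2])
            failed = None
            if not quality_ok[i]:
                failed = "quality_pass"
            else:
                stage_reached = 1
                denovo = (
                    f == 0
                    and m == 0
                    and (
                        (c == 1 and not (is_x[i] and ped.child_sex == "male"))
                        or (c == 2 and (not config.require_child_het or (is_x[i] and ped.child_sex == "male")))
                    )
                )
                if f == 0 and m == 0 and c == 2 and not is_x[i] and config.require_child_het:
                    double_hits.append((ped.trio_id, site))
                if not denovo:
                    failed = "denovo_config"
                else:
                    stage_reached = 2
                    ann = annotate_variant(
                        site, tx_by_chrom.get(normalize_chrom(site.chrom), []), resources.reference
                    )
                    impact = impact_class(ann.consequence)
                    if impact == "other":
                        failed = "protein_altering"
                    else:
                        stage_reached = 3
                        maf = max_panel_maf(site, resources.panels)
                        if maf > maf_limit:
                            failed = "rare"
                        else:
                            stage_reached = 4
                            scores = resources.scores.get(key)
                            candidates.append(
                                DNMCandidate(
                                    trio_id=ped.trio_id,
                                    site=site,
                                    gene=ann.gene,
                                    transcript_id=ann.transcript_id,
                                    consequence=ann.consequence,
                                    impact=impact,
                                    protein_change=ann.protein_change,
                                    max_maf=maf,
                                    cadd_phred=scores.cadd_phred if scores else None,
                                    sift=scores.sift if scores else None,
                                    polyphen=scores.polyphen if scores else None,
                                )
                            )
                            per_trio[ped.trio_id] += 1
            funnel.record_pass(stage_reached)
            if attribution is not None:
                attribution[(ped.trio_id, key)] = failed or "retained"
    funnel.validate()
    return DiscoveryResult(
        candidates=candidates,
        funnel=funnel,
        per_trio_counts=per_trio,
        double_hit_flags=double_hits,
        stage_attribution=attribution,
    )
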