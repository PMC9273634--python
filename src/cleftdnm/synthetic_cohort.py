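"""Synthetic trio cohorts with planted truth.

The generator emits a desk-scale mini-genome (22 autosomal contigs + X, each
60 kb), transcript models with realistic exon structure, trio VCF genotype
matrices with Hardy-Weinberg background sites, planted de novo mutations
(child het, parents hom-ref, high quality, rare), one decoy class per funnel
stage, and trios constructed to violate exactly one QC rule each. Every
planted object is recorded in a ledger so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigurationError, ValidationError
from .io_formats import (
    read_pedigree,
    read_resources,
    read_trio_vcf,
    write_pedigree,
    write_resources,
    write_trio_vcf,
)
from .models import (
    AUTOSOMES,
    EvidenceRecord,
    ExpressionMatrix,
    FrequencyPanel,
    GeneSet,
    GeneSetCollection,
    ResourceBundle,
    ScoreEntry,
    TranscriptModel,
    TrioGenotypeMatrix,
    TrioPedigree,
    VariantSite,
    normalize_chrom,
)
from .trio_qc import MENDELIAN_CONSISTENT_TABLE

CONTIG_LENGTH = 60_000
TRANSCRIPT_REGION = (2_001, 40_000)
INTERGENIC_REGION = (41_001, 44_000)
BACKGROUND_REGION = (45_001, 59_000)

QC_FAILURE_CLASSES = ("missingness", "sex_mismatch", "relatedness", "mendelian_outlier")
DECOY_CLASSES = ("low_gq", "low_dp", "inherited", "common_maf", "noncoding", "parent_missing", "double_hit")

# Table-1 style craniofacial-evidence genes used throughout the fixtures
EVIDENCE_GENES = {
    "ACAN": ("cleft", False, False),
    "DHRS3": ("cleft", False, True),
    "KMT2D": ("cleft", True, False),
    "RECQL4": ("cleft", False, False),
    "SHH": ("cleft", True, True),
    "TP63": ("cleft", False, True),
    "ACTL6A": ("lethal", True, False),
    "MINK1": ("craniofacial", False, False),
    "DLX6": ("craniofacial", True, False),
    "EPHB2": ("craniofacial", False, False),
    "SEMA3C": ("craniofacial", False, False),
    "SEMA4D": ("craniofacial", False, False),
    "ARHGAP10": ("none", True, False),
    "TMEM5": ("none", True, True),
    "TTN": ("none", False, True),
    "FKBP10": ("none", True, False),
    "TULP4": ("none", False, True),
}
EXTRA_GENES = ("MMP9", "JUNB", "JUP", "DNAJC3", "IRF6", "PAX9", "MSX1", "BMP4", "GRHL3", "CTNNB1")
ALL_GENES = tuple(EVIDENCE_GENES) + EXTRA_GENES

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the study's scale."""

    n_trios: int = 150
    qc_failures: dict = field(
        default_factory=lambda: {
            "missingness": 8,
            "sex_mismatch": 4,
            "relatedness": 4,
            "mendelian_outlier": 4,
        }
    )
    dnm_rate: float = 1.2  # Poisson mean of coding protein-altering DNMs per retained case
    decoys: dict = field(
        default_factory=lambda: {
            "low_gq": 6,
            "low_dp": 6,
            "inherited": 6,
            "common_maf": 6,
            "noncoding": 6,
            "parent_missing": 6,
            "double_hit": 0,
        }
    )
    n_background_autosomal: int = 1200
    n_background_x: int = 800
    n_mendelian_errors: int = 40
    missingness_fraction: float = 0.15
    common_maf_value: float = 0.05
    seed: int = 1

    def __post_init__(self):
        for name, count in {**self.qc_failures, **self.decoys}.items():
            if count < 0:
                raise ValidationError(f"negative count for {name}")
        for name in self.qc_failures:
            if name not in QC_FAILURE_CLASSES:
                raise ConfigurationError(f"unknown QC failure class {name!r}")
        for name in self.decoys:
            if name not in DECOY_CLASSES:
                raise ConfigurationError(f"unknown decoy class {name!r}")
        if sum(self.qc_failures.values()) > self.n_trios:
            raise ConfigurationError("more planted QC failures than trios")
        if self.dnm_rate < 0:
            raise ValidationError("dnm_rate must be >= 0")


@dataclass(frozen=True)
class PlantedVariant:
    trio_id: str
    site: VariantSite
    vclass: str  # true_dnm | decoy_<class>
    consequence: Optional[str]
    gene: Optional[str]
    maf: float
    cadd_phred: Optional[float]
    sift: Optional[float]
    polyphen: Optional[float]


@dataclass
class PlantedTruth:
    """Generator-side ledger: the acceptance surface for recovery tests."""

    seed: int
    qc_failures: dict[str, str]  # trio_id -> failure class
    variants: list[PlantedVariant]

    def by_class(self, vclass: str) -> list[PlantedVariant]:
        return [v for v in self.variants if v.vclass == vclass]

    def true_dnm_keys(self) -> set:
        return {(v.trio_id, v.site.key()) for v in self.by_class("true_dnm")}


@dataclass
class SimulatedCohort:
    pedigrees: list[TrioPedigree]
    trios: dict[str, TrioGenotypeMatrix]
    truth: PlantedTruth
    resources: ResourceBundle


# ---------------------------------------------------------------------------
# resources
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    return codons


def _build_gene(
    rng: np.random.Generator,
    gene: str,
    chrom: str,
    strand: str,
    start: int,
    n_exons: int,
    n_codons: int,
    special_codons: Optional[dict[int, str]] = None,
) -> tuple[TranscriptModel, str]:
    """Construct one transcript and its spliced sequence (5'UTR + CDS + 3'UTR)."""
    u5 = int(rng.choice([0, 30]))
    u3 = int(rng.choice([0, 30]))
    codons = _random_codons(rng, n_codons - 2)
    codons = ["ATG"] + codons + [str(rng.choice(_STOP_CODONS))]
    for idx, codon in (special_codons or {}).items():
        codons[idx - 1] = codon
    cds = "".join(codons)
    utr5 = "".join(rng.choice(list(_BASES), size=u5))
    utr3 = "".join(rng.choice(list(_BASES), size=u3))
    tx_seq = utr5 + cds + utr3
    length = len(tx_seq)

    # split the spliced length into n_exons chunks of >= 10 bases
    if n_exons * 10 > length:
        n_exons = max(1, length // 10)
    cuts = np.sort(rng.choice(np.arange(10, length - 9), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    bounds = [0, *cuts.tolist(), length]
    exon_lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    if min(exon_lengths) < 2:  # degenerate split; fall back to even chunks
        base = length // n_exons
        exon_lengths = [base] * (n_exons - 1) + [length - base * (n_exons - 1)]

    exons = []
    pos = start
    for el in exon_lengths:
        exons.append((pos, pos + el - 1))
        pos += el + int(rng.integers(150, 401))
    transcript = TranscriptModel(
        gene=gene,
        transcript_id=f"TX_{gene}",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=u5 + 1,
        cds_end=u5 + len(cds),
    )
    return transcript, tx_seq


def _embed_transcript(contig: np.ndarray, transcript: TranscriptModel, tx_seq: str) -> None:
    offset = 0
    for s, e in transcript.transcription_order_exons:
        n = e - s + 1
        chunk = tx_seq[offset : offset + n]
        offset += n
        if transcript.strand == "-":
            chunk = _revcomp(chunk)
        contig[s - 1 : e] = list(chunk)


# deterministic per-gene layout: (contig, strand, n_exons, n_codons)
def _gene_layout() -> dict[str, tuple[str, str, int, int]]:
    layout: dict[str, tuple[str, str, int, int]] = {"TTN": ("2", "+", 50, 5000)}
    contigs = [c for c in AUTOSOMES if c != "2"]
    strands = ("+", "-")
    genes = [g for g in ALL_GENES if g != "TTN"]
    for i, gene in enumerate(genes):
        layout[gene] = (contigs[i % len(contigs)], strands[i % 2], 2 + i % 7, 120 + 17 * (i % 14))
    return layout


def generate_resources(seed: int) -> ResourceBundle:
    """Deterministic annotation bundle: mini-genome FASTA, >= 20 transcripts
    on both strands (one with >= 40 exons), frequency panels, score table,
    gene sets including palate-development and neural-crest-migration terms,
    evidence table marking the 17 craniofacial genes, and an expression
    matrix with maxillary/mandibular E10.5 columns (TULP4 absent)."""
    rng = np.random.default_rng([seed, 101])
    contigs: dict[str, np.ndarray] = {
        c: rng.choice(list(_BASES), size=CONTIG_LENGTH) for c in (*AUTOSOMES, "X")
    }

    layout = _gene_layout()
    special = {
        "TTN": {4738: "CGA"},  # Arg codon deep in a 50-exon transcript
        "DHRS3": {37: "TCG"},  # Ser codon in the catalytic-domain fixture
    }
    transcripts: list[TranscriptModel] = []
    next_start: dict[str, int] = {}
    for gene in ALL_GENES:
        chrom, strand, n_exons, n_codons = layout[gene]
        start = next_start.get(chrom, TRANSCRIPT_REGION[0])
        tx, tx_seq = _build_gene(rng, gene, chrom, strand, start, n_exons, n_codons, special.get(gene))
        if tx.span[1] >= TRANSCRIPT_REGION[1]:
            raise ValidationError(f"transcript {gene} overflows its contig region")
        _embed_transcript(contigs[chrom], tx, tx_seq)
        next_start[chrom] = tx.span[1] + 2000
        transcripts.append(tx)

    reference = {c: "".join(arr) for c, arr in contigs.items()}
    for t in transcripts:
        t.validate_against_reference(reference)

    panels = [FrequencyPanel("thousand_genomes"), FrequencyPanel("evs"), FrequencyPanel("gnomad_afr")]

    evidence = {
        gene: EvidenceRecord(gene=gene, knockout_phenotype=ko, cnv_report=cnv, snv_report=snv)
        for gene, (ko, cnv, snv) in EVIDENCE_GENES.items()
    }

    fillers = [f"GENE{i:03d}" for i in range(1, 74)]
    gene_sets = GeneSetCollection()
    gene_sets.add(GeneSet(
        "GO:0060021_palate_development", "palate development",
        frozenset({"DHRS3", "DLX6", "EPHB2", "SHH", "TP63", "PAX9", "MSX1", "BMP4", *fillers[:2]}),
    ))
    gene_sets.add(GeneSet(
        "GO:0001755_neural_crest_migration", "neural crest cell migration",
        frozenset({"SEMA3C", "SEMA4D", "SHH", "CTNNB1", *fillers[2:3]}),
    ))
    gene_sets.add(GeneSet("GO:0007507_heart_development", "heart development", frozenset(fillers[3:15])))
    gene_sets.add(GeneSet(
        "GO:0001501_skeletal_system_development", "skeletal system development",
        frozenset({"ACAN", "TTN", *fillers[15:25]}),
    ))
    gene_sets.add(GeneSet("GO:0006915_apoptotic_process", "apoptotic process", frozenset(fillers[25:40])))
    gene_sets.add(GeneSet(
        "GO:0016055_wnt_signaling", "Wnt signaling pathway",
        frozenset({"ARHGAP10", "CTNNB1", *fillers[40:48]}),
    ))
    remaining = set(ALL_GENES) | set(fillers)
    remaining -= gene_sets.universe()
    gene_sets.add(GeneSet("GO:0030154_cell_differentiation", "cell differentiation", frozenset(remaining)))

    expr_genes = [g for g in ALL_GENES if g != "TULP4"]  # TULP4 ortholog undetected in mouse
    columns = ["maxillary_E10.5", "mandibular_E10.5", "frontonasal_E10.5", "palate_E13.5", "palate_P0"]
    data = rng.uniform(50, 400, size=(len(expr_genes), len(columns)))
    for i, gene in enumerate(expr_genes):
        if gene in EVIDENCE_GENES:
            data[i, 0] = data[i, 1] * rng.uniform(1.5, 3.0)  # maxillary elevated vs mandibular
            data[i, 3] = max(data[i, 3], data[i].max() * rng.uniform(1.0, 1.3))
    expression = ExpressionMatrix(pd.DataFrame(np.round(data, 2), index=expr_genes, columns=columns))

    return ResourceBundle(
        reference=reference,
        transcripts=transcripts,
        panels=panels,
        scores={},
        evidence=evidence,
        gene_sets=gene_sets,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

from .dnm_discovery import call_consequence  # noqa: E402  (cycle-free: discovery imports models only)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _coding_to_genomic(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMPLEMENT)


class _VariantPlanter:
    """Constructs planted variants of requested consequence classes."""

    def __init__(self, rng: np.random.Generator, resources: ResourceBundle, used: set):
        self.rng = rng
        self.resources = resources
        self.used = used  # occupied (chrom, pos) slots
        self._cds_cache: dict[str, str] = {}

    def _cds(self, tx: TranscriptModel) -> str:
        if tx.transcript_id not in self._cds_cache:
            self._cds_cache[tx.transcript_id] = tx.cds_sequence(self.resources.reference)
        return self._cds_cache[tx.transcript_id]

    def _claim(self, chrom: str, *positions: int) -> bool:
        slots = [(chrom, p) for p in positions]
        if any(s in self.used for s in slots):
            return False
        self.used.update(slots)
        return True

    def _pick_tx(self) -> TranscriptModel:
        idx = int(self.rng.integers(len(self.resources.transcripts)))
        return self.resources.transcripts[idx]

    def plant(self, category: str) -> tuple[VariantSite, str, TranscriptModel]:
        for _ in range(200):
            tx = self._pick_tx()
            out = getattr(self, f"_plant_{category}")(tx)
            if out is None:
                continue
            site, expected = out
            ann = call_consequence(site, tx, self.resources.reference)
            if ann.consequence != expected:  # sanity net, should not trigger
                continue
            return site, expected, tx
        raise ValidationError(f"could not plant a {category} variant")

    # -- coding SNVs --------------------------------------------------------

    def _codon_snv(self, tx: TranscriptModel, accept) -> Optional[tuple[VariantSite, str]]:
        cds = self._cds(tx)
        n_codons = len(cds) // 3
        ci = int(self.rng.integers(2, n_codons))  # 1-based codon in [2, n_codons-1]
        ref_codon = cds[3 * (ci - 1) : 3 * ci]
        if ref_codon in _STOP_CODONS:
            return None
        order = self.rng.permutation(3)
        for within in order:
            coding_ref = ref_codon[within]
            for base in self.rng.permutation(list(_BASES)):
                if base == coding_ref:
                    continue
                alt_codon = ref_codon[:within] + base + ref_codon[within + 1 :]
                if not accept(ref_codon, alt_codon):
                    continue
                tpos = tx.cds_start + 3 * (ci - 1) + int(within)
                gpos = tx.transcript_to_genomic(tpos)
                if not self._claim(tx.chrom, gpos):
                    return None
                gref = self.resources.reference[tx.chrom][gpos - 1]
                galt = _coding_to_genomic(base, tx.strand)
                return VariantSite(tx.chrom, gpos, gref, galt), None  # consequence filled by caller
        return None

    def _plant_missense(self, tx: TranscriptModel):
        from .dnm_discovery import _translate_codon

        def accept(ref_codon, alt_codon):
            ra, aa = _translate_codon(ref_codon), _translate_codon(alt_codon)
            return ra != "*" and aa != "*" and ra != aa

        out = self._codon_snv(tx, accept)
        return (out[0], "missense_variant") if out else None

    def _plant_stop_gained(self, tx: TranscriptModel):
        from .dnm_discovery import _translate_codon

        def accept(ref_codon, alt_codon):
            return _translate_codon(ref_codon) != "*" and alt_codon in _STOP_CODONS

        out = self._codon_snv(tx, accept)
        return (out[0], "stop_gained") if out else None

    def _plant_start_lost(self, tx: TranscriptModel):
        cds = self._cds(tx)
        if cds[:3] != "ATG":
            return None
        within = int(self.rng.integers(3))
        coding_ref = cds[within]
        choices = [b for b in _BASES if b != coding_ref]
        base = str(self.rng.choice(choices))
        tpos = tx.cds_start + within
        gpos = tx.transcript_to_genomic(tpos)
        if not self._claim(tx.chrom, gpos):
            return None
        gref = self.resources.reference[tx.chrom][gpos - 1]
        return VariantSite(tx.chrom, gpos, gref, _coding_to_genomic(base, tx.strand)), "start_lost"

    def _plant_splice_donor_variant(self, tx: TranscriptModel):
        donors, _ = tx.splice_positions()
        if not donors:
            return None
        gpos = int(self.rng.choice(sorted(donors)))
        if not self._claim(tx.chrom, gpos):
            return None
        gref = self.resources.reference[tx.chrom][gpos - 1]
        galt = str(self.rng.choice([b for b in _BASES if b != gref]))
        return VariantSite(tx.chrom, gpos, gref, galt), "splice_donor_variant"

    def _plant_frameshift_variant(self, tx: TranscriptModel):
        cds_len = tx.cds_end - tx.cds_start + 1
        tpos = tx.cds_start + int(self.rng.integers(3, cds_len - 6))
        gpos = tx.transcript_to_genomic(tpos)
        # need the anchored and the deleted base adjacent in the genome and both coding
        neighbor = tx.genomic_to_transcript(gpos + 1)
        if neighbor is None or not (tx.cds_start <= neighbor <= tx.cds_end):
            return None
        if not self._claim(tx.chrom, gpos, gpos + 1):
            return None
        ref = self.resources.reference[tx.chrom][gpos - 1 : gpos + 1]
        return VariantSite(tx.chrom, gpos, ref, ref[0]), "frameshift_variant"

    # -- non protein-altering ----------------------------------------------

    def _plant_intronic(self, tx: TranscriptModel):
        if len(tx.exons) < 2:
            return None
        i = int(self.rng.integers(len(tx.exons) - 1))
        intron_start, intron_end = tx.exons[i][1] + 1, tx.exons[i + 1][0] - 1
        if intron_end - intron_start < 100:
            return None
        gpos = int(self.rng.integers(intron_start + 40, intron_end - 40))
        if not self._claim(tx.chrom, gpos):
            return None
        gref = self.resources.reference[tx.chrom][gpos - 1]
        galt = str(self.rng.choice([b for b in _BASES if b != gref]))
        return VariantSite(tx.chrom, gpos, gref, galt), "intron_variant"

    def plant_noncoding(self) -> tuple[VariantSite, str, Optional[TranscriptModel]]:
        for _ in range(200):
            if self.rng.random() < 0.5:
                tx = self._pick_tx()
                out = self._plant_intronic(tx)
                if out is not None:
                    ann = call_consequence(out[0], tx, self.resources.reference)
                    if ann.consequence == "intron_variant":
                        return out[0], "intron_variant", tx
            else:
                chrom = str(self.rng.choice(list(AUTOSOMES)))
                gpos = int(self.rng.integers(*INTERGENIC_REGION))
                if self._claim(chrom, gpos):
                    gref = self.resources.reference[chrom][gpos - 1]
                    galt = str(self.rng.choice([b for b in _BASES if b != gref]))
                    return VariantSite(chrom, gpos, gref, galt), "other", None
        raise ValidationError("could not plant a noncoding variant")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _background_sites(
    rng: np.random.Generator,
    reference: dict[str, str],
    chroms: list[str],
    n_sites: int,
    region: tuple[int, int],
    freq_range: tuple[float, float],
    used: set,
) -> tuple[list[VariantSite], np.ndarray]:
    sites: list[VariantSite] = []
    freqs = rng.uniform(*freq_range, size=n_sites)
    per_chrom = np.array_split(np.arange(n_sites), len(chroms))
    for chrom, idxs in zip(chroms, per_chrom):
        positions = rng.choice(np.arange(region[0], region[1]), size=len(idxs), replace=False)
        for gpos in np.sort(positions):
            gpos = int(gpos)
            if (chrom, gpos) in used:
                continue
            used.add((chrom, gpos))
            ref = reference[chrom][gpos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            sites.append(VariantSite(chrom, gpos, ref, alt))
    return sites, freqs[: len(sites)]


def _transmit(rng: np.random.Generator, parent_codes: np.ndarray) -> np.ndarray:
    """Draw one transmitted allele per site from a diploid parent."""
    return (rng.random(parent_codes.shape) < parent_codes / 2.0).astype(np.int8)


# Maximum of the per-trio inbreeding-like factor applied to parental autosomal
# draws. Real cohorts show bounded between-sample het/hom heterogeneity; with
# a pure-HWE null the 4 SD outlier rule is dominated by skewed binomial noise
# and false-positives on ~20% of cohorts. A bounded uniform spread dominates
# the pooled SD, so no clean sample can reach 4 SD, while parent-offspring
# kinship stays inside [0.15, 0.35] (phi = (1-f)/(2(2-f)) >= 0.21).
MAX_PARENT_INBREEDING = 0.25


def _parent_autosomal_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Diploid genotype codes with inbreeding coefficient f at frequencies p."""
    het = 2.0 * p * (1.0 - p) * (1.0 - f)
    hom_alt = p * p + f * p * (1.0 - p)
    u = rng.random(p.shape)
    return ((u < hom_alt) * 2 + ((u >= hom_alt) & (u < hom_alt + het)) * 1).astype(np.int8)


def corrupt_for_qc(
    trio: TrioGenotypeMatrix,
    failure_class: str,
    rng: np.random.Generator,
    spec: CohortSpec,
    x_freqs_by_key: dict,
    child_sex: str = "female",
) -> TrioGenotypeMatrix:
    """Make one trio violate exactly the targeted QC rule (with margin)."""
    if failure_class not in QC_FAILURE_CLASSES:
        raise ConfigurationError(f"unknown QC failure class {failure_class!r}")
    n = trio.n_sites
    if failure_class == "missingness":
        k = int(round(spec.missingness_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        trio.gt[idx, 2] = -1
        trio.gq[idx, 2] = 0
        trio.dp[idx, 2] = 0
    elif failure_class == "sex_mismatch":
        x_idx = np.flatnonzero(trio.x_mask)
        p = np.asarray([x_freqs_by_key[trio.sites[i].key()] for i in x_idx])
        if child_sex == "male":  # plant a female (heterozygote-rich) X pattern
            new = (rng.random(p.size) < p).astype(np.int8) + (rng.random(p.size) < p).astype(np.int8)
        else:  # plant a male (hemizygous, all-homozygous) X pattern
            new = 2 * (rng.random(p.size) < p).astype(np.int8)
        trio.gt[x_idx, 2] = new
    elif failure_class == "relatedness":
        # duplicate-sample anomaly: father's autosomal genotypes become a copy
        # of the child's (kinship ~0.5, no new Mendelian errors, X untouched)
        auto = np.flatnonzero(trio.autosome_mask)
        trio.gt[auto, 0] = trio.gt[auto, 2]
    elif failure_class == "mendelian_outlier":
        # het child at hom-ref/hom-ref (or hom-alt/hom-alt) parent sites: an
        # untransmittable configuration that leaves the KING kinship numerator
        # and the opposite-homozygote count untouched
        auto = np.flatnonzero(trio.autosome_mask)
        f, m = trio.gt[auto, 0], trio.gt[auto, 1]
        eligible = auto[((f == 0) & (m == 0)) | ((f == 2) & (m == 2))]
        k = min(spec.n_mendelian_errors, eligible.size)
        chosen = rng.choice(eligible, size=k, replace=False)
        trio.gt[chosen, 2] = 1
        assert not MENDELIAN_CONSISTENT_TABLE[0, 0, 1] and not MENDELIAN_CONSISTENT_TABLE[2, 2, 1]
    return trio


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a full synthetic cohort with planted truth.

    True DNMs are child-het / parents-hom-ref, GQ >= 20 and DP >= 10 in all
    members, MAF <= 0.01; each decoy violates exactly one filter stage; each
    QC-failing trio violates exactly its assigned rule.
    """
    resources = generate_resources(spec.seed)
    rng = np.random.default_rng([spec.seed, 202])
    used: set = set()

    auto_sites, auto_freqs = _background_sites(
        rng, resources.reference, list(AUTOSOMES), spec.n_background_autosomal,
        BACKGROUND_REGION, (0.05, 0.5), used,
    )
    x_sites, x_freqs = _background_sites(
        rng, resources.reference, ["X"], spec.n_background_x,
        (1_001, CONTIG_LENGTH - 1_000), (0.2, 0.5), used,
    )
    bg_sites = auto_sites + x_sites
    n_auto, n_x = len(auto_sites), len(x_sites)
    x_freqs_by_key = {s.key(): f for s, f in zip(x_sites, x_freqs)}

    # background sites go into all panels with small panel-to-panel jitter
    for panel in resources.panels:
        jitter = np.clip(
            np.concatenate([auto_freqs, x_freqs]) + rng.normal(0, 0.01, size=len(bg_sites)),
            0.001, 0.999,
        )
        for site, f in zip(bg_sites, jitter):
            panel.add(site, float(round(f, 4)))

    # pedigree + QC failure assignment
    pedigrees: list[TrioPedigree] = []
    for i in range(spec.n_trios):
        tid = f"trio{i:03d}"
        pedigrees.append(
            TrioPedigree(
                trio_id=tid,
                father_id=f"{tid}_fa",
                mother_id=f"{tid}_mo",
                child_id=f"{tid}_ch",
                child_sex="male" if rng.random() < 0.5 else "female",
                cleft_status="CL" if rng.random() < 51 / 130 else "CLP",
                country="Ghana" if rng.random() < 104 / 130 else "Nigeria",
            )
        )
    fail_assignment: dict[str, str] = {}
    n_fail = sum(spec.qc_failures.values())
    if n_fail:
        fail_idx = rng.choice(spec.n_trios, size=n_fail, replace=False)
        classes = [c for c in QC_FAILURE_CLASSES for _ in range(spec.qc_failures.get(c, 0))]
        for idx, cls in zip(fail_idx, classes):
            fail_assignment[pedigrees[idx].trio_id] = cls

    # background genotypes per trio
    trios: dict[str, TrioGenotypeMatrix] = {}
    extras: dict[str, list] = {p.trio_id: [] for p in pedigrees}
    for ped in pedigrees:
        f_trio = float(rng.uniform(0.0, MAX_PARENT_INBREEDING))
        fa_a = _parent_autosomal_draw(rng, auto_freqs, f_trio)
        mo_a = _parent_autosomal_draw(rng, auto_freqs, f_trio)
        ch_a = (_transmit(rng, fa_a) + _transmit(rng, mo_a)).astype(np.int8)
        fa_x = (2 * (rng.random(n_x) < x_freqs)).astype(np.int8)
        mo_x = rng.binomial(2, x_freqs).astype(np.int8)
        if ped.child_sex == "male":
            ch_x = (2 * _transmit(rng, mo_x)).astype(np.int8)
        else:
            ch_x = ((fa_x // 2) + _transmit(rng, mo_x)).astype(np.int8)
        gt = np.column_stack(
            [np.concatenate([fa_a, fa_x]), np.concatenate([mo_a, mo_x]), np.concatenate([ch_a, ch_x])]
        ).astype(np.int8)
        n = n_auto + n_x
        trio = TrioGenotypeMatrix(
            sites=list(bg_sites),
            gt=gt,
            gq=rng.integers(30, 100, size=(n, 3)).astype(np.int32),
            dp=rng.integers(20, 41, size=(n, 3)).astype(np.int32),
        )
        if ped.trio_id in fail_assignment:
            corrupt_for_qc(trio, fail_assignment[ped.trio_id], rng, spec, x_freqs_by_key, ped.child_sex)
        trios[ped.trio_id] = trio

    # plant true DNMs and decoys in clean trios
    planter = _VariantPlanter(rng, resources, used)
    planted: list[PlantedVariant] = []
    clean = [p for p in pedigrees if p.trio_id not in fail_assignment]
    consequence_menu = np.array(
        ["missense", "stop_gained", "splice_donor_variant", "start_lost", "frameshift_variant"]
    )
    consequence_p = np.array([0.80, 0.08, 0.05, 0.02, 0.05])

    def _scores_for(consequence: str) -> ScoreEntry:
        if consequence == "missense_variant":
            sift = round(float(rng.uniform(0.0, 0.04) if rng.random() < 0.7 else rng.uniform(0.06, 0.6)), 3)
            poly = round(float(rng.uniform(0.85, 1.0) if rng.random() < 0.6 else rng.uniform(0.0, 0.85)), 3)
            return ScoreEntry(cadd_phred=round(float(rng.uniform(12, 34)), 2), sift=sift, polyphen=poly)
        return ScoreEntry(cadd_phred=round(float(rng.uniform(33, 45)), 2), sift=None, polyphen=None)

    def _register(ped, site, vclass, consequence, gene, maf, gt_row, gq_row, dp_row):
        entry = _scores_for(consequence if consequence == "missense_variant" else "truncating")
        resources.scores[site.key()] = entry
        if maf > 0:
            panel = resources.panels[int(rng.integers(len(resources.panels)))]
            panel.add(site, maf)
        extras[ped.trio_id].append((site, gt_row, gq_row, dp_row))
        planted.append(
            PlantedVariant(
                trio_id=ped.trio_id, site=site, vclass=vclass, consequence=consequence,
                gene=gene, maf=maf, cadd_phred=entry.cadd_phred, sift=entry.sift, polyphen=entry.polyphen,
            )
        )

    def _quality_rows():
        gq_row = rng.integers(40, 100, size=3).astype(np.int32)
        dp_row = rng.integers(15, 41, size=3).astype(np.int32)
        dp_row[dp_row < 10] = 10
        return gq_row, dp_row

    for ped in clean:
        for _ in range(int(rng.poisson(spec.dnm_rate))):
            category = str(rng.choice(consequence_menu, p=consequence_p))
            site, consequence, tx = planter.plant(category)
            maf = 0.0 if rng.random() < 0.8 else round(float(rng.uniform(0.0005, 0.0095)), 4)
            gq_row, dp_row = _quality_rows()
            _register(
                ped, site, "true_dnm", consequence, tx.gene, maf,
                np.array([0, 0, 1], dtype=np.int8), gq_row, dp_row,
            )

    decoy_order = [c for c in DECOY_CLASSES for _ in range(spec.decoys.get(c, 0))]
    if decoy_order and not clean:
        raise ConfigurationError("cannot plant decoys: no QC-clean trios")
    for dclass in decoy_order:
        ped = clean[int(rng.integers(len(clean)))]
        gq_row, dp_row = _quality_rows()
        gt_row = np.array([0, 0, 1], dtype=np.int8)
        maf = 0.0
        if dclass == "noncoding":
            site, consequence, tx = planter.plant_noncoding()
            gene = tx.gene if tx else None
        else:
            site, consequence, tx = planter.plant("missense")
            gene = tx.gene
            if dclass == "low_gq":
                gq_row[2] = 15
            elif dclass == "low_dp":
                dp_row[0] = 5
            elif dclass == "inherited":
                gt_row = np.array([1, 0, 1], dtype=np.int8)
            elif dclass == "common_maf":
                maf = spec.common_maf_value
            elif dclass == "parent_missing":
                gt_row = np.array([-1, 0, 1], dtype=np.int8)
                gq_row[0] = 0
                dp_row[0] = 0
            elif dclass == "double_hit":
                gt_row = np.array([0, 0, 2], dtype=np.int8)
        _register(ped, site, f"decoy_{dclass}", consequence, gene, maf, gt_row, gq_row, dp_row)

    # merge extras into each trio's matrix, sorted by genome coordinate
    for ped in pedigrees:
        extra = extras[ped.trio_id]
        trio = trios[ped.trio_id]
        if extra:
            sites = trio.sites + [e[0] for e in extra]
            gt = np.vstack([trio.gt, np.stack([e[1] for e in extra])])
            gq = np.vstack([trio.gq, np.stack([e[2] for e in extra])])
            dp = np.vstack([trio.dp, np.stack([e[3] for e in extra])])
        else:
            sites, gt, gq, dp = trio.sites, trio.gt, trio.gq, trio.dp
        order = sorted(
            range(len(sites)),
            key=lambda i: (_chrom_order(sites[i].chrom), sites[i].pos, sites[i].ref, sites[i].alt),
        )
        idx = np.asarray(order)
        trios[ped.trio_id] = TrioGenotypeMatrix(
            sites=[sites[i] for i in order], gt=gt[idx], gq=gq[idx], dp=dp[idx]
        )

    truth = PlantedTruth(seed=spec.seed, qc_failures=fail_assignment, variants=planted)
    return SimulatedCohort(pedigrees=pedigrees, trios=trios, truth=truth, resources=resources)


def _chrom_order(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (int(c), "") if c.isdigit() else (99, c)


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict:
    """Write PED + per-trio VCFs + resource bundle + truth ledger."""
    out = Path(out_dir)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    contig_lengths = {c: len(seq) for c, seq in cohort.resources.reference.items()}
    write_pedigree(out / "cohort.ped", cohort.pedigrees)
    for ped in cohort.pedigrees:
        write_trio_vcf(
            vcf_dir / f"{ped.trio_id}.vcf", ped, cohort.trios[ped.trio_id].to_records(), contig_lengths
        )
    resource_paths = write_resources(out / "resources", cohort.resources)

    rows = [
        {
            "trio_id": v.trio_id, "chrom": v.site.chrom, "pos": v.site.pos,
            "ref": v.site.ref, "alt": v.site.alt, "class": v.vclass,
            "consequence": v.consequence or "", "gene": v.gene or "", "maf": v.maf,
        }
        for v in cohort.truth.variants
    ]
    pd.DataFrame(
        rows, columns=["trio_id", "chrom", "pos", "ref", "alt", "class", "consequence", "gene", "maf"]
    ).to_csv(out / "planted_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"trio_id": t, "failure_class": c} for t, c in sorted(cohort.truth.qc_failures.items())],
        columns=["trio_id", "failure_class"],
    ).to_csv(out / "planted_qc_failures.tsv", sep="\t", index=False)
    return {"ped": out / "cohort.ped", "vcf_dir": vcf_dir, "resources": resource_paths}


def load_cohort(cohort_dir: str | Path) -> tuple[list[TrioPedigree], dict[str, TrioGenotypeMatrix], ResourceBundle]:
    """Load a written cohort back (PED + VCFs + resources)."""
    cohort_dir = Path(cohort_dir)
    pedigrees = read_pedigree(cohort_dir / "cohort.ped")
    trios = {}
    for ped in pedigrees:
        result = read_trio_vcf(cohort_dir / "vcf" / f"{ped.trio_id}.vcf", ped)
        trios[ped.trio_id] = TrioGenotypeMatrix.from_records(result.records)
    res_dir = cohort_dir / "resources"
    paths = {
        "reference": res_dir / "reference.fa",
        "transcripts": res_dir / "transcripts.tsv",
        "scores": res_dir / "scores.tsv",
        "evidence": res_dir / "evidence.tsv",
        "gene_sets": res_dir / "gene_sets.gmt",
        "expression": res_dir / "expression.tsv",
        "panels": sorted(res_dir.glob("panel_*.tsv")),
    }
    return pedigrees, trios, read_resources(paths)
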