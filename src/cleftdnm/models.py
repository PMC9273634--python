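"""Internal data model: variant sites, genotypes, pedigrees, transcripts, resources.

Coordinates follow the VCF convention (1-based, inclusive) at every public
interface. Genotypes are unordered allele pairs; phase is discarded on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

AUTOSOMES = tuple(str(i) for i in range(1, 23))
VALID_CHROMS = frozenset(AUTOSOMES) | {"X"}
SKIPPED_CHROMS = frozenset({"Y", "MT", "M"})

_BASES = frozenset("ACGT")

CLEFT_STATUSES = ("CL", "CLP", "CP")
SEXES = ("male", "female")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and canonicalize mitochondrial names."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.upper() in {"M", "MT"}:
        return "MT"
    return c.upper() if c.upper() in {"X", "Y"} else c


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix of an allele pair.

    This is parsimonious trimming (no reference-window left-shifting); panels
    and score tables are keyed on the trimmed representation.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant site in VCF convention."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _BASES:
                raise ValidationError(
                    f"{name} allele must be a non-empty uppercase ACGT string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def key(self) -> tuple[str, int, str, str]:
        """Normalized lookup key used by panels and score tables."""
        pos, ref, alt = normalize_variant(self.pos, self.ref, self.alt)
        return (normalize_chrom(self.chrom), pos, ref, alt)


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid genotype with its quality fields.

    ``allele_a``/``allele_b`` are 0 (ref) or 1 (alt); both ``None`` when the
    genotype is missing. Male hemizygous X calls are stored in the common VCF
    dialect as homozygous diploid calls.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    gq: int = 0
    dp: int = 0

    def __post_init__(self):
        missing = (self.allele_a is None, self.allele_b is None)
        if any(missing) and not all(missing):
            raise ValidationError("missing genotype must have both alleles missing")
        if self.allele_a is not None:
            for a in (self.allele_a, self.allele_b):
                if a not in (0, 1):
                    raise ValidationError(f"allele index must be 0 or 1, got {a}")
        if self.gq < 0 or self.dp < 0:
            raise ValidationError("GQ and DP must be non-negative")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def code(self) -> int:
        """-1 missing, 0 hom-ref, 1 het, 2 hom-alt."""
        if self.is_missing:
            return -1
        return self.allele_a + self.allele_b

    @property
    def n_alt(self) -> int:
        return max(self.code, 0)

    @classmethod
    def from_code(cls, code: int, gq: int = 99, dp: int = 30) -> "GenotypeCall":
        if code == -1:
            return cls(None, None, gq, dp)
        if code not in (0, 1, 2):
            raise ValidationError(f"bad genotype code {code}")
        return cls(0 if code < 2 else 1, 0 if code < 1 else 1, gq, dp)


class TrioSiteRecord(NamedTuple):
    """One variant site with the three members' calls (father, mother, child)."""

    site: VariantSite
    father: GenotypeCall
    mother: GenotypeCall
    child: GenotypeCall


@dataclass(frozen=True)
class TrioPedigree:
    trio_id: str
    father_id: str
    mother_id: str
    child_id: str
    child_sex: str
    cleft_status: str = "CLP"
    country: str = "NA"

    def __post_init__(self):
        ids = {self.father_id, self.mother_id, self.child_id}
        if len(ids) != 3:
            raise ValidationError(f"trio {self.trio_id}: member ids must be distinct")
        if self.child_sex not in SEXES:
            raise ValidationError(f"trio {self.trio_id}: bad sex {self.child_sex!r}")
        if self.cleft_status not in CLEFT_STATUSES:
            raise ValidationError(
                f"trio {self.trio_id}: cleft status must be one of {CLEFT_STATUSES}"
            )

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.father_id, self.mother_id, self.child_id)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with genomic exons and transcript-relative CDS bounds.

    Exons are 1-based inclusive genomic intervals sorted by genomic start;
    ``cds_start``/``cds_end`` are 1-based positions in the spliced transcript
    (5' to 3' in transcription order).
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValidationError(f"{self.transcript_id}: bad exon [{start},{end}]")
            if start <= prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = end
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise ValidationError(f"{self.transcript_id}: CDS bounds outside transcript")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValidationError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def transcription_order_exons(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """1-based transcript coordinate of a genomic position, or None if intronic/outside."""
        offset = 0
        for start, end in self.transcription_order_exons:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start + 1)
                return offset + (end - pos + 1)
            offset += end - start + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 1 <= tpos <= self.length:
            raise ValidationError(f"{self.transcript_id}: tpos {tpos} outside transcript")
        offset = 0
        for start, end in self.transcription_order_exons:
            n = end - start + 1
            if tpos <= offset + n:
                within = tpos - offset
                return start + within - 1 if self.strand == "+" else end - within + 1
            offset += n
        raise AssertionError("unreachable")

    def spliced_sequence(self, reference: dict[str, str]) -> str:
        from Bio.Seq import Seq  # local import keeps module import light

        contig = reference[normalize_chrom(self.chrom)]
        chunks = [contig[start - 1 : end] for start, end in self.exons]
        seq = "".join(chunks)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_sequence(self, reference: dict[str, str]) -> str:
        return self.spliced_sequence(reference)[self.cds_start - 1 : self.cds_end]

    def splice_positions(self) -> tuple[set[int], set[int]]:
        """Genomic positions of canonical donor (+1/+2) and acceptor (-1/-2) bases."""
        donors: set[int] = set()
        acceptors: set[int] = set()
        exons = self.transcription_order_exons
        for upstream, downstream in zip(exons, exons[1:]):
            if self.strand == "+":
                donors.update((upstream[1] + 1, upstream[1] + 2))
                acceptors.update((downstream[0] - 1, downstream[0] - 2))
            else:
                donors.update((upstream[0] - 1, upstream[0] - 2))
                acceptors.update((downstream[1] + 1, downstream[1] + 2))
        return donors, acceptors

    def validate_against_reference(self, reference: dict[str, str]) -> None:
        cds = self.cds_sequence(reference)
        if cds[:3] != "ATG":
            raise ValidationError(f"{self.transcript_id}: first CDS codon is not ATG")


@dataclass
class FrequencyPanel:
    """A population allele-frequency panel keyed by normalized variant."""

    name: str
    freqs: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for key, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"panel {self.name}: frequency {f} at {key} outside [0,1]")

    def add(self, site: VariantSite, freq: float) -> None:
        if not 0.0 <= freq <= 1.0:
            raise ValidationError(f"panel {self.name}: frequency {freq} outside [0,1]")
        self.freqs[site.key()] = freq

    def lookup(self, site: VariantSite) -> float:
        """Frequency of the site; absent key means 0 by convention (unreported = rare)."""
        return self.freqs.get(site.key(), 0.0)


@dataclass(frozen=True)
class GeneSet:
    term: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.term} is empty")
        for g in self.genes:
            if g != g.upper():
                raise ValidationError(f"gene set {self.term}: symbol {g} not uppercase")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.term] = gene_set

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExpressionMatrix:
    """Genes x tissue-stage fluorescence intensities (non-negative)."""

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ValidationError("expression matrix has duplicated gene rows")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("expression intensities must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ScoreEntry:
    cadd_phred: Optional[float] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self):
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError("CADD phred must be >= 0")
        for name, v in (("SIFT", self.sift), ("PolyPhen", self.polyphen)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} score {v} outside [0,1]")


KNOCKOUT_PHENOTYPES = ("cleft", "craniofacial", "lethal", "none")


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-gene craniofacial evidence from knockout/CNV/SNV lookups."""

    gene: str
    knockout_phenotype: str = "none"
    cnv_report: bool = False
    snv_report: bool = False

    def __post_init__(self):
        if self.knockout_phenotype not in KNOCKOUT_PHENOTYPES:
            raise ValidationError(
                f"{self.gene}: knockout phenotype must be one of {KNOCKOUT_PHENOTYPES}"
            )

    @property
    def any_craniofacial(self) -> bool:
        return (
            self.knockout_phenotype in ("cleft", "craniofacial", "lethal")
            or self.cnv_report
            or self.snv_report
        )


@dataclass
class ResourceBundle:
    """Everything the annotation stages need, loaded from files or simulated."""

    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    panels: list[FrequencyPanel]
    scores: dict[tuple[str, int, str, str], ScoreEntry]
    evidence: dict[str, EvidenceRecord]
    gene_sets: GeneSetCollection
    expression: ExpressionMatrix

    def transcripts_by_chrom(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            out.setdefault(normalize_chrom(t.chrom), []).append(t)
        return out


@dataclass
class TrioGenotypeMatrix:
    """Array-backed genotypes of one trio across its variant sites.

    Member order is always (father, mother, child). ``gt`` holds genotype
    codes: -1 missing, 0 hom-ref, 1 het, 2 hom-alt.
    """

    sites: list[VariantSite]
    gt: np.ndarray  # (n_sites, 3) int8
    gq: np.ndarray  # (n_sites, 3) int32
    dp: np.ndarray  # (n_sites, 3) int32

    def __post_init__(self):
        n = len(self.sites)
        for arr in (self.gt, self.gq, self.dp):
            if arr.shape != (n, 3):
                raise ValidationError("genotype arrays must have shape (n_sites, 3)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([normalize_chrom(s.chrom) for s in self.sites], dtype=object)

    @property
    def x_mask(self) -> np.ndarray:
        return np.asarray([normalize_chrom(s.chrom) == "X" for s in self.sites])

    @property
    def autosome_mask(self) -> np.ndarray:
        return ~self.x_mask

    @classmethod
    def from_records(cls, records: Iterable[TrioSiteRecord]) -> "TrioGenotypeMatrix":
        sites, gts, gqs, dps = [], [], [], []
        for rec in records:
            sites.append(rec.site)
            calls = (rec.father, rec.mother, rec.child)
            gts.append([c.code for c in calls])
            gqs.append([c.gq for c in calls])
            dps.append([c.dp for c in calls])
        n = len(sites)
        return cls(
            sites=sites,
            gt=np.asarray(gts, dtype=np.int8).reshape(n, 3),
            gq=np.asarray(gqs, dtype=np.int32).reshape(n, 3),
            dp=np.asarray(dps, dtype=np.int32).reshape(n, 3),
        )

    def to_records(self) -> list[TrioSiteRecord]:
        out = []
        for i, site in enumerate(self.sites):
            calls = [
                GenotypeCall.from_code(int(self.gt[i, j]), int(self.gq[i, j]), int(self.dp[i, j]))
                for j in range(3)
            ]
            out.append(TrioSiteRecord(site, *calls))
        return out


def as_codes(genotypes) -> np.ndarray:
    """Coerce a genotype sequence (GenotypeCall objects or codes) to a code array."""
    if isinstance(genotypes, np.ndarray):
        return genotypes.astype(np.int64)
    codes = []
    for g in genotypes:
        codes.append(g.code if isinstance(g, GenotypeCall) else int(g))
    return np.asarray(codes, dtype=np.int64)
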