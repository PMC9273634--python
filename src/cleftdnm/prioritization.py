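"""Pathogenicity binning and craniofacial-evidence prioritization.

CADD bins come straight from the phred definition C = -10*log10(rank
fraction): a score of 30 marks the top 0.1% most deleterious substitutions,
20 the top 1%, 10 the top 10%. SIFT/PolyPhen class cutoffs are
configuration (HumDiv-convention defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError
from .dnm_discovery import DNMCandidate
from .models import EvidenceRecord

CADD_BINS = ("top0.1%", "top1%", "top10%", "lower")
_CADD_BIN_RANK = {b: i for i, b in enumerate(CADD_BINS)}
_IMPACT_RANK = {"protein_truncating": 0, "missense": 1, "other": 2}


@dataclass(frozen=True)
class InsilicoThresholds:
    sift_deleterious_max: float = 0.05  # strict <
    polyphen_possibly_min: float = 0.446
    polyphen_probably_min: float = 0.85


@dataclass(frozen=True)
class PathogenicityAnnotation:
    cadd_phred: Optional[float] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self):
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError("CADD phred score must be >= 0")
        for name, v in (("SIFT", self.sift), ("PolyPhen", self.polyphen)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} score {v} outside [0,1]")


@dataclass(frozen=True)
class InsilicoClasses:
    sift_label: str  # deleterious | tolerated | N/A
    polyphen_label: str  # probably_damaging | possibly_damaging | benign | N/A
    damaging_any: Optional[bool]  # None when undefined (no scores)


def cadd_bin(phred_score: float) -> str:
    """Percentile bin of a CADD phred score."""
    if phred_score < 0:
        raise ValidationError("CADD phred score must be >= 0")
    if phred_score >= 30.0:
        return "top0.1%"
    if phred_score >= 20.0:
        return "top1%"
    if phred_score >= 10.0:
        return "top10%"
    return "lower"


def insilico_classes(
    annotation: PathogenicityAnnotation,
    thresholds: InsilicoThresholds = InsilicoThresholds(),
) -> InsilicoClasses:
    """Per-tool class labels plus a combined at-least-one-damaging flag.

    Protein-truncating variants come with absent scores; both labels are then
    N/A and the combined flag is undefined (excluded from missense summaries).
    """
    if annotation.sift is None and annotation.polyphen is None:
        return InsilicoClasses("N/A", "N/A", None)
    sift_label = "N/A"
    sift_damaging = False
    if annotation.sift is not None:
        sift_damaging = annotation.sift < thresholds.sift_deleterious_max
        sift_label = "deleterious" if sift_damaging else "tolerated"
    poly_label = "N/A"
    poly_damaging = False
    if annotation.polyphen is not None:
        if annotation.polyphen >= thresholds.polyphen_probably_min:
            poly_label = "probably_damaging"
        elif annotation.polyphen >= thresholds.polyphen_possibly_min:
            poly_label = "possibly_damaging"
        else:
            poly_label = "benign"
        poly_damaging = poly_label != "benign"
    return InsilicoClasses(sift_label, poly_label, sift_damaging or poly_damaging)


def evidence_join(gene: Optional[str], evidence: dict[str, EvidenceRecord]) -> EvidenceRecord:
    """Evidence record for a gene; unknown genes get an all-none record."""
    if gene is None:
        return EvidenceRecord(gene="NA")
    return evidence.get(gene.upper(), EvidenceRecord(gene=gene.upper()))


@dataclass(frozen=True)
class PrioritizedRow:
    candidate: DNMCandidate
    evidence: EvidenceRecord
    cadd_bin: Optional[str]
    classes: InsilicoClasses


def build_prioritized_table(
    candidates: list[DNMCandidate],
    evidence: dict[str, EvidenceRecord],
) -> list[PrioritizedRow]:
    """Keep DNMs whose gene has any craniofacial evidence; deterministic order.

    Pure filter: rows are a subset of the input candidates and no annotation
    is mutated. Sort keys: impact class, CADD bin, gene.
    """
    rows = []
    for cand in candidates:
        rec = evidence_join(cand.gene, evidence)
        if not rec.any_craniofacial:
            continue
        bin_label = None if cand.cadd_phred is None else cadd_bin(cand.cadd_phred)
        rows.append(
            PrioritizedRow(
                candidate=cand,
                evidence=rec,
                cadd_bin=bin_label,
                classes=insilico_classes(
                    PathogenicityAnnotation(cand.cadd_phred, cand.sift, cand.polyphen)
                ),
            )
        )
    rows.sort(
        key=lambda r: (
            _IMPACT_RANK.get(r.candidate.impact, 9),
            _CADD_BIN_RANK.get(r.cadd_bin, 9),
            r.candidate.gene or "~",
            r.candidate.site.key(),
            r.candidate.trio_id,
        )
    )
    return rows


def prioritized_table_frame(rows: list[PrioritizedRow]):
    """Tabular (Table-1 style) view of prioritized DNMs."""
    import pandas as pd

    out = []
    for r in rows:
        c = r.candidate
        out.append(
            {
                "gene": c.gene,
                "trio_id": c.trio_id,
                "variant": f"{c.site.chrom}:{c.site.pos}{c.site.ref}>{c.site.alt}",
                "protein_change": c.protein_change or "",
                "consequence": c.consequence,
                "impact": c.impact,
                "cadd_phred": "" if c.cadd_phred is None else c.cadd_phred,
                "cadd_bin": r.cadd_bin or "N/A",
                "sift_class": r.classes.sift_label,
                "polyphen_class": r.classes.polyphen_label,
                "mouse_knockout": r.evidence.knockout_phenotype,
                "cnv_report": int(r.evidence.cnv_report),
                "snv_report": int(r.evidence.snv_report),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "gene",
            "trio_id",
            "variant",
            "protein_change",
            "consequence",
            "impact",
            "cadd_phred",
            "cadd_bin",
            "sift_class",
            "polyphen_class",
            "mouse_knockout",
            "cnv_report",
            "snv_report",
        ],
    )
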