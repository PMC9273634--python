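"""Cohort quality control: per-sample and per-trio screens.

The screen applies, per sample: missingness, X-homozygosity sex check, and a
het/hom-ratio outlier rule; per trio: Mendelian-error excess and
parent-offspring kinship. Sites out of Hardy-Weinberg equilibrium in the
founders are removed cohort-wide before any per-sample metric is computed
(site-level interpretation of the HWE rule; a sample-level variant is
available behind ``hwe_excludes_samples``).

All thresholds are strict inequalities. The SD-based outlier rules use
mean/SD computed once on the full pre-exclusion cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .errors import InsufficientDataError, ValidationError
from .models import GenotypeCall, TrioGenotypeMatrix, TrioPedigree, as_codes

__all__ = [
    "QCThresholds",
    "SampleQCMetrics",
    "TrioQCResult",
    "CohortStats",
    "QCOutcome",
    "missingness",
    "x_inbreeding_f",
    "infer_sex",
    "hwe_exact_p",
    "mendelian_consistent",
    "het_hom_ratio",
    "kinship",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    max_missingness: float = 0.10
    hwe_alpha: float = 1e-6
    mendelian_sd: float = 3.0
    hethom_sd: float = 4.0
    sex_female_max_f: float = 0.2
    sex_male_min_f: float = 0.8
    kinship_parent_min: float = 0.15
    kinship_parent_max: float = 0.35
    min_gq_for_mendelian: int = 20
    hwe_excludes_samples: bool = False  # deviation knob; default removes sites

    def __post_init__(self):
        if self.sex_female_max_f >= self.sex_male_min_f:
            raise ValidationError("female F cutoff must be below male F cutoff")
        for v in (self.max_missingness, self.hwe_alpha, self.mendelian_sd, self.hethom_sd):
            if v <= 0:
                raise ValidationError("QC thresholds must be positive")


@dataclass
class SampleQCMetrics:
    sample_id: str
    missingness: float
    het_hom_ratio: float
    x_f: Optional[float]
    inferred_sex: str
    n_sites: int
    n_x_sites: int


@dataclass
class TrioQCResult:
    trio_id: str
    mendelian_errors: int
    mendelian_rate: float
    kinship_father_child: float
    kinship_mother_child: float
    kinship_father_mother: float
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons

    @property
    def reason_categories(self) -> set[str]:
        return {r.split(":", 1)[0] for r in self.reasons}


@dataclass
class CohortStats:
    mendelian_mean: float
    mendelian_sd: float
    hethom_mean: float
    hethom_sd: float


@dataclass
class QCOutcome:
    retained: list[str]
    results: dict[str, TrioQCResult]
    sample_metrics: dict[str, SampleQCMetrics]
    excluded_sites: set
    stats: CohortStats


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def missingness(genotypes) -> float:
    """Fraction of missing genotypes in a sample's call sequence."""
    codes = as_codes(genotypes)
    if codes.size == 0:
        raise InsufficientDataError("missingness requires at least one site")
    return float(np.mean(codes == -1))


def x_inbreeding_f(genotypes, freqs) -> float:
    """X-chromosome inbreeding coefficient F = (O_hom - E_hom) / (N - E_hom).

    ``freqs`` are per-site alternate allele frequencies aligned with the
    genotype sequence; sites that are missing or monomorphic are dropped.
    """
    codes = as_codes(genotypes)
    p = np.asarray(freqs, dtype=float)
    if codes.shape != p.shape:
        raise ValidationError("genotypes and freqs must align")
    mask = (codes != -1) & (p > 0.0) & (p < 1.0)
    codes, p = codes[mask], p[mask]
    n = codes.size
    if n == 0:
        raise InsufficientDataError("no informative polymorphic X sites")
    o_hom = float(np.sum(codes != 1))
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    denom = n - e_hom
    if denom <= 0:
        raise InsufficientDataError("undefined F: all sites effectively monomorphic")
    return (o_hom - e_hom) / denom


def infer_sex(f: float, thresholds: QCThresholds = QCThresholds()) -> str:
    if f > thresholds.sex_male_min_f:
        return "male"
    if f < thresholds.sex_female_max_f:
        return "female"
    return "ambiguous"


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities that do not exceed the observed configuration's
    probability (two-sided exact test conditioned on allele counts).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValidationError("total genotype count must be >= 1")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: single attainable configuration
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (max(n_a, n_b) - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard accumulated rounding
    p_obs = probs[hets == n_het]
    if p_obs.size != 1:
        raise ValidationError("genotype counts inconsistent with allele counts")
    p = float(probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def mendelian_consistent(g_father: GenotypeCall, g_mother: GenotypeCall, g_child: GenotypeCall) -> bool:
    """True iff the child's alleles can be formed by one allele from each parent."""
    for g in (g_father, g_mother, g_child):
        if g.is_missing:
            raise ValidationError("mendelian_consistent requires non-missing genotypes")
    child = tuple(sorted((g_child.allele_a, g_child.allele_b)))
    for fa in {g_father.allele_a, g_father.allele_b}:
        for ma in {g_mother.allele_a, g_mother.allele_b}:
            if tuple(sorted((fa, ma))) == child:
                return True
    return False


def _mendelian_table() -> np.ndarray:
    """3x3x3 boolean lookup of trio genotype-code consistency."""
    table = np.zeros((3, 3, 3), dtype=bool)
    for f in range(3):
        for m in range(3):
            for c in range(3):
                table[f, m, c] = mendelian_consistent(
                    GenotypeCall.from_code(f), GenotypeCall.from_code(m), GenotypeCall.from_code(c)
                )
    return table

MENDELIAN_CONSISTENT_TABLE = _mendelian_table()


def het_hom_ratio(genotypes) -> float:
    """(# het calls) / (# non-ref homozygous calls); inf flags the degenerate case."""
    codes = as_codes(genotypes)
    n_het = int(np.sum(codes == 1))
    n_hom_alt = int(np.sum(codes == 2))
    if n_hom_alt == 0:
        return math.inf if n_het > 0 else 0.0
    return n_het / n_hom_alt


def kinship(genotypes_a, genotypes_b, min_overlap: int = 50) -> float:
    """Method-of-moments (KING-robust style) kinship coefficient.

    Expected values: duplicates ~0.5, parent-offspring ~0.25, unrelated ~0.
    Robust to allele-frequency misspecification because it uses only the two
    samples' genotype concordance pattern.
    """
    a = as_codes(genotypes_a)
    b = as_codes(genotypes_b)
    if a.shape != b.shape:
        raise ValidationError("genotype sequences must align")
    mask = (a != -1) & (b != -1)
    a, b = a[mask], b[mask]
    if a.size < min_overlap:
        raise InsufficientDataError(
            f"kinship needs >= {min_overlap} overlapping non-missing sites, got {a.size}"
        )
    n_both_het = int(np.sum((a == 1) & (b == 1)))
    n_opposite_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    denom = int(np.sum(a == 1)) + int(np.sum(b == 1))
    if denom == 0:
        raise InsufficientDataError("no heterozygous calls in either sample")
    return (n_both_het - 2.0 * n_opposite_hom) / denom


# ---------------------------------------------------------------------------
# cohort screen
# ---------------------------------------------------------------------------


def _hwe_site_screen(
    cohort: dict[str, TrioGenotypeMatrix], thresholds: QCThresholds
) -> set:
    """Identify autosomal sites out of HWE in the founders (parents) cohort-wide."""
    counts: dict[tuple, list[int]] = {}
    for trio in cohort.values():
        auto = trio.autosome_mask
        for idx in np.flatnonzero(auto):
            key = trio.sites[idx].key()
            c = counts.setdefault(key, [0, 0, 0])
            for member in (0, 1):  # founders only
                g = int(trio.gt[idx, member])
                if g != -1:
                    c[g] += 1
    excluded = set()
    for key, (n0, n1, n2) in counts.items():
        if n0 + n1 + n2 == 0:
            continue
        if hwe_exact_p(n0, n1, n2) < thresholds.hwe_alpha:
            excluded.add(key)
    return excluded


def compute_cohort_metrics(
    pedigrees: list[TrioPedigree],
    cohort: dict[str, TrioGenotypeMatrix],
    thresholds: QCThresholds = QCThresholds(),
):
    """Per-sample and per-trio metrics plus the cohort-wide site exclusions."""
    excluded_sites = _hwe_site_screen(cohort, thresholds)

    # pooled X allele frequencies across all samples
    x_counts: dict[tuple, list[int]] = {}
    for trio in cohort.values():
        for idx in np.flatnonzero(trio.x_mask):
            key = trio.sites[idx].key()
            c = x_counts.setdefault(key, [0, 0])  # [alt alleles, total alleles]
            for member in range(3):
                g = int(trio.gt[idx, member])
                if g != -1:
                    c[0] += g
                    c[1] += 2
    x_freq = {k: (c[0] / c[1] if c[1] else 0.0) for k, c in x_counts.items()}

    sample_metrics: dict[str, SampleQCMetrics] = {}
    trio_metrics: dict[str, TrioQCResult] = {}
    for ped in pedigrees:
        trio = cohort[ped.trio_id]
        keys = [s.key() for s in trio.sites]
        keep = np.asarray([k not in excluded_sites for k in keys])
        x_mask = trio.x_mask & keep
        auto_mask = trio.autosome_mask & keep
        x_idx = np.flatnonzero(x_mask)
        x_p = np.asarray([x_freq.get(keys[i], 0.0) for i in x_idx])

        for member, sample_id in enumerate(ped.sample_ids):
            codes_all = trio.gt[keep, member]
            codes_auto = trio.gt[auto_mask, member]
            codes_x = trio.gt[x_mask, member]
            try:
                f = x_inbreeding_f(codes_x, x_p)
                sex = infer_sex(f, thresholds)
            except InsufficientDataError:
                f, sex = None, "ambiguous"
            sample_metrics[sample_id] = SampleQCMetrics(
                sample_id=sample_id,
                missingness=missingness(codes_all),
                het_hom_ratio=het_hom_ratio(codes_auto),
                x_f=f,
                inferred_sex=sex,
                n_sites=int(codes_all.size),
                n_x_sites=int(codes_x.size),
            )

        gt_auto = trio.gt[auto_mask]
        gq_auto = trio.gq[auto_mask]
        complete = (gt_auto != -1).all(axis=1) & (gq_auto >= thresholds.min_gq_for_mendelian).all(axis=1)
        g = gt_auto[complete]
        n_tested = int(g.shape[0])
        if n_tested:
            consistent = MENDELIAN_CONSISTENT_TABLE[g[:, 0], g[:, 1], g[:, 2]]
            n_errors = int(np.sum(~consistent))
        else:
            n_errors = 0
        trio_metrics[ped.trio_id] = TrioQCResult(
            trio_id=ped.trio_id,
            mendelian_errors=n_errors,
            mendelian_rate=n_errors / n_tested if n_tested else 0.0,
            kinship_father_child=kinship(gt_auto[:, 0], gt_auto[:, 2]),
            kinship_mother_child=kinship(gt_auto[:, 1], gt_auto[:, 2]),
            kinship_father_mother=kinship(gt_auto[:, 0], gt_auto[:, 1]),
        )
    return sample_metrics, trio_metrics, excluded_sites


def apply_qc(
    pedigrees: list[TrioPedigree],
    cohort: dict[str, TrioGenotypeMatrix],
    thresholds: QCThresholds = QCThresholds(),
    stats: Optional[CohortStats] = None,
) -> QCOutcome:
    """Run the full QC screen; a trio is excluded iff any member fails any
    sample rule or the trio fails any trio rule.

    ``stats`` lets a caller reuse cohort mean/SD computed on the original
    pre-exclusion cohort (the screen is a single pass, not iterative).
    """
    if len(pedigrees) < 2:
        raise InsufficientDataError("SD-based QC rules need a cohort of >= 2 trios")
    sample_metrics, trio_metrics, excluded_sites = compute_cohort_metrics(
        pedigrees, cohort, thresholds
    )

    if stats is None:
        mend = np.asarray([trio_metrics[p.trio_id].mendelian_errors for p in pedigrees], dtype=float)
        ratios = np.asarray(
            [
                sample_metrics[sid].het_hom_ratio
                for p in pedigrees
                for sid in p.sample_ids
                if math.isfinite(sample_metrics[sid].het_hom_ratio)
            ]
        )
        stats = CohortStats(
            mendelian_mean=float(mend.mean()),
            mendelian_sd=float(mend.std(ddof=1)) if mend.size > 1 else 0.0,
            hethom_mean=float(ratios.mean()) if ratios.size else 0.0,
            hethom_sd=float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        )

    retained: list[str] = []
    for ped in pedigrees:
        res = trio_metrics[ped.trio_id]
        reported_sex ={ped.father_id: "male", ped.mother_id: "female", ped.child_id: ped.child_sex}
        for sample_id in ped.sample_ids:
            m = sample_metrics[sample_id]
            if m.missingness > thresholds.max_missingness:
                res.reasons.append(f"missingness:{sample_id}")
            if m.inferred_sex != reported_sex[sample_id]:
                res.reasons.append(f"sex_mismatch:{sample_id}")
            r = m.het_hom_ratio
            if not math.isfinite(r):
                res.reasons.append(f"het_hom:{sample_id}")
            elif stats.hethom_sd > 0 and abs(r - stats.hethom_mean) > thresholds.hethom_sd * stats.hethom_sd:
                res.reasons.append(f"het_hom:{sample_id}")
        if stats.mendelian_sd > 0:
            limit = stats.mendelian_mean + thresholds.mendelian_sd * stats.mendelian_sd
        else:
            limit = stats.mendelian_mean
        if res.mendelian_errors > limit:
            res.reasons.append("mendelian_outlier")
        for label, phi in (
            ("father_child", res.kinship_father_child),
            ("mother_child", res.kinship_mother_child),
        ):
            if not thresholds.kinship_parent_min <= phi <= thresholds.kinship_parent_max:
                res.reasons.append(f"relatedness:{label}")
        if res.passed:
            retained.append(ped.trio_id)
    return QCOutcome(
        retained=retained,
        results=trio_metrics,
        sample_metrics=sample_metrics,
        excluded_sites=excluded_sites,
        stats=stats,
    )
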