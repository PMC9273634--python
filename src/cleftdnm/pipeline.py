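"""End-to-end orchestration: simulate -> qc -> discover -> prioritize ->
stability -> enrich/expression, with cohort summary tables and a Markdown
report whose numbers are all derivable from the stage TSVs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io_formats
from .dnm_discovery import FilterConfig, discover_dnms
from .enrichment_expression import enrich, heat_values, tissue_contrast
from .errors import CleftDnmError, ConfigurationError
from .models import TrioPedigree
from .prioritization import build_prioritized_table, prioritized_table_frame
from .stability import read_ddg_replicates, summarize_stability, write_stability_table
from .synthetic_cohort import CohortSpec, generate_cohort, write_cohort
from .trio_qc import QCThresholds, apply_qc

log = logging.getLogger("cleftdnm")


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 1
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    ddg_replicates: Optional[str] = None  # optional TSV of folding-energy replicates
    run_enrichment: bool = True
    run_expression: bool = True
    write_cohort_files: bool = False

    def __post_init__(self):
        if self.filter_config.min_gq <= 0 or self.filter_config.min_dp <= 0:
            raise ConfigurationError("filter thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort_spec" in raw:
            kwargs["cohort_spec"] = CohortSpec(**raw.pop("cohort_spec"))
        if "qc_thresholds" in raw:
            kwargs["qc_thresholds"] = QCThresholds(**raw.pop("qc_thresholds"))
        if "filter_config" in raw:
            kwargs["filter_config"] = FilterConfig(**raw.pop("filter_config"))
        kwargs.update(raw)
        kwargs.update(overrides)  # CLI flags beat the config file
        cfg = cls(**kwargs)
        cfg.cohort_spec.seed = cfg.seed
        return cfg


@dataclass
class CohortSummary:
    """Country x cleft-status cross-tabulation with marginal totals."""

    table: pd.DataFrame  # countries x statuses, including Total row/column

    @property
    def total(self) -> int:
        return int(self.table.at["Total", "Total"])

    def count(self, country: str, status: str) -> int:
        return int(self.table.at[country, status])

    def status_total(self, status: str) -> int:
        return int(self.table.at["Total", status])


def summarize_cohort(pedigrees: list[TrioPedigree]) -> CohortSummary:
    statuses = ["CL", "CLP", "CP"]
    if not pedigrees:
        table = pd.DataFrame(0, index=["Total"], columns=statuses + ["Total"])
        return CohortSummary(table=table)
    df = pd.DataFrame(
        {"country": [p.country for p in pedigrees], "status": [p.cleft_status for p in pedigrees]}
    )
    table = pd.crosstab(df["country"], df["status"]).reindex(columns=statuses, fill_value=0)
    table = table.sort_index()
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = None
    table.columns.name = None
    return CohortSummary(table=table)


def mean_dnms_per_case(total_dnms: int, retained_trios: int, decimals: int = 1) -> float:
    """Reported DNM burden: total protein-altering DNMs / retained trios."""
    if retained_trios <= 0:
        raise ConfigurationError("retained trio count must be positive")
    return round(total_dnms / retained_trios, decimals)


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; outputs are byte-stable for a fixed config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    stage = "simulate"
    try:
        config.cohort_spec.seed = config.seed
        cohort = generate_cohort(config.cohort_spec)
        results["cohort"] = cohort
        if config.write_cohort_files:
            write_cohort(cohort, out / "cohort")
        log.info("stage=simulate trios=%d seed=%d", len(cohort.pedigrees), config.seed)

        stage = "qc"
        qc = apply_qc(cohort.pedigrees, cohort.trios, config.qc_thresholds)
        results["qc"] = qc
        retained_peds = [p for p in cohort.pedigrees if p.trio_id in set(qc.retained)]
        log.info(
            "stage=qc in=%d retained=%d thresholds=%s",
            len(cohort.pedigrees), len(qc.retained), config.qc_thresholds,
        )

        stage = "discover"
        discovery = discover_dnms(
            retained_peds,
            cohort.trios,
            cohort.resources,
            config.filter_config,
            excluded_sites=qc.excluded_sites,
        )
        results["discovery"] = discovery
        log.info("stage=discover funnel=%s", discovery.funnel.as_dict())

        stage = "prioritize"
        prioritized = build_prioritized_table(discovery.candidates, cohort.resources.evidence)
        results["prioritized"] = prioritized
        log.info("stage=prioritize dnms=%d prioritized=%d", len(discovery.candidates), len(prioritized))

        stage = "stability"
        if config.ddg_replicates:
            replicates = read_ddg_replicates(config.ddg_replicates)
            results["stability"] = {v: summarize_stability(reps) for v, reps in replicates.items()}
            write_stability_table(out / "stability.tsv", results["stability"])

        stage = "enrich"
        if config.run_enrichment and discovery.candidates:
            genes = sorted({c.gene for c in discovery.candidates if c.gene})
            if genes:
                results["enrichment"] = enrich(genes, cohort.resources.gene_sets)

        stage = "expression"
        if config.run_expression:
            genes = sorted(
                {c.gene for c in discovery.candidates if c.gene}
                & set(cohort.resources.expression.genes)
            )
            if genes:
                results["contrasts"] = tissue_contrast(
                    cohort.resources.expression, genes, "maxillary_E10.5", "mandibular_E10.5"
                )
                heat = heat_values(cohort.resources.expression, genes)
                heat.to_csv(out / "heat.tsv", sep="\t", index_label="gene")

        stage = "write"
        io_formats.write_outputs(
            {
                "dnms": discovery.candidates,
                "funnel": discovery.funnel,
                "qc_results": qc.results,
                **({"enrichment": results["enrichment"]} if "enrichment" in results else {}),
            },
            out,
        )
        prioritized_table_frame(prioritized).to_csv(out / "table1.tsv", sep="\t", index=False)
        if "contrasts" in results:
            pd.DataFrame(
                [
                    {
                        "gene": c.gene,
                        "maxillary": "" if c.intensity_a is None else c.intensity_a,
                        "mandibular": "" if c.intensity_b is None else c.intensity_b,
                        "ratio": "" if c.ratio is None else round(c.ratio, 4),
                        "elevated": "" if c.elevated is None else int(c.elevated),
                        "missing": int(c.missing),
                    }
                    for c in results["contrasts"]
                ],
                columns=["gene", "maxillary", "mandibular", "ratio", "elevated", "missing"],
            ).to_csv(out / "contrasts.tsv", sep="\t", index=False)
        _write_report(out / "report.md", config, results)
    except CleftDnmError as exc:
        raise CleftDnmError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results


def _write_report(path: Path, config: RunConfig, results: dict) -> None:
    cohort = results["cohort"]
    qc = results["qc"]
    discovery = results["discovery"]
    n_retained = len(qc.retained)
    total_dnms = len(discovery.candidates)
    mean_burden = mean_dnms_per_case(total_dnms, n_retained) if n_retained else float("nan")
    counts = sorted(discovery.per_trio_counts.values())

    lines = [
        "# Trio DNM pipeline report",
        "",
        f"- seed: {config.seed}",
        f"- trios simulated: {len(cohort.pedigrees)}",
        f"- trios retained after QC: {n_retained}",
        f"- sites removed by HWE screen: {len(qc.excluded_sites)}",
        "",
        "## Cohort summary",
        "",
        summarize_cohort(cohort.pedigrees).table.to_markdown(),
        "",
        "## Filtration funnel",
        "",
        "| stage | retained |",
        "|---|---|",
    ]
    for name, count in discovery.funnel.as_dict().items():
        lines.append(f"| {name} | {count} |")
    lines += [
        "",
        "## DNM burden",
        "",
        f"- protein-altering DNMs: {total_dnms}",
        f"- mean DNMs per case: {mean_burden}",
        f"- per-case count range: {counts[0] if counts else 0}..{counts[-1] if counts else 0}",
        "",
        "## QC exclusions",
        "",
        "| trio | reasons |",
        "|---|---|",
    ]
    for trio_id in sorted(qc.results):
        res = qc.results[trio_id]
        if not res.passed:
            lines.append(f"| {trio_id} | {';'.join(res.reasons)} |")
    lines += ["", f"## Prioritized DNMs: {len(results.get('prioritized', []))}", ""]
    if "enrichment" in results:
        lines += ["## Enrichment", "", "| term | p | significant |", "|---|---|---|"]
        for r in results["enrichment"]:
            lines.append(f"| {r.term} | {r.p_value:.4g} | {int(r.significant)} |")
        lines.append("")
    if "contrasts" in results:
        elevated = sum(1 for c in results["contrasts"] if c.elevated)
        lines += [
            "## Expression contrasts (maxillary vs mandibular, E10.5)",
            "",
            f"- genes elevated in maxillary: {elevated}/{len(results['contrasts'])}",
            "",
        ]
    path.write_text("\n".join(lines) + "\n")
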