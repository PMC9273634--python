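"""Readers and writers for the external file formats the pipeline touches.

The VCF dialect handled here is deliberately narrow: uncompressed VCF 4.x
with GT/GQ/DP FORMAT fields, which is what the simulator emits and what the
trio filters consume. Multi-allelic rows are decomposed into biallelic
records at read time; phase separators are accepted and discarded.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError
from .models import (
    EvidenceRecord,
    ExpressionMatrix,
    FrequencyPanel,
    GeneSet,
    GeneSetCollection,
    GenotypeCall,
    ResourceBundle,
    ScoreEntry,
    TranscriptModel,
    TrioPedigree,
    TrioSiteRecord,
    VariantSite,
    normalize_chrom,
    SKIPPED_CHROMS,
    VALID_CHROMS,
)

_BASES = set("ACGT")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfReadResult:
    """Records plus an accounting of everything that was not turned into one."""

    records: list[TrioSiteRecord]
    n_rows: int = 0
    n_alt_alleles: int = 0
    skipped: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _parse_gt(token: str, n_alts: int, line_no: int) -> tuple[Optional[int], Optional[int]]:
    token = token.replace("|", "/")
    parts = token.split("/")
    if len(parts) != 2:
        raise ParseError(f"malformed GT string {token!r}", line=line_no)
    alleles: list[Optional[int]] = []
    for p in parts:
        if p == ".":
            alleles.append(None)
            continue
        if not p.isdigit():
            raise ParseError(f"malformed GT string {token!r}", line=line_no)
        a = int(p)
        if a > n_alts:
            raise ParseError(f"GT allele index {a} exceeds ALT count {n_alts}", line=line_no)
        alleles.append(a)
    if (alleles[0] is None) != (alleles[1] is None):
        # half-missing genotypes are normalized to fully missing
        return (None, None)
    return (alleles[0], alleles[1])


def _parse_int_field(token: str) -> int:
    if token in (".", ""):
        return 0
    try:
        return int(token)
    except ValueError:
        return 0


def read_trio_vcf(path: str | Path, pedigree: TrioPedigree) -> VcfReadResult:
    """Read one trio's VCF into decomposed biallelic records.

    Multi-allelic rows are split one record per ALT allele; in each split
    record, genotype alleles equal to the kept ALT become 1 and every other
    allele becomes 0. Y and mitochondrial records are skipped with a counter.
    """
    path = Path(path)
    result = VcfReadResult(records=[])
    sample_cols: Optional[dict[str, int]] = None
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.split("\t")
                if len(header) < 10:
                    raise ParseError("VCF header has no sample columns", line=line_no)
                samples = header[9:]
                sample_cols = {}
                for sid in pedigree.sample_ids:
                    if sid not in samples:
                        raise ConfigurationError(
                            f"sample {sid!r} of trio {pedigree.trio_id} missing from VCF header"
                        )
                    sample_cols[sid] = 9 + samples.index(sid)
                continue
            if sample_cols is None:
                raise ParseError("VCF data line before #CHROM header", line=line_no)

            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError("truncated VCF data line", line=line_no)
            chrom = normalize_chrom(fields[0])
            result.n_rows += 1
            if chrom in SKIPPED_CHROMS:
                result.skipped[f"chrom_{chrom}"] += 1
                continue
            if chrom not in VALID_CHROMS:
                result.skipped["chrom_other"] += 1
                continue
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"bad POS {fields[1]!r}", line=line_no) from exc
            vid = None if fields[2] == "." else fields[2]
            ref = fields[3].upper()
            alts = [a.upper() for a in fields[4].split(",")]
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError as exc:
                raise ParseError("FORMAT lacks GT", line=line_no) from exc
            gq_idx = fmt.index("GQ") if "GQ" in fmt else None
            dp_idx = fmt.index("DP") if "DP" in fmt else None

            parsed: dict[str, tuple[tuple[Optional[int], Optional[int]], int, int]] = {}
            for sid, col in sample_cols.items():
                toks = fields[col].split(":")
                alleles = _parse_gt(toks[gt_idx], len(alts), line_no)
                gq = _parse_int_field(toks[gq_idx]) if gq_idx is not None and gq_idx < len(toks) else 0
                dp = _parse_int_field(toks[dp_idx]) if dp_idx is not None and dp_idx < len(toks) else 0
                parsed[sid] = (alleles, gq, dp)

            for alt_index, alt in enumerate(alts, start=1):
                if alt in ("*", ".", "<NON_REF>") or not set(alt) <= _BASES:
                    result.skipped["symbolic_alt"] += 1
                    continue
                result.n_alt_alleles += 1
                try:
                    site = VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, id=vid)
                except ValidationError as exc:
                    raise ParseError(str(exc), line=line_no) from exc
                calls = []
                for sid in pedigree.sample_ids:
                    (a, b), gq, dp = parsed[sid]
                    if a is None:
                        calls.append(GenotypeCall(None, None, gq, dp))
                    else:
                        ra = 1 if a == alt_index else 0
                        rb = 1 if b == alt_index else 0
                        calls.append(GenotypeCall(min(ra, rb), max(ra, rb), gq, dp))
                result.records.append(TrioSiteRecord(site, *calls))
    if sample_cols is None:
        raise ParseError(f"{path}: no #CHROM header found")
    return result


def write_trio_vcf(
    path: str | Path,
    pedigree: TrioPedigree,
    records: list[TrioSiteRecord],
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write biallelic trio records as an uncompressed VCF 4.2 file."""
    path = Path(path)
    gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
    ]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(pedigree.sample_ids)
    )
    ordered = sorted(
        records, key=lambda r: (_chrom_sort_key(r.site.chrom), r.site.pos, r.site.ref, r.site.alt)
    )
    for rec in ordered:
        cols = [
            rec.site.chrom,
            str(rec.site.pos),
            rec.site.id or ".",
            rec.site.ref,
            rec.site.alt,
            ".",
            "PASS",
            ".",
            "GT:GQ:DP",
        ]
        for call in (rec.father, rec.mother, rec.child):
            cols.append(f"{gt_strings[call.code]}:{call.gq}:{call.dp}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (int(c), "") if c.isdigit() else (99, c)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "male", "2": "female"}


def read_pedigree(path: str | Path) -> list[TrioPedigree]:
    """Read a 6+ column PED file, keeping only complete case-parent trios.

    Optional columns 7 and 8 carry cleft status (CL/CLP/CP) and country.
    Dyads and other incomplete families are dropped with a warning.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    order: list[str] = []
    for line_no, line in enumerate(path.open(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise ParseError("PED line has fewer than 6 columns", line=line_no)
        fam, iid, pat, mat, sex, pheno = cols[:6]
        if sex not in _PED_SEX:
            raise ParseError(f"unknown sex code {sex!r} for sample {iid}", line=line_no)
        if iid in rows:
            raise ConfigurationError(f"duplicated sample id {iid} in pedigree")
        rows[iid] = {
            "fam": fam,
            "pat": pat,
            "mat": mat,
            "sex": _PED_SEX[sex],
            "pheno": pheno,
            "cleft": cols[6] if len(cols) > 6 else "CLP",
            "country": cols[7] if len(cols) > 7 else "NA",
        }
        order.append(iid)

    trios: list[TrioPedigree] = []
    used_parents: set[str] = set()
    for iid in order:
        row = rows[iid]
        pat, mat = row["pat"], row["mat"]
        if pat == "0" or mat == "0":
            continue  # founder row
        if pat not in rows or mat not in rows:
            warnings.warn(
                f"family {row['fam']}: incomplete trio for child {iid} "
                "(dyads are excluded; only case-parent trios are analyzed)",
                UserWarning,
            )
            continue
        for pid in (pat, mat):
            if pid in used_parents:
                raise ConfigurationError(
                    f"sample {pid} appears as a parent in more than one trio"
                )
        used_parents.update((pat, mat))
        trios.append(
            TrioPedigree(
                trio_id=row["fam"],
                father_id=pat,
                mother_id=mat,
                child_id=iid,
                child_sex=row["sex"],
                cleft_status=row["cleft"],
                country=row["country"],
            )
        )
    if len({t.trio_id for t in trios}) != len(trios):
        raise ConfigurationError("duplicated trio (family) id in pedigree")
    return trios


def write_pedigree(path: str | Path, trios: list[TrioPedigree]) -> None:
    lines = []
    for t in trios:
        lines.append(f"{t.trio_id}\t{t.father_id}\t0\t0\t1\t1\t{t.cleft_status}\t{t.country}")
        lines.append(f"{t.trio_id}\t{t.mother_id}\t0\t0\t2\t1\t{t.cleft_status}\t{t.country}")
        sex = "1" if t.child_sex == "male" else "2"
        lines.append(
            f"{t.trio_id}\t{t.child_id}\t{t.father_id}\t{t.mother_id}\t{sex}\t2\t"
            f"{t.cleft_status}\t{t.country}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {normalize_chrom(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, reference: dict[str, str], width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV resources
# ---------------------------------------------------------------------------


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Transcript table: gene, transcript_id, chrom, strand, exon_starts,
    exon_ends (comma lists, 1-based inclusive), cds_start, cds_end
    (transcript-relative, 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "transcript_id", "chrom", "strand", "exon_starts", "exon_ends", "cds_start", "cds_end"}
    if not required <= set(df.columns):
        raise ValidationError(f"transcript table missing columns {required - set(df.columns)}")
    out = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise ValidationError(f"{row.transcript_id}: exon_starts/exon_ends length mismatch")
        out.append(
            TranscriptModel(
                gene=row.gene,
                transcript_id=row.transcript_id,
                chrom=normalize_chrom(row.chrom),
                strand=row.strand,
                exons=tuple(zip(starts, ends)),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return out


def write_transcripts(path: str | Path, transcripts: list[TranscriptModel]) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            {
                "gene": t.gene,
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "exon_starts": ",".join(str(s) for s, _ in t.exons),
                "exon_ends": ",".join(str(e) for _, e in t.exons),
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_frequency_panel(path: str | Path, name: Optional[str] = None) -> FrequencyPanel:
    """Panel table: chrom, pos, ref, alt, af."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    panel = FrequencyPanel(name=name or path.stem)
    for row in df.itertuples(index=False):
        af = float(row.af)
        if not 0.0 <= af <= 1.0:
            raise ValidationError(
                f"panel {panel.name}: frequency {af} at {row.chrom}:{row.pos} outside [0,1]"
            )
        site = VariantSite(normalize_chrom(str(row.chrom)), int(row.pos), str(row.ref), str(row.alt))
        panel.add(site, af)
    return panel


def write_frequency_panel(path: str | Path, panel: FrequencyPanel) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "af": f}
        for k, f in sorted(panel.freqs.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


def read_score_table(path: str | Path) -> dict[tuple[str, int, str, str], ScoreEntry]:
    """Score table: chrom, pos, ref, alt, cadd_phred, sift, polyphen (blank = N/A)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    scores = {}
    for row in df.itertuples(index=False):
        site = VariantSite(normalize_chrom(str(row.chrom)), int(row.pos), str(row.ref), str(row.alt))
        scores[site.key()] = ScoreEntry(
            cadd_phred=None if pd.isna(row.cadd_phred) else float(row.cadd_phred),
            sift=None if pd.isna(row.sift) else float(row.sift),
            polyphen=None if pd.isna(row.polyphen) else float(row.polyphen),
        )
    return scores


def write_score_table(path: str | Path, scores: dict[tuple[str, int, str, str], ScoreEntry]) -> None:
    rows = []
    for key in sorted(scores):
        e = scores[key]
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "cadd_phred": e.cadd_phred,
                "sift": e.sift,
                "polyphen": e.polyphen,
            }
        )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "cadd_phred", "sift", "polyphen"]).to_csv(
        path, sep="\t", index=False
    )


def read_evidence_table(path: str | Path) -> dict[str, EvidenceRecord]:
    """Evidence table: gene, knockout_phenotype, cnv_report, snv_report."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        gene = str(row.gene).upper()
        out[gene] = EvidenceRecord(
            gene=gene,
            knockout_phenotype=str(row.knockout_phenotype),
            cnv_report=bool(int(row.cnv_report)),
            snv_report=bool(int(row.snv_report)),
        )
    return out


def write_evidence_table(path: str | Path, evidence: dict[str, EvidenceRecord]) -> None:
    rows = [
        {
            "gene": e.gene,
            "knockout_phenotype": e.knockout_phenotype,
            "cnv_report": int(e.cnv_report),
            "snv_report": int(e.snv_report),
        }
        for e in sorted(evidence.values(), key=lambda e: e.gene)
    ]
    pd.DataFrame(rows, columns=["gene", "knockout_phenotype", "cnv_report", "snv_report"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    collection = GeneSetCollection()
    for line_no, line in enumerate(Path(path).open(), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError("GMT line needs term, description and >= 1 gene", line=line_no)
        term, desc, genes = parts[0], parts[1], parts[2:]
        collection.add(GeneSet(term=term, description=desc, genes=frozenset(g.upper() for g in genes if g)))
    return collection


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    lines = []
    for term in sorted(collection.sets):
        s = collection.sets[term]
        lines.append("\t".join([s.term, s.description] + sorted(s.genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(data=df)


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_resources(paths: dict[str, str | Path]) -> ResourceBundle:
    """Load the full resource bundle from a path mapping.

    Required keys: reference, transcripts, panels (list), scores, evidence,
    gene_sets, expression.
    """
    reference = read_fasta(paths["reference"])
    transcripts = read_transcripts(paths["transcripts"])
    for t in transcripts:
        if normalize_chrom(t.chrom) not in reference:
            raise ValidationError(f"{t.transcript_id}: chromosome {t.chrom} not in reference")
        t.validate_against_reference(reference)
    panel_paths = paths["panels"]
    if isinstance(panel_paths, (str, Path)):
        panel_paths = [panel_paths]
    panels = [read_frequency_panel(p) for p in panel_paths]
    return ResourceBundle(
        reference=reference,
        transcripts=transcripts,
        panels=panels,
        scores=read_score_table(paths["scores"]),
        evidence=read_evidence_table(paths["evidence"]),
        gene_sets=read_gmt(paths["gene_sets"]),
        expression=read_expression_matrix(paths["expression"]),
    )


def write_resources(out_dir: str | Path, bundle: ResourceBundle) -> dict[str, object]:
    """Write a bundle into a directory; returns the path mapping read_resources accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {
        "reference": out / "reference.fa",
        "transcripts": out / "transcripts.tsv",
        "scores": out / "scores.tsv",
        "evidence": out / "evidence.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "expression": out / "expression.tsv",
    }
    write_fasta(paths["reference"], bundle.reference)
    write_transcripts(paths["transcripts"], bundle.transcripts)
    write_score_table(paths["scores"], bundle.scores)
    write_evidence_table(paths["evidence"], bundle.evidence)
    write_gmt(paths["gene_sets"], bundle.gene_sets)
    write_expression_matrix(paths["expression"], bundle.expression)
    panel_paths = []
    for panel in bundle.panels:
        p = out / f"panel_{panel.name}.tsv"
        write_frequency_panel(p, panel)
        panel_paths.append(p)
    paths["panels"] = panel_paths
    return paths


# ---------------------------------------------------------------------------
# Pipeline outputs
# ---------------------------------------------------------------------------

DNM_TABLE_COLUMNS = [
    "trio_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "transcript_id",
    "consequence",
    "impact",
    "protein_change",
    "max_maf",
    "cadd_phred",
    "sift",
    "polyphen",
]


def write_outputs(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard report tables; outputs are byte-stable given fixed inputs."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: dict[str, Path] = {}

    if "dnms" in results:
        rows = []
        for d in results["dnms"]:
            rows.append(
                {
                    "trio_id": d.trio_id,
                    "gene": d.gene,
                    "chrom": d.site.chrom,
                    "pos": d.site.pos,
                    "ref": d.site.ref,
                    "alt": d.site.alt,
                    "transcript_id": d.transcript_id,
                    "consequence": d.consequence,
                    "impact": d.impact,
                    "protein_change": d.protein_change or "",
                    "max_maf": d.max_maf,
                    "cadd_phred": "" if d.cadd_phred is None else d.cadd_phred,
                    "sift": "" if d.sift is None else d.sift,
                    "polyphen": "" if d.polyphen is None else d.polyphen,
                }
            )
        df = pd.DataFrame(rows, columns=DNM_TABLE_COLUMNS)
        df = df.sort_values(["trio_id", "chrom", "pos", "ref", "alt"], kind="mergesort")
        path = out / "dnms.tsv"
        df.to_csv(path, sep="\t", index=False)
        written["dnms"] = path

    if "funnel" in results:
        funnel = results["funnel"]
        df = pd.DataFrame({"stage": funnel.stage_names, "retained": funnel.counts})
        path = out / "funnel.tsv"
        df.to_csv(path, sep="\t", index=False)
        written["funnel"] = path

    if "qc_results" in results:
        rows = []
        for trio_id in sorted(results["qc_results"]):
            res = results["qc_results"][trio_id]
            rows.append(
                {
                    "trio_id": trio_id,
                    "pass": int(res.passed),
                    "reasons": ";".join(res.reasons),
                    "mendelian_errors": res.mendelian_errors,
                    "kinship_father_child": round(res.kinship_father_child, 6),
                    "kinship_mother_child": round(res.kinship_mother_child, 6),
                }
            )
        path = out / "qc_exclusions.tsv"
        pd.DataFrame(
            rows,
            columns=[
                "trio_id",
                "pass",
                "reasons",
                "mendelian_errors",
                "kinship_father_child",
                "kinship_mother_child",
            ],
        ).to_csv(path, sep="\t", index=False)
        written["qc_exclusions"] = path

    if "enrichment" in results:
        rows = [
            {
                "term": r.term,
                "overlap": r.k,
                "query_size": r.n,
                "set_size": r.K,
                "background": r.N,
                "p_value": r.p_value,
                "significant": int(r.significant),
            }
            for r in results["enrichment"]
        ]
        path = out / "enrichment.tsv"
        pd.DataFrame(
            rows,
            columns=["term", "overlap", "query_size", "set_size", "background", "p_value", "significant"],
        ).to_csv(path, sep="\t", index=False)
        written["enrichment"] = path

    return written


def read_dnm_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
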