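"""Folding free-energy arithmetic and the >1 kcal/mol disease rule.

The molecular-dynamics estimation of the per-replicate folded/unfolded free
energies happens upstream; this module only subtracts, summarizes replicates
and classifies.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import InsufficientDataError, ValidationError

DISEASE_DDG_THRESHOLD = 1.0  # kcal/mol, strict >


@dataclass(frozen=True)
class FoldingEnergyReplicate:
    dg_folded: float  # kcal/mol
    dg_unfolded: float  # kcal/mol
    replicate_id: str = "r1"

    def __post_init__(self):
        if not (math.isfinite(self.dg_folded) and math.isfinite(self.dg_unfolded)):
            raise ValidationError("free energies must be finite")


@dataclass(frozen=True)
class StabilityResult:
    ddg_mean: float  # kcal/mol
    ddg_sd: float  # sample SD, kcal/mol
    n_replicates: int
    destabilizing: bool  # mean > 0
    disease_likely: bool  # mean > 1 kcal/mol


def ddg(replicate: FoldingEnergyReplicate) -> float:
    """Folding free-energy change: dG_folded - dG_unfolded (kcal/mol)."""
    return replicate.dg_folded - replicate.dg_unfolded


def summarize_stability(replicates: Iterable[FoldingEnergyReplicate]) -> StabilityResult:
    """Mean/sample-SD over replicates plus the destabilizing / disease flags.

    SD uses the n-1 denominator and is 0 for a single replicate. Flags use
    strict inequalities: mean exactly 0 is not destabilizing, mean exactly
    1 kcal/mol is not disease-likely.
    """
    values = [ddg(r) for r in replicates]
    if not values:
        raise InsufficientDataError("summarize_stability needs >= 1 replicate")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return StabilityResult(
        ddg_mean=mean,
        ddg_sd=sd,
        n_replicates=len(values),
        destabilizing=mean > 0.0,
        disease_likely=mean > DISEASE_DDG_THRESHOLD,
    )


def read_ddg_replicates(path: str | Path) -> dict[str, list[FoldingEnergyReplicate]]:
    """Replicate table: variant, replicate, dg_folded, dg_unfolded."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[FoldingEnergyReplicate]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.variant), []).append(
            FoldingEnergyReplicate(
                dg_folded=float(row.dg_folded),
                dg_unfolded=float(row.dg_unfolded),
                replicate_id=str(row.replicate),
            )
        )
    return out


def write_stability_table(path: str | Path, results: dict[str, StabilityResult]) -> None:
    rows = [
        {
            "variant": variant,
            "ddg_mean": round(r.ddg_mean, 6),
            "ddg_sd": round(r.ddg_sd, 6),
            "n_replicates": r.n_replicates,
            "destabilizing": int(r.destabilizing),
            "disease_likely": int(r.disease_likely),
        }
        for variant, r in sorted(results.items())
    ]
    pd.DataFrame(
        rows, columns=["variant", "ddg_mean", "ddg_sd", "n_replicates", "destabilizing", "disease_likely"]
    ).to_csv(path, sep="\t", index=False)
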