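"""Efficiency-corrected qPCR quantification and nonparametric comparisons.

Amplification efficiency E is estimated from a 3-fold dilution series
(five steps, triplicate wells) as E = 10^(-1/slope), where the slope is
the least-squares regression of Cq on log10 relative input; E = 2 is
perfect per-cycle doubling. Relative expression between infarct and remote
tissue uses the efficiency-corrected (Pfaffl) ratio

    R = E_target^(Cq_target,control - Cq_target,case)
        / E_ref^(Cq_ref,control - Cq_ref,case)

with control = remote and case = infarct, so R < 1 means lower in the
infarct. Reference-gene stability is summarized as mean Cq and SD per
(chemistry x preservation x assay) cell; group comparisons use the
Wilcoxon signed-rank test and Spearman's rho at p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import CqRecord, EfficiencyFit, ModelIOError

WILCOXON_EXACT_MAX_N = 15


@dataclass(frozen=True)
class DilutionSeries:
    """Cq observations over a dilution ladder for one assay.

    ``points`` are (relative input amount, Cq) pairs; the study design is
    five 3-fold steps (1/3 .. 1/243), each in triplicate.
    """

    assay: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if any(amount <= 0 for amount, _ in self.points):
            raise ModelIOError(f"{self.assay}: non-positive relative input")
        if len({amount for amount, _ in self.points}) < 3:
            raise ModelIOError(f"{self.assay}: need >= 3 distinct dilution levels")


def fit_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Standard-curve fit: Cq on log10(relative input).

    The fit is rejected (raised) when the implied efficiency leaves
    (1, 2.2] — slower than no amplification or implausibly above doubling.
    """
    x = np.log10([amount for amount, _ in series.points])
    y = np.array([cq for _, cq in series.points])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ModelIOError(f"{series.assay}: non-negative dilution slope")
    efficiency = 10.0 ** (-1.0 / res.slope)
    if not 1 < efficiency <= 2.2:
        raise ModelIOError(
            f"{series.assay}: efficiency {efficiency:.3f} outside (1, 2.2]"
        )
    return EfficiencyFit(
        assay=series.assay,
        slope=float(res.slope),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
    )


def pfaffl_ratio(
    e_target: float,
    cq_target_control: float,
    cq_target_case: float,
    e_ref: float,
    cq_ref_control: float,
    cq_ref_case: float,
) -> float:
    """Efficiency-corrected relative expression of case vs. control.

    With both efficiencies equal to 2 this reduces to 2^-ddCq.
    """
    for e in (e_target, e_ref):
        if not 1 < e <= 2.2:
            raise ModelIOError(f"efficiency {e} outside (1, 2.2]")
    return float(
        e_target ** (cq_target_control - cq_target_case)
        / e_ref ** (cq_ref_control - cq_ref_case)
    )


def rg_stability(records: Sequence[CqRecord]) -> pd.DataFrame:
    """Mean Cq and sample SD per (chemistry, preservation, assay) cell."""
    if not records:
        raise ModelIOError("no Cq records")
    df = pd.DataFrame(
        {
            "chemistry": [r.chemistry for r in records],
            "preservation": [r.preservation for r in records],
            "assay": [r.assay for r in records],
            "Cq": [r.Cq for r in records],
        }
    )
    grouped = df.groupby(["chemistry", "preservation", "assay"])["Cq"]
    if (grouped.count() < 2).any():
        raise ModelIOError("need >= 2 Cq records per reported cell")
    out = grouped.agg(mean_cq="mean", sd_cq=lambda s: s.std(ddof=1)).reset_index()
    return out.sort_values(["chemistry", "preservation", "assay"], ignore_index=True)


class GroupComparison(NamedTuple):
    wilcoxon_p: Optional[float]
    spearman_rho: Optional[float]
    spearman_p: Optional[float]
    significant: Optional[bool]
    degenerate: bool


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Paired Wilcoxon signed-rank test plus Spearman correlation.

    The signed-rank p-value uses the exact null distribution up to
    n = 15 pairs and the normal approximation beyond; Spearman uses
    average ranks for ties. All-zero differences are degenerate (the
    signed-rank statistic is undefined) and yield no p-value.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape:
        raise ModelIOError("paired samples must align")
    if xa.size < 5:
        raise ModelIOError("need >= 5 pairs for a p-value")
    rho, rho_p = stats.spearmanr(xa, ya)
    diffs = xa - ya
    if np.all(diffs == 0):
        return GroupComparison(None, float(rho), float(rho_p), None, True)
    method = "exact" if xa.size <= WILCOXON_EXACT_MAX_N else "approx"
    try:
        w = stats.wilcoxon(xa, ya, method=method)
    except ValueError:  # exact method refuses zero differences
        w = stats.wilcoxon(xa, ya, method="approx")
    return GroupComparison(
        float(w.pvalue), float(rho), float(rho_p), bool(w.pvalue < alpha), False
    )


def sample_ratios(
    records: Sequence[CqRecord],
    target: str,
    reference: str,
    e_target: float,
    e_ref: float,
) -> pd.DataFrame:
    """Per-sample Pfaffl ratios (infarct vs. remote) for one target/RG pair.

    Replicate Cqs are averaged within (sample, tissue, assay) before the
    ratio is formed, one ratio per (sample, preservation, chemistry).
    """
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "tissue": [r.tissue for r in records],
            "preservation": [r.preservation for r in records],
            "chemistry": [r.chemistry for r in records],
            "assay": [r.assay for r in records],
            "Cq": [r.Cq for r in records],
        }
    )
    keys = ["sample_id", "preservation", "chemistry"]
    mean_cq = df.groupby(keys + ["tissue", "assay"])["Cq"].mean()
    rows = []
    for key, _ in df.groupby(keys):
        try:
            cqs = {
                (tissue, assay): mean_cq[(*key, tissue, assay)]
                for tissue in ("infarct", "remote")
                for assay in (target, reference)
            }
        except KeyError:
            continue  # sample lacks a needed assay/tissue combination
        ratio = pfaffl_ratio(
            e_target,
            cqs[("remote", target)],
            cqs[("infarct", target)],
            e_ref,
            cqs[("remote", reference)],
            cqs[("infarct", reference)],
        )
        rows.append(dict(zip(keys, key)) | {"ratio": ratio})
    return pd.DataFrame(rows)


__all__ = [
    "DilutionSeries",
    "fit_efficiency",
    "pfaffl_ratio",
    "rg_stability",
    "compare_groups",
    "GroupComparison",
    "sample_ratios",
    "WILCOXON_EXACT_MAX_N",
]
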