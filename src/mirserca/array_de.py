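"""Dual-color miRNA microarray processing and differential expression.

Stages, in the order a two-channel experiment flows through them:
background subtraction (running-median local regression over probe index),
cyclic LOWESS normalization of the two channels, 3-of-5 replicate
detection calls, dye-swap-balanced log2 ratios, a per-miRNA one-sample
t-test against 0 (p < 0.01, no multiple-testing correction), and
average-linkage hierarchical clustering of the DE log2 matrix for heat-map
row ordering.

Three arrays are hybridized in both dye orientations (Cy3/Cy5 and the
swap); each miRNA probe is replicated five times per channel. The tissue
on channel 1 is infarct in the forward orientation and remote in the swap,
so the balanced ratio (M_forward - M_swap)/2 estimates log2(infarct/remote)
with additive dye effects cancelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model_io import ModelIOError, ProbeMeasurement, ScreenConfig

BACKGROUND_WINDOW = 21  # probes, running-median local regression
LOWESS_FRAC = 0.4
LOWESS_MAX_ITER = 10
LOWESS_TOL = 0.01
INTENSITY_FLOOR = 1.0
MIN_PROBES = 30


@dataclass
class ArrayExperiment:
    """Measurements of 3 dual-color arrays, each in forward and swap
    orientation, 5 replicate probes per miRNA per channel."""

    measurements: list[ProbeMeasurement]
    detection_level: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def array_ids(self) -> list[str]:
        return sorted({m.array_id for m in self.measurements})

    @property
    def mirna_names(self) -> list[str]:
        return sorted({m.mirna_name for m in self.measurements})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": [m.array_id for m in self.measurements],
                "orientation": [m.orientation for m in self.measurements],
                "mirna": [m.mirna_name for m in self.measurements],
                "replicate": [m.replicate for m in self.measurements],
                "channel": [m.channel for m in self.measurements],
                "signal": [m.signal for m in self.measurements],
                "background": [m.background for m in self.measurements],
            }
        )


def correct_background(
    signal: Sequence[float],
    background: Sequence[float],
    window: int = BACKGROUND_WINDOW,
    floor: float = INTENSITY_FLOOR,
) -> np.ndarray:
    """Subtract a running-median smooth of the background, clamped at a floor.

    Smoothing the background estimate along the probe index before
    subtracting removes spatial background gradients without chasing
    probe-level background noise.
    """
    sig = np.asarray(signal, dtype=float)
    bg = np.asarray(background, dtype=float)
    if np.any(sig < 0):
        raise ModelIOError("negative raw signal")
    smoothed = (
        pd.Series(bg).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    return np.maximum(sig - smoothed, floor)


def detection_call(replicates: Sequence[float], level: float, min_above: int = 3) -> bool:
    """True iff strictly more-than-``level`` intensity in >= 3 of 5 replicates."""
    if len(replicates) != 5:
        raise ModelIOError(f"expected 5 replicate probes, got {len(replicates)}")
    return sum(1 for r in replicates if r > level) >= min_above


def cyclic_lowess(
    log2_matrix: np.ndarray,
    frac: float = LOWESS_FRAC,
    max_iter: int = LOWESS_MAX_ITER,
    tol: float = LOWESS_TOL,
) -> np.ndarray:
    """Cyclic LOWESS normalization of a probes x channels log2 matrix.

    Each channel pair is brought onto a common intensity scale by fitting
    a LOWESS of M (difference) on A (average) and moving half the fitted
    trend out of each channel, preserving per-probe total intensity A.
    Iterates until max |median M| over pairs < tol, or ``max_iter`` sweeps.
    """
    x = np.array(log2_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n < MIN_PROBES:
        raise ModelIOError(f"need >= {MIN_PROBES} probes for LOWESS, got {n}")
    if k < 2:
        return x
    def worst_median() -> float:
        return max(
            abs(float(np.median(x[:, a] - x[:, b_])))
            for a in range(k)
            for b_ in range(a + 1, k)
        )

    for _ in range(max_iter):
        if worst_median() < tol:  # already normalized: leave untouched
            break
        for a in range(k):
            for b_ in range(a + 1, k):
                m = x[:, a] - x[:, b_]
                av = 0.5 * (x[:, a] + x[:, b_])
                fit = lowess(m, av, frac=frac, return_sorted=False)
                x[:, a] -= fit / 2
                x[:, b_] += fit / 2
    return x


def dye_swap_ratio(m_forward: float, m_swap: float):
    """Dye-swap-balanced log2 ratio: (M_forward - M_swap) / 2."""
    return (np.asarray(m_forward) - np.asarray(m_swap)) / 2.0


class DEResult(NamedTuple):
    mean_log2: float
    p_value: Optional[float]
    de: bool
    degenerate: bool


def de_test(ratios: Sequence[float], alpha: float = 0.01) -> DEResult:
    """Two-sided one-sample t-test of the balanced ratios against 0.

    Follows the study's decision rule: differential expression iff
    p < alpha (0.01), with no multiple-testing correction. Fewer than two
    ratios, or zero variance, is degenerate: no p-value is produced.
    """
    r = np.asarray(ratios, dtype=float)
    mean = float(r.mean()) if r.size else 0.0
    if r.size < 2 or float(np.var(r)) == 0.0:
        return DEResult(mean, None, False, True)
    t, p = stats.ttest_1samp(r, 0.0)
    return DEResult(mean, float(p), bool(p < alpha), False)


def _row_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows get distance 1 to all."""
    m = np.asarray(matrix, dtype=float)
    sd = m.std(axis=1)
    n = m.shape[0]
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    ok = sd > 0
    if ok.sum() >= 2:
        corr = np.corrcoef(m[ok])
        d[np.ix_(ok, ok)] = 1.0 - corr
        np.fill_diagonal(d, 0.0)
    return squareform(np.clip(d, 0.0, 2.0), checks=False)


def average_linkage(matrix: np.ndarray) -> np.ndarray:
    """Average-linkage tree on 1 - Pearson row distance."""
    if matrix.shape[0] < 2:
        raise ModelIOError("need >= 2 rows to cluster")
    return hierarchy.linkage(_row_distance(matrix), method="average")

def cluster_order(log2_frame: pd.DataFrame) -> list[str]:
    """Heat-map leaf order of miRNA rows (labels = index).

    Rows are sorted by label before clustering so that ties in the
    distance matrix break deterministically by row label.
    """
    frame = log2_frame.sort_index()
    z = average_linkage(frame.to_numpy())
    leaves = hierarchy.leaves_list(z)
    return [frame.index[i] for i in leaves]


# ---------------------------------------------------------------------------
# experiment-level pipeline


def balanced_ratios(exp: ArrayExperiment) -> pd.DataFrame:
    """Per (miRNA, array, replicate) dye-swap-balanced log2 ratios.

    Runs background correction and cyclic LOWESS per hybridization, forms
    M = log2(ch1) - log2(ch2), and balances forward against swap.
    """
    df = exp.frame().sort_values(["mirna", "replicate"], kind="stable")
    m_tables = {}
    for (array_id, orientation), sub in df.groupby(["array_id", "orientation"]):
        ch = {}
        for channel, chsub in sub.groupby("channel"):
            chsub = chsub.sort_values(["mirna", "replicate"], kind="stable")
            ch[channel] = (
                chsub.set_index(["mirna", "replicate"]),
                correct_background(chsub["signal"], chsub["background"]),
            )
        if set(ch) != {"ch1", "ch2"}:
            raise ModelIOError(f"{array_id}/{orientation}: missing channel")
        idx = ch["ch1"][0].index
        if not idx.equals(ch["ch2"][0].index):
            raise ModelIOError(f"{array_id}/{orientation}: probe sets differ")
        mat = np.log2(np.column_stack([ch["ch1"][1], ch["ch2"][1]]))
        norm = cyclic_lowess(mat)
        m_tables[(array_id, orientation)] = pd.Series(
            norm[:, 0] - norm[:, 1], index=idx
        )
    rows = []
    for array_id in exp.array_ids:
        fwd = m_tables.get((array_id, "forward"))
        swp = m_tables.get((array_id, "swap"))
        if fwd is None or swp is None:
            raise ModelIOError(f"{array_id}: missing dye orientation")
        bal = (fwd - swp.reindex(fwd.index)) / 2.0
        for (mirna, replicate), value in bal.items():
            rows.append(
                {"mirna": mirna, "array_id": array_id, "replicate": replicate,
                 "ratio": value}
            )
    return pd.DataFrame(rows)


def detected_mirnas(exp: ArrayExperiment) -> set[str]:
    """miRNAs passing the 3-of-5 detection call in every hybridization
    (on at least one channel of each)."""
    df = exp.frame()
    out = set(exp.mirna_names)
    for (_, _), sub in df.groupby(["array_id", "orientation"]):
        # one channel passing suffices for the hybridization
        passed = set()
        for mirna, msub in sub.groupby("mirna"):
            ok = False
            for channel in ("ch1", "ch2"):
                reps = msub[msub["channel"] == channel].sort_values("replicate")
                sig = correct_background(reps["signal"], reps["background"])
                if detection_call(sig, exp.detection_level):
                    ok = True
                    break
            if ok:
                passed.add(mirna)
        out &= passed
    return out


def analyze_experiment(
    exp: ArrayExperiment, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Full array stage: detection, balanced ratios, per-miRNA DE t-test."""
    config = config or ScreenConfig()
    detected = detected_mirnas(exp)
    ratios = balanced_ratios(exp)
    rows = []
    for mirna, sub in ratios.groupby("mirna"):
        res = de_test(sub["ratio"].to_numpy(), alpha=config.de_alpha)
        rows.append(
            {
                "mirna": mirna,
                "detected": mirna in detected,
                "mean_log2": res.mean_log2,
                "p_value": res.p_value,
                "de": bool(res.de and mirna in detected),
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows).sort_values("mirna", ignore_index=True)


__all__ = [
    "ArrayExperiment",
    "correct_background",
    "detection_call",
    "cyclic_lowess",
    "dye_swap_ratio",
    "de_test",
    "DEResult",
    "cluster_order",
    "average_linkage",
    "balanced_ratios",
    "detected_mirnas",
    "analyze_experiment",
]
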