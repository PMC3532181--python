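"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and emits
ground truth alongside the data so recovery can be scored directly. The
defaults emulate the study's conditions: ~800-nt 3'-UTRs, three dual-color
arrays hybridized in both dye orientations with 5 replicate probes per
miRNA, intensity-dependent dye bias, and Cq tables with per-assay
efficiencies plus an FFPE-vs-RNAlater shift in mean and spread.

A single pipeline seed fans out to per-generator streams by stable name
hashing, so adding a generator never perturbs existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .flank_fold import fold_mfe
from .model_io import (
    CqRecord,
    MatureMiRNA,
    ModelIOError,
    NNParameterTable,
    ProbeMeasurement,
    UTRRegion,
)
from .array_de import ArrayExperiment
from .qpcr import DilutionSeries
from .seed_scan import revcomp

ACCESSIBLE_FLANK_CEILING = -5.0  # kcal/mol: flank must fold at least this weakly
INACCESSIBLE_FLANK_FLOOR = -25.0  # kcal/mol: hairpin flank must fold at most this
MAX_RESAMPLES = 1000


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream under one pipeline seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def gen_utr(
    length: int = 800,
    gc_fraction: float = 0.45,
    seed: int = 0,
    transcript_id: str = "synthetic-utr",
) -> UTRRegion:
    """Random i.i.d. UTR at the requested GC fraction."""
    if length <= 0:
        raise ModelIOError("length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ModelIOError("gc_fraction outside [0, 1]")
    rng = rng_for(seed, f"utr:{transcript_id}")
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    seq = "".join(rng.choice(list("ACGU"), size=length, p=p))
    return UTRRegion(transcript_id=transcript_id, sequence=seq)


@dataclass(frozen=True)
class PlantSpec:
    """A site to plant: miRNA, 1-based start, and flank accessibility."""

    mirna: MatureMiRNA
    position: int
    accessible: bool = True
    hairpin_arm: int = 16
    flank_width: int = 70

    def __post_init__(self):
        if not self.accessible and self.hairpin_arm < 8:
            raise ModelIOError("hairpin arms must be >= 8 nt")


def _sample_open_flank(rng: np.random.Generator, length: int) -> str:
    # A/C-rich: no intra-flank pairs, so the window folds weakly
    return "".join(rng.choice(list("AC"), size=length, p=[0.6, 0.4]))


def _hairpin(arm: int, loop: int = 4) -> str:
    return "G" * arm + "A" * loop + "C" * arm


def plant_site(
    utr: UTRRegion,
    spec: PlantSpec,
    params: NNParameterTable,
    seed: int = 0,
) -> tuple[UTRRegion, dict]:
    """Write the reverse complement of the miRNA into the UTR.

    For an accessible plant, both flanking windows are rejection-sampled
    (unpairable-alphabet proposals) until each folds no lower than
    -5 kcal/mol. For an inaccessible plant, a deep G/C hairpin is written
    into each flank so both windows fold below -25 kcal/mol — under the
    one-flank accessibility criterion a site stays accessible as long as
    either side is open, so occluding it requires structure on both.
    """
    m = spec.mirna.sequence
    if m is None:
        raise ModelIOError(f"{spec.mirna.name}: no sequence")
    site_seq = revcomp(m)
    start, end = spec.position, spec.position + len(site_seq) - 1
    if start < 1 or end > len(utr):
        raise ModelIOError("planted interval outside UTR")
    rng = rng_for(seed, f"plant:{spec.mirna.name}:{spec.position}")
    chars = list(utr.sequence)
    chars[start - 1 : end] = site_seq

    f5_lo, f5_hi = max(1, start - spec.flank_width), start - 1
    f3_lo, f3_hi = end + 1, min(len(utr), end + spec.flank_width)

    def fill(lo: int, hi: int, flank_seq: str) -> None:
        chars[lo - 1 : hi] = flank_seq

    for lo, hi in ((f5_lo, f5_hi), (f3_lo, f3_hi)):
        if hi < lo:
            continue
        width = hi - lo + 1
        if spec.accessible:
            for attempt in range(MAX_RESAMPLES):
                cand = _sample_open_flank(rng, width)
                if fold_mfe(cand, params).mfe >= ACCESSIBLE_FLANK_CEILING:
                    break
            else:
                raise ModelIOError("could not sample an open flank")
            fill(lo, hi, cand)
        else:
            hp = _hairpin(spec.hairpin_arm)
            if len(hp) > width:
                raise ModelIOError("flank too short for the requested hairpin")
            pad = _sample_open_flank(rng, width - len(hp))
            cand = hp + pad if lo == f3_lo else pad + hp
            if fold_mfe(cand, params).mfe > INACCESSIBLE_FLANK_FLOOR:
                raise ModelIOError("hairpin flank folded too weakly")
            fill(lo, hi, cand)

    truth = {
        "mirna": spec.mirna.name,
        "start": start,
        "end": end,
        "accessible": spec.accessible,
    }
    return UTRRegion(utr.transcript_id, "".join(chars), utr.isoform_label), truth


# ---------------------------------------------------------------------------
# arrays


def gen_array_experiment(
    n_mirnas: int = 36,
    de_effects: dict[str, float] | None = None,
    dye_bias_amplitude: float = 0.6,
    seed: int = 0,
    n_arrays: int = 3,
    n_replicates: int = 5,
    noise_sd: float = 0.35,
    detection_level: float = 50.0,
) -> ArrayExperiment:
    """Three dual-color arrays with dye swap and planted log2 effects.

    Baselines are log-normal, the background has a smooth spatial gradient,
    and channel 1 carries a sigmoid intensity-dependent dye bias that the
    cyclic LOWESS stage must remove. ``de_effects`` maps miRNA names to
    planted log2(infarct/remote) effects; unnamed miRNAs are null.
    """
    if n_mirnas < 30:
        raise ModelIOError("need >= 30 miRNA probes for LOWESS support")
    de_effects = de_effects or {}
    rng = rng_for(seed, "arrays")
    names = [f"mir-synth-{i:03d}" for i in range(1, n_mirnas + 1)]
    unknown = set(de_effects) - set(names)
    if unknown:
        raise ModelIOError(f"effects for unknown probes: {sorted(unknown)}")
    base = rng.normal(10.0, 1.2, size=n_mirnas)  # log2 baseline intensity
    effects = np.array([de_effects.get(n, 0.0) for n in names])
    if not np.all(np.isfinite(effects)):
        raise ModelIOError("non-finite planted effect")

    measurements = []
    n_probes = n_mirnas * n_replicates
    for a in range(1, n_arrays + 1):
        for orientation in ("forward", "swap"):
            # smooth background gradient along the probe index
            idx = np.arange(n_probes)
            bg_true = 120.0 + 40.0 * idx / n_probes + rng.normal(0, 3.0, n_probes)
            pos = 0
            for mi, name in enumerate(names):
                for rep in range(1, n_replicates + 1):
                    infarct = base[mi] + effects[mi] / 2 + rng.normal(0, noise_sd)
                    remote = base[mi] - effects[mi] / 2 + rng.normal(0, noise_sd)
                    ch1_expr = infarct if orientation == "forward" else remote
                    ch2_expr = remote if orientation == "forward" else infarct
                    a_level = (ch1_expr + ch2_expr) / 2
                    bias = dye_bias_amplitude / (1 + np.exp(-(a_level - 10.0)))
                    ch1 = ch1_expr + bias
                    ch2 = ch2_expr
                    for channel, x in (("ch1", ch1), ("ch2", ch2)):
                        measurements.append(
                            ProbeMeasurement(
                                array_id=f"array{a}",
                                orientation=orientation,
                                mirna_name=name,
                                replicate=rep,
                                channel=channel,
                                signal=float(2.0**x + bg_true[pos]),
                                background=float(
                                    bg_true[pos] + rng.normal(0, 2.0)
                                ),
                            )
                        )
                    pos += 1
    return ArrayExperiment(
        measurements=measurements,
        detection_level=detection_level,
        ground_truth={"effects": dict(zip(names, map(float, effects)))},
    )


# ---------------------------------------------------------------------------
# qPCR


def gen_qpcr(
    assays: dict[str, float] | None = None,
    group_shifts: dict[str, float] | None = None,
    preservation_shift: float = 3.0,
    preservation_sd_factor: float = 2.0,
    seed: int = 0,
    n_samples: int = 6,
    noise_sd: float = 0.15,
    reference: str = "RNU6B",
) -> tuple[list[CqRecord], dict[str, DilutionSeries], dict]:
    """Cq tables plus dilution series with planted efficiencies and shifts.

    ``assays`` maps assay name to true amplification efficiency;
    ``group_shifts`` maps target assays to log2(infarct/remote) expression
    shifts (the reference stays flat). FFPE records get the configured
    mean Cq shift and SD inflation relative to RNAlater.
    """
    assays = assays or {reference: 2.0, "mir-synth-t1": 2.0}
    group_shifts = group_shifts or {}
    for name, e in assays.items():
        if not 1 < e <= 2.2:
            raise ModelIOError(f"{name}: efficiency {e} outside (1, 2.2]")
    rng = rng_for(seed, "qpcr")
    baselines = {name: 22.0 + rng.uniform(-2, 6) for name in sorted(assays)}

    records: list[CqRecord] = []
    for s in range(1, n_samples + 1):
        for preservation in ("RNAlater", "FFPE"):
            shift = preservation_shift if preservation == "FFPE" else 0.0
            sdf = preservation_sd_factor if preservation == "FFPE" else 1.0
            # per-(sample, preservation) loading offset, log2 input units;
            # degraded FFPE input scatters more, inflating cell SDs but
            # cancelling inside efficiency-corrected ratios
            sample_level = rng.normal(0, 0.3 * sdf)
            for tissue in ("infarct", "remote"):
                for assay, e in sorted(assays.items()):
                    log2_expr = sample_level + (
                        group_shifts.get(assay, 0.0) if tissue == "infarct" else 0.0
                    )
                    # Cq = baseline - log_E(input); input = 2^log2_expr
                    cq = (
                        baselines[assay]
                        - log2_expr * np.log(2) / np.log(e)
                        + shift
                        + rng.normal(0, noise_sd * sdf)
                    )
                    records.append(
                        CqRecord(
                            sample_id=f"S{s}",
                            tissue=tissue,
                            preservation=preservation,
                            chemistry="dye_based",
                            assay=assay,
                            Cq=float(np.clip(cq, 1.0, 44.0)),
                        )
                    )

    series: dict[str, DilutionSeries] = {}
    for assay, e in sorted(assays.items()):
        points = []
        for step in range(1, 6):  # 3-fold .. 243-fold dilution
            amount = 3.0**-step
            for _ in range(3):
                cq = (
                    baselines[assay]
                    - np.log(amount) / np.log(e)
                    + rng.normal(0, noise_sd)
                )
                points.append((amount, float(cq)))
        series[assay] = DilutionSeries(assay=assay, points=tuple(points))

    truth = {
        "efficiencies": dict(assays),
        "group_shifts": dict(group_shifts),
        "preservation_shift": preservation_shift,
        "preservation_sd_factor": preservation_sd_factor,
    }
    return records, series, truth


__all__ = [
    "rng_for",
    "gen_utr",
    "PlantSpec",
    "plant_site",
    "gen_array_experiment",
    "gen_qpcr",
    "ACCESSIBLE_FLANK_CEILING",
    "INACCESSIBLE_FLANK_FLOOR",
]
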