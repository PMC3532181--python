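"""Domain types, FASTA/table readers and writers, and the packaged fixtures.

The screening stages all speak in terms of a small set of record types:
mature miRNAs, 3'-UTR regions, predicted duplex binding sites (with their
binding and flanking free energies), merged "hot-spot" intervals, folding
results, and the expression-stage records (array probes, qPCR Cq values).

Three fixtures ship with the package as tab-separated text: the
differential-expression miRNA table for infarcted vs. remote myocardium and
the two binding-site tables for the SERCA2a and SERCA2b 3'-UTR isoforms.
UTR coordinates are 1-based inclusive throughout, matching the
"671-692"-style position notation of the site tables.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
SEED_POSITIONS = frozenset(range(1, 9))

#: Nominal 3'-UTR lengths implied by the largest printed site coordinates.
SERCA2A_UTR_LEN = 766
SERCA2B_UTR_LEN = 819

ISOFORM_FIXTURES = {
    "SERCA2a": "table2_serca2a_sites.tsv",
    "SERCA2b": "table3_serca2b_sites.tsv",
}


class ModelIOError(ValueError):
    """Malformed input: bad residue, duplicate id, unparsable table row."""


def _clean_rna(seq: str, context: str = "sequence") -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ModelIOError(f"invalid residue(s) {sorted(bad)} in {context}")
    return s


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3' RNA residues, with family/cluster annotation."""

    name: str
    sequence: Optional[str] = None
    accession: Optional[str] = None
    family: Optional[str] = None
    cluster_note: str = ""

    def __post_init__(self):
        if self.sequence is not None:
            object.__setattr__(self, "sequence", _clean_rna(self.sequence, self.name))
            if not 17 <= len(self.sequence) <= 27:
                raise ModelIOError(
                    f"{self.name}: mature miRNA length {len(self.sequence)} "
                    "outside 17..27"
                )


@dataclass(frozen=True)
class UTRRegion:
    """A 3'-UTR sequence; coordinates on it are 1-based inclusive."""

    transcript_id: str
    sequence: str
    isoform_label: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ModelIOError(f"{self.transcript_id}: empty UTR sequence")
        object.__setattr__(
            self, "sequence", _clean_rna(self.sequence, self.transcript_id)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice1(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive [start, end]; empty if start > end."""
        if start > end:
            return ""
        if start < 1 or end > len(self):
            raise ModelIOError(
                f"{self.transcript_id}: [{start},{end}] outside 1..{len(self)}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class DEMiRNARecord:
    """One differentially expressed miRNA (infarct vs. remote myocardium).

    ``log2_ratio_prev`` is the average log2 against healthy hearts from the
    earlier companion comparison; it is absent (None) where the table prints
    ND, never coerced to 0.
    """

    name: str
    log2_ratio: float
    log2_ratio_prev: Optional[float]
    predicted_serca2: bool
    family: str
    cluster_note: str = ""

    def __post_init__(self):
        if not math.isfinite(self.log2_ratio):
            raise ModelIOError(f"{self.name}: non-finite log2 ratio")


def classify_matched(matched: frozenset[int], seed_positions=SEED_POSITIONS) -> str:
    """Seed class from the matched miRNA 5'-end positions.

    perfect iff all seed positions are matched, partial iff some but not
    all, none otherwise. Matched positions beyond the seed are ignored.
    """
    if not seed_positions:
        raise ModelIOError("empty seed position set")
    hit = frozenset(seed_positions) & matched
    if hit == frozenset(seed_positions):
        return "perfect"
    return "partial" if hit else "none"


@dataclass(frozen=True)
class DuplexSite:
    """One predicted miRNA binding site on a UTR.

    ``matched_seed_positions`` counts miRNA positions from the 5' end that
    are paired in the duplex; the seed class is fully determined by its
    intersection with positions 1..8.
    """

    mirna_name: str
    utr_id: str
    start: int
    end: int
    dG_bind: float
    matched_seed_positions: frozenset[int] = frozenset()
    dG_flank5: Optional[float] = None
    dG_flank3: Optional[float] = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ModelIOError(
                f"{self.mirna_name}@{self.utr_id}: bad interval "
                f"{self.start}-{self.end}"
            )
        if not self.dG_bind < 0:
            raise ModelIOError(
                f"{self.mirna_name}@{self.utr_id}: dG_bind must be negative"
            )
        object.__setattr__(
            self, "matched_seed_positions", frozenset(self.matched_seed_positions)
        )

    @property
    def seed_class(self) -> str:
        return classify_matched(self.matched_seed_positions)

    def flanks_set(self) -> bool:
        return self.dG_flank5 is not None and self.dG_flank3 is not None


@dataclass(frozen=True)
class HotSpot:
    """A merged, overlap-connected cluster of binding sites on one UTR."""

    utr_id: str
    start: int
    end: int
    member_sites: tuple[DuplexSite, ...]

    def __post_init__(self):
        if not self.member_sites:
            raise ModelIOError("hot-spot without member sites")
        if self.start != min(s.start for s in self.member_sites) or self.end != max(
            s.end for s in self.member_sites
        ):
            raise ModelIOError("hot-spot bounds do not match members")

    @property
    def n_distinct_mirnas(self) -> int:
        return len({s.mirna_name for s in self.member_sites})

    @property
    def cooperative(self) -> bool:
        return self.n_distinct_mirnas >= 2


@dataclass(frozen=True)
class FoldResult:
    """MFE and one optimal dot-bracket structure of a sequence."""

    sequence: str
    mfe: float
    structure: str

    def __post_init__(self):
        if len(self.structure) != len(self.sequence):
            raise ModelIOError("structure/sequence length mismatch")


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor free-energy parameters at 37 degrees C (kcal/mol).

    ``stack`` maps ((top1, bottom1), (top2, bottom2)) base-pair doublets to
    stacking increments; lookups are closed under the strand-flip symmetry.
    Loop penalties are affine in loop size; hairpin penalties are tabulated
    by loop size with a logarithmic extrapolation beyond the table.
    """

    version: str
    duplex_init: float
    stack: dict
    bulge_open: float
    bulge_ext: float
    internal_open: float
    internal_ext: float
    hairpin_by_size: dict
    mb_offset: float
    mb_per_branch: float
    mb_per_unpaired: float

    RT37 = 0.61633  # kcal/mol

    def stack_energy(self, p1: tuple[str, str], p2: tuple[str, str]) -> float:
        return self.stack[(p1, p2)]

    def bulge(self, size: int) -> float:
        return self.bulge_open + self.bulge_ext * size

    def internal(self, size: int) -> float:
        return self.internal_open + self.internal_ext * size

    def hairpin(self, size: int) -> float:
        if size < 3:
            raise ModelIOError(f"hairpin loop of size {size} < 3")
        if size in self.hairpin_by_size:
            return self.hairpin_by_size[size]
        nmax = max(self.hairpin_by_size)
        return self.hairpin_by_size[nmax] + 1.75 * self.RT37 * math.log(size / nmax)


ALLOWED_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)
WC_PAIRS = frozenset([("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")])


def can_pair(a: str, b: str) -> bool:
    return (a, b) in ALLOWED_PAIRS


@dataclass(frozen=True)
class ProbeMeasurement:
    """One replicate probe signal on one channel of one hybridization."""

    array_id: str
    orientation: str  # forward | swap
    mirna_name: str
    replicate: int
    channel: str  # ch1 | ch2
    signal: float
    background: float

    def __post_init__(self):
        if self.orientation not in ("forward", "swap"):
            raise ModelIOError(f"bad orientation {self.orientation!r}")
        if self.channel not in ("ch1", "ch2"):
            raise ModelIOError(f"bad channel {self.channel!r}")
        if not 1 <= self.replicate <= 5:
            raise ModelIOError("replicate index outside 1..5")
        if self.signal < 0:
            raise ModelIOError("negative raw signal")


@dataclass(frozen=True)
class CqRecord:
    """One qPCR quantification-cycle observation."""

    sample_id: str
    tissue: str  # infarct | remote
    preservation: str  # FFPE | RNAlater
    chemistry: str  # probe_based | dye_based
    assay: str
    Cq: float
    replicate: int = 1

    def __post_init__(self):
        if not 0 < self.Cq < 45:
            raise ModelIOError(f"Cq {self.Cq} outside (0, 45)")


@dataclass(frozen=True)
class EfficiencyFit:
    """Per-assay amplification efficiency from a dilution series."""

    assay: str
    slope: float
    efficiency: float
    r_squared: float

    def __post_init__(self):
        if self.slope >= 0:
            raise ModelIOError(f"{self.assay}: non-negative dilution slope")
        if not 1 < self.efficiency <= 2.2:
            raise ModelIOError(
                f"{self.assay}: efficiency {self.efficiency:.3f} outside (1, 2.2]"
            )


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable screening/analysis parameters with the study's defaults."""

    flank_width: int = 70
    accessibility_gap: float = 10.0
    seed_positions: frozenset[int] = SEED_POSITIONS
    seed_min_candidate: int = 4
    window_slack: int = 3
    duplex_ceiling: float = -15.0
    up_threshold: float = 0.1
    de_alpha: float = 0.01
    detection_min: int = 3
    qpcr_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.flank_width <= 0:
            raise ModelIOError("flank_width must be positive")
        if self.accessibility_gap < 0:
            raise ModelIOError("accessibility_gap must be >= 0")
        if not 0 < self.de_alpha < 1:
            raise ModelIOError("de_alpha must be in (0, 1)")
        object.__setattr__(self, "seed_positions", frozenset(self.seed_positions))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, RNA sequence) pairs.

    DNA input is accepted (T mapped to U) and case is folded to upper.
    Duplicate ids, invalid residues and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ModelIOError(f"{path}: empty or non-FASTA file")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ModelIOError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, _clean_rna(str(rec.seq), rec.id)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# matched-position range strings ("1-5, 7-12"; en dash accepted)

_RANGE_RE = re.compile(r"^\s*(\d+)\s*(?:[-–]\s*(\d+))?\s*$")


def parse_matched(text: str) -> frozenset[int]:
    """Parse a comma-separated run list like ``1-5, 7-12`` into a position set."""
    text = text.strip()
    if not text:
        return frozenset()
    positions: set[int] = set()
    for chunk in text.split(","):
        m = _RANGE_RE.match(chunk)
        if not m:
            raise ModelIOError(f"unparsable position range {chunk!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise ModelIOError(f"descending range {chunk!r}")
        positions.update(range(lo, hi + 1))
    return frozenset(positions)


def parse_seed_cell(cell: str) -> frozenset[int]:
    """Parse a seed-column cell: yes / no / partially (positions)."""
    c = cell.strip().lower()
    if c == "yes":
        return SEED_POSITIONS
    if c == "no":
        return frozenset()
    m = re.match(r"^partially\s*\((.*)\)$", c)
    if not m:
        raise ModelIOError(f"unparsable seed cell {cell!r}")
    return parse_matched(m.group(1))


# ---------------------------------------------------------------------------
# fixtures and site tables


def _data_path(name: str) -> Path:
    return Path(resources.files("mirserca").joinpath("data", name))


def load_de_table(path) -> list[DEMiRNARecord]:
    """Read a DE miRNA table (TSV with one header line)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows = [ln for ln in lines if ln.strip()]
    if len(rows) < 2:
        raise ModelIOError(f"{path}: empty DE table")
    header = rows[0].split("\t")
    expected = ["mirna", "log2_ratio", "log2_ratio_prev", "predicted", "family"]
    if header[: len(expected)] != expected:
        raise ModelIOError(f"{path}: unexpected header {header!r}")
    records = []
    for ln in rows[1:]:
        cells = ln.split("\t")
        if len(cells) < 5:
            raise ModelIOError(f"{path}: malformed row {ln!r}")
        name, log2s, prevs, pred, family = cells[:5]
        note = cells[5].strip() if len(cells) > 5 else ""
        try:
            log2 = float(log2s)
        except ValueError as exc:
            raise ModelIOError(f"{path}: non-numeric log2 in row {ln!r}") from exc
        prev = None if prevs.strip().upper() == "ND" else float(prevs)
        if pred.strip().lower() not in ("yes", "no"):
            raise ModelIOError(f"{path}: bad predicted flag {pred!r}")
        records.append(
            DEMiRNARecord(
                name=name.strip(),
                log2_ratio=log2,
                log2_ratio_prev=prev,
                predicted_serca2=pred.strip().lower() == "yes",
                family=family.strip(),
                cluster_note=note,
            )
        )
    return records


def load_de_fixture() -> list[DEMiRNARecord]:
    """The packaged differential-expression miRNA table (one record per row)."""
    return load_de_table(_data_path("table1_de.tsv"))


SITE_COLUMNS = ["mirna", "dG_bind", "dG_flank3", "dG_flank5", "position", "seed"]


def load_site_table(path, utr_id: str) -> list[DuplexSite]:
    """Read a binding-site table (site-table column order) for one UTR."""
    path = Path(path)
    rows = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not rows:
        raise ModelIOError(f"{path}: empty site table")
    if rows[0].split("\t") != SITE_COLUMNS:
        raise ModelIOError(f"{path}: unexpected header {rows[0]!r}")
    sites = []
    for ln in rows[1:]:
        cells = ln.split("\t")
        if len(cells) != 6:
            raise ModelIOError(f"{path}: malformed row {ln!r}")
        name, g_bind, g3, g5, pos, seed = cells
        m = re.match(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$", pos)
        if not m:
            raise ModelIOError(f"{path}: unparsable position {pos!r}")
        sites.append(
            DuplexSite(
                mirna_name=name.strip(),
                utr_id=utr_id,
                start=int(m.group(1)),
                end=int(m.group(2)),
                dG_bind=float(g_bind),
                dG_flank3=float(g3),
                dG_flank5=float(g5),
                matched_seed_positions=parse_seed_cell(seed),
            )
        )
    return sites


def load_site_fixture(isoform: str) -> list[DuplexSite]:
    """Packaged binding-site table for one UTR isoform (SERCA2a or SERCA2b)."""
    if isoform not in ISOFORM_FIXTURES:
        raise ModelIOError(
            f"unknown isoform {isoform!r}; expected one of {sorted(ISOFORM_FIXTURES)}"
        )
    return load_site_table(_data_path(ISOFORM_FIXTURES[isoform]), isoform)


def _format_runs(positions: frozenset[int]) -> str:
    # local copy of the run formatter to keep model_io import-independent of
    # seed_scan; seed_scan.format_matched is the public surface
    if not positions:
        return ""
    xs = sorted(positions)
    runs, lo, hi = [], xs[0], xs[0]
    for x in xs[1:]:
        if x == hi + 1:
            hi = x
        else:
            runs.append((lo, hi))
            lo = hi = x
    runs.append((lo, hi))
    return ", ".join(f"{a}" if a == b else f"{a}-{b}" for a, b in runs)


def seed_cell_text(site: DuplexSite) -> str:
    cls = site.seed_class
    if cls == "perfect":
        return "yes"
    if cls == "none":
        return "no"
    return f"partially ({_format_runs(site.matched_seed_positions)})"


def write_site_table(sites: Sequence[DuplexSite], path) -> None:
    """Write sites as TSV in the site-table column order.

    Energies are rendered to one decimal, positions as ``start-end``;
    the output round-trips through :func:`load_site_table`.
    """
    for s in sites:
        if not s.flanks_set():
            raise ModelIOError(f"{s.mirna_name}@{s.utr_id}: flank energies unset")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.mirna_name,
                        f"{s.dG_bind:.1f}",
                        f"{s.dG_flank3:.1f}",
                        f"{s.dG_flank5:.1f}",
                        f"{s.start}-{s.end}",
                        seed_cell_text(s),
                    ]
                )
                + "\n"
            )


__all__ = [
    "MatureMiRNA",
    "UTRRegion",
    "DEMiRNARecord",
    "DuplexSite",
    "HotSpot",
    "FoldResult",
    "NNParameterTable",
    "ProbeMeasurement",
    "CqRecord",
    "EfficiencyFit",
    "ScreenConfig",
    "ModelIOError",
    "read_fasta",
    "write_fasta",
    "load_de_table",
    "load_de_fixture",
    "load_site_table",
    "load_site_fixture",
    "write_site_table",
    "parse_matched",
    "parse_seed_cell",
    "classify_matched",
    "can_pair",
    "ALLOWED_PAIRS",
    "WC_PAIRS",
    "SEED_POSITIONS",
    "SERCA2A_UTR_LEN",
    "SERCA2B_UTR_LEN",
    "replace",
]
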