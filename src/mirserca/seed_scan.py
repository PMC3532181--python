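"""Seed-region pairing classification and candidate window enumeration.

The seed region is defined as miRNA positions 1-8 counted from the 5' end.
"Perfect" seed complementarity requires Watson-Crick pairing at every seed
position; G:U wobbles contribute binding energy in the duplex stage but do
not count toward perfection here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_io import (
    ALLOWED_PAIRS,
    RNA_ALPHABET,
    MatureMiRNA,
    ModelIOError,
    ScreenConfig,
    UTRRegion,
    classify_matched,
)

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence under A-U / C-G."""
    bad = set(seq.upper()) - RNA_ALPHABET
    if bad:
        raise ModelIOError(f"invalid residue(s) {sorted(bad)} in revcomp input")
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class PairingTrace:
    """The paired positions of an intermolecular duplex.

    ``pairs`` is a tuple of (miRNA position, UTR position) tuples, both
    1-based within their sequences; antiparallel geometry means miRNA
    positions strictly increase while UTR positions strictly decrease.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i1 < i2 and j1 > j2):
                raise ModelIOError("pairing trace is not antiparallel-monotone")

    @property
    def mirna_matched(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.pairs)

    @property
    def utr_matched(self) -> frozenset[int]:
        return frozenset(j for _, j in self.pairs)

    def transposed(self) -> "PairingTrace":
        return PairingTrace(tuple((j, i) for i, j in reversed(self.pairs)))


def classify_seed(trace: PairingTrace, seed_positions) -> str:
    """Classify seed pairing as perfect / partial / none.

    Only the positions in ``seed_positions`` matter; matched positions
    beyond the seed are carried in the trace but ignored here.
    """
    return classify_matched(trace.mirna_matched, frozenset(seed_positions))


def format_matched(positions) -> str:
    """Render a position set as comma-separated maximal runs, e.g. ``1-5, 7-12``."""
    positions = frozenset(positions)
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


def _seed_oppositions(mirna_seq: str, utr_seq: str, start: int, end: int) -> int:
    """Count pairable seed positions under ungapped antiparallel opposition.

    The miRNA 5' end is laid against the window's 3' end, so miRNA position
    k opposes UTR position end - k + 1. G:U counts as pairing here (the
    filter feeds the energy stage, where wobbles are worth energy).
    """
    n = 0
    for k in range(1, 9):
        if k > len(mirna_seq):
            break
        j = end - k + 1
        if j < start:
            break
        if (mirna_seq[k - 1], utr_seq[j - 1]) in ALLOWED_PAIRS:
            n += 1
    return n


def scan_windows(
    mirna: MatureMiRNA, utr: UTRRegion, config: ScreenConfig | None = None
) -> list[tuple[int, int]]:
    """Enumerate candidate UTR windows for a miRNA.

    Windows of length len(miRNA) + b for b in -slack..+slack are stepped by
    one position; a window is retained when at least ``seed_min_candidate``
    of the seed positions 1..8 can oppose a pairable UTR base without gaps.
    The retained set is a superset of everything the duplex stage can score
    as seed partial or perfect, since a duplex seed pairing with a bulge
    budget of +-slack implies at least that many ungapped oppositions in
    one of the slid windows.
    """
    config = config or ScreenConfig()
    m = mirna.sequence
    if m is None:
        raise ModelIOError(f"{mirna.name}: no sequence")
    L, U = len(m), len(utr)
    if U < L:
        raise ModelIOError(f"{utr.transcript_id}: UTR shorter than miRNA {mirna.name}")
    kept: set[tuple[int, int]] = set()
    for b in range(-config.window_slack, config.window_slack + 1):
        w = L + b
        if w < 1 or w > U:
            continue
        for start in range(1, U - w + 2):
            end = start + w - 1
            if _seed_oppositions(m, utr.sequence, start, end) >= config.seed_min_candidate:
                kept.add((start, end))
    return sorted(kept)


__all__ = [
    "PairingTrace",
    "revcomp",
    "classify_seed",
    "format_matched",
    "scan_windows",
]
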