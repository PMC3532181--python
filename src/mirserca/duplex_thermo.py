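"""Minimum free energy of the intermolecular miRNA:mRNA heteroduplex.

Dynamic programming over the nearest-neighbor model: a duplex is an
antiparallel, non-crossing chain of base pairs (Watson-Crick or G:U)
between the two molecules, with stacking increments for adjacent pairs and
affine penalties for bulge and internal loops. Intramolecular pairs and
multiloops are not part of the duplex model, and loop sides are capped
(default 6 nt). The empty pairing scores 0; a duplex pays the initiation
penalty once.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources

from .model_io import (
    ALLOWED_PAIRS,
    RNA_ALPHABET,
    DuplexSite,
    MatureMiRNA,
    ModelIOError,
    NNParameterTable,
    ScreenConfig,
    UTRRegion,
)
from .seed_scan import PairingTrace

log = logging.getLogger("mirserca")

MAX_SEQ = 10_000
LOOP_CAP = 6  # max bulge/internal-loop size per side inside a duplex

_BASES = "ACGU"


def _flip(doublet):
    (t1, b1), (t2, b2) = doublet
    return ((b2, t2), (b1, t1))


def load_default_params() -> NNParameterTable:
    """Load the packaged nearest-neighbor parameter table (37 degrees C).

    The stack map is expanded to be closed under the strand-flip symmetry
    and validated to cover every ordered doublet of allowed pairs.
    """
    path = resources.files("mirserca").joinpath("data", "nn_params.tsv")
    version = "unversioned"
    init = None
    stack: dict = {}
    loops: dict = {}
    hairpin: dict = {}
    mb: dict = {}
    with path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            kind, key, value = row["kind"], row["key"], row["value"]
            if kind == "meta" and key == "version":
                version = value
            elif kind == "init":
                init = float(value)
            elif kind == "stack":
                top, bottom = key.split("/")
                d = ((top[0], bottom[0]), (top[1], bottom[1]))
                stack[d] = float(value)
                stack[_flip(d)] = float(value)
            elif kind == "loop":
                loops[key] = float(value)
            elif kind == "hairpin":
                hairpin[int(key)] = float(value)
            elif kind == "multibranch":
                mb[key] = float(value)
    for p1 in ALLOWED_PAIRS:
        for p2 in ALLOWED_PAIRS:
            if (p1, p2) not in stack:
                raise ModelIOError(f"stack table missing doublet {p1}/{p2}")
    params = NNParameterTable(
        version=version,
        duplex_init=init,
        stack=stack,
        bulge_open=loops["bulge_open"],
        bulge_ext=loops["bulge_ext"],
        internal_open=loops["internal_open"],
        internal_ext=loops["internal_ext"],
        hairpin_by_size=hairpin,
        mb_offset=mb["offset"],
        mb_per_branch=mb["per_branch"],
        mb_per_unpaired=mb["per_unpaired"],
    )
    log.info("loaded nearest-neighbor parameter table %s", version)
    return params


def _check_seq(seq: str, what: str) -> str:
    s = seq.upper()
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ModelIOError(f"invalid residue(s) {sorted(bad)} in {what}")
    if len(s) > MAX_SEQ:
        raise ModelIOError(f"{what} longer than {MAX_SEQ} nt")
    return s


def duplex_energy(
    mirna: str, window: str, params: NNParameterTable, loop_cap: int = LOOP_CAP
) -> tuple[float, PairingTrace]:
    """Minimum free energy (kcal/mol) of the miRNA:window duplex.

    Returns the optimal energy and one optimal pairing trace; when forming
    any pair costs more than it gains, returns (0.0, empty trace).
    """
    m = _check_seq(mirna, "miRNA")
    w = _check_seq(window, "window")
    if not m or not w:
        raise ModelIOError("empty sequence in duplex_energy")
    M, W = len(m), len(w)

    INF = float("inf")
    # best[i][j]: minimal link-sum of a chain ending with pair (i, j)
    # (1-based; miRNA position increases, window position decreases)
    best = [[INF] * (W + 1) for _ in range(M + 1)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for i in range(1, M + 1):
        for j in range(W, 0, -1):
            if (m[i - 1], w[j - 1]) not in ALLOWED_PAIRS:
                continue
            best[i][j] = 0.0
            back[(i, j)] = None
            p2 = (m[i - 1], w[j - 1])
            for i0 in range(max(1, i - 1 - loop_cap), i):
                ga = i - i0 - 1
                for j0 in range(j + 1, min(W, j + 1 + loop_cap) + 1):
                    if best[i0][j0] == INF:
                        continue
                    gb = j0 - j - 1
                    if ga == 0 and gb == 0:
                        link = params.stack_energy((m[i0 - 1], w[j0 - 1]), p2)
                    elif ga == 0 or gb == 0:
                        link = params.bulge(ga + gb)
                    else:
                        link = params.internal(ga + gb)
                    cand = best[i0][j0] + link
                    if cand < best[i][j] - 1e-12:
                        best[i][j] = cand
                        back[(i, j)] = (i0, j0)

    best_val, best_end = 0.0, None
    for i in range(1, M + 1):
        for j in range(1, W + 1):
            if best[i][j] is not INF:
                total = params.duplex_init + best[i][j]
                if total < best_val - 1e-12:
                    best_val, best_end = total, (i, j)
    if best_end is None:
        return 0.0, PairingTrace(())
    chain = []
    cur = best_end
    while cur is not None:
        chain.append(cur)
        cur = back[cur]
    chain.reverse()
    return best_val, PairingTrace(tuple(chain))


def best_site(
    mirna: MatureMiRNA,
    utr: UTRRegion,
    windows: list[tuple[int, int]],
    params: NNParameterTable,
    config: ScreenConfig | None = None,
) -> list[DuplexSite]:
    """Score candidate windows and keep the strongest non-overlapping sites.

    Windows whose duplex energy is above the configured ceiling are
    discarded; overlapping survivors for the same miRNA collapse to the
    lowest-energy one. Site coordinates are the paired span on the UTR;
    flank energies are left unset for the folding stage.
    """
    config = config or ScreenConfig()
    scored: list[DuplexSite] = []
    for start, end in windows:
        seq = utr.slice1(start, end)
        dG, trace = duplex_energy(mirna.sequence, seq, params)
        if dG >= config.duplex_ceiling or not trace.pairs:
            continue
        utr_positions = [start + j - 1 for _, j in trace.pairs]
        scored.append(
            DuplexSite(
                mirna_name=mirna.name,
                utr_id=utr.transcript_id,
                start=min(utr_positions),
                end=max(utr_positions),
                dG_bind=dG,
                matched_seed_positions=trace.mirna_matched,
            )
        )
    scored.sort(key=lambda s: (s.dG_bind, s.start, s.end))
    kept: list[DuplexSite] = []
    for site in scored:
        if any(site.start <= k.end and k.start <= site.end for k in kept):
            continue
        kept.append(site)
    kept.sort(key=lambda s: s.start)
    return kept


__all__ = ["load_default_params", "duplex_energy", "best_site", "LOOP_CAP"]
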