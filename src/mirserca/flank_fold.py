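"""Flanking-window extraction and intramolecular MFE folding.

The accessibility argument contrasts the binding energy of a site with the
folding energy of the 70-nt windows on its 5' and 3' sides: a site whose
neighborhood folds weakly (MFE near 0) is locally accessible, while a
strongly structured flank suggests the site is occluded.

The folder is a Zuker-style minimum-free-energy dynamic program over the
same nearest-neighbor parameter table the duplex stage uses: stacking,
bulge and internal loops (affine, sides capped), tabulated hairpin
penalties (loop >= 3), and a linear multibranch penalty. No dangling-end
or coaxial-stacking terms. The open chain scores 0, so the MFE is never
positive.
"""

from __future__ import annotations

import logging
import shutil
import subprocess

from .model_io import (
    ALLOWED_PAIRS,
    DuplexSite,
    FoldResult,
    ModelIOError,
    NNParameterTable,
    ScreenConfig,
    UTRRegion,
    replace,
)

log = logging.getLogger("mirserca")

MAX_FOLD_LEN = 500
FOLD_LOOP_CAP = 6  # max bulge/internal size per side
MIN_HAIRPIN = 3
_EPS = 1e-9


def extract_flanks(utr: UTRRegion, site: DuplexSite, width: int) -> tuple[str, str]:
    """The up-to-``width``-nt windows 5' and 3' of a site (site excluded).

    Windows are truncated silently at the UTR boundaries (logged); a site
    touching an end of the UTR has an empty flank on that side.
    """
    if width <= 0:
        raise ModelIOError("flank width must be positive")
    if site.start < 1 or site.end > len(utr):
        raise ModelIOError(
            f"site {site.start}-{site.end} outside UTR {utr.transcript_id}"
        )
    f5_start, f5_end = max(1, site.start - width), site.start - 1
    f3_start, f3_end = site.end + 1, min(len(utr), site.end + width)
    flank5 = utr.slice1(f5_start, f5_end) if f5_end >= f5_start else ""
    flank3 = utr.slice1(f3_start, f3_end) if f3_end >= f3_start else ""
    if len(flank5) < width or len(flank3) < width:
        log.debug(
            "flanks of %s@%d-%d truncated to %d/%d nt at UTR boundary",
            site.mirna_name, site.start, site.end, len(flank5), len(flank3),
        )
    return flank5, flank3


def fold_mfe(seq: str, params: NNParameterTable) -> FoldResult:
    """Minimum-free-energy secondary structure of one RNA sequence."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ModelIOError(f"invalid residue(s) {sorted(bad)} in fold input")
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ModelIOError(f"fold input longer than {MAX_FOLD_LEN} nt")
    if n == 0:
        return FoldResult("", 0.0, "")

    INF = float("inf")

    def pairable(i: int, j: int) -> bool:
        return (s[i - 1], s[j - 1]) in ALLOWED_PAIRS

    b = params.mb_per_branch
    c = params.mb_per_unpaired
    a = params.mb_offset

    V = [[INF] * (n + 2) for _ in range(n + 2)]
    WM = [[INF] * (n + 2) for _ in range(n + 2)]
    WM2 = [[INF] * (n + 2) for _ in range(n + 2)]

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            # V: structure closed by pair (i, j)
            if pairable(i, j):
                best = params.hairpin(j - i - 1)
                p_out = (s[i - 1], s[j - 1])
                for k in range(i + 1, min(i + FOLD_LOOP_CAP + 2, j)):
                    ga = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - FOLD_LOOP_CAP)
                    for l in range(lmin, j):
                        if V[k][l] == INF:
                            continue
                        gb = j - l - 1
                        if ga == 0 and gb == 0:
                            cost = params.stack_energy(p_out, (s[k - 1], s[l - 1]))
                        elif ga == 0 or gb == 0:
                            cost = params.bulge(ga + gb)
                        else:
                            cost = params.internal(ga + gb)
                        best = min(best, cost + V[k][l])
                if WM2[i + 1][j - 1] < INF:
                    best = min(best, a + b + WM2[i + 1][j - 1])
                V[i][j] = best
            # WM: >= 1 multiloop branch in [i, j]
            cand = INF
            if WM[i + 1][j] < INF:
                cand = min(cand, WM[i + 1][j] + c)
            if WM[i][j - 1] < INF:
                cand = min(cand, WM[i][j - 1] + c)
            if V[i][j] < INF:
                cand = min(cand, V[i][j] + b)
            for k in range(i + 1, j + 1):
                if WM[i][k - 1] < INF and WM[k][j] < INF:
                    cand = min(cand, WM[i][k - 1] + WM[k][j])
            WM[i][j] = cand
            # WM2: >= 2 branches in [i, j]
            cand = INF
            if WM2[i][j - 1] < INF:
                cand = min(cand, WM2[i][j - 1] + c)
            for k in range(i + 1, j + 1):
                if WM[i][k - 1] < INF and V[k][j] < INF:
                    cand = min(cand, WM[i][k - 1] + V[k][j] + b)
            WM2[i][j] = cand

    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        for i in range(1, j):
            if V[i][j] < INF:
                W[j] = min(W[j], W[i - 1] + V[i][j])

    # traceback
    structure = ["."] * n
    stack: list[tuple] = [("W", n)]
    while stack:
        frame = stack.pop()
        if frame[0] == "W":
            j = frame[1]
            if j == 0:
                continue
            if abs(W[j] - W[j - 1]) < _EPS:
                stack.append(("W", j - 1))
                continue
            done = False
            for i in range(1, j):
                if V[i][j] < INF and abs(W[j] - (W[i - 1] + V[i][j])) < _EPS:
                    stack.append(("W", i - 1))
                    stack.append(("V", i, j))
                    done = True
                    break
            if not done:  # numerical fallback
                stack.append(("W", j - 1))
        elif frame[0] == "V":
            _, i, j = frame
            structure[i - 1] = "("
            structure[j - 1] = ")"
            if abs(V[i][j] - params.hairpin(j - i - 1)) < _EPS:
                continue
            p_out = (s[i - 1], s[j - 1])
            found = False
            for k in range(i + 1, min(i + FOLD_LOOP_CAP + 2, j)):
                ga = k - i - 1
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - FOLD_LOOP_CAP)
                for l in range(lmin, j):
                    if V[k][l] == INF:
                        continue
                    gb = j - l - 1
                    if ga == 0 and gb == 0:
                        cost = params.stack_energy(p_out, (s[k - 1], s[l - 1]))
                    elif ga == 0 or gb == 0:
                        cost = params.bulge(ga + gb)
                    else:
                        cost = params.internal(ga + gb)
                    if abs(V[i][j] - (cost + V[k][l])) < _EPS:
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if not found:
                stack.append(("WM2", i + 1, j - 1))
        elif frame[0] == "WM2":
            _, i, j = frame
            if WM2[i][j - 1] < INF and abs(WM2[i][j] - (WM2[i][j - 1] + c)) < _EPS:
                stack.append(("WM2", i, j - 1))
                continue
            for k in range(i + 1, j + 1):
                if (
                    WM[i][k - 1] < INF
                    and V[k][j] < INF
                    and abs(WM2[i][j] - (WM[i][k - 1] + V[k][j] + b)) < _EPS
                ):
                    stack.append(("WM", i, k - 1))
                    stack.append(("V", k, j))
                    break
        elif frame[0] == "WM":
            _, i, j = frame
            if V[i][j] < INF and abs(WM[i][j] - (V[i][j] + b)) < _EPS:
                stack.append(("V", i, j))
                continue
            if WM[i + 1][j] < INF and abs(WM[i][j] - (WM[i + 1][j] + c)) < _EPS:
                stack.append(("WM", i + 1, j))
                continue
            if WM[i][j - 1] < INF and abs(WM[i][j] - (WM[i][j - 1] + c)) < _EPS:
                stack.append(("WM", i, j - 1))
                continue
            for k in range(i + 1, j + 1):
                if (
                    WM[i][k - 1] < INF
                    and WM[k][j] < INF
                    and abs(WM[i][j] - (WM[i][k - 1] + WM[k][j])) < _EPS
                ):
                    stack.append(("WM", i, k - 1))
                    stack.append(("WM", k, j))
                    break

    return FoldResult(s, W[n], "".join(structure))


def annotate_flank_energies(
    utr: UTRRegion,
    sites: list[DuplexSite],
    params: NNParameterTable,
    config: ScreenConfig | None = None,
) -> list[DuplexSite]:
    """Attach 5'/3' flanking-window MFEs to each site (empty flank scores 0)."""
    config = config or ScreenConfig()
    out = []
    for site in sites:
        flank5, flank3 = extract_flanks(utr, site, config.flank_width)
        g5 = fold_mfe(flank5, params).mfe if flank5 else 0.0
        g3 = fold_mfe(flank3, params).mfe if flank3 else 0.0
        out.append(replace(site, dG_flank5=g5, dG_flank3=g3))
    return out


def crosscheck_rnafold(seq: str, params: NNParameterTable) -> float | None:
    """Log (never assert) the MFE difference against an external folder.

    Returns the external MFE when the ``RNAfold`` executable is on PATH,
    else None. Diagnostic only: the two folders use different parameter
    details, so differences are expected.
    """
    exe = shutil.which("RNAfold")
    if exe is None:
        return None
    proc = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    line = proc.stdout.strip().splitlines()[-1]
    ext = float(line.rsplit("(", 1)[1].rstrip(")").strip())
    ours = fold_mfe(seq, params).mfe
    log.info("RNAfold cross-check: ours %.2f vs external %.2f", ours, ext)
    return ext


__all__ = [
    "extract_flanks",
    "fold_mfe",
    "annotate_flank_energies",
    "crosscheck_rnafold",
    "MIN_HAIRPIN",
    "FOLD_LOOP_CAP",
]
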