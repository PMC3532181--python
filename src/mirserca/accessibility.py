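"""Accessibility filtering and hot-spot aggregation of binding sites.

A predicted site is called accessible when its duplex binding energy is at
least ``gap`` kcal/mol below the folding energy of at least one of its
flanking windows: the miRNA gains much more by hybridizing than the
neighborhood gains by folding onto itself, so the site sits in a locally
open region. The one-flank reading is deliberate — sites selected in the
study include rows where only one flank clears the 10 kcal/mol gap.

Sites that overlap on the UTR are merged transitively into "hot-spots";
a hot-spot bound by two or more distinct mature miRNAs is cooperative.
"""

from __future__ import annotations

from .model_io import (
    DuplexSite,
    HotSpot,
    MatureMiRNA,
    ModelIOError,
    NNParameterTable,
    ScreenConfig,
    UTRRegion,
)
from .duplex_thermo import best_site
from .flank_fold import annotate_flank_energies
from .seed_scan import scan_windows


def accessibility_pass(site: DuplexSite, gap: float) -> bool:
    """True iff the binding-vs-flank free-energy gap reaches ``gap`` on
    at least one side."""
    if not site.flanks_set():
        raise ModelIOError(
            f"{site.mirna_name}@{site.utr_id}: flank energies not annotated"
        )
    return (site.dG_flank5 - site.dG_bind >= gap) or (
        site.dG_flank3 - site.dG_bind >= gap
    )


def merge_hotspots(sites: list[DuplexSite]) -> list[HotSpot]:
    """Merge sites sharing at least one UTR position, transitively.

    All sites must lie on one UTR. Output is sorted by start; merged
    intervals are pairwise disjoint and cover exactly the union of their
    members.
    """
    if not sites:
        return []
    utr_ids = {s.utr_id for s in sites}
    if len(utr_ids) > 1:
        raise ModelIOError(f"sites from multiple UTRs: {sorted(utr_ids)}")
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna_name))
    clusters: list[list[DuplexSite]] = [[ordered[0]]]
    hi = ordered[0].end
    for site in ordered[1:]:
        if site.start <= hi:  # 1-based inclusive: sharing a position merges
            clusters[-1].append(site)
            hi = max(hi, site.end)
        else:
            clusters.append([site])
            hi = site.end
    return [
        HotSpot(
            utr_id=members[0].utr_id,
            start=min(s.start for s in members),
            end=max(s.end for s in members),
            member_sites=tuple(members),
        )
        for members in clusters
    ]


def multiplicity(sites: list[DuplexSite]) -> dict[str, int]:
    """Number of binding sites per miRNA name."""
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.mirna_name] = counts.get(s.mirna_name, 0) + 1
    return counts


def screen_utr(
    mirnas: list[MatureMiRNA],
    utr: UTRRegion,
    params: NNParameterTable,
    config: ScreenConfig | None = None,
) -> list[DuplexSite]:
    """Full per-UTR screen: windows -> duplex energies -> flank folding ->
    accessibility filter. Deterministic; output sorted by (miRNA, start)."""
    config = config or ScreenConfig()
    accessible: list[DuplexSite] = []
    for mirna in mirnas:
        windows = scan_windows(mirna, utr, config)
        sites = best_site(mirna, utr, windows, params, config)
        sites = annotate_flank_energies(utr, sites, params, config)
        accessible.extend(
            s for s in sites if accessibility_pass(s, config.accessibility_gap)
        )
    accessible.sort(key=lambda s: (s.mirna_name, s.start))
    return accessible


def hotspot_summary(sites: list[DuplexSite]) -> dict:
    """JSON-ready summary of hot-spots, cooperativity and multiplicity."""
    spots = merge_hotspots(sites) if sites else []
    return {
        "n_sites": len(sites),
        "n_hotspots": len(spots),
        "n_cooperative": sum(1 for h in spots if h.cooperative),
        "hotspots": [
            {
                "start": h.start,
                "end": h.end,
                "n_sites": len(h.member_sites),
                "n_distinct_mirnas": h.n_distinct_mirnas,
                "cooperative": h.cooperative,
                "mirnas": sorted({s.mirna_name for s in h.member_sites}),
            }
            for h in spots
        ],
        "multiplicity": dict(sorted(multiplicity(sites).items())),
    }


__all__ = [
    "accessibility_pass",
    "merge_hotspots",
    "multiplicity",
    "screen_utr",
    "hotspot_summary",
]
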