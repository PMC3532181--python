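"""Integration of the DE miRNA table with predictions, annotation and the
thermodynamic screen: summary counts and the candidate-regulator report.

Name matching is case-insensitive and ignores the species prefix
(``hsa-``); arm suffixes (-5p/-3p) are significant, since the two arms are
distinct mature miRNAs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .accessibility import accessibility_pass, multiplicity
from .model_io import DEMiRNARecord, DuplexSite, ModelIOError, ScreenConfig, replace

_SEED_RANK = {"perfect": 2, "partial": 1, "none": 0}


def normalize_name(name: str) -> str:
    n = name.strip().lower()
    return n[4:] if n.startswith("hsa-") else n


def _strip_locus(gene: str) -> str:
    """Drop a single-digit genomic-locus suffix (miR-133a-1 -> miR-133a).

    Only applies when a family number remains, so miR-1 or miR-3120 are
    left alone.
    """
    m = re.match(r"^(.*\d\w*)-[1-9]$", gene)
    return m.group(1) if m else gene


def flag_predicted(
    records: Sequence[DEMiRNARecord], predicted_names: Iterable[str]
) -> tuple[list[DEMiRNARecord], int]:
    """Set the predicted-target flag from an external prediction name set."""
    predicted = {normalize_name(n) for n in predicted_names}
    out = [
        replace(r, predicted_serca2=normalize_name(r.name) in predicted)
        for r in records
    ]
    return out, sum(r.predicted_serca2 for r in out)


def count_predicted(records: Sequence[DEMiRNARecord]) -> int:
    """Predicted-target count from the records' own flags."""
    return sum(r.predicted_serca2 for r in records)


def count_families(records: Sequence[DEMiRNARecord]) -> int:
    """Number of distinct miRNA gene families among the records."""
    families = set()
    for r in records:
        if not r.family:
            continue  # flagged missing label, excluded
        families.add(r.family.strip().lower())
    return len(families)


_NOTE_SEG = re.compile(r"^\s*([0-9XY]+)\s*[:.]\s*([^;]*)(?:;\s*(.*))?$")


def _parse_note(note: str) -> list[tuple[str, list[str]]]:
    """Parse a cluster note into (chromosome, partner gene names) segments.

    Segments are separated by '|' (one per genomic locus); a partner text
    reading 'as single gene' (or variants) carries no partners.
    """
    segments = []
    for chunk in note.split("|"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _NOTE_SEG.match(chunk)
        if not m:
            raise ModelIOError(f"unparsable cluster note segment {chunk!r}")
        chrom, partner_text = m.group(1), m.group(2).strip()
        if "single gene" in partner_text.lower():
            partners: list[str] = []
        else:
            partners = [p.strip() for p in partner_text.split(",") if p.strip()]
        segments.append((chrom, partners))
    return segments


def clustered_summary(
    records: Sequence[DEMiRNARecord],
) -> tuple[int, list[frozenset[str]]]:
    """Genomic-cluster summary of the DE records.

    A record counts as clustered when at least one of its loci names a
    partner miRNA gene. A cluster — identified by (chromosome, member
    set) so that e.g. the two miR-1/miR-133a loci stay distinct — is
    fully represented when every named partner is itself in the DE list.
    Returns (number of clustered records, fully represented member sets).
    """
    de_names = {normalize_name(r.name) for r in records}
    n_clustered = 0
    clusters: dict[tuple[str, frozenset[str]], bool] = {}
    for r in records:
        if not r.cluster_note.strip():
            continue
        try:
            segments = _parse_note(r.cluster_note)
        except ModelIOError:
            continue  # flagged, treated unclustered
        partner_segments = [(c, p) for c, p in segments if p]
        if not partner_segments:
            continue
        n_clustered += 1
        self_name = normalize_name(r.name)
        for chrom, partners in partner_segments:
            norm = [normalize_name(_strip_locus(p)) for p in partners]
            key = (chrom, frozenset([self_name, *norm]))
            ok = all(p in de_names for p in norm)
            clusters[key] = clusters.get(key, True) and ok
    fully = sorted(
        (members for (_, members), ok in clusters.items() if ok),
        key=sorted,
    )
    return n_clustered, fully


def count_upregulated(
    records: Sequence[DEMiRNARecord], up_threshold: float = 0.1
) -> int:
    """Records with average log2 ratio strictly above the threshold.

    The +0.1 default separates genuine up-regulation from ratios at the
    noise floor (a +0.04 entry does not count, a +0.32 one does).
    """
    return sum(1 for r in records if r.log2_ratio > up_threshold)


@dataclass(frozen=True)
class Candidate:
    name: str
    direction: str
    n_sites: dict
    best_gap: float
    seed_summary: str
    multiplicity_total: int


@dataclass(frozen=True)
class CandidateReport:
    candidates: tuple[Candidate, ...]
    counts: dict

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "candidates": [
                {
                    "name": c.name,
                    "direction": c.direction,
                    "n_sites": c.n_sites,
                    "best_flank_gap_kcal_mol": round(c.best_gap, 1),
                    "seed_summary": c.seed_summary,
                    "multiplicity": c.multiplicity_total,
                }
                for c in self.candidates
            ],
        }


def _site_gap(site: DuplexSite) -> float:
    return max(site.dG_flank5 - site.dG_bind, site.dG_flank3 - site.dG_bind)


def candidate_report(
    records: Sequence[DEMiRNARecord],
    sites_by_isoform: dict[str, Sequence[DuplexSite]],
    config: ScreenConfig | None = None,
) -> CandidateReport:
    """Rank up-regulated miRNAs with accessible binding sites.

    Candidates are ordered by (largest binding-vs-flank gap, best seed
    class, site multiplicity), ties broken by name; the counts block
    repeats the table-level summary counts.
    """
    config = config or ScreenConfig()
    up = [r for r in records if r.log2_ratio > config.up_threshold]
    candidates = []
    for r in up:
        norm = normalize_name(r.name)
        per_isoform: dict[str, list[DuplexSite]] = {}
        for isoform, sites in sites_by_isoform.items():
            mine = [
                s
                for s in sites
                if normalize_name(s.mirna_name) == norm
                and accessibility_pass(s, config.accessibility_gap)
            ]
            if mine:
                per_isoform[isoform] = mine
        all_sites = [s for ss in per_isoform.values() for s in ss]
        if not all_sites:
            continue
        best_seed = max(_SEED_RANK[s.seed_class] for s in all_sites)
        candidates.append(
            Candidate(
                name=r.name,
                direction="up",
                n_sites={iso: len(ss) for iso, ss in sorted(per_isoform.items())},
                best_gap=max(_site_gap(s) for s in all_sites),
                seed_summary={2: "perfect", 1: "partial", 0: "none"}[best_seed],
                multiplicity_total=len(all_sites),
            )
        )
    candidates.sort(
        key=lambda c: (
            -c.best_gap,
            -_SEED_RANK[c.seed_summary],
            -c.multiplicity_total,
            c.name.lower(),
        )
    )
    n_clustered, fully = clustered_summary(records)
    counts = {
        "n_de": len(records),
        "n_upregulated": count_upregulated(records, config.up_threshold),
        "n_predicted": count_predicted(records),
        "n_families": count_families(records),
        "n_clustered": n_clustered,
        "n_fully_represented_clusters": len(fully),
        "fully_represented_clusters": [sorted(m) for m in fully],
    }
    return CandidateReport(tuple(candidates), counts)


__all__ = [
    "normalize_name",
    "flag_predicted",
    "count_predicted",
    "count_families",
    "clustered_summary",
    "count_upregulated",
    "Candidate",
    "CandidateReport",
    "candidate_report",
]
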