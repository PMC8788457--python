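"""Aggregate per-read chimeras into RNA-RNA interactions and report tables.

One *interaction* is the set of all chimeric reads supporting one
(regulatory RNA, target RNA) pair; sites on the target are merged when their
spans overlap by at least 1 nt. Three browse views (by regulatory RNA, by
target RNA, by pair) and the two run-summary tables are emitted as
deterministic CSVs. All report coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chimera_search import ChimeraCandidate
from .io_formats import write_csv_table
from .preprocess import ReadStats


@dataclass
class Site:
    """One merged interaction site on the target (1-based inclusive spans)."""

    tgt_span: tuple[int, int]
    reg_span: tuple[int, int]
    read_count: int
    n_unique: int
    hybrid_dG: float
    diagram: str
    region: str = ""
    read_ids: list[str] = field(default_factory=list)


@dataclass
class Interaction:
    """All chimeric evidence for one (regulatory RNA, target RNA) pair."""

    reg_name: str
    tgt_name: str
    sites: list[Site]
    total_read_count: int
    n_unique_chimeras: int

    @property
    def best_dG(self) -> float:
        return min(site.hybrid_dG for site in self.sites)


def group_interactions(candidates: Iterable[ChimeraCandidate]) -> list[Interaction]:
    """Group dG-annotated candidates by (regulatory, target) pair and merge
    sites whose target spans overlap by >= 1 nt.

    A unique read contributes its count once per interaction it supports (a
    read with several interpretations of the same pair is counted once).
    """
    by_pair: dict[tuple[str, str], list[ChimeraCandidate]] = {}
    for cand in candidates:
        key = (cand.reg_hit.ref_name, cand.tgt_hit.ref_name)
        by_pair.setdefault(key, []).append(cand)

    interactions: list[Interaction] = []
    for (reg_name, tgt_name), cands in sorted(by_pair.items()):
        # cluster candidates by overlapping target ref spans (0-based here)
        cands = sorted(cands, key=lambda c: (c.tgt_hit.ref_span, c.read_id))
        clusters: list[list[ChimeraCandidate]] = []
        cluster_end = -1
        for cand in cands:
            s, e = cand.tgt_hit.ref_span
            if clusters and s < cluster_end:
                clusters[-1].append(cand)
                cluster_end = max(cluster_end, e)
            else:
                clusters.append([cand])
                cluster_end = e
        sites: list[Site] = []
        for cluster in clusters:
            seen_reads: dict[str, int] = {}
            for cand in cluster:
                seen_reads.setdefault(cand.read_id, cand.read_count)
            best = min(cluster, key=lambda c: (c.hybrid_dG, -c.combined_score, c.read_id))
            hull = (
                min(c.tgt_hit.ref_span[0] for c in cluster),
                max(c.tgt_hit.ref_span[1] for c in cluster),
            )
            sites.append(
                Site(
                    tgt_span=(hull[0] + 1, hull[1]),
                    reg_span=(best.reg_hit.ref_span[0] + 1, best.reg_hit.ref_span[1]),
                    read_count=sum(seen_reads.values()),
                    n_unique=len(seen_reads),
                    hybrid_dG=best.hybrid_dG,
                    diagram=best.duplex.diagram if best.duplex is not None else "",
                    read_ids=sorted(seen_reads),
                )
            )
        pair_reads: dict[str, int] = {}
        for cand in cands:
            pair_reads.setdefault(cand.read_id, cand.read_count)
        interactions.append(
            Interaction(
                reg_name=reg_name,
                tgt_name=tgt_name,
                sites=sites,
                total_read_count=sum(pair_reads.values()),
                n_unique_chimeras=len(pair_reads),
            )
        )
    return interactions


def view_by_regulatory(interactions: list[Interaction]) -> list[tuple]:
    """(reg_name, n_targets, n_unique_chimeras, total_read_count), sorted by
    descending target count then name."""
    agg: dict[str, dict] = {}
    for it in interactions:
        entry = agg.setdefault(it.reg_name, {"targets": set(), "uniq": 0, "count": 0})
        entry["targets"].add(it.tgt_name)
        entry["uniq"] += it.n_unique_chimeras
        entry["count"] += it.total_read_count
    rows = [
        (name, len(e["targets"]), e["uniq"], e["count"]) for name, e in agg.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def view_by_target(interactions: list[Interaction]) -> list[tuple]:
    """(tgt_name, n_unique_chimeras, n_regulatory, total_read_count), sorted
    by descending unique-chimera count then name."""
    agg: dict[str, dict] = {}
    for it in interactions:
        entry = agg.setdefault(it.tgt_name, {"regs": set(), "uniq": 0, "count": 0})
        entry["regs"].add(it.reg_name)
        entry["uniq"] += it.n_unique_chimeras
        entry["count"] += it.total_read_count
    rows = [
        (name, e["uniq"], len(e["regs"]), e["count"]) for name, e in agg.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def view_by_pair(interactions: list[Interaction], sort_key: str = "read_count") -> list[tuple]:
    """One row per site: (reg, tgt, tgt_start, tgt_end, reg_start, reg_end,
    read_count, hybrid_dG, region, diagram).

    ``sort_key='read_count'`` ranks by descending support (ties: lower dG);
    ``sort_key='energy'`` by ascending dG (ties: higher support).
    """
    if sort_key not in ("read_count", "energy"):
        raise ValueError(f"unknown sort key {sort_key!r}; use 'read_count' or 'energy'")
    rows = []
    for it in interactions:
        for site in it.sites:
            rows.append(
                (
                    it.reg_name, it.tgt_name,
                    site.tgt_span[0], site.tgt_span[1],
                    site.reg_span[0], site.reg_span[1],
                    site.read_count, site.hybrid_dG, site.region, site.diagram,
                )
            )
    if sort_key == "read_count":
        rows.sort(key=lambda r: (-r[6], r[7], r[0], r[1], r[2]))
    else:
        rows.sort(key=lambda r: (r[7], -r[6], r[0], r[1], r[2]))
    return rows


@dataclass
class RegionTable:
    """Region annotation of targets: (tgt_name, label, 1-based inclusive span).

    Intervals must not overlap within a transcript.
    """

    rows: list[tuple[str, str, int, int]]

    def __post_init__(self) -> None:
        by_tgt: dict[str, list[tuple[int, int]]] = {}
        for tgt, _, start, end in self.rows:
            if start > end or start < 1:
                raise ValueError(f"invalid region interval {start}-{end} on {tgt}")
            by_tgt.setdefault(tgt, []).append((start, end))
        for tgt, spans in by_tgt.items():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping regions on {tgt}")

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tgt, label, start, end = line.split("\t")[:4]
                rows.append((tgt, label, int(start), int(end)))
        return cls(rows)

    @classmethod
    def from_bed(cls, path) -> "RegionTable":
        """BED input: 0-based half-open converted to 1-based inclusive."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                tgt, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else "region"
                rows.append((tgt, label, start + 1, end))
        return cls(rows)


def annotate_regions(
    interactions: list[Interaction], regions: RegionTable
) -> dict[str, int]:
    """Label each site with the region holding the majority of its target
    span (boundary ties go to the downstream-most region); returns site
    counts per label. Sites on transcripts absent from the table are
    'unannotated'."""
    by_tgt: dict[str, list[tuple[str, int, int]]] = {}
    for tgt, label, start, end in regions.rows:
        by_tgt.setdefault(tgt, []).append((label, start, end))
    for spans in by_tgt.values():
        spans.sort(key=lambda r: r[1])

    summary: dict[str, int] = {}
    for it in interactions:
        spans = by_tgt.get(it.tgt_name)
        for site in it.sites:
            if spans is None:
                site.region = "unannotated"
            else:
                s, e = site.tgt_span
                best_label, best_ov, best_start = "unannotated", 0, -1
                for label, rs, re_ in spans:
                    ov = min(e, re_) - max(s, rs) + 1
                    # ties go downstream (larger region start)
                    if ov > 0 and (ov > best_ov or (ov == best_ov and rs > best_start)):
                        best_label, best_ov, best_start = label, ov, rs
                site.region = best_label
            summary[site.region] = summary.get(site.region, 0) + 1
    return summary


def summarize(stats: ReadStats, params: dict) -> tuple[list[tuple], list[tuple]]:
    """The two run-summary tables: (parameter, value) rows for every setting
    actually used, and the read-accounting counts."""
    param_rows = [(key, str(value)) for key, value in params.items()]
    count_rows = [
        ("reads_input", stats.n_input),
        ("reads_after_trimming", stats.n_after_trim),
        ("unique_reads_after_trimming", stats.n_unique_after_trim),
        ("reads_identified_as_chimeric", stats.n_chimeric),
        ("rna_rna_interactions", stats.n_interactions),
    ]
    return param_rows, count_rows


PER_READ_HEADER = [
    "read_id", "count",
    "reg_name", "reg_read_start", "reg_read_end", "reg_ref_start", "reg_ref_end",
    "tgt_name", "tgt_read_start", "tgt_read_end", "tgt_ref_start", "tgt_ref_end",
    "orientation", "overlap_nt", "gap_nt", "score", "hybrid_dG_kcal_mol",
]


def per_read_rows(candidates: Sequence[ChimeraCandidate]) -> list[tuple]:
    """Per-read candidate table rows (coordinates 1-based inclusive), sorted
    by read_id then descending score."""
    rows = []
    for c in candidates:
        rows.append(
            (
                c.read_id, c.read_count,
                c.reg_hit.ref_name,
                c.reg_hit.read_span[0] + 1, c.reg_hit.read_span[1],
                c.reg_hit.ref_span[0] + 1, c.reg_hit.ref_span[1],
                c.tgt_hit.ref_name,
                c.tgt_hit.read_span[0] + 1, c.tgt_hit.read_span[1],
                c.tgt_hit.ref_span[0] + 1, c.tgt_hit.ref_span[1],
                c.orientation, c.overlap_nt, c.gap_nt,
                c.combined_score, c.hybrid_dG,
            )
        )
    rows.sort(key=lambda r: (r[0], -r[15], r[2], r[7], r[3], r[8]))
    return rows


def write_reports(
    out_dir,
    candidates: Sequence[ChimeraCandidate],
    interactions: list[Interaction],
    stats: ReadStats,
    params: dict,
    pair_sort: str = "read_count",
) -> None:
    """Write the four browse CSVs plus the parameters and counts tables.

    Coordinate columns are 1-based inclusive (stated in the headers).
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv_table(per_read_rows(candidates), PER_READ_HEADER, out_dir / "per_read.csv")
    write_csv_table(
        view_by_regulatory(interactions),
        ["reg_name", "n_targets", "n_unique_chimeras", "total_read_count"],
        out_dir / "by_regulatory.csv",
    )
    write_csv_table(
        view_by_target(interactions),
        ["tgt_name", "n_unique_chimeras", "n_regulatory", "total_read_count"],
        out_dir / "by_target.csv",
    )
    write_csv_table(
        view_by_pair(interactions, pair_sort),
        [
            "reg_name", "tgt_name",
            "tgt_start_1based", "tgt_end_1based",
            "reg_start_1based", "reg_end_1based",
            "read_count", "hybrid_dG_kcal_mol", "region", "pairing_diagram",
        ],
        out_dir / "by_pair.csv",
    )
    param_rows, count_rows = summarize(stats, params)
    write_csv_table(param_rows, ["parameter", "value"], out_dir / "parameters.csv")
    write_csv_table(count_rows, ["metric", "value"], out_dir / "counts.csv")
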