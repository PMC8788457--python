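"""Chimeric-read identification under three stringency modes.

A chimeric CLASH read carries a regulatory-RNA fragment ligated to a target-RNA
fragment (either order). Three search modes trade sensitivity for stringency:

* ``strict``   — the read must contain an intact, full-length regulatory RNA
  matched exactly, and the entire remaining sequence must match a target RNA
  exactly with no insertion between the fragments (piRTarBase-like).
* ``scored``   — gapped local alignment of both fragments; of all valid
  fragment pairings, only the single highest-scoring interpretation is kept
  (Hyb-like).
* ``exhaustive`` — gapped local alignment; every valid interpretation is
  reported, so one read may support several interactions (CLAN-like; the
  pipeline default).

Both fragments map sense to their references: the chimera contains both
molecules' sequences, and complementarity between them is assessed only by the
duplex-energy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from .io_formats import Read, SequenceSet


@dataclass
class SearchParams:
    """Knobs of the chimera search.

    ``max_overlap`` bases at the ligation junction may map to both fragments
    simultaneously (default 4); ``max_gap_between`` unassigned bases may sit
    between them (0 in strict mode). ``max_hits_per_fragment`` caps how many
    references each fragment may match.
    """

    mode: str = "exhaustive"
    min_fragment_len: int = 16
    max_overlap: int = 4
    max_gap_between: int | None = None
    max_hits_per_fragment: int = 10
    align_match: float = 1.0
    align_mismatch: float = -2.0
    align_gap_open: float = -5.0
    align_gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "scored", "exhaustive"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.min_fragment_len < 8:
            raise ValueError("min_fragment_len must be >= 8")
        if self.max_overlap < 0:
            raise ValueError("max_overlap must be >= 0")
        if self.max_hits_per_fragment < 1:
            raise ValueError("max_hits_per_fragment must be >= 1")
        if self.max_gap_between is None:
            self.max_gap_between = 0 if self.mode == "strict" else 4


@dataclass(frozen=True)
class FragmentHit:
    """One fragment of a read mapped to one reference (sense strand).

    Spans are 0-based half-open; strict-mode hits have no mismatches or
    indels.
    """

    ref_name: str
    ref_role: str
    read_span: tuple[int, int]
    ref_span: tuple[int, int]
    n_mismatch: int = 0
    n_indel: int = 0
    align_score: float = 0.0


@dataclass
class ChimeraCandidate:
    """One interpretation of one read as (regulatory, target) fragments."""

    read_id: str
    read_count: int
    reg_hit: FragmentHit
    tgt_hit: FragmentHit
    orientation: str  # reg_first | target_first
    overlap_nt: int
    gap_nt: int
    combined_score: float
    duplex: object = None  # DuplexResult, attached by duplex_energy.score_chimeras

    @property
    def hybrid_dG(self) -> float:
        return self.duplex.dG if self.duplex is not None and self.duplex.stable else 0.0

    def sort_key(self):
        return (
            -self.combined_score,
            self.reg_hit.ref_name,
            self.tgt_hit.ref_name,
            self.orientation,
            self.reg_hit.read_span,
            self.tgt_hit.read_span,
        )


@dataclass
class SeqIndex:
    """Exact k-mer seed index over one reference set."""

    role: str
    k: int
    refs: SequenceSet
    seeds: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.seeds.get(kmer, [])


def build_index(refs: SequenceSet, k: int = 12) -> SeqIndex:
    """Index every k-mer of every reference to its occurrence positions."""
    seeds: dict[str, list[tuple[str, int]]] = {}
    for name, seq in refs.items():
        if len(seq) < k:
            raise ValueError(f"reference {name!r} is shorter than seed length k={k}")
        for off in range(len(seq) - k + 1):
            seeds.setdefault(seq[off : off + k], []).append((name, off))
    return SeqIndex(role=refs.role, k=k, refs=refs, seeds=seeds)


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def find_fragments_exact(read: Read, index: SeqIndex, min_fragment_len: int) -> list[FragmentHit]:
    """All maximal exact matches of length >= min_fragment_len between the
    read and any reference, by seed-and-extend. N never matches.
    """
    seq = _as_rna(read.sequence)
    k = index.k
    found: set[tuple[str, int, int, int]] = set()
    hits: list[FragmentHit] = []
    for s in range(len(seq) - k + 1):
        kmer = seq[s : s + k]
        if "N" in kmer:
            continue
        for ref_name, off in index.lookup(kmer):
            ref = index.refs[ref_name]
            rs, os_ = s, off
            while rs > 0 and os_ > 0 and seq[rs - 1] == ref[os_ - 1] and seq[rs - 1] != "N":
                rs -= 1
                os_ -= 1
            re_, oe = s + k, off + k
            while re_ < len(seq) and oe < len(ref) and seq[re_] == ref[oe] and seq[re_] != "N":
                re_ += 1
                oe += 1
            if re_ - rs < min_fragment_len:
                continue
            key = (ref_name, rs, re_, os_)
            if key in found:
                continue
            found.add(key)
            hits.append(
                FragmentHit(
                    ref_name=ref_name,
                    ref_role=index.role,
                    read_span=(rs, re_),
                    ref_span=(os_, oe),
                    align_score=float(re_ - rs),
                )
            )
    hits.sort(key=lambda h: (-h.align_score, h.ref_name, h.read_span, h.ref_span))
    return hits


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.align_match
    aligner.mismatch_score = params.align_mismatch
    aligner.open_gap_score = params.align_gap_open
    aligner.extend_gap_score = params.align_gap_extend
    return aligner


def find_fragments_aligned(read: Read, index: SeqIndex, params: SearchParams) -> list[FragmentHit]:
    """Seed-and-extend gapped local alignment of read fragments to references.

    References sharing at least one exact k-mer with the read are aligned with
    Smith-Waterman (scoring from ``params``); hits must score above
    min_fragment_len * align_match * 0.8 and span at least min_fragment_len on
    the read. At most ``max_hits_per_fragment`` hits are kept, by descending
    score.
    """
    seq = _as_rna(read.sequence)
    k = index.k
    candidate_refs: list[str] = []
    seen: set[str] = set()
    for s in range(len(seq) - k + 1):
        kmer = seq[s : s + k]
        if "N" in kmer:
            continue
        for ref_name, _ in index.lookup(kmer):
            if ref_name not in seen:
                seen.add(ref_name)
                candidate_refs.append(ref_name)
    if not candidate_refs:
        return []
    aligner = _make_aligner(params)
    threshold = params.min_fragment_len * params.align_match * 0.8
    hits: list[FragmentHit] = []
    for ref_name in candidate_refs:
        ref = index.refs[ref_name]
        alignments = aligner.align(seq, ref)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        if aln.score <= threshold:
            continue
        read_blocks, ref_blocks = aln.aligned
        read_span = (int(read_blocks[0][0]), int(read_blocks[-1][1]))
        ref_span = (int(ref_blocks[0][0]), int(ref_blocks[-1][1]))
        if read_span[1] - read_span[0] < params.min_fragment_len:
            continue
        n_mismatch = sum(
            1
            for (ra, rb), (oa, _) in zip(read_blocks, ref_blocks)
            for t in range(rb - ra)
            if seq[ra + t] != ref[oa + t]
        )
        n_indel = (read_span[1] - read_span[0] - sum(rb - ra for ra, rb in read_blocks)) + (
            ref_span[1] - ref_span[0] - sum(ob - oa for oa, ob in ref_blocks)
        )
        hits.append(
            FragmentHit(
                ref_name=ref_name,
                ref_role=index.role,
                read_span=read_span,
                ref_span=ref_span,
                n_mismatch=n_mismatch,
                n_indel=n_indel,
                align_score=float(aln.score),
            )
        )
    hits.sort(key=lambda h: (-h.align_score, h.ref_name, h.read_span, h.ref_span))
    return hits[: params.max_hits_per_fragment]


def pair_fragments(
    read: Read,
    reg_hits: list[FragmentHit],
    tgt_hits: list[FragmentHit],
    params: SearchParams,
) -> list[ChimeraCandidate]:
    """Combine regulatory and target fragment hits of one read into chimera
    candidates, in either ligation order, honoring the junction overlap and
    gap budgets. combined_score = sum of alignment scores - overlap.
    """
    candidates: list[ChimeraCandidate] = []
    for reg in reg_hits:
        for tgt in tgt_hits:
            if reg.read_span[0] <= tgt.read_span[0]:
                first, second = reg, tgt
                orientation = "reg_first"
            else:
                first, second = tgt, reg
                orientation = "target_first"
            delta = second.read_span[0] - first.read_span[1]
            overlap = max(0, -delta)
            gap = max(0, delta)
            if second.read_span[1] <= first.read_span[1]:
                continue  # nested spans are not a ligation junction
            if overlap > params.max_overlap or gap > params.max_gap_between:
                continue
            candidates.append(
                ChimeraCandidate(
                    read_id=read.read_id,
                    read_count=read.count,
                    reg_hit=reg,
                    tgt_hit=tgt,
                    orientation=orientation,
                    overlap_nt=overlap,
                    gap_nt=gap,
                    combined_score=reg.align_score + tgt.align_score - overlap,
                )
            )
    candidates.sort(key=ChimeraCandidate.sort_key)
    return candidates


def search_strict(
    read: Read, reg_index: SeqIndex, tgt_index: SeqIndex, params: SearchParams
) -> list[ChimeraCandidate]:
    """Intact-guide search: the full regulatory sequence must occur exactly in
    the read, at one end of it, and the entire remainder must match a target
    reference exactly (>= min_fragment_len). No mismatches, indels, junction
    overlaps or insertions are tolerated. All qualifying interpretations are
    returned.
    """
    seq = _as_rna(read.sequence)
    candidates: list[ChimeraCandidate] = []
    for reg_name, reg_seq in reg_index.refs.items():
        start = seq.find(reg_seq)
        while start != -1:
            end = start + len(reg_seq)
            remainder: Optional[tuple[int, int, str]] = None
            if start == 0 and end < len(seq):
                remainder = (end, len(seq), "reg_first")
            elif end == len(seq) and start > 0:
                remainder = (0, start, "target_first")
            if remainder is not None:
                r0, r1, orientation = remainder
                tgt_frag = seq[r0:r1]
                if len(tgt_frag) >= params.min_fragment_len and "N" not in tgt_frag:
                    reg_hit = FragmentHit(
                        ref_name=reg_name,
                        ref_role="regulatory",
                        read_span=(start, end),
                        ref_span=(0, len(reg_seq)),
                        align_score=float(len(reg_seq)),
                    )
                    n_tgt = 0
                    for tgt_name, tgt_seq in tgt_index.refs.items():
                        pos = tgt_seq.find(tgt_frag)
                        while pos != -1 and n_tgt < params.max_hits_per_fragment:
                            tgt_hit = FragmentHit(
                                ref_name=tgt_name,
                                ref_role="target",
                                read_span=(r0, r1),
                                ref_span=(pos, pos + len(tgt_frag)),
                                align_score=float(len(tgt_frag)),
                            )
                            candidates.append(
                                ChimeraCandidate(
                                    read_id=read.read_id,
                                    read_count=read.count,
                                    reg_hit=reg_hit,
                                    tgt_hit=tgt_hit,
                                    orientation=orientation,
                                    overlap_nt=0,
                                    gap_nt=0,
                                    combined_score=reg_hit.align_score + tgt_hit.align_score,
                                )
                            )
                            n_tgt += 1
                            pos = tgt_seq.find(tgt_frag, pos + 1)
            start = seq.find(reg_seq, start + 1)
    candidates.sort(key=ChimeraCandidate.sort_key)
    return candidates


def _aligned_candidates(
    read: Read, reg_index: SeqIndex, tgt_index: SeqIndex, params: SearchParams
) -> list[ChimeraCandidate]:
    reg_hits = find_fragments_aligned(read, reg_index, params)
    if not reg_hits:
        return []
    tgt_hits = find_fragments_aligned(read, tgt_index, params)
    if not tgt_hits:
        return []
    return pair_fragments(read, reg_hits, tgt_hits, params)


def search_scored(
    read: Read, reg_index: SeqIndex, tgt_index: SeqIndex, params: SearchParams
) -> list[ChimeraCandidate]:
    """Single best interpretation per read (highest combined score; ties to
    the lexicographically smaller (regulatory, target) names)."""
    candidates = _aligned_candidates(read, reg_index, tgt_index, params)
    return candidates[:1]


def search_exhaustive(
    read: Read, reg_index: SeqIndex, tgt_index: SeqIndex, params: SearchParams
) -> list[ChimeraCandidate]:
    """All interpretations, sorted by descending combined score.

    Includes both gapped-alignment interpretations and intact-guide (strict)
    interpretations, so the strict-mode output is always a subset of the
    exhaustive-mode output: the stringency ordering of the three modes.
    """
    candidates = _aligned_candidates(read, reg_index, tgt_index, params)
    strict_params = SearchParams(
        mode="strict",
        min_fragment_len=params.min_fragment_len,
        max_hits_per_fragment=params.max_hits_per_fragment,
    )
    seen = {
        (c.reg_hit.ref_name, c.reg_hit.read_span, c.reg_hit.ref_span,
         c.tgt_hit.ref_name, c.tgt_hit.read_span, c.tgt_hit.ref_span, c.orientation)
        for c in candidates
    }
    for cand in search_strict(read, reg_index, tgt_index, strict_params):
        key = (
            cand.reg_hit.ref_name, cand.reg_hit.read_span, cand.reg_hit.ref_span,
            cand.tgt_hit.ref_name, cand.tgt_hit.read_span, cand.tgt_hit.ref_span,
            cand.orientation,
        )
        if key not in seen:
            seen.add(key)
            candidates.append(cand)
    candidates.sort(key=ChimeraCandidate.sort_key)
    return candidates


SEARCHERS = {
    "strict": search_strict,
    "scored": search_scored,
    "exhaustive": search_exhaustive,
}


def search_reads(
    reads: list[Read],
    reg_index: SeqIndex,
    tgt_index: SeqIndex,
    params: SearchParams,
) -> list[ChimeraCandidate]:
    """Run the configured search mode over a collection of unique reads."""
    searcher = SEARCHERS[params.mode]
    out: list[ChimeraCandidate] = []
    for read in reads:
        out.extend(searcher(read, reg_index, tgt_index, params))
    return out
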