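"""Synthetic CLASH library generator with known ground truth.

Emulates the CLASH library structure: a chimeric insert (regulatory fragment
ligated to a target fragment, either order) flanked by a 5' barcode/UMI and a
3' adaptor, mixed with non-chimeric background reads, with optional per-base
substitution errors. Every planted chimera is recorded in a manifest that the
recovery tests use as oracle.

All randomness flows through a single numpy ``default_rng(seed)`` (PCG64), so
identical seeds give byte-identical libraries on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .io_formats import Read, SequenceSet, write_fasta, write_fastq

BASES = np.array(list("ACGU"))
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SynthConfig:
    """Study conditions for one simulated library.

    Defaults emulate a small-RNA CLASH experiment: guides of miRNA/piRNA size
    (19-31 nt), mRNA-sized targets (200-1500 nt) each carrying one perfectly
    complementary site for some guide, reads built as
    barcode/UMI + insert + 3' adaptor with constant Q40 qualities (Q20 at
    simulated errors).
    """

    seed: int = 1
    n_regulatory: int = 20
    n_target: int = 20
    reg_len: tuple[int, int] = (19, 31)
    tgt_len: tuple[int, int] = (200, 1500)
    n_chimeric_reads: int = 200
    n_background_reads: int = 100
    n_decoy_chimeras: int = 0
    frac_target_first: float = 0.3
    complementary_site: bool = True
    mismatches_in_site: int = 0
    adapter5: str = ""
    adapter3: str = "AGAUCGGAAGAGCACACGUC"
    barcode5_pattern: str = "NNNNNN"
    error_rate: float = 0.0
    indel_rate: float = 0.0
    decoy_multimap: bool = False
    max_site_flank: int = 8
    #: library size selection: inserts never exceed this length
    max_insert_len: int = 70

    def __post_init__(self) -> None:
        for frac in (self.frac_target_first, self.error_rate, self.indel_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for count in (
            self.n_regulatory, self.n_target, self.n_chimeric_reads,
            self.n_background_reads, self.n_decoy_chimeras,
        ):
            if count < 0:
                raise ValueError("counts must be >= 0")


class PlantedSite(NamedTuple):
    """Where a complementary guide site was planted in one target."""

    reg_name: str
    start: int  # 0-based half-open on the target
    end: int


@dataclass
class ManifestRow:
    """Ground truth for one planted chimeric read (spans 0-based half-open)."""

    read_id: str
    kind: str  # "true" (complementary site) or "decoy" (random ligation)
    reg_name: str
    reg_start: int
    reg_end: int
    tgt_name: str
    tgt_start: int
    tgt_end: int
    orientation: str
    insert: str
    umi: str


@dataclass
class GroundTruthManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def by_read(self) -> dict[str, ManifestRow]:
        return {row.read_id: row for row in self.rows}

    HEADER = [
        "read_id", "kind", "reg_name", "reg_start", "reg_end",
        "tgt_name", "tgt_start", "tgt_end", "orientation", "insert", "umi",
    ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("\t".join(self.HEADER) + "\n")
            for r in self.rows:
                out.write(
                    "\t".join(
                        str(v)
                        for v in (
                            r.read_id, r.kind, r.reg_name, r.reg_start, r.reg_end,
                            r.tgt_name, r.tgt_start, r.tgt_end, r.orientation,
                            r.insert, r.umi,
                        )
                    )
                    + "\n"
                )


class SynthReferences(NamedTuple):
    regulatory: SequenceSet
    target: SequenceSet
    planted_sites: dict[str, PlantedSite]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def generate_references(cfg: SynthConfig, rng: np.random.Generator | None = None) -> SynthReferences:
    """Random regulatory and target reference sets.

    With ``complementary_site`` each target carries one embedded reverse
    complement of a full regulatory sequence (with ``mismatches_in_site``
    substitutions); with ``decoy_multimap`` one 20-mer is copied into two
    targets to create an ambiguous mapping.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    reg_names, reg_seqs = [], {}
    for idx in range(cfg.n_regulatory):
        name = f"reg{idx + 1:03d}"
        reg_names.append(name)
        reg_seqs[name] = _random_seq(rng, int(rng.integers(cfg.reg_len[0], cfg.reg_len[1] + 1)))
    regulatory = SequenceSet(role="regulatory", names=reg_names, sequences=reg_seqs)

    tgt_names, tgt_seqs = [], {}
    planted: dict[str, PlantedSite] = {}
    for idx in range(cfg.n_target):
        name = f"tgt{idx + 1:03d}"
        length = int(rng.integers(cfg.tgt_len[0], cfg.tgt_len[1] + 1))
        seq = list(_random_seq(rng, length))
        if cfg.complementary_site and cfg.n_regulatory > 0:
            # round-robin guide assignment keeps planted sites unique across
            # targets whenever n_target <= n_regulatory
            reg_name = reg_names[idx % cfg.n_regulatory]
            site = list(reverse_complement(reg_seqs[reg_name]))
            for _ in range(cfg.mismatches_in_site):
                pos = int(rng.integers(len(site)))
                site[pos] = str(rng.choice([b for b in "ACGU" if b != site[pos]]))
            start = int(rng.integers(0, length - len(site) + 1))
            seq[start : start + len(site)] = site
            planted[name] = PlantedSite(reg_name, start, start + len(site))
        tgt_names.append(name)
        tgt_seqs[name] = "".join(seq)
    if cfg.decoy_multimap and cfg.n_target >= 2:
        kmer = _random_seq(rng, 20)
        for name in tgt_names[:2]:
            seq = tgt_seqs[name]
            pos = int(rng.integers(0, len(seq) - 20 + 1))
            site = planted.get(name)
            if site is not None and not (pos + 20 <= site.start or pos >= site.end):
                pos = 0 if site.start >= 20 else site.end
            tgt_seqs[name] = seq[:pos] + kmer + seq[pos + 20 :]
    target = SequenceSet(role="target", names=tgt_names, sequences=tgt_seqs)
    return SynthReferences(regulatory, target, planted)


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    chars = list(seq)
    errored = []
    for i, base in enumerate(chars):
        if rng.random() < error_rate:
            choices = [b for b in "ACGU" if b != base]
            chars[i] = str(rng.choice(choices))
            errored.append(i)
    return "".join(chars), errored


def _assemble_read(
    rng: np.random.Generator, read_id: str, insert: str, cfg: SynthConfig
) -> tuple[Read, str]:
    umi_chars = []
    prefix = []
    for pat in cfg.barcode5_pattern:
        if pat == "N":
            base = str(rng.choice(BASES))
            umi_chars.append(base)
            prefix.append(base)
        else:
            prefix.append(pat)
    umi = "".join(umi_chars)
    raw = "".join(prefix) + insert + cfg.adapter3
    seq, errored = _apply_errors(rng, raw, cfg.error_rate)
    quals = [40] * len(seq)
    for i in errored:
        quals[i] = 20
    return Read(read_id, seq, quals), umi


def generate_reads(
    refs: SynthReferences, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[Read], GroundTruthManifest]:
    """Build the simulated library in memory.

    Chimeric reads use the full regulatory sequence as the guide fragment and
    the planted complementary site (plus random flanks up to
    ``max_site_flank``) as the target fragment; decoy chimeras ligate a guide
    to a uniformly random target fragment. Background reads are 50/50
    single-reference fragments and uniform random sequence.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    regulatory, target, planted = refs.regulatory, refs.target, refs.planted_sites
    reads: list[Read] = []
    manifest = GroundTruthManifest()

    plantable = [t for t in target.names if t in planted]
    for idx in range(cfg.n_chimeric_reads):
        read_id = f"chim{idx + 1:05d}"
        tgt_name = plantable[int(rng.integers(len(plantable)))]
        site = planted[tgt_name]
        reg_seq = regulatory[site.reg_name]
        tgt_seq = target[tgt_name]
        budget = max(0, cfg.max_insert_len - (site.end - site.start) - len(reg_seq))
        left = min(int(rng.integers(0, cfg.max_site_flank + 1)), budget)
        right = min(int(rng.integers(0, cfg.max_site_flank + 1)), budget - left)
        t0 = max(0, site.start - left)
        t1 = min(len(tgt_seq), site.end + right)
        tgt_frag = tgt_seq[t0:t1]
        orientation = "target_first" if rng.random() < cfg.frac_target_first else "reg_first"
        insert = tgt_frag + reg_seq if orientation == "target_first" else reg_seq + tgt_frag
        read, umi = _assemble_read(rng, read_id, insert, cfg)
        reads.append(read)
        manifest.rows.append(
            ManifestRow(
                read_id, "true", site.reg_name, 0, len(reg_seq),
                tgt_name, t0, t1, orientation, insert, umi,
            )
        )

    for idx in range(cfg.n_decoy_chimeras):
        read_id = f"decoy{idx + 1:05d}"
        reg_name = regulatory.names[int(rng.integers(len(regulatory.names)))]
        reg_seq = regulatory[reg_name]
        tgt_name = target.names[int(rng.integers(len(target.names)))]
        tgt_seq = target[tgt_name]
        frag_len = int(rng.integers(17, 31))
        t0 = int(rng.integers(0, max(1, len(tgt_seq) - frag_len + 1)))
        t1 = min(len(tgt_seq), t0 + frag_len)
        tgt_frag = tgt_seq[t0:t1]
        orientation = "target_first" if rng.random() < cfg.frac_target_first else "reg_first"
        insert = tgt_frag + reg_seq if orientation == "target_first" else reg_seq + tgt_frag
        read, umi = _assemble_read(rng, read_id, insert, cfg)
        reads.append(read)
        manifest.rows.append(
            ManifestRow(
                read_id, "decoy", reg_name, 0, len(reg_seq),
                tgt_name, t0, t1, orientation, insert, umi,
            )
        )

    for idx in range(cfg.n_background_reads):
        read_id = f"bg{idx + 1:05d}"
        if rng.random() < 0.5 and len(target.names) > 0:
            tgt_name = target.names[int(rng.integers(len(target.names)))]
            tgt_seq = target[tgt_name]
            frag_len = int(rng.integers(17, min(61, len(tgt_seq) + 1)))
            t0 = int(rng.integers(0, max(1, len(tgt_seq) - frag_len + 1)))
            insert = tgt_seq[t0 : t0 + frag_len]
        else:
            insert = _random_seq(rng, int(rng.integers(20, 61)))
        read, _ = _assemble_read(rng, read_id, insert, cfg)
        reads.append(read)

    return reads, manifest


def generate_library(
    refs: SynthReferences, cfg: SynthConfig, out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[Path, GroundTruthManifest]:
    """Write reads.fastq.gz, regulatory.fa, targets.fa and truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, manifest = generate_reads(refs, cfg, rng)
    fastq = out_dir / "reads.fastq.gz"
    write_fastq(reads, fastq)
    write_fasta(refs.regulatory.items(), out_dir / "regulatory.fa")
    write_fasta(refs.target.items(), out_dir / "targets.fa")
    manifest.write_tsv(out_dir / "truth.tsv")
    return fastq, manifest


@dataclass
class RecoveryStats:
    precision: float
    recall: float
    span_exact: float
    n_true_positive: int = 0
    n_candidates: int = 0
    n_truth: int = 0


def evaluate_recovery(candidates, manifest: GroundTruthManifest, read_members=None) -> RecoveryStats:
    """Compare pipeline candidates against the planted truth.

    A candidate is a true positive iff (reg_name, tgt_name, orientation)
    matches the manifest row of its read; span-exact additionally requires the
    fragments' reference spans to equal the planted ones. ``read_members``
    maps a collapsed unique read id to the original read ids it represents.
    """
    truth = manifest.by_read()
    n_candidates = 0
    n_tp_candidates = 0
    matched: set[str] = set()
    span_exact: set[str] = set()
    for cand in candidates:
        n_candidates += 1
        originals = read_members.get(cand.read_id, [cand.read_id]) if read_members else [cand.read_id]
        is_tp = False
        for rid in originals:
            row = truth.get(rid)
            if row is None:
                continue
            if (
                row.reg_name == cand.reg_hit.ref_name
                and row.tgt_name == cand.tgt_hit.ref_name
                and row.orientation == cand.orientation
            ):
                is_tp = True
                matched.add(rid)
                if (
                    cand.reg_hit.ref_span == (row.reg_start, row.reg_end)
                    and cand.tgt_hit.ref_span == (row.tgt_start, row.tgt_end)
                ):
                    span_exact.add(rid)
        if is_tp:
            n_tp_candidates += 1
    n_truth = len(manifest)
    return RecoveryStats(
        precision=n_tp_candidates / n_candidates if n_candidates else 0.0,
        recall=len(matched) / n_truth if n_truth else 0.0,
        span_exact=len(span_exact) / n_truth if n_truth else 0.0,
        n_true_positive=n_tp_candidates,
        n_candidates=n_candidates,
        n_truth=n_truth,
    )
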