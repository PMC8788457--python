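"""Native read preprocessing: adaptor/barcode/UMI trimming, filtering, collapsing.

The CLASH library layout is  5' barcode/UMI -- insert -- 3' adaptor.  Stages
run in that physical order: 5' trim (barcode + UMI extraction), 3' adaptor
trim, length/quality filter, then collapsing identical molecules to unique
reads with counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .io_formats import Read

BARCODE_ALPHABET = set("ACGUN")


@dataclass
class TrimConfig:
    """Trimming and filtering parameters.

    ``barcode5_pattern`` is given over {A,C,G,U,N} where each N marks a UMI
    position (e.g. ``"NNNNNN"`` for a 6-nt UMI); fixed bases must match the
    read exactly. Reads of 17-70 nt with mean Phred >= 30 are kept by default.
    """

    adapter5: str = ""
    barcode5_pattern: str = ""
    adapter3: str = ""
    min_len: int = 17
    max_len: int = 70
    min_phred: int = 30
    min_adapter_overlap: int = 3
    max_trim_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        self.adapter5 = self.adapter5.upper().replace("T", "U")
        self.adapter3 = self.adapter3.upper().replace("T", "U")
        self.barcode5_pattern = self.barcode5_pattern.upper().replace("T", "U")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"need 0 < min_len <= max_len, got {self.min_len}..{self.max_len}")
        if not (0 <= self.min_phred <= 93):
            raise ValueError(f"min_phred must be in [0, 93], got {self.min_phred}")
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")
        bad = set(self.barcode5_pattern) - BARCODE_ALPHABET
        if bad:
            raise ValueError(f"barcode5_pattern has invalid characters {sorted(bad)}")

    @property
    def umi_aware(self) -> bool:
        return "N" in self.barcode5_pattern


@dataclass
class ReadStats:
    """Read accounting across the pipeline (the run-summary counts)."""

    n_input: int = 0
    n_after_trim: int = 0
    n_unique_after_trim: int = 0
    n_chimeric: int = 0
    n_interactions: int = 0
    discard_reasons: dict[str, int] = field(default_factory=dict)


def phred_to_accuracy(q: float) -> float:
    """Probability that a base call with Phred score ``q`` is correct.

    Q = -10*log10(P_error), so accuracy = 1 - 10^(-q/10): Q30 -> 0.999,
    Q50 -> 0.99999.
    """
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def _matches(observed: str, expected: str, max_rate: float) -> bool:
    """Mismatch-tolerant equality; N in the read never matches."""
    mismatches = sum(1 for o, e in zip(observed, expected) if o != e or o == "N")
    return mismatches <= int(max_rate * len(expected))


def trim_adapter3(read: Read, cfg: TrimConfig) -> Read:
    """Trim the 3' adaptor: the leftmost occurrence of an adaptor prefix that
    runs through the read's 3' end (or a full internal occurrence), at least
    ``min_adapter_overlap`` long and within the mismatch-rate budget.

    No match leaves the read unchanged.
    """
    adapter = cfg.adapter3
    if not adapter:
        return read
    seq = read.sequence
    rna = seq.replace("T", "U")
    for start in range(len(seq)):
        olen = min(len(adapter), len(seq) - start)
        if olen < cfg.min_adapter_overlap:
            break
        if _matches(rna[start : start + olen], adapter[:olen], cfg.max_trim_mismatch_rate):
            return replace(
                read, sequence=seq[:start], qualities=read.qualities[:start], members=list(read.members)
            )
    return read


class ReadDiscarded(Exception):
    """Signals that a read failed a hard preprocessing check."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def trim_5prime(read: Read, cfg: TrimConfig) -> Read:
    """Remove the 5' adaptor and barcode/UMI, populating ``read.umi``.

    The (optional) fixed 5' adaptor is removed first: the longest suffix of
    ``adapter5`` found at the read start within the mismatch budget. Then the
    barcode pattern is consumed: N positions become the UMI, fixed positions
    must match exactly. A fixed-base mismatch or a too-short read raises
    :class:`ReadDiscarded`.
    """
    seq = read.sequence
    quals = read.qualities
    if cfg.adapter5:
        rna = seq.replace("T", "U")
        for olen in range(min(len(cfg.adapter5), len(seq)), cfg.min_adapter_overlap - 1, -1):
            if _matches(rna[:olen], cfg.adapter5[-olen:], cfg.max_trim_mismatch_rate):
                seq, quals = seq[olen:], quals[olen:]
                break
    pattern = cfg.barcode5_pattern
    if not pattern:
        return replace(read, sequence=seq, qualities=quals, members=list(read.members))
    if len(seq) < len(pattern):
        raise ReadDiscarded("read_shorter_than_barcode")
    umi_chars = []
    for base, pat in zip(seq, pattern):
        rna_base = "U" if base == "T" else base
        if pat == "N":
            umi_chars.append(base)
        elif rna_base != pat:
            raise ReadDiscarded("barcode_mismatch")
    n = len(pattern)
    return replace(
        read,
        sequence=seq[n:],
        qualities=quals[n:],
        umi="".join(umi_chars),
        members=list(read.members),
    )


def filter_read(read: Read, cfg: TrimConfig) -> bool:
    """Keep iff min_len <= length <= max_len and mean Phred >= min_phred."""
    n = len(read.sequence)
    if n < cfg.min_len or n > cfg.max_len:
        return False
    return read.mean_quality >= cfg.min_phred


def collapse_reads(reads: Iterable[Read], umi_aware: bool = True) -> list[Read]:
    """Merge reads with identical sequence (and identical UMI when
    ``umi_aware``) into unique reads with counts.

    The representative keeps the first read's id; all merged ids are recorded
    in ``members``. Output is sorted by descending count, then sequence.
    """
    groups: dict[tuple, Read] = {}
    for read in reads:
        key = (read.sequence, read.umi) if umi_aware else (read.sequence,)
        kept = groups.get(key)
        if kept is None:
            groups[key] = replace(read, count=read.count, members=[read.read_id])
        else:
            kept.count += read.count
            kept.members.append(read.read_id)
    return sorted(groups.values(), key=lambda r: (-r.count, r.sequence, r.umi))


def preprocess_run(
    reads: Iterable[Read], cfg: TrimConfig
) -> tuple[list[Read], ReadStats]:
    """Run 5' trim -> 3' trim -> length/quality filter -> collapse.

    Returns the unique surviving reads and a partially filled
    :class:`ReadStats` (input / after-trim / unique counts plus per-reason
    discard tallies).
    """
    stats = ReadStats()
    survivors: list[Read] = []
    for read in reads:
        stats.n_input += 1
        try:
            read = trim_5prime(read, cfg)
        except ReadDiscarded as exc:
            stats.discard_reasons[exc.reason] = stats.discard_reasons.get(exc.reason, 0) + 1
            continue
        read = trim_adapter3(read, cfg)
        if not filter_read(read, cfg):
            reason = "length_out_of_range" if not (
                cfg.min_len <= len(read.sequence) <= cfg.max_len
            ) else "low_quality"
            stats.discard_reasons[reason] = stats.discard_reasons.get(reason, 0) + 1
            continue
        survivors.append(read)
    stats.n_after_trim = len(survivors)
    unique = collapse_reads(survivors, umi_aware=cfg.umi_aware)
    stats.n_unique_after_trim = len(unique)
    return unique, stats
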