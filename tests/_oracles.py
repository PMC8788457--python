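"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code path with the package internals they check:
fragment search is validated against an all-substrings scan, and the duplex
dynamic program against exhaustive enumeration of every antiparallel pairing.
"""

from __future__ import annotations

import math

from clashkit.duplex_energy import EnergyModel, structure_energy

PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}


def brute_force_fragments(read_seq: str, refs: dict[str, str], min_len: int):
    """All maximal exact matches >= min_len between a read and references,
    found by scanning every (read offset, reference offset) pair."""
    hits = set()
    n = len(read_seq)
    for name, ref in refs.items():
        m = len(ref)
        for rs in range(n):
            for os_ in range(m):
                if read_seq[rs] != ref[os_] or read_seq[rs] == "N":
                    continue
                # left-maximality: skip if the previous position also matches
                if rs > 0 and os_ > 0 and read_seq[rs - 1] == ref[os_ - 1] and read_seq[rs - 1] != "N":
                    continue
                length = 0
                while (
                    rs + length < n
                    and os_ + length < m
                    and read_seq[rs + length] == ref[os_ + length]
                    and read_seq[rs + length] != "N"
                ):
                    length += 1
                if length >= min_len:
                    hits.add((name, (rs, rs + length), (os_, os_ + length)))
    return hits


def enumerate_duplex_min(a: str, b: str, model: EnergyModel) -> float:
    """Minimum energy over every valid antiparallel pairing of a and b
    (math.inf when no pairing is possible)."""
    n, m = len(a), len(b)
    best = math.inf

    def rec(i: int, j: int, pairs: list[tuple[int, int]]) -> None:
        nonlocal best
        if pairs:
            energy = structure_energy(pairs, a, b, model)
            if energy < best:
                best = energy
        for ii in range(i, n):
            for jj in range(j, -1, -1):
                if (a[ii], b[jj]) in PAIRABLE:
                    rec(ii + 1, jj - 1, pairs + [(ii, jj)])

    rec(0, m - 1, [])
    return best
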