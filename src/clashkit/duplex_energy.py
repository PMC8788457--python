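"""Intermolecular RNA/RNA duplex free energy and pairing structure.

Predicts the minimum-free-energy hybrid between a regulatory RNA fragment and
its target fragment, considering *intermolecular* base pairs only (no hairpin
/ accessibility terms). The model is a nearest-neighbor stack model: duplex
initiation penalty, Watson-Crick and GU-wobble helix-step stacking energies,
affine bulge and internal-loop penalties, and a terminal penalty for AU/GU
closing pairs. Lower dG means a thermodynamically more favorable interaction;
a hybrid whose best total dG is not negative is reported as having no stable
duplex.

Parameters ship as a human-readable TSV (``data/rna_duplex_params.tsv``) and
can be substituted wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}
GU_PAIRS = {("G", "U"), ("U", "G")}
WEAK_TERMINAL = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
RNA_ALPHABET = set("ACGU")

_EPS = 1e-6


@dataclass
class EnergyModel:
    """Nearest-neighbor duplex energy parameters (kcal/mol, 37 C).

    ``stack_dG`` keys are helix steps ``"XY/ZW"``: top strand 5'-XY-3' over
    bottom strand 3'-ZW-5' (pairs X:Z and Y:W). Bulge/internal loop penalties
    are affine in total loop length; loops longer than ``max_loop`` on either
    side are disallowed.
    """

    stack_dG: dict[str, float]
    init_dG: float
    terminal_AU_dG: float
    bulge_open_dG: float
    bulge_ext_dG: float
    internal_open_dG: float
    internal_ext_dG: float
    max_loop: int = 30

    def __post_init__(self) -> None:
        for key, value in self.stack_dG.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite stack energy for step {key}")
        for penalty in (
            self.terminal_AU_dG, self.bulge_open_dG, self.bulge_ext_dG,
            self.internal_open_dG, self.internal_ext_dG,
        ):
            if penalty < 0:
                raise ValueError("loop/terminal penalties must be >= 0")

    def stack(self, x: str, z: str, y: str, w: str) -> float:
        """Energy of stacking pair (x:z) under pair (y:w)."""
        return self.stack_dG[f"{x}{y}/{z}{w}"]

    def bulge(self, length: int) -> float:
        return self.bulge_open_dG + self.bulge_ext_dG * length

    def internal(self, length: int) -> float:
        return self.internal_open_dG + self.internal_ext_dG * length

    def loop_cost(self, da: int, db: int) -> float:
        """Penalty for da unpaired bases in a and db in b between two pairs."""
        if da == 0 and db == 0:
            raise ValueError("adjacent pairs stack; no loop")
        if da > self.max_loop or db > self.max_loop or da + db > self.max_loop:
            return math.inf
        if da == 0 or db == 0:
            return self.bulge(da + db)
        return self.internal(da + db)

    def terminal(self, x: str, z: str) -> float:
        return self.terminal_AU_dG if (x, z) in WEAK_TERMINAL else 0.0


def load_energy_model(path: str | Path | None = None) -> EnergyModel:
    """Load the packaged parameter table, or a user-supplied one."""
    if path is None:
        source = resources.files("clashkit.data").joinpath("rna_duplex_params.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    stacks: dict[str, float] = {}
    params: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            stacks[key] = float(value)
        elif kind == "param":
            params[key] = float(value)
        else:
            raise ValueError(f"unknown parameter row kind {kind!r}")
    return EnergyModel(
        stack_dG=stacks,
        init_dG=params["init_dG"],
        terminal_AU_dG=params["terminal_AU_dG"],
        bulge_open_dG=params["bulge_open_dG"],
        bulge_ext_dG=params["bulge_ext_dG"],
        internal_open_dG=params["internal_open_dG"],
        internal_ext_dG=params["internal_ext_dG"],
        max_loop=int(params["max_loop"]),
    )


_DEFAULT_MODEL: EnergyModel | None = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


@dataclass
class DuplexResult:
    """Minimum-energy intermolecular pairing between two fragments.

    ``pairs`` are 0-based (position in a, position in b), strictly increasing
    in a and strictly decreasing in b (antiparallel, no pseudoknots). When no
    pairing achieves negative free energy, ``stable`` is False, ``pairs`` is
    empty and ``dG`` is reported as 0.0.
    """

    dG: float
    pairs: list[tuple[int, int]]
    stable: bool
    n_wc: int = 0
    n_gu: int = 0
    n_unpaired_a: int = 0
    n_unpaired_b: int = 0
    diagram: str = ""


def _check_rna(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid RNA characters {sorted(bad)}")


def structure_energy(
    pairs: list[tuple[int, int]], a: str, b: str, model: EnergyModel
) -> float:
    """Total free energy of an explicit antiparallel pairing.

    Shared by the DP and by the brute-force enumeration used to validate it.
    """
    if not pairs:
        return math.inf
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j1 > j2):
            raise ValueError("pairs must increase in a and decrease in b")
    total = model.init_dG
    first_i, first_j = pairs[0]
    last_i, last_j = pairs[-1]
    total += model.terminal(a[first_i], b[first_j])
    total += model.terminal(a[last_i], b[last_j])
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        da, db = i2 - i1 - 1, j1 - j2 - 1
        if da == 0 and db == 0:
            total += model.stack(a[i1], b[j1], a[i2], b[j2])
        else:
            total += model.loop_cost(da, db)
    return total


def duplex_fold(seq_a: str, seq_b: str, model: EnergyModel | None = None) -> DuplexResult:
    """Minimum-free-energy intermolecular duplex between two RNA fragments.

    Dynamic program over all antiparallel pairings (WC + GU), O(n*m*L^2) with
    loop size capped at ``model.max_loop``. Ties are broken toward structures
    with more base pairs, then toward the leftmost structure.
    """
    model = model or default_energy_model()
    _check_rna(seq_a, "seq_a")
    _check_rna(seq_b, "seq_b")
    if len(seq_a) > 200 or len(seq_b) > 200:
        raise ValueError("duplex_fold supports fragments up to 200 nt")

    n, m = len(seq_a), len(seq_b)
    L = model.max_loop
    # loop-cost lookup for window transitions; (0,0) handled as a stack
    cost = np.full((L + 1, L + 1), np.inf)
    for da in range(L + 1):
        for db in range(L + 1):
            if da == 0 and db == 0:
                continue
            if da + db <= L:
                cost[da, db] = model.bulge(da + db) if (da == 0 or db == 0) else model.internal(da + db)

    can_pair = np.zeros((n, m), dtype=bool)
    for i, x in enumerate(seq_a):
        for j, y in enumerate(seq_b):
            can_pair[i, j] = (x, y) in PAIRABLE

    H = np.full((n, m), np.inf)   # min energy of structure whose last pair is (i,j)
    K = np.zeros((n, m), dtype=int)  # pair count among those optima
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not can_pair[i, j]:
                continue
            options = [(model.init_dG + model.terminal(seq_a[i], seq_b[j]), 1)]
            # stack on the immediately preceding pair
            if i >= 1 and j + 1 < m and np.isfinite(H[i - 1, j + 1]):
                cand = H[i - 1, j + 1] + model.stack(seq_a[i - 1], seq_b[j + 1], seq_a[i], seq_b[j])
                options.append((cand, K[i - 1, j + 1] + 1))
            # loop transition from any pair in the (max_loop) window
            p0 = max(0, i - 1 - L)
            q1 = min(m, j + 2 + L)
            sub = H[p0:i, j + 1 : q1]
            if sub.size:
                wa, wb = sub.shape
                total = sub + cost[:wa][::-1, :wb]
                wmin = total.min()
                if np.isfinite(wmin):
                    mask = total < wmin + _EPS
                    k_cand = int(K[p0:i, j + 1 : q1][mask].max()) + 1
                    options.append((float(wmin), k_cand))
            best = min(value for value, _ in options)
            best_k = max(k for value, k in options if value < best + _EPS)
            H[i, j] = best
            K[i, j] = best_k

    # close the duplex: add the terminal penalty of the last pair
    best_total = math.inf
    best_cell: tuple[int, int] | None = None
    best_k = -1
    for i in range(n):
        for j in range(m):
            if not np.isfinite(H[i, j]):
                continue
            total = H[i, j] + model.terminal(seq_a[i], seq_b[j])
            if (
                total < best_total - _EPS
                or (abs(total - best_total) <= _EPS and K[i, j] > best_k)
            ):
                best_total, best_cell, best_k = min(total, best_total), (i, j), K[i, j]

    if best_cell is None or best_total >= -_EPS:
        return DuplexResult(
            dG=0.0, pairs=[], stable=False,
            n_unpaired_a=n, n_unpaired_b=m,
            diagram="",
        )

    pairs = _traceback(H, K, best_cell, seq_a, seq_b, model)
    energy = structure_energy(pairs, seq_a, seq_b, model)
    n_gu = sum(1 for i, j in pairs if (seq_a[i], seq_b[j]) in GU_PAIRS)
    result = DuplexResult(
        dG=round(energy, 6),
        pairs=pairs,
        stable=True,
        n_wc=len(pairs) - n_gu,
        n_gu=n_gu,
        n_unpaired_a=n - len(pairs),
        n_unpaired_b=m - len(pairs),
    )
    result.diagram = render_diagram(result, seq_a, seq_b)
    return result


def _traceback(
    H: np.ndarray, K: np.ndarray, cell: tuple[int, int], a: str, b: str, model: EnergyModel
) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    i, j = cell
    L = model.max_loop
    while True:
        pairs.append((i, j))
        value = H[i, j]
        first_cost = model.init_dG + model.terminal(a[i], b[j])
        if K[i, j] == 1 and abs(value - first_cost) <= _EPS:
            break
        candidates: list[tuple[int, int]] = []
        if i >= 1 and j + 1 < len(b) and np.isfinite(H[i - 1, j + 1]):
            cand = H[i - 1, j + 1] + model.stack(a[i - 1], b[j + 1], a[i], b[j])
            if abs(cand - value) <= _EPS and K[i - 1, j + 1] + 1 == K[i, j]:
                candidates.append((i - 1, j + 1))
        if not candidates:
            for p in range(i - 1, max(0, i - 1 - L) - 1, -1):
                for q in range(j + 1, min(len(b), j + 2 + L)):
                    if not np.isfinite(H[p, q]):
                        continue
                    da, db = i - p - 1, q - j - 1
                    if da == 0 and db == 0:
                        continue
                    lc = cost_of(model, da, db)
                    if not math.isfinite(lc):
                        continue
                    if abs(H[p, q] + lc - value) <= _EPS and K[p, q] + 1 == K[i, j]:
                        candidates.append((p, q))
            # deterministic: prefer the closest predecessor (smallest loop),
            # then leftmost in a
            candidates.sort(key=lambda pq: (i - pq[0] - 1 + pq[1] - j - 1, i - pq[0], pq[0]))
        if not candidates:  # numerical safety net
            break
        i, j = candidates[0]
    pairs.reverse()
    return pairs


def cost_of(model: EnergyModel, da: int, db: int) -> float:
    if da > model.max_loop or db > model.max_loop or da + db > model.max_loop:
        return math.inf
    return model.bulge(da + db) if (da == 0 or db == 0) else model.internal(da + db)


def render_diagram(result: DuplexResult, seq_a: str, seq_b: str) -> str:
    """Three-line text rendering of the duplex.

    Line 1: seq_a 5'->3'. Line 2: '|' for WC pairs, ':' for GU, ' ' elsewhere.
    Line 3: seq_b 3'->5'. Bulged columns are padded with '-' on the gapless
    strand.
    """
    if result.pairs:
        max_i = max(i for i, _ in result.pairs)
        max_j = max(j for _, j in result.pairs)
        if max_i >= len(seq_a) or max_j >= len(seq_b):
            raise ValueError("diagram requested for sequences shorter than the structure")
    top: list[str] = []
    mid: list[str] = []
    bot: list[str] = []

    def emit_unpaired(a_seg: str, b_seg: str) -> None:
        width = max(len(a_seg), len(b_seg))
        top.append(a_seg.ljust(width, "-") if width else "")
        bot.append(b_seg.ljust(width, "-") if width else "")
        mid.append(" " * width)

    if not result.pairs:
        emit_unpaired(seq_a, seq_b[::-1])
    else:
        prev_i, prev_j = -1, len(seq_b)
        for i, j in result.pairs:
            a_seg = seq_a[prev_i + 1 : i]
            b_seg = seq_b[j + 1 : prev_j][::-1]
            emit_unpaired(a_seg, b_seg)
            top.append(seq_a[i])
            bot.append(seq_b[j])
            mid.append(":" if (seq_a[i], seq_b[j]) in GU_PAIRS else "|")
            prev_i, prev_j = i, j
        emit_unpaired(seq_a[prev_i + 1 :], seq_b[:prev_j][::-1])
    lines = ["".join(top), "".join(mid), "".join(bot)]
    width = max(len(l) for l in lines)
    return "\n".join(l.ljust(width) for l in lines)


def score_chimeras(candidates, regulatory, targets, model: EnergyModel | None = None):
    """Attach a DuplexResult (regulatory fragment vs target fragment) to each
    chimera candidate; identical fragment pairs are folded once.

    Fragment sequences are taken from the reference sets at the candidate's
    reference spans.
    """
    model = model or default_energy_model()
    cache: dict[tuple[str, str], DuplexResult] = {}
    for cand in candidates:
        reg_seq = regulatory[cand.reg_hit.ref_name][
            cand.reg_hit.ref_span[0] : cand.reg_hit.ref_span[1]
        ]
        tgt_seq = targets[cand.tgt_hit.ref_name][
            cand.tgt_hit.ref_span[0] : cand.tgt_hit.ref_span[1]
        ]
        key = (reg_seq, tgt_seq)
        if key not in cache:
            cache[key] = duplex_fold(reg_seq, tgt_seq, model)
        cand.duplex = cache[key]
    return candidates
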