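import numpy as np
import pytest

from clashkit.chimera_search import SearchParams, build_index, search_reads
from clashkit.preprocess import TrimConfig, preprocess_run
from clashkit.synth import SynthConfig, generate_reads, generate_references


@pytest.fixture
def small_refs():
    """Tiny hand-built reference sets with one planted complementary pair."""
    from clashkit.io_formats import SequenceSet
    from clashkit.synth import reverse_complement

    reg = "UCCCUGAGACCUCAAGUGUGA"  # 21 nt
    site = reverse_complement(reg)
    tgt = "ACGGAUUACCGAGGAAGCCUAAG" + site + "CCAAGGUUCAACGGAUCCAGAUU"
    regulatory = SequenceSet(
        role="regulatory", names=["lin-4"], sequences={"lin-4": reg}
    )
    targets = SequenceSet(role="target", names=["tA"], sequences={"tA": tgt})
    return regulatory, targets, reg, tgt, site


def make_library(seed: int, **overrides):
    """Generate a small in-memory synthetic library plus its truth manifest."""
    defaults = dict(
        seed=seed, n_regulatory=12, n_target=12, tgt_len=(150, 400),
        n_chimeric_reads=60, n_background_reads=30,
    )
    defaults.update(overrides)
    cfg = SynthConfig(**defaults)
    rng = np.random.default_rng(cfg.seed)
    refs = generate_references(cfg, rng)
    reads, manifest = generate_reads(refs, cfg, rng)
    return cfg, refs, reads, manifest


def run_search(cfg, refs, reads, mode: str):
    """Preprocess a simulated library and run one search mode.

    Returns (candidates, unique reads, stats, collapsed-read membership map).
    """
    trim = TrimConfig(
        adapter5=cfg.adapter5,
        barcode5_pattern=cfg.barcode5_pattern,
        adapter3=cfg.adapter3,
    )
    unique, stats = preprocess_run(reads, trim)
    params = SearchParams(mode=mode)
    k = 12 if mode == "strict" else 8
    reg_index = build_index(refs.regulatory, k=k)
    tgt_index = build_index(refs.target, k=k)
    candidates = search_reads(unique, reg_index, tgt_index, params)
    members = {r.read_id: r.members for r in unique}
    return candidates, unique, stats, members
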