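import numpy as np
import pytest

import mitoval as mv


@pytest.fixture(scope="session")
def ref_full():
    """Full-length (16,569 nt) synthetic circular reference with the
    canonical poly-C homopolymer tracts planted."""
    return mv.synthetic_reference(seed=7)


@pytest.fixture(scope="session")
def panel_full(ref_full):
    return mv.simulate_panel(109, 163, 11, L=ref_full.length, seed=3)


@pytest.fixture(scope="session")
def ref_small():
    """1,200 nt circle (fast tests); carries the 303-315 and 568-573 tracts."""
    return mv.synthetic_reference(L=1200, seed=5)


@pytest.fixture(scope="session")
def panel_small(ref_small):
    return mv.simulate_panel(12, 120, 10, L=ref_small.length, seed=2)


def transition(base: str) -> str:
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


def variant_positions(ref, n, start=101, step=97):
    """n well-spaced positions avoiding homopolymer tracts (for clean calls)."""
    out = []
    pos = start
    while len(out) < n:
        s, e = ref.homopolymer_run(pos)
        if e - s + 1 < 3:
            out.append(pos)
        pos += step
        if pos > ref.length - 100:
            raise RuntimeError("ran out of positions")
    return out


def flat_pileup(ref, depth=100, sample_id="flat"):
    """Reference-matching pileup at a constant even depth, balanced strands."""
    half = depth // 2
    positions = {
        pos: mv.PositionCounts(pos, {ref.base(pos): (half, depth - half)})
        for pos in range(1, ref.length + 1)
    }
    return mv.Pileup(sample_id=sample_id, positions=positions)
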