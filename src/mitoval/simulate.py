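"""Seedable generators for panels, pileups, mixtures, negatives, and dilutions.

The generator emulates the statistical structure that the analysis modules
assume of tiled short-amplicon mtGenome sequencing:

* per-amplicon depth: a target median scaled by a per-amplicon balance
  profile and log-normal run-to-run dispersion; per-position read counts are
  Poisson around the summed depth of covering amplicons, so amplicon
  overlaps are deeper than amplicon interiors;
* allele counts: multinomial over A/C/G/T/del with probabilities set by the
  contributor haplotype(s), heteroplasmy fractions, and a uniform
  substitution miscall rate; strands split binomially;
* homopolymer indel noise: at the 3' end of each homopolymer tract, indel
  probability grows linearly with tract length (``base_indel x length``) --
  long poly-C stretches are noisy, unique sequence is quiet;
* NUMT carry-in: a *fixed* read count at catalogued positions, independent of
  mitochondrial depth (nuclear copy number does not dilute with mtDNA), so
  NUMT-associated variant frequencies rise as input falls;
* negatives: a configurable percentage of a paired positive's depth plus
  localized primer-artifact hotspots;
* two-contributor mixtures: each read drawn from the minor contributor with
  probability ``mixture_minor_fraction``.

``stochastic=False`` switches every draw to deterministic rounding of its
expectation, producing the exact allele frequencies of a noiseless design
(used for threshold-boundary analyses). Every output is bit-for-bit
reproducible from the scenario seed, and every generator returns a
machine-readable truth record alongside the pileup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .pileup import Pileup, PositionCounts
from .reference import (
    Amplicon,
    MtReference,
    Panel,
    RCRS_LENGTH,
    VariantName,
    parse_variant,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_DEL = 4  # column index of the deletion state


@dataclass
class DepthModel:
    """Target per-amplicon median depth with dispersion and balance profile."""

    median: float = 1000.0
    amplicon_sigma: float = 0.25  # log-normal sigma of per-amplicon depth
    balance: dict[str, float] = field(default_factory=dict)  # amplicon id -> multiplier


@dataclass
class ErrorModel:
    substitution_rate: float = 0.002  # per read-base miscall probability
    base_indel_rate: float = 0.005  # indel prob = base_indel x tract length
    min_tract_length: int = 2  # tracts shorter than this get no indel noise
    insertion_share: float = 0.5  # of the indel probability; rest is deletion


@dataclass
class NumtModel:
    catalog: dict[int, str]  # position -> nuclear-insert allele
    read_count: int = 0  # fixed, independent of mtDNA depth


@dataclass
class NegativeModel:
    scale_pct: float = 1.0  # background depth as % of the paired positive
    hotspots: list[tuple[int, int, float]] = field(default_factory=list)
    # (start, end, relative depth %) primer-artifact spans


@dataclass
class SimScenario:
    """Full generative description of one simulated sample."""

    reference: MtReference
    panel: Panel
    haplotypes: list[list[str]] = field(default_factory=lambda: [[]])
    variant_fractions: dict[str, float] = field(default_factory=dict)
    mixture_minor_fraction: float = 0.0
    depth: DepthModel = field(default_factory=DepthModel)
    error: ErrorModel = field(default_factory=ErrorModel)
    numt: NumtModel | None = None
    negative: NegativeModel | None = None
    strand_fraction: float = 0.5
    stochastic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.haplotypes) <= 2:
            raise ValueError("scenario takes one or two contributor haplotypes")
        if not 0 <= self.mixture_minor_fraction < 1:
            raise ValueError("mixture_minor_fraction must be in [0, 1)")
        for f in self.variant_fractions.values():
            if not 0 < f <= 1:
                raise ValueError("variant fractions must be in (0, 1]")


# ---------------------------------------------------------------------------
# Panel generator


def simulate_panel(
    n_amplicons: int,
    target_mean_length: float,
    target_mean_overlap: float,
    L: int = RCRS_LENGTH,
    seed: int = 0,
) -> Panel:
    """Circularly tiled overlapping amplicons, pools alternating 1/2.

    Amplicon boundaries are evenly spaced with small seeded jitter; each
    amplicon is extended by the target overlap so adjacent spans share bases
    and coverage of the circle is complete. The achieved mean length and
    overlap are descriptive statistics recomputed by the Panel itself.
    """
    # achieved integer lengths may exceed the target mean by up to 1 bp each
    # (boundary rounding), so feasibility allows that slack
    if n_amplicons * (target_mean_length + 1 - target_mean_overlap) < L:
        raise ValueError(
            "infeasible panel: n_amplicons * (mean_length + 1 - mean_overlap) = "
            f"{n_amplicons} * ({target_mean_length} + 1 - {target_mean_overlap}) "
            f"= {n_amplicons * (target_mean_length + 1 - target_mean_overlap):.0f} "
            f"< L = {L}"
        )
    rng = np.random.default_rng(seed)
    bounds = [round(i * L / n_amplicons) for i in range(n_amplicons + 1)]
    if n_amplicons > 1:
        jitter = rng.integers(-2, 3, size=n_amplicons - 1)
        for i in range(1, n_amplicons):
            lo, hi = bounds[i - 1] + 1, bounds[i + 1] - 1
            bounds[i] = int(min(max(bounds[i] + jitter[i - 1], lo), hi))
    overlap = int(round(target_mean_overlap))
    amplicons = []
    for i in range(n_amplicons):
        start = bounds[i] + 1
        end = bounds[i + 1] + (overlap if n_amplicons > 1 else 0)
        if end > L:
            end -= L  # wraps across the origin
        amplicons.append(
            Amplicon(id=f"mt_{i + 1}", pool=1 + i % 2, start=start, end=end)
        )
    panel = Panel(amplicons=amplicons, L=L)
    panel.check_coverage()
    return panel


# ---------------------------------------------------------------------------
# Reference generator (synthetic stand-in; rCRS itself is not distributed here)


def synthetic_reference(L: int = RCRS_LENGTH, seed: int = 2024) -> MtReference:
    """A SYNTHETIC rCRS-like circular reference.

    Random sequence of length *L* with the characteristic error-prone poly-C
    homopolymer tracts planted at the canonical control-region coordinates
    (HVII 303-309 and 311-315 separated by 310T, HVI 16184-16193, and
    568-573) when *L* accommodates them. This is a stand-in for testing and
    simulation, not the real reference; load the actual rCRS from FASTA for
    casework coordinates.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(_BASES), size=L, p=[0.31, 0.31, 0.13, 0.25])
    # keep the background largely homopolymer-free so planted tracts dominate
    for i in range(2, L):
        if seq[i] == seq[i - 1] == seq[i - 2]:
            choices = [b for b in _BASES if b != seq[i - 1]]
            seq[i] = choices[rng.integers(len(choices))]
    tracts = [(303, 309, "C"), (310, 310, "T"), (311, 315, "C"),
              (16184, 16193, "C"), (568, 573, "C")]
    for start, end, base in tracts:
        if end <= L:
            seq[start - 1 : end] = base
            if end < L and seq[end] == base:  # terminate the tract crisply
                seq[end] = "T" if base != "T" else "A"
            if start >= 2 and seq[start - 2] == base:
                seq[start - 2] = "T" if base != "T" else "A"
    return MtReference(name=f"synthetic_circle_{L}", sequence="".join(seq))


# ---------------------------------------------------------------------------
# Pileup generator


def _coverage_index(panel: Panel, L: int) -> list[tuple[Amplicon, np.ndarray]]:
    out = []
    for a in panel.amplicons:
        out.append((a, np.fromiter(a.positions(L), dtype=np.int64) - 1))
    return out


def _haplotype_matrix(
    ref: MtReference, variants: list[str], fractions: dict[str, float]
) -> tuple[np.ndarray, dict[int, tuple[str, float]]]:
    """(L, 5) allele-probability matrix for one contributor, plus its
    insertion events {anchor position -> (inserted sequence, carry fraction)}."""
    L = ref.length
    P = np.zeros((L, 5))
    ref_idx = np.fromiter((_BASE_INDEX[b] for b in ref.sequence), dtype=np.int64)
    P[np.arange(L), ref_idx] = 1.0
    ins_groups: dict[int, list[VariantName]] = {}
    for name in variants:
        v = parse_variant(name) if isinstance(name, str) else name
        frac = fractions.get(str(v), 1.0)
        if v.kind == "insertion":
            ins_groups.setdefault(v.position, []).append(v)
            continue
        row = P[v.position - 1]
        if v.kind == "substitution":
            row[:] = 0.0
            row[_BASE_INDEX[v.allele]] = frac
            row[ref_idx[v.position - 1]] += 1.0 - frac
        elif v.kind == "deletion":
            row *= 1.0 - frac
            row[_DEL] += frac
        elif v.kind == "heteroplasmy":
            raise ValueError(
                f"specify heteroplasmies as a substitution with a fraction, not {name!r}"
            )
        else:
            raise ValueError(f"cannot simulate variant kind {v.kind!r} ({name})")
    insertions: dict[int, tuple[str, float]] = {}
    for pos, group in ins_groups.items():
        group.sort(key=lambda v: v.insert_index)
        seq = "".join(v.allele for v in group)
        frac = fractions.get(str(group[0]), 1.0)
        insertions[pos] = (seq, frac)
    return P, insertions


def _tract_ends(ref: MtReference, min_len: int) -> list[tuple[int, int]]:
    """(0-based end index, tract length) of each homopolymer run >= min_len."""
    ends = []
    seq = ref.sequence
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            ends.append((j, j - i + 1))
        i = j + 1
    return ends


def _round_multinomial(n: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Deterministic expectation-rounding with the residual on the largest cell."""
    counts = np.floor(n[:, None] * P + 0.5).astype(np.int64)
    short = n - counts.sum(axis=1)
    top = np.argmax(P, axis=1)
    counts[np.arange(len(n)), top] += short
    np.maximum(counts, 0, out=counts)
    return counts


def simulate_pileup(
    sc: SimScenario,
    rng: np.random.Generator | None = None,
    depth_scale: float = 1.0,
) -> tuple[Pileup, dict]:
    """Draw a per-position stranded pileup for the scenario.

    Returns the pileup and a truth record listing every injected variant with
    its expected (pre-error) frequency, the expected mixed-variant positions,
    and the NUMT catalog in play.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    ref, panel = sc.reference, sc.panel
    L = ref.length

    # expected depth per position: sum of covering amplicons' depths
    expected = np.zeros(L)
    for amp, idx in _coverage_index(panel, L):
        d = sc.depth.median * depth_scale * sc.depth.balance.get(amp.id, 1.0)
        if sc.stochastic and sc.depth.amplicon_sigma > 0:
            d *= rng.lognormal(0.0, sc.depth.amplicon_sigma)
        expected[idx] += d
    n = rng.poisson(expected) if sc.stochastic else np.round(expected).astype(np.int64)

    # contributor allele probabilities, mixture-weighted
    mats, ins_specs = [], []
    for hap in sc.haplotypes:
        P_h, ins_h = _haplotype_matrix(ref, hap, sc.variant_fractions)
        mats.append(P_h)
        ins_specs.append(ins_h)
    if len(mats) == 2 and sc.mixture_minor_fraction > 0:
        f = sc.mixture_minor_fraction
        P = (1 - f) * mats[0] + f * mats[1]
        ins_weights = [1 - f, f]
    else:
        P = mats[0]
        ins_weights = [1.0] + [0.0] * (len(mats) - 1)
    P_true = P.copy()

    # homopolymer indel noise at tract 3' ends, growing with tract length
    p_ins_noise = np.zeros(L)
    if sc.error is not None and sc.error.base_indel_rate > 0:
        for end_idx, tract_len in _tract_ends(ref, sc.error.min_tract_length):
            p_indel = min(sc.error.base_indel_rate * tract_len, 0.5)
            p_del = p_indel * (1 - sc.error.insertion_share)
            P[end_idx] *= 1 - p_del
            P[end_idx, _DEL] += p_del
            p_ins_noise[end_idx] = p_indel * sc.error.insertion_share

    # uniform substitution miscalls across the base states
    if sc.error is not None and sc.error.substitution_rate > 0:
        e = sc.error.substitution_rate
        base_mass = P[:, :4].sum(axis=1, keepdims=True)
        P[:, :4] = P[:, :4] * (1 - e) + (e / 3) * (base_mass - P[:, :4])

    P = P / P.sum(axis=1, keepdims=True)
    if sc.stochastic:
        counts = rng.multinomial(n, P)
    else:
        counts = _round_multinomial(n, P)

    # NUMT carry-in: fixed absolute read counts, independent of mtDNA depth
    if sc.numt is not None and sc.numt.read_count > 0:
        for pos, allele in sc.numt.catalog.items():
            counts[pos - 1, _BASE_INDEX[allele]] += sc.numt.read_count

    if sc.stochastic:
        fwd = rng.binomial(counts, sc.strand_fraction)
    else:
        fwd = np.floor(counts * sc.strand_fraction + 0.5).astype(np.int64)
    rev = counts - fwd

    # insertion-carrying reads (a subset of the reads counted above)
    ins_events: dict[int, dict[str, tuple[int, int]]] = {}

    def _draw_ins(pos0: int, p_carry: float, seq_dist: dict[str, float]) -> None:
        total_reads = int(counts[pos0, :4].sum())
        if total_reads == 0 or p_carry <= 0:
            return
        n_ins = (
            int(rng.binomial(total_reads, min(p_carry, 1.0)))
            if sc.stochastic
            else int(round(total_reads * min(p_carry, 1.0)))
        )
        if n_ins == 0:
            return
        seqs = list(seq_dist)
        probs = np.array([seq_dist[s] for s in seqs])
        probs = probs / probs.sum()
        if sc.stochastic:
            per_seq = rng.multinomial(n_ins, probs)
        else:
            per_seq = _round_multinomial(np.array([n_ins]), probs[None, :])[0]
        table = ins_events.setdefault(pos0 + 1, {})
        for s, c in zip(seqs, per_seq):
            if c == 0:
                continue
            f = (
                int(rng.binomial(c, sc.strand_fraction))
                if sc.stochastic
                else int(round(c * sc.strand_fraction))
            )
            f0, r0 = table.get(s, (0, 0))
            table[s] = (f0 + f, r0 + (c - f))

    for spec, w in zip(ins_specs, ins_weights):
        for pos, (seq, frac) in spec.items():
            if w <= 0:
                continue
            # reads show a variable number of inserted bases around the true one
            dist = {seq: 0.75}
            if sc.stochastic and sc.error is not None and sc.error.base_indel_rate > 0:
                if len(seq) > 1:
                    dist[seq[:-1]] = 0.15
                dist[seq + seq[-1]] = 0.10
            else:
                dist = {seq: 1.0}
            _draw_ins(pos - 1, w * frac, dist)
    if sc.stochastic:
        for pos0 in np.nonzero(p_ins_noise)[0]:
            _draw_ins(int(pos0), float(p_ins_noise[pos0]), {ref.sequence[pos0]: 1.0})

    # assemble the pileup
    positions: dict[int, PositionCounts] = {}
    nonzero = np.nonzero(counts.sum(axis=1))[0]
    for pos0 in nonzero:
        row = counts[pos0]
        table = {}
        for col, allele in enumerate(("A", "C", "G", "T", "del")):
            if row[col]:
                table[allele] = (int(fwd[pos0, col]), int(rev[pos0, col]))
        positions[int(pos0) + 1] = PositionCounts(
            position=int(pos0) + 1,
            counts=table,
            insertions=ins_events.get(int(pos0) + 1, {}),
        )

    truth = _truth_record(sc, P_true, depth_scale)
    pileup = Pileup(
        sample_id=f"sim_seed{sc.seed}",
        positions=positions,
        metadata={"seed": sc.seed, "depth_scale": depth_scale, "role": "sample"},
    )
    return pileup, truth


def _truth_record(sc: SimScenario, P_true: np.ndarray, depth_scale: float) -> dict:
    ref = sc.reference
    variants = []
    seen = set()
    for hap in sc.haplotypes:
        for name in hap:
            if name in seen:
                continue
            seen.add(name)
            v = parse_variant(name)
            if v.kind == "substitution":
                freq = float(P_true[v.position - 1, _BASE_INDEX[v.allele]])
            elif v.kind == "deletion":
                freq = float(P_true[v.position - 1, _DEL])
            else:
                w = 1.0
                if len(sc.haplotypes) == 2 and sc.mixture_minor_fraction > 0:
                    w = (
                        sc.mixture_minor_fraction
                        if name in sc.haplotypes[1] and name not in sc.haplotypes[0]
                        else 1 - sc.mixture_minor_fraction
                        if name not in sc.haplotypes[1]
                        else 1.0
                    )
                freq = w * sc.variant_fractions.get(name, 1.0)
            variants.append({"name": name, "true_frequency": freq})
    mv_positions: list[int] = []
    if len(sc.haplotypes) == 2 and sc.mixture_minor_fraction > 0:
        alleles = []
        for hap in sc.haplotypes:
            table = {}
            for name in hap:
                v = parse_variant(name)
                if v.kind == "substitution":
                    table[v.position] = v.allele
            alleles.append(table)
        for pos in sorted(set(alleles[0]) | set(alleles[1])):
            a0 = alleles[0].get(pos, ref.base(pos))
            a1 = alleles[1].get(pos, ref.base(pos))
            if a0 != a1:
                mv_positions.append(pos)
    return {
        "seed": sc.seed,
        "depth_scale": depth_scale,
        "minor_fraction": sc.mixture_minor_fraction,
        "haplotypes": [list(h) for h in sc.haplotypes],
        "variants": variants,
        "mv_positions": mv_positions,
        "numt_catalog": dict(sc.numt.catalog) if sc.numt else {},
        "numt_read_count": sc.numt.read_count if sc.numt else 0,
    }


def simulate_mixture(
    sc: SimScenario,
    minor_fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Pileup, dict]:
    """Two-contributor mixture draw; each read comes from the minor
    contributor with probability *minor_fraction*."""
    if len(sc.haplotypes) != 2:
        raise ValueError("simulate_mixture needs a scenario with two haplotypes")
    if minor_fraction is not None:
        sc = dc_replace(sc, mixture_minor_fraction=minor_fraction)
    if set(sc.haplotypes[0]) == set(sc.haplotypes[1]):
        warnings.warn(
            "contributor haplotypes are identical; the mixture is undetectable "
            "by design",
            stacklevel=2,
        )
    return simulate_pileup(sc, rng=rng)


def simulate_negative(
    sc: SimScenario,
    positive: Pileup,
    rng: np.random.Generator | None = None,
) -> Pileup:
    """Negative-control pileup: scaled background of the positive plus hotspots.

    Background depth is ``negative.scale_pct`` percent of the positive's depth
    at each position; hotspot spans override that with their own relative
    percentage (emulating primer artifacts in amplicon overlaps). All reads
    carry the reference base.
    """
    model = sc.negative or NegativeModel()
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    ref = sc.reference
    L = ref.length
    pos_depth = np.array([positive.depth(i) for i in range(1, L + 1)], dtype=float)
    rel = np.full(L, model.scale_pct / 100.0)
    for start, end, pct in model.hotspots:
        rel[start - 1 : end] = pct / 100.0
    expected = rel * pos_depth
    n = rng.poisson(expected) if sc.stochastic else np.round(expected).astype(np.int64)
    positions: dict[int, PositionCounts] = {}
    for pos0 in np.nonzero(n)[0]:
        c = int(n[pos0])
        f = int(rng.binomial(c, sc.strand_fraction)) if sc.stochastic else (c + 1) // 2
        positions[int(pos0) + 1] = PositionCounts(
            position=int(pos0) + 1,
            counts={ref.sequence[pos0]: (f, c - f)},
        )
    return Pileup(
        sample_id=f"neg_seed{sc.seed}",
        positions=positions,
        metadata={"seed": sc.seed, "role": "negative", "scale_pct": model.scale_pct},
    )


def dilution_series(
    sc: SimScenario, factors: list[float]
) -> list[tuple[Pileup, dict]]:
    """One pileup per dilution factor (descending), NUMT read count held fixed.

    Each step uses an independent child stream of the scenario seed, so the
    series is reproducible as a whole.
    """
    if any(f <= 0 for f in factors):
        raise ValueError("dilution factors must be positive")
    if list(factors) != sorted(factors, reverse=True):
        raise ValueError("dilution factors must be in descending order")
    out = []
    for i, f in enumerate(factors):
        rng = np.random.default_rng([sc.seed, i])
        pileup, truth = simulate_pileup(sc, rng=rng, depth_scale=f)
        pileup.metadata["dilution_factor"] = f
        pileup.sample_id = f"{pileup.sample_id}_dil{i}"
        out.append((pileup, truth))
    return out
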