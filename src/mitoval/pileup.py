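"""Stranded per-position allele counts and the frequency/bias primitives.

A :class:`PositionCounts` holds, for one circular-genome position, the number
of forward- and reverse-oriented reads supporting each of A/C/G/T/del, plus
insertion-supporting reads keyed by the inserted sequence. Total depth is the
sum over A/C/G/T/del only: insertion-carrying reads are a subset of those
reads (attached to their 5' anchor position) and are never double-counted.

All frequencies are fractions of total depth. A position with zero depth has
no defined frequency; asking for one raises :class:`UndefinedFrequencyError`
rather than silently returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

import pandas as pd

#: allele states that contribute to total depth
ALLELES = ("A", "C", "G", "T", "del")


class UndefinedFrequencyError(ValueError):
    """Frequency requested at a position with zero read depth."""


class DominantInsertion(NamedTuple):
    sequence: str
    fraction: float  # share of all insertion-supporting reads
    tie: bool


@dataclass
class PositionCounts:
    """Stranded read counts at one 1-based circular position."""

    position: int
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    insertions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.counts, self.insertions):
            for key, (fwd, rev) in table.items():
                if fwd < 0 or rev < 0:
                    raise ValueError(f"negative count for {key!r} at {self.position}")
        bad = set(self.counts) - set(ALLELES)
        if bad:
            raise ValueError(f"unknown allele keys {sorted(bad)} at {self.position}")

    def allele_depth(self, allele: str) -> int:
        fwd, rev = self.counts.get(allele, (0, 0))
        return fwd + rev

    def total_depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    def insertion_depth(self) -> int:
        return sum(f + r for f, r in self.insertions.values())

    def variant_frequency(self, allele: str) -> float:
        depth = self.total_depth()
        if depth == 0:
            raise UndefinedFrequencyError(f"zero depth at position {self.position}")
        return self.allele_depth(allele) / depth

    def insertion_frequency(self) -> float:
        depth = self.total_depth()
        if depth == 0:
            raise UndefinedFrequencyError(f"zero depth at position {self.position}")
        return self.insertion_depth() / depth

    def dominant_insertion(self) -> DominantInsertion:
        """The inserted sequence with the most supporting reads.

        The fraction is taken over insertion-supporting reads only. Ties are
        broken toward the lexicographically smaller sequence and flagged.
        """
        total = self.insertion_depth()
        if total == 0:
            raise ValueError(f"no insertion reads at position {self.position}")
        by_reads = sorted(
            self.insertions.items(), key=lambda kv: (-(kv[1][0] + kv[1][1]), kv[0])
        )
        (seq, (fwd, rev)) = by_reads[0]
        best = fwd + rev
        tie = len(by_reads) > 1 and sum(by_reads[1][1]) == best
        return DominantInsertion(seq, best / total, tie)

    def strand_counts(self, allele: str) -> tuple[int, int]:
        if allele == "ins":
            fwd = sum(f for f, _ in self.insertions.values())
            rev = sum(r for _, r in self.insertions.values())
            return fwd, rev
        return self.counts.get(allele, (0, 0))

    def strand_bias(self, allele: str, mode: Literal["allele", "position"] = "allele") -> float:
        """1 - (minor-direction reads / major-direction reads) in [0, 1].

        0 means perfectly balanced strands, 1 means single-direction only.
        ``mode="allele"`` (default) uses only reads supporting *allele*;
        ``mode="position"`` uses all reads at the position regardless of
        allele (both interpretations are in circulation; per-allele is the
        stricter one).
        """
        if mode == "position":
            fwd = sum(f for f, _ in self.counts.values())
            rev = sum(r for _, r in self.counts.values())
        else:
            fwd, rev = self.strand_counts(allele)
        if fwd + rev == 0:
            raise ValueError(
                f"strand bias undefined: no reads for {allele!r} at {self.position}"
            )
        lo, hi = min(fwd, rev), max(fwd, rev)
        return 1.0 - lo / hi if hi else 1.0


# module-level functional aliases matching the operation names


def total_depth(pc: PositionCounts) -> int:
    return pc.total_depth()


def variant_frequency(pc: PositionCounts, allele: str) -> float:
    return pc.variant_frequency(allele)


def insertion_frequency(pc: PositionCounts) -> float:
    return pc.insertion_frequency()


def dominant_insertion(pc: PositionCounts) -> DominantInsertion:
    return pc.dominant_insertion()


def strand_bias(pc: PositionCounts, allele: str, mode: str = "allele") -> float:
    return pc.strand_bias(allele, mode=mode)  # type: ignore[arg-type]


@dataclass
class Pileup:
    """Per-sample collection of position counts; missing positions mean 0 depth."""

    sample_id: str
    positions: dict[int, PositionCounts] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def depth(self, position: int) -> int:
        pc = self.positions.get(position)
        return pc.total_depth() if pc else 0

    def get(self, position: int) -> PositionCounts:
        return self.positions.get(position) or PositionCounts(position=position)

    def __contains__(self, position: int) -> bool:
        return position in self.positions

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample_id, position, allele, fwd, rev.

        Insertion rows use allele ``ins:<seq>``.
        """
        rows = []
        for pos in sorted(self.positions):
            pc = self.positions[pos]
            for allele, (fwd, rev) in sorted(pc.counts.items()):
                rows.append((self.sample_id, pos, allele, fwd, rev))
            for seq, (fwd, rev) in sorted(pc.insertions.items()):
                rows.append((self.sample_id, pos, f"ins:{seq}", fwd, rev))
        return pd.DataFrame(rows, columns=["sample_id", "position", "allele", "fwd", "rev"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> Pileup:
    """Read the long-format pileup TSV dialect written by :meth:`Pileup.write_tsv`.

    Missing rows are zero counts; rows may arrive in any order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "allele": str})
    required = {"sample_id", "position", "allele", "fwd", "rev"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) > 1:
        raise ValueError(f"pileup TSV contains multiple samples: {list(sample_ids)}")
    sample_id = str(sample_ids[0]) if len(sample_ids) else ""
    positions: dict[int, PositionCounts] = {}
    for row in df.itertuples(index=False):
        pos = int(row.position)
        pc = positions.setdefault(pos, PositionCounts(position=pos))
        fwd, rev = int(row.fwd), int(row.rev)
        if row.allele.startswith("ins:"):
            seq = row.allele[4:]
            f0, r0 = pc.insertions.get(seq, (0, 0))
            pc.insertions[seq] = (f0 + fwd, r0 + rev)
        else:
            if row.allele not in ALLELES:
                raise ValueError(f"unknown allele {row.allele!r} at position {pos}")
            f0, r0 = pc.counts.get(row.allele, (0, 0))
            pc.counts[row.allele] = (f0 + fwd, r0 + rev)
    return Pileup(sample_id=sample_id, positions=positions)
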