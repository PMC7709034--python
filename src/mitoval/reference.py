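"""Circular mitochondrial reference model, amplicon panels, and variant nomenclature.

The human mtGenome is a 16,569-nt circle. Short-amplicon panels tile it in an
overlapping manner, and reads spanning the origin are handled by aligning
against an *extended* reference in which the first 80 nucleotides are repeated
after position 16,569. All user-facing coordinates are 1-based inclusive, the
convention of forensic mtDNA nomenclature; BED input is converted on read.

Variants are difference-coded against the reference in EMPOP-style forensic
notation: ``263G`` (substitution), ``11562R`` (point heteroplasmy, two-base
IUPAC code), ``309.1C`` (first inserted base after position 309), ``16193del``
(deletion), and ``8943N`` (position left uncalled, e.g. a suspected NUMT
artifact).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterator, Literal

from Bio import SeqIO

RCRS_LENGTH = 16569
#: number of origin-spanning nucleotides appended after the last position
CIRCULAR_EXTENSION = 80

IUPAC_TWO_BASE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}
IUPAC_DECODE = {code: pair for pair, code in IUPAC_TWO_BASE.items()}


class ReferenceError(ValueError):
    """Raised for malformed reference input."""


class NomenclatureError(ValueError):
    """Raised when a variant name cannot be parsed."""


@dataclass(frozen=True)
class MtReference:
    """A circular mitochondrial reference sequence.

    ``extended_sequence`` carries the first ``min(80, L)`` nucleotides repeated
    after the end so that origin-spanning amplicons align contiguously.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ReferenceError("reference sequence is empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-nucleotide characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def extension(self) -> int:
        return min(CIRCULAR_EXTENSION, self.length)

    @property
    def extended_sequence(self) -> str:
        return self.sequence + self.sequence[: self.extension]

    def base(self, position: int) -> str:
        """Reference base at a 1-based circular position."""
        if not 1 <= position <= self.length:
            raise ReferenceError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def homopolymer_run(self, position: int) -> tuple[int, int]:
        """(start, end) of the maximal run of identical bases containing *position*."""
        b = self.base(position)
        start = position
        while start > 1 and self.sequence[start - 2] == b:
            start -= 1
        end = position
        while end < self.length and self.sequence[end] == b:
            end += 1
        return start, end


def load_reference(fasta_path) -> MtReference:
    """Read a single-record FASTA into an :class:`MtReference`.

    A non-rCRS length is allowed (toy circles for testing) but draws a warning;
    the circular extension is then ``min(80, L)``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    if len(records) > 1:
        raise ReferenceError(f"expected one FASTA record, found {len(records)} in {fasta_path}")
    rec = records[0]
    if len(rec.seq) != RCRS_LENGTH:
        warnings.warn(
            f"reference length {len(rec.seq)} != {RCRS_LENGTH} (rCRS); "
            "treating as a non-standard circular reference",
            stacklevel=2,
        )
    return MtReference(name=rec.id, sequence=str(rec.seq))


def canonical_position(extended_pos: int, L: int) -> int:
    """Map a position on the extended (origin-repeated) axis back onto the circle.

    Identity for 1..L; positions L+1..L+ext map onto 1..ext.
    """
    ext = min(CIRCULAR_EXTENSION, L)
    if not 1 <= extended_pos <= L + ext:
        raise ValueError(f"extended position {extended_pos} outside 1..{L + ext}")
    return extended_pos if extended_pos <= L else extended_pos - L


# ---------------------------------------------------------------------------
# Amplicon panel


@dataclass(frozen=True)
class Amplicon:
    """One tiled amplicon on the circular genome.

    ``end < start`` means the amplicon wraps across the origin.
    """

    id: str
    pool: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def length_on(self, L: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return L - self.start + 1 + self.end

    def positions(self, L: int) -> Iterator[int]:
        """Yield every 1-based circular position covered by the amplicon."""
        if not (1 <= self.start <= L and 1 <= self.end <= L):
            raise ValueError(f"amplicon {self.id} coordinates outside 1..{L}")
        if self.end >= self.start:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, L + 1)
            yield from range(1, self.end + 1)


@dataclass
class Panel:
    """An ordered collection of amplicons tiling the circle.

    ``mean_length`` and ``mean_overlap`` are always recomputed from the
    amplicons themselves (descriptive statistics, never trusted from input).
    Overlap is the count of shared positions between circularly adjacent
    amplicons (adjacency by sorted start), averaged over all n adjacencies.
    """

    amplicons: list[Amplicon]
    L: int = RCRS_LENGTH

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate amplicon ids: {dup}")

    def __len__(self) -> int:
        return len(self.amplicons)

    def by_id(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    @property
    def mean_length(self) -> float:
        return sum(a.length_on(self.L) for a in self.amplicons) / len(self.amplicons)

    @property
    def mean_overlap(self) -> float:
        """Mean junction overlap between circularly adjacent amplicons.

        Overlap at each adjacency is measured at the junction (how far the
        upstream amplicon's end reaches into the downstream amplicon's
        start), so a two-amplicon panel with one overlapping and one abutting
        junction averages the two.
        """
        amps = sorted(self.amplicons, key=lambda a: a.start)
        if len(amps) == 1:
            return 0.0
        total = 0
        for i, a in enumerate(amps):
            b = amps[(i + 1) % len(amps)]
            a_end = a.start + a.length_on(self.L) - 1  # linear (unwrapped)
            b_start = b.start + (self.L if i + 1 == len(amps) else 0)
            total += max(0, min(a_end - b_start + 1, b.length_on(self.L)))
        return total / len(amps)

    def uncovered_positions(self) -> list[int]:
        covered: set[int] = set()
        for a in self.amplicons:
            covered.update(a.positions(self.L))
        return sorted(set(range(1, self.L + 1)) - covered)

    def check_coverage(self) -> None:
        gaps = self.uncovered_positions()
        if gaps:
            warnings.warn(
                f"panel does not cover {len(gaps)} positions "
                f"(first gaps: {gaps[:10]})",
                stacklevel=2,
            )

    def amplicons_overlapping(self, start: int, end: int) -> list[str]:
        """Ids of amplicons sharing at least one position with [start, end]."""
        span = set(range(start, end + 1))
        return [a.id for a in self.amplicons if span & set(a.positions(self.L))]


def load_panel(bed_path, L: int = RCRS_LENGTH) -> Panel:
    """Read a BED-like panel table (0-based half-open) into a 1-based Panel.

    Columns: chrom, start, end, name, score, strand, pool. Missing pool
    defaults to 1. A coverage gap is a warning, not an error.
    """
    amplicons = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{bed_path}:{lineno}: expected >=4 BED columns")
            start0, end0 = int(parts[1]), int(parts[2])
            pool = int(parts[6]) if len(parts) > 6 and parts[6] else 1
            # BED half-open 0-based -> 1-based inclusive; end0 > L encodes a wrap
            start1 = start0 + 1
            end1 = end0 if end0 <= L else end0 - L
            amplicons.append(Amplicon(id=parts[3], pool=pool, start=start1, end=end1))
    panel = Panel(amplicons=amplicons, L=L)
    panel.check_coverage()
    return panel


# ---------------------------------------------------------------------------
# Variant nomenclature

VariantKind = Literal["substitution", "heteroplasmy", "insertion", "deletion", "uncalled_N"]

_VARIANT_RE = re.compile(
    r"""^(?P<pos>[1-9]\d*)
        (?:
            (?P<del>del)
          | \.(?P<idx>[1-9]\d*)(?P<ins_base>[ACGT])
          | (?P<base>[ACGTNRYSWKM])
        )$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class VariantName:
    """A difference-coded variant in forensic mtDNA notation."""

    position: int
    insert_index: int  # 0 for non-insertions; n >= 1 in "pos.nN" names
    kind: VariantKind
    allele: str

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.position, self.insert_index)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise NomenclatureError(f"position must be >= 1, got {self.position}")
        if self.kind == "insertion" and self.insert_index < 1:
            raise NomenclatureError("insertion names carry insert_index >= 1")
        if self.kind == "heteroplasmy" and self.allele not in IUPAC_DECODE:
            raise NomenclatureError(
                f"heteroplasmy allele must be a two-base IUPAC code, got {self.allele!r}"
            )

    @property
    def rendered(self) -> str:
        if self.kind == "deletion":
            return f"{self.position}del"
        if self.kind == "insertion":
            return f"{self.position}.{self.insert_index}{self.allele}"
        if self.kind == "uncalled_N":
            return f"{self.position}N"
        return f"{self.position}{self.allele}"

    def __str__(self) -> str:
        return self.rendered


def substitution(position: int, allele: str) -> VariantName:
    return VariantName(position, 0, "substitution", allele)


def heteroplasmy(position: int, alleles) -> VariantName:
    """Heteroplasmy name from the pair of observed alleles, e.g. {A, G} -> R."""
    code = IUPAC_TWO_BASE.get(frozenset(alleles))
    if code is None:
        raise NomenclatureError(f"no two-base IUPAC code for alleles {sorted(alleles)}")
    return VariantName(position, 0, "heteroplasmy", code)


def insertion(position: int, insert_index: int, base: str) -> VariantName:
    return VariantName(position, insert_index, "insertion", base)


def deletion(position: int) -> VariantName:
    return VariantName(position, 0, "deletion", "")


def uncalled(position: int) -> VariantName:
    return VariantName(position, 0, "uncalled_N", "N")


def render_variant(v: VariantName) -> str:
    return v.rendered


def parse_variant(text: str) -> VariantName:
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        # locate the first offending character for the error message
        bad_at = next(
            (i for i, c in enumerate(text) if not (c.isdigit() or c.isalpha() or c == ".")),
            len(text),
        )
        raise NomenclatureError(f"cannot parse variant name {text!r} (near index {bad_at})")
    pos = int(m.group("pos"))
    if m.group("del"):
        return deletion(pos)
    if m.group("idx"):
        return insertion(pos, int(m.group("idx")), m.group("ins_base"))
    base = m.group("base")
    if base == "N":
        return uncalled(pos)
    if base in IUPAC_DECODE:
        return VariantName(pos, 0, "heteroplasmy", base)
    return substitution(pos, base)
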