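"""Threshold-based haplotype calling with review flags and artifact handling.

Calling is purely threshold-based, with every threshold inclusive (>=):

* a non-reference base at frequency >= ``php_min`` (default 10%) and below
  ``1 - php_min`` is a point heteroplasmy, reported as a two-base IUPAC code;
  at or above ``1 - php_min`` it is a substitution;
* deletion-supporting reads at frequency >= ``del_min`` (default 40%) call a
  deletion;
* insertion-supporting reads at frequency >= ``ins_min`` (default 30%) call an
  insertion, named by the dominant inserted sequence expanded to
  ``pos.1N, pos.2N, ...``;
* positions below ``min_depth`` (default 20X) are masked and never called.

Calls whose supporting reads show extreme strand bias (> ``strand_bias_review``,
default 0.89) are flagged ``review`` rather than suppressed: automated
suppression is known to drop true variants in homopolymer-adjacent regions
that an analyst would rescue. Deletions at the ends of the long poly-C
stretches (309del, 315del, 16193del by default) are systematic platform
artifacts; :func:`apply_suspect_deletions` suppresses them post hoc while
keeping them in the audit record. Heteroplasmies whose minor allele matches a
catalogued NUMT (nuclear mtDNA insert) allele are demoted to ``posN``
uncalled markers by :func:`flag_nav`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .pileup import Pileup, PositionCounts
from .reference import (
    IUPAC_DECODE,
    MtReference,
    Panel,
    VariantName,
    deletion,
    heteroplasmy,
    insertion,
    parse_variant,
    substitution,
    uncalled,
)

DEFAULT_SUSPECT_DELETIONS = frozenset({"309del", "315del", "16193del"})


@dataclass(frozen=True)
class Thresholds:
    """Calling parameters.

    php_min/ins_min/del_min are fractions of total depth; min_depth is reads;
    strand_bias_review is the bias value above which a call is flagged for
    analyst review; mv_min_count is the number of mixed-variant sites that
    indicates a mixture.
    """

    php_min: float = 0.10
    ins_min: float = 0.30
    del_min: float = 0.40
    min_depth: int = 20
    strand_bias_review: float = 0.89
    mv_min_count: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.php_min <= self.ins_min <= self.del_min <= 1):
            raise ValueError(
                "thresholds must satisfy 0 < php_min <= ins_min <= del_min <= 1"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class VariantCall:
    name: VariantName
    frequency: float
    depth: int
    strand_bias: float
    status: str = "confirmed"  # confirmed | review | suppressed_suspect | uncalled_N
    dominant_fraction: float | None = None  # insertions only
    evidence: str = ""

    @property
    def rendered(self) -> str:
        return self.name.rendered


@dataclass
class Haplotype:
    """Difference-coded calls vs the reference plus a below-min-depth mask."""

    sample_id: str
    calls: list[VariantCall] = field(default_factory=list)
    coverage_mask: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.calls.sort(key=lambda c: c.name.sort_key)

    def exported_calls(self) -> list[VariantCall]:
        """Calls that enter the exported haplotype (confirmed and N markers)."""
        return [c for c in self.calls if c.status in ("confirmed", "uncalled_N")]

    def rendered(self, include_review: bool = False) -> list[str]:
        keep = {"confirmed", "uncalled_N"} | ({"review"} if include_review else set())
        return [c.rendered for c in self.calls if c.status in keep]

    def masked_ranges(self) -> list[tuple[int, int]]:
        if not self.coverage_mask:
            return []
        ranges = []
        run_start = prev = None
        for pos in sorted(self.coverage_mask):
            if run_start is None:
                run_start = prev = pos
            elif pos == prev + 1:
                prev = pos
            else:
                ranges.append((run_start, prev))
                run_start = prev = pos
        ranges.append((run_start, prev))
        return ranges


def _right_align_deletion(position: int, ref: MtReference) -> int:
    """3'-aligned (right-most) placement of a deletion within its homopolymer."""
    _, end = ref.homopolymer_run(position)
    return end


def _anchor_insertion(position: int, inserted: str, ref: MtReference) -> int:
    """Anchor an insertion at the right-most base of a matching homopolymer."""
    if inserted and ref.base(position) == inserted[0]:
        _, end = ref.homopolymer_run(position)
        return end
    return position


def call_position(
    pc: PositionCounts,
    ref_base: str,
    th: Thresholds,
    ref: MtReference | None = None,
) -> list[VariantCall]:
    """Threshold calls at one position; empty when depth < min_depth.

    If *ref* is given, indel names are right-aligned within homopolymers.
    """
    depth = pc.total_depth()
    if depth < th.min_depth:
        return []
    calls: list[VariantCall] = []

    base_freqs = {
        b: pc.allele_depth(b) / depth for b in "ACGT" if pc.allele_depth(b) > 0
    }
    above = {b: f for b, f in base_freqs.items() if f >= th.php_min}
    ranked = sorted(above.items(), key=lambda kv: (-kv[1], kv[0]))

    def bias(allele: str) -> float:
        try:
            return pc.strand_bias(allele)
        except ValueError:
            return 0.0

    def status_for(sb: float) -> str:
        return "review" if sb > th.strand_bias_review else "confirmed"

    if ranked:
        top_base, top_freq = ranked[0]
        # two states above php_min is a heteroplasmy even when the major sits
        # exactly at 1 - php_min: with inclusive thresholds the 1:9 boundary
        # must be detected as mixed, not collapsed to a substitution
        if len(ranked) >= 2:
            (a, fa), (b, fb) = ranked[0], ranked[1]
            minor = b if fb <= fa else a
            sb = bias(minor)
            note = ""
            if len(ranked) > 2:
                extra = [x for x, _ in ranked[2:]]
                note = f"multi-allele site; additional states above threshold: {extra}"
            calls.append(
                VariantCall(
                    heteroplasmy(pc.position, {a, b}),
                    fb,  # frequency of the minor state
                    depth,
                    sb,
                    status=status_for(sb),
                    evidence=note,
                )
            )
        elif top_base != ref_base:
            sb = bias(top_base)
            if top_freq >= 1 - th.php_min:
                calls.append(
                    VariantCall(
                        substitution(pc.position, top_base), top_freq, depth, sb,
                        status=status_for(sb),
                    )
                )
            else:
                # a lone non-reference state between php_min and 1 - php_min
                # (the remainder spread below threshold, e.g. into deletions)
                calls.append(
                    VariantCall(
                        heteroplasmy(pc.position, {top_base, ref_base}),
                        top_freq, depth, sb, status=status_for(sb),
                    )
                )

    del_freq = pc.allele_depth("del") / depth
    if del_freq >= th.del_min:
        sb = bias("del")
        name_pos = _right_align_deletion(pc.position, ref) if ref else pc.position
        calls.append(
            VariantCall(
                deletion(name_pos), del_freq, depth, sb, status=status_for(sb)
            )
        )

    if pc.insertion_depth() > 0:
        ins_freq = pc.insertion_frequency()
        if ins_freq >= th.ins_min:
            dom = pc.dominant_insertion()
            sb = pc.strand_bias("ins")
            anchor = (
                _anchor_insertion(pc.position, dom.sequence, ref)
                if ref
                else pc.position
            )
            note = "dominant-insertion tie" if dom.tie else ""
            for n, base in enumerate(dom.sequence, start=1):
                calls.append(
                    VariantCall(
                        insertion(anchor, n, base),
                        ins_freq,
                        depth,
                        sb,
                        status=status_for(sb),
                        dominant_fraction=dom.fraction,
                        evidence=note,
                    )
                )
    return calls


def assemble_haplotype(
    p: Pileup,
    ref: MtReference,
    panel: Panel | None = None,
    th: Thresholds = Thresholds(),
) -> Haplotype:
    """Call every reference position; positions below min_depth go to the mask."""
    calls: list[VariantCall] = []
    mask: set[int] = set()
    for pos in range(1, ref.length + 1):
        pc = p.positions.get(pos)
        if pc is None or pc.total_depth() < th.min_depth:
            mask.add(pos)
            continue
        calls.extend(call_position(pc, ref.base(pos), th, ref=ref))
    # right-alignment can name a call at a masked position's tract end; the
    # mask records *coverage*, so a call is kept only if its pileup position
    # (not its name) was covered -- which is already guaranteed above.
    return Haplotype(sample_id=p.sample_id, calls=calls, coverage_mask=mask)


def apply_suspect_deletions(
    h: Haplotype, suspect_list=DEFAULT_SUSPECT_DELETIONS
) -> Haplotype:
    """Suppress known false deletions (long poly-C tract ends) post hoc.

    Suppressed calls remain in the haplotype's call list with status
    ``suppressed_suspect`` (the audit record) but leave the exported
    difference code.
    """
    suspects = {s if isinstance(s, str) else s.rendered for s in suspect_list}
    new_calls = []
    for c in h.calls:
        if c.name.kind == "deletion" and c.rendered in suspects:
            c = replace(
                c,
                status="suppressed_suspect",
                evidence=(c.evidence + "; " if c.evidence else "")
                + "suspect deletion suppressed (known platform artifact)",
            )
        new_calls.append(c)
    return Haplotype(h.sample_id, new_calls, set(h.coverage_mask))


def flag_nav(
    h: Haplotype, p: Pileup, numt_catalog: dict[int, str]
) -> Haplotype:
    """Demote heteroplasmies whose minor allele matches a catalogued NUMT allele.

    The call becomes an uncalled ``posN`` marker (kept in the exported
    haplotype, as the position cannot be resolved to a single true state).
    Catalog positions where the catalogued allele is the *dominant* state are
    left alone: a near-fixed allele is a true variant, not NUMT carry-in.
    """
    new_calls = []
    for c in h.calls:
        if c.name.kind == "heteroplasmy" and c.name.position in numt_catalog:
            pair = IUPAC_DECODE[c.name.allele]
            pc = p.get(c.name.position)
            by_depth = sorted(pair, key=lambda b: (-pc.allele_depth(b), b))
            minor = by_depth[-1]
            if numt_catalog[c.name.position] == minor:
                c = replace(
                    c,
                    name=uncalled(c.name.position),
                    status="uncalled_N",
                    evidence=(c.evidence + "; " if c.evidence else "")
                    + f"minor allele {minor} matches NUMT catalog; reported as N",
                )
        new_calls.append(c)
    return Haplotype(h.sample_id, new_calls, set(h.coverage_mask))


def export_haplotype(h: Haplotype) -> str:
    """EMPOP-style difference-coded string with masked-range annotation."""
    variants = " ".join(c.rendered for c in h.exported_calls())
    if h.coverage_mask:
        spans = ";".join(f"{a}-{b}" for a, b in h.masked_ranges())
        annot = f"# masked (<min depth): {spans}"
        return f"{variants}\n{annot}" if variants else annot
    return variants


def export_vcf(h: Haplotype, ref: MtReference, path) -> None:
    """Write exported calls as minimal VCF 4.2 (1-based positions).

    Deletions/insertions use the standard left-anchor representation; a
    variant at position 1 (circular origin) is anchored on its right side.
    Heteroplasmies are written as the minor allele with its frequency in AF.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.name},length={ref.length}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=VT,Number=1,Type=String,Description="Forensic variant kind">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in h.exported_calls():
        pos = c.name.position
        kind = c.name.kind
        if kind == "substitution":
            row = (pos, ref.base(pos), c.name.allele)
        elif kind == "heteroplasmy":
            pair = set(IUPAC_DECODE[c.name.allele])
            alts = sorted(pair - {ref.base(pos)}) or sorted(pair)
            row = (pos, ref.base(pos), ",".join(alts))
        elif kind == "uncalled_N":
            row = (pos, ref.base(pos), "N")
        elif kind == "deletion":
            if pos > 1:
                row = (pos - 1, ref.base(pos - 1) + ref.base(pos), ref.base(pos - 1))
            else:  # circular origin: right-anchored
                row = (pos, ref.base(pos) + ref.base(pos + 1), ref.base(pos + 1))
        else:  # insertion (one row per haplotype call run is redundant; emit at .1)
            if c.name.insert_index != 1:
                continue
            inserted = "".join(
                x.name.allele
                for x in h.exported_calls()
                if x.name.kind == "insertion" and x.name.position == pos
            )
            row = (pos, ref.base(pos), ref.base(pos) + inserted)
        info = f"AF={c.frequency:.4f};DP={c.depth};VT={kind}"
        lines.append(
            f"{ref.name}\t{row[0]}\t{c.rendered}\t{row[1]}\t{row[2]}\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def haplotype_from_strings(sample_id: str, names: list[str]) -> Haplotype:
    """Build a truth/known haplotype from rendered variant names (no pileup)."""
    calls = [
        VariantCall(parse_variant(n), frequency=1.0, depth=0, strand_bias=0.0)
        for n in names
    ]
    return Haplotype(sample_id=sample_id, calls=calls)
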