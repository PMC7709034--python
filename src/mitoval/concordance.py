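"""Replicate reproducibility metrics and discordance classification.

Two haplotypes for the same sample (replicates, or calls from two platforms)
are compared call-by-call after removing positions masked for low coverage in
either source. Each discordant call is placed in exactly one category, tried
in this order:

1. ``suspect_deletion`` -- the call is one of the known false deletions at the
   ends of the long poly-C stretches;
2. ``dominant_variant_differs`` -- both sources call an insertion at the same
   position but disagree on the dominant inserted sequence;
3. ``threshold_miss`` -- the other source's pileup carries the variant below
   its calling threshold (requires pileups);
4. ``homopolymer_indel`` -- an indel inside or adjacent to a reference
   homopolymer tract of length >= 4 (requires the reference);
5. ``php_only_one_source`` -- a point heteroplasmy present in one source only;
6. ``other``.

Replicate spread is summarised by the maximum pairwise difference in variant
frequency (max minus min, as a percentage) per shared variant, grouped by
variant type, and each replicate lists variants that are present in its
pileup but below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calling import DEFAULT_SUSPECT_DELETIONS, Haplotype, Thresholds, VariantCall
from .pileup import Pileup, UndefinedFrequencyError
from .reference import IUPAC_DECODE, MtReference, VariantName

CATEGORIES = (
    "suspect_deletion",
    "dominant_variant_differs",
    "threshold_miss",
    "homopolymer_indel",
    "php_only_one_source",
    "other",
)


@dataclass(frozen=True)
class DiscordanceRecord:
    variant: VariantName
    present_in: frozenset[str]
    category: str
    note: str = ""


@dataclass
class ReplicateSet:
    sample_id: str
    replicates: list[tuple[str, Haplotype, Pileup]]

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValueError("a replicate set needs at least two replicates")


def _observed_frequency(p: Pileup, v: VariantName, th: Thresholds) -> float | None:
    """Frequency of the variant state in a pileup, regardless of thresholds."""
    pc = p.get(v.position)
    try:
        if v.kind == "deletion":
            return pc.variant_frequency("del")
        if v.kind == "insertion":
            return pc.insertion_frequency()
        if v.kind == "substitution":
            return pc.variant_frequency(v.allele)
        if v.kind == "heteroplasmy":
            pair = sorted(IUPAC_DECODE[v.allele])
            freqs = [pc.variant_frequency(b) for b in pair]
            return min(freqs)  # the minor state is what the threshold gates
    except UndefinedFrequencyError:
        return None
    return None


def _threshold_for(v: VariantName, th: Thresholds) -> float:
    return {
        "deletion": th.del_min,
        "insertion": th.ins_min,
    }.get(v.kind, th.php_min)


def _in_homopolymer(v: VariantName, ref: MtReference, min_tract: int = 4) -> bool:
    for pos in (v.position, max(1, v.position - 1), min(ref.length, v.position + 1)):
        start, end = ref.homopolymer_run(pos)
        if end - start + 1 >= min_tract:
            return True
    return False


def compare_haplotypes(
    a: Haplotype,
    b: Haplotype,
    pileup_a: Pileup | None = None,
    pileup_b: Pileup | None = None,
    ref: MtReference | None = None,
    th: Thresholds = Thresholds(),
    suspect_list=DEFAULT_SUSPECT_DELETIONS,
    labels: tuple[str, str] = ("a", "b"),
    homopolymer_min_tract: int = 4,
) -> list[DiscordanceRecord]:
    """Categorised discordances between two haplotypes (symmetric).

    Positions masked in either haplotype are excluded from the comparison.
    Concordant calls produce no record.
    """
    excluded = a.coverage_mask | b.coverage_mask
    calls_a = {c.rendered: c for c in a.exported_calls() if c.name.position not in excluded}
    calls_b = {c.rendered: c for c in b.exported_calls() if c.name.position not in excluded}
    only_a = set(calls_a) - set(calls_b)
    only_b = set(calls_b) - set(calls_a)

    ins_positions_a = {c.name.position for c in calls_a.values() if c.name.kind == "insertion"}
    ins_positions_b = {c.name.position for c in calls_b.values() if c.name.kind == "insertion"}

    records = []
    for rendered, here, there_ins, partner_pileup, label in (
        *[(r, calls_a, ins_positions_b, pileup_b, labels[0]) for r in sorted(only_a)],
        *[(r, calls_b, ins_positions_a, pileup_a, labels[1]) for r in sorted(only_b)],
    ):
        call = here[rendered]
        v = call.name
        category, note = "other", ""
        if v.kind == "deletion" and rendered in {
            s if isinstance(s, str) else s.rendered for s in suspect_list
        }:
            category = "suspect_deletion"
            note = "known false-deletion artifact at a poly-C tract end"
        elif v.kind == "insertion" and v.position in there_ins:
            category = "dominant_variant_differs"
            note = "both sources insert at this position with different dominant sequences"
        elif partner_pileup is not None and (
            (f := _observed_frequency(partner_pileup, v, th)) is not None
            and 0 < f < _threshold_for(v, th)
        ):
            category = "threshold_miss"
            note = f"present in partner pileup at {100 * f:.1f}%, below threshold"
        elif (
            ref is not None
            and v.kind in ("insertion", "deletion")
            and _in_homopolymer(v, ref, homopolymer_min_tract)
        ):
            category = "homopolymer_indel"
            note = f"indel within a homopolymer tract (>= {homopolymer_min_tract} bases)"
        elif v.kind == "heteroplasmy":
            category = "php_only_one_source"
            note = "point heteroplasmy called in one source only"
        records.append(
            DiscordanceRecord(v, frozenset({label}), category, note)
        )
    return records


def max_pairwise_difference(freqs: list[float]) -> float:
    """100 * (max - min) over replicate frequencies; equals the all-pairs max."""
    if len(freqs) < 2:
        raise ValueError("need at least two replicate frequencies")
    return 100.0 * (max(freqs) - min(freqs))


def discordance_rate(a: Haplotype, b: Haplotype, records: list[DiscordanceRecord]) -> float:
    """Discordant calls over the union of exported calls from both sources."""
    union = {c.rendered for c in a.exported_calls()} | {
        c.rendered for c in b.exported_calls()
    }
    return len(records) / len(union) if union else 0.0


def _variant_group(v: VariantName) -> str:
    if v.kind in ("insertion", "deletion"):
        return "indel"
    if v.kind == "heteroplasmy":
        return "PHP"
    return "substitution"


def replicate_summary(rs: ReplicateSet, th: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-variant replicate spread table.

    One row per variant seen in any replicate's exported haplotype:
    variant, type, number of replicates where called, max pairwise frequency
    difference (%) over replicates where the state is observable in the
    pileup, the same statistic for the dominant-insertion fraction (indels
    only), and the labels of replicates where the variant is present in the
    pileup but below its calling threshold.
    """
    variants: dict[str, VariantCall] = {}
    called_in: dict[str, list[str]] = {}
    for label, hap, _ in rs.replicates:
        for c in hap.exported_calls():
            variants.setdefault(c.rendered, c)
            called_in.setdefault(c.rendered, []).append(label)

    rows = []
    for rendered in sorted(variants, key=lambda r: variants[r].name.sort_key):
        v = variants[rendered].name
        freqs, dom_fracs, subthreshold = [], [], []
        for label, hap, pileup in rs.replicates:
            f = _observed_frequency(pileup, v, th)
            if f is None:
                continue
            freqs.append(f)
            if f > 0 and f < _threshold_for(v, th) and rendered not in {
                c.rendered for c in hap.exported_calls()
            }:
                subthreshold.append(label)
            if v.kind == "insertion":
                pc = pileup.get(v.position)
                if pc.insertion_depth() > 0:
                    dom_fracs.append(pc.dominant_insertion().fraction)
        rows.append(
            {
                "variant": rendered,
                "type": _variant_group(v),
                "n_called": len(called_in[rendered]),
                "max_pairwise_diff_pct": (
                    max_pairwise_difference(freqs) if len(freqs) >= 2 else float("nan")
                ),
                "dominant_max_pairwise_diff_pct": (
                    max_pairwise_difference(dom_fracs)
                    if len(dom_fracs) >= 2
                    else float("nan")
                ),
                "subthreshold_in": ",".join(subthreshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "type",
            "n_called",
            "max_pairwise_diff_pct",
            "dominant_max_pairwise_diff_pct",
            "subthreshold_in",
        ],
    )
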