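"""Two-contributor mtDNA mixture detection and quantitative deconvolution.

A position carrying two or more base states, each at or above the point
heteroplasmy threshold (10% by default) and with adequate depth, is a mixed
variant site (MV). Because a single individual can legitimately carry a few
point heteroplasmies, a sample is flagged as a mixture only when it shows at
least ``mv_min_count`` MVs (default 3).

Deconvolution is frequency-based: at each MV the higher-frequency state is
assigned to the major contributor and the lower to the minor; indels are
excluded throughout (their frequencies are too noisy and sit under different
thresholds). Site-level assignments are reconciled against the global
frequency structure by a two-cluster split of the sorted per-site minor
frequencies, since no read-phasing information exists at pileup level. The
major and minor mean frequencies (+/- sample SD over MVs) give an effective
mixture ratio; when the two means are within an indistinguishability band
(default 10 percentage points, i.e. close to 1:1) the mixture is reported as
unresolvable. MVs whose minor frequency lies more than ``k`` SD (default 3)
from the minor mean are flagged as possible stochastic variation or NUMT
carry-in and excluded from the minor haplotype, with an audit note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .calling import Haplotype, Thresholds, VariantCall
from .pileup import Pileup
from .reference import MtReference, substitution


@dataclass(frozen=True)
class MixedVariantSite:
    position: int
    alleles: dict[str, float]  # base state -> frequency, all >= php_min
    major_allele: str
    minor_allele: str
    minor_frequency: float

    @property
    def major_frequency(self) -> float:
        return self.alleles[self.major_allele]


@dataclass
class MixtureResult:
    mv_sites: list[MixedVariantSite]
    is_mixture: bool
    major_haplotype: Haplotype | None = None
    minor_haplotype: Haplotype | None = None
    major_mean_freq: float = float("nan")
    major_sd: float = float("nan")
    minor_mean_freq: float = float("nan")
    minor_sd: float = float("nan")
    effective_ratio: float = float("nan")  # major : minor, as major/minor
    unresolvable: bool = False
    audit: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MixtureDesign:
    constant_contributor_pg: float
    variable_contributor_pg: float
    target_ratio: tuple[float, float]  # variable : constant

    @property
    def total_pg(self) -> float:
        return self.constant_contributor_pg + self.variable_contributor_pg


def find_mvs(p: Pileup, th: Thresholds = Thresholds()) -> list[MixedVariantSite]:
    """Positions with >= 2 base states each at frequency >= php_min (inclusive).

    Only A/C/G/T states count (indels excluded); positions below min_depth
    are skipped. Sorted by position.
    """
    sites = []
    for pos in sorted(p.positions):
        pc = p.positions[pos]
        depth = pc.total_depth()
        if depth < th.min_depth:
            continue
        states = {
            b: pc.allele_depth(b) / depth
            for b in "ACGT"
            if pc.allele_depth(b) / depth >= th.php_min
        }
        if len(states) < 2:
            continue
        ranked = sorted(states.items(), key=lambda kv: (-kv[1], kv[0]))
        sites.append(
            MixedVariantSite(
                position=pos,
                alleles=states,
                major_allele=ranked[0][0],
                minor_allele=ranked[1][0],
                minor_frequency=ranked[1][1],
            )
        )
    return sites


def flag_mixture(mv_count: int, th: Thresholds = Thresholds()) -> bool:
    """Three or more MVs (by default) indicate a mixture, allowing for
    personal point heteroplasmies in single-source samples."""
    return mv_count >= th.mv_min_count


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, float("nan")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def deconvolve(
    p: Pileup,
    mvs: list[MixedVariantSite],
    th: Thresholds = Thresholds(),
    ref: MtReference | None = None,
    outlier_sd: float = 3.0,
    indistinguishable_band: float = 0.10,
) -> MixtureResult:
    """Quantitatively separate a two-contributor mixture by allele frequency.

    Requires a flagged mixture (>= mv_min_count MVs). The returned major and
    minor haplotypes are difference-coded against *ref* when it is supplied
    (consensus substitutions shared by both contributors plus each
    contributor's own MV alleles); without a reference only the summary
    statistics are populated.
    """
    result = MixtureResult(mv_sites=mvs, is_mixture=flag_mixture(len(mvs), th))
    if not result.is_mixture:
        result.audit.append(
            f"only {len(mvs)} MV(s) < {th.mv_min_count}; not treated as a mixture"
        )
        return result

    # Per-site assignment can only flip phase when a site's minor frequency
    # crosses 50%, which happens within the near-1:1 band that is declared
    # unresolvable below; outside the band the per-site major/minor split is
    # globally consistent and outliers are handled by the SD rule.
    minor_freqs = [s.minor_frequency for s in mvs]
    minor_mean, minor_sd = _mean_sd(minor_freqs)
    major_freqs = [s.major_frequency for s in mvs]
    major_mean, major_sd = _mean_sd(major_freqs)

    flagged: list[MixedVariantSite] = []
    kept: list[MixedVariantSite] = []
    for s in mvs:
        if (
            not math.isnan(minor_sd)
            and minor_sd > 0
            and abs(s.minor_frequency - minor_mean) > outlier_sd * minor_sd
        ):
            flagged.append(s)
            result.audit.append(
                f"MV at {s.position}: minor frequency {100 * s.minor_frequency:.1f}% "
                f"is > {outlier_sd:g} SD from the minor mean "
                f"({100 * minor_mean:.1f}% +/- {100 * minor_sd:.1f}%); "
                "possible stochastic variation or NUMT; excluded from minor haplotype"
            )
        else:
            kept.append(s)
    if flagged:
        minor_mean, minor_sd = _mean_sd([s.minor_frequency for s in kept])
        major_mean, major_sd = _mean_sd([s.major_frequency for s in kept])

    result.major_mean_freq, result.major_sd = major_mean, major_sd
    result.minor_mean_freq, result.minor_sd = minor_mean, minor_sd
    result.effective_ratio = major_mean / minor_mean if minor_mean > 0 else float("inf")

    if abs(major_mean - minor_mean) < indistinguishable_band:
        result.unresolvable = True
        result.audit.append(
            "major and minor mean frequencies within "
            f"{100 * indistinguishable_band:.0f} percentage points "
            "(approximately 1:1); contributors too similar to separate quantitatively"
        )
        return result

    if ref is not None:
        mv_positions = {s.position for s in mvs}
        consensus: list[VariantCall] = []
        for pos in sorted(p.positions):
            if pos in mv_positions:
                continue
            pc = p.positions[pos]
            depth = pc.total_depth()
            if depth < th.min_depth:
                continue
            ranked = sorted(
                ((pc.allele_depth(b) / depth, b) for b in "ACGT"), reverse=True
            )
            top_f, top_b = ranked[0]
            if top_b != ref.base(pos) and top_f >= 1 - th.php_min:
                consensus.append(
                    VariantCall(substitution(pos, top_b), top_f, depth, 0.0)
                )
        major_calls = list(consensus)
        minor_calls = list(consensus)
        for s in mvs:
            depth = p.get(s.position).total_depth()
            if s.major_allele != ref.base(s.position):
                major_calls.append(
                    VariantCall(
                        substitution(s.position, s.major_allele),
                        s.major_frequency,
                        depth,
                        0.0,
                    )
                )
            if s in kept and s.minor_allele != ref.base(s.position):
                minor_calls.append(
                    VariantCall(
                        substitution(s.position, s.minor_allele),
                        s.minor_frequency,
                        depth,
                        0.0,
                    )
                )
        result.major_haplotype = Haplotype(f"{p.sample_id}:major", major_calls)
        result.minor_haplotype = Haplotype(f"{p.sample_id}:minor", minor_calls)
    return result


def mixture_design(
    constant_pg: float = 2.0, target_ratio: tuple[float, float] = (1.0, 1.0)
) -> MixtureDesign:
    """Dilution-design arithmetic for a two-contributor mixture.

    One contributor is held constant (2 pg by default, the "1" side of the
    ratio); the variable contributor's mass is ``constant * a / b`` for a
    target ratio ``a:b`` expressed as variable:constant. A 20:1 design with a
    2 pg constant contributor therefore uses 40 pg of the variable
    contributor (42 pg total); a 1:10 design uses 0.2 pg (2.2 pg total).
    """
    a, b = target_ratio
    if a <= 0 or b <= 0:
        raise ValueError(f"ratio components must be positive, got {target_ratio}")
    variable = constant_pg * a / b
    return MixtureDesign(
        constant_contributor_pg=constant_pg,
        variable_contributor_pg=variable,
        target_ratio=(a, b),
    )
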