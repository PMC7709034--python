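"""Generator properties: determinism, tiling, error structure, dilutions."""

import numpy as np
import pytest

import mitoval as mv
from mitoval.reference import MtReference
from mitoval.simulate import (
    DepthModel,
    ErrorModel,
    NegativeModel,
    NumtModel,
    SimScenario,
    dilution_series,
    simulate_mixture,
    simulate_negative,
    simulate_panel,
    simulate_pileup,
    synthetic_reference,
)

from conftest import transition


class TestSimulatePanel:
    def test_full_coverage_and_alternating_pools(self):
        panel = simulate_panel(109, 163, 11, L=16569, seed=4)
        assert len(panel) == 109
        assert panel.uncovered_positions() == []
        pools = [a.pool for a in panel.amplicons]
        assert pools[:4] == [1, 2, 1, 2]
        assert panel.mean_length == pytest.approx(163, abs=2)
        assert panel.mean_overlap == pytest.approx(11, abs=2)

    def test_single_spanning_amplicon(self):
        panel = simulate_panel(1, 500, 0, L=500, seed=0)
        assert len(panel) == 1
        assert panel.uncovered_positions() == []
        assert panel.mean_overlap == 0.0

    def test_infeasible_parameters_error_names_inequality(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_panel(10, 50, 11, L=16569, seed=0)


class TestSyntheticReference:
    def test_planted_homopolymer_tracts(self, ref_full):
        assert ref_full.sequence[302:309] == "C" * 7  # 303-309
        assert ref_full.sequence[309] == "T"  # 310
        assert ref_full.sequence[310:315] == "C" * 5  # 311-315
        assert ref_full.sequence[16183:16193] == "C" * 10  # 16184-16193
        assert ref_full.homopolymer_run(16190) == (16184, 16193)

    def test_reproducible(self):
        assert synthetic_reference(seed=3).sequence == synthetic_reference(seed=3).sequence


class TestDeterminism:
    def test_same_seed_same_pileup(self, ref_small, panel_small):
        sc = SimScenario(reference=ref_small, panel=panel_small, seed=42)
        a, _ = simulate_pileup(sc)
        b, _ = simulate_pileup(sc)
        assert a.to_frame().equals(b.to_frame())

    def test_different_seeds_differ(self, ref_small, panel_small):
        a, _ = simulate_pileup(SimScenario(reference=ref_small, panel=panel_small, seed=1))
        b, _ = simulate_pileup(SimScenario(reference=ref_small, panel=panel_small, seed=2))
        assert not a.to_frame().equals(b.to_frame())


class TestAlleleFrequencies:
    def test_law_of_large_numbers_at_high_depth(self, ref_small, panel_small):
        pos = 150
        alt = transition(ref_small.base(pos))
        name = f"{pos}{alt}"
        sc = SimScenario(
            reference=ref_small, panel=panel_small, haplotypes=[[name]],
            variant_fractions={name: 0.35},
            depth=DepthModel(median=10_000, amplicon_sigma=0), seed=8,
        )
        p, truth = simulate_pileup(sc)
        observed = p.get(pos).variant_frequency(alt)
        assert observed == pytest.approx(0.35, abs=0.01)
        [v] = [v for v in truth["variants"] if v["name"] == name]
        assert v["true_frequency"] == pytest.approx(0.35)

    def test_php_replicates_within_binomial_interval(self, ref_small, panel_small):
        pos, frac, depth = 150, 0.15, 500
        alt = transition(ref_small.base(pos))
        name = f"{pos}{alt}"
        sigma = np.sqrt(frac * (1 - frac) / depth)
        for i in range(8):
            sc = SimScenario(
                reference=ref_small, panel=panel_small, haplotypes=[[name]],
                variant_fractions={name: frac},
                depth=DepthModel(median=depth, amplicon_sigma=0), error=None,
                seed=300 + i,
            )
            p, _ = simulate_pileup(sc)
            # 99%+ binomial interval around the injected fraction
            assert abs(p.get(pos).variant_frequency(alt) - frac) < 3 * sigma


class TestHomopolymerIndelNoise:
    def test_indel_noise_grows_with_tract_length(self):
        seq = list("ACGT" * 100)
        seq[40:44] = "C" * 4  # tract of 4
        seq[200:208] = "C" * 8  # tract of 8
        ref = MtReference("toy", "".join(seq))
        panel = mv.simulate_panel(4, 120, 10, L=ref.length, seed=1)
        sc = SimScenario(
            reference=ref, panel=panel,
            depth=DepthModel(median=20_000, amplicon_sigma=0),
            error=ErrorModel(substitution_rate=0.0), seed=5,
        )
        p, _ = simulate_pileup(sc)

        def indel_freq(tract_end):
            pc = p.get(tract_end)
            return (pc.allele_depth("del") + pc.insertion_depth()) / pc.total_depth()

        assert indel_freq(208) > indel_freq(44) > 0


class TestSimulateMixture:
    def test_requires_two_haplotypes(self, ref_small, panel_small):
        sc = SimScenario(reference=ref_small, panel=panel_small, haplotypes=[[]])
        with pytest.raises(ValueError):
            simulate_mixture(sc)

    def test_identical_haplotypes_warn(self, ref_small, panel_small):
        sc = SimScenario(
            reference=ref_small, panel=panel_small, haplotypes=[["150G"], ["150G"]],
            mixture_minor_fraction=0.2,
        )
        with pytest.warns(UserWarning, match="identical"):
            simulate_mixture(sc)


class TestSimulateNegative:
    def test_scale_zero_is_empty(self, ref_small, panel_small):
        sc = SimScenario(
            reference=ref_small, panel=panel_small,
            depth=DepthModel(median=500, amplicon_sigma=0), error=None,
            stochastic=False, seed=2, negative=NegativeModel(scale_pct=0.0),
        )
        pos, _ = simulate_pileup(sc)
        neg = simulate_negative(sc, pos)
        assert neg.positions == {}

    def test_scale_one_percent_flat_profile(self, ref_small, panel_small):
        sc = SimScenario(
            reference=ref_small, panel=panel_small,
            depth=DepthModel(median=2000, amplicon_sigma=0), error=None,
            stochastic=False, seed=2, negative=NegativeModel(scale_pct=1.0),
        )
        pos, _ = simulate_pileup(sc)
        neg = simulate_negative(sc, pos)
        rel = mv.relative_read_depth(neg, pos, L=ref_small.length)
        assert rel.min() == pytest.approx(1.0, abs=0.05)
        assert rel.max() == pytest.approx(1.0, abs=0.05)


class TestDilutionSeries:
    def test_mean_depths_halve(self, ref_small, panel_small):
        sc = SimScenario(
            reference=ref_small, panel=panel_small,
            depth=DepthModel(median=1280, amplicon_sigma=0), seed=9,
        )
        factors = [1 / 2**k for k in range(7)]
        series = dilution_series(sc, factors)
        means = [
            np.mean([pc.total_depth() for pc in p.positions.values()])
            for p, _ in series
        ]
        for m, f in zip(means, factors):
            # coverage overlap inflates the per-position mean slightly above
            # the per-amplicon median
            assert m == pytest.approx(1280 * f * (1 + panel_small.mean_overlap * len(panel_small) / panel_small.L), rel=0.1)

    def test_numt_frequency_rises_as_depth_falls(self, ref_small, panel_small):
        pos = 400
        alt = transition(ref_small.base(pos))
        sc = SimScenario(
            reference=ref_small, panel=panel_small,
            numt=NumtModel(catalog={pos: alt}, read_count=10),
            depth=DepthModel(median=1000, amplicon_sigma=0), seed=9,
        )
        series = dilution_series(sc, [1.0, 0.05])
        f_high = series[0][0].get(pos).variant_frequency(alt)
        f_low = series[1][0].get(pos).variant_frequency(alt)
        assert f_high == pytest.approx(10 / 1010, rel=0.5)
        assert f_low > f_high
        assert f_low == pytest.approx(10 / 60, rel=0.5)

    @pytest.mark.parametrize("factors", [[0.5, 1.0], [1.0, -0.5]])
    def test_bad_factors_rejected(self, factors, ref_small, panel_small):
        sc = SimScenario(reference=ref_small, panel=panel_small)
        with pytest.raises(ValueError):
            dilution_series(sc, factors)
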