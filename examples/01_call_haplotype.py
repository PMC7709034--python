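"""Call a difference-coded mtDNA haplotype from a simulated pileup.

Simulates one contributor carrying a common control-region motif plus a 15%
point heteroplasmy, then runs threshold calling (10% heteroplasmy / 30%
insertion / 40% deletion, 20X minimum depth) and prints the exported
haplotype. The heteroplasmy appears as an IUPAC two-base code.
"""

import mitoval as mv
from mitoval.simulate import DepthModel, SimScenario, simulate_pileup

ref = mv.synthetic_reference(seed=11)
panel = mv.simulate_panel(109, 163, 11, L=ref.length, seed=11)

haplotype = ["263G", "750G", "1438G", "4769G", "309.1C"]
php = "8860G" if ref.base(8860) != "G" else "8860A"
scenario = SimScenario(
    reference=ref,
    panel=panel,
    haplotypes=[haplotype + [php]],
    variant_fractions={php: 0.15},  # a 15% point heteroplasmy
    depth=DepthModel(median=800),
    seed=11,
)
pileup, truth = simulate_pileup(scenario)

hap = mv.assemble_haplotype(pileup, ref, panel)
hap = mv.apply_suspect_deletions(hap)

print("exported haplotype:", mv.export_haplotype(hap))
print(f"masked positions below 20X: {len(hap.coverage_mask)}")
for call in hap.calls:
    if call.status != "confirmed":
        print(f"  [{call.status}] {call.rendered}: {call.evidence}")
print()
print("Each token is one difference from the reference; the two-base IUPAC")
print("code marks the injected heteroplasmy, called because its minor allele")
print("reached the inclusive 10% threshold.")
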