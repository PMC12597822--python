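"""Detect recurrence hotspots in a simulated tumor cohort.

Simulates 5,000 tumors with a strand/region-asymmetric background
signature plus three spiked hotspot alleles, applies the somatic retention
rules, fits the 64-context mutability model, and runs the one-sided
binomial recurrence test with BH correction.
"""

import mthotspot as mh

ref = mh.load_reference(seed=11)

spikes = (
    mh.SpikedHotspot(pos=1227, alt="A" if ref.base(1227) != "A" else "C", prob=0.004),
    mh.SpikedHotspot(pos=2571, alt="A" if ref.base(2571) != "A" else "C", prob=0.003),
    mh.SpikedHotspot(pos=10398, alt="A" if ref.base(10398) != "A" else "C", prob=0.002),
)
cfg = mh.CohortSimConfig(n_tumors=5000, spiked_hotspots=spikes, seed=7)
calls, truth = mh.simulate_cohort(ref, cfg)
print(f"simulated {len(calls)} somatic SNVs across {cfg.n_tumors} tumors")

kept = mh.filter_somatic(calls, ref)
print(f"{len(kept)} calls survive the >5%/<1%/strand/blacklist rules")

model = mh.fit_mutability(kept, ref)
top_ctx = model.as_frame().nlargest(3, "mu")
print("most mutable trinucleotide contexts (fraction of all SNVs):")
print(top_ctx.to_string(index=False))

res = mh.detect_hotspots(kept, ref, mode="position")
hot = res[res["is_hotspot"]]
print(f"\n{len(hot)} hotspot positions at Q < 0.05 "
      f"(truth: {sorted(truth['pos'])}):")
print(hot[["pos", "gene", "x", "n", "p_binom", "q"]].to_string(index=False))
# x = tumors mutated at the position, n = mutation events in its gene;
# q is the BH-adjusted probability of seeing >= x recurrences by chance
# under the position's context mutability.
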