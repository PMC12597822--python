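"""Tissue enrichment and nuclear-driver co-occurrence tests.

Simulates a cohort, derives per-sample mtDNA alteration indicators at five
levels, tests a deliberately enriched tissue for excess rRNA-hotspot
carriers, and screens nuclear driver genes for co-occurrence with mtDNA
alterations within a cancer type.
"""

import numpy as np
import pandas as pd

import mthotspot as mh

ref = mh.load_reference(seed=11)
spike = mh.SpikedHotspot(1227, "A" if ref.base(1227) != "A" else "C", 0.01)
calls, _ = mh.simulate_cohort(
    ref, mh.CohortSimConfig(n_tumors=4000, spiked_hotspots=(spike,), seed=3)
)
kept = mh.filter_somatic(calls, ref)

samples = [f"T{i:05d}" for i in range(4000)]  # all tumors, mutated or not
levels = mh.mt_alteration_levels(kept, ref, hotspot_positions=[1227], samples=samples)
print("per-sample mtDNA alteration prevalence:")
print(levels.mean().round(4).to_string())

# Tissue enrichment: one tissue with twice the cohort-wide carrier rate.
p_overall = levels["rrna_hotspot"].mean()
rng = np.random.default_rng(5)
n_tissue = 800
x = int(rng.binomial(n_tissue, 2 * p_overall))
p = mh.tissue_enrichment(n_tissue, x, p_overall)
print(f"\ntissue with {x}/{n_tissue} rRNA-hotspot carriers vs cohort rate "
      f"{p_overall:.3f}: two-sided binomial p = {p:.3g}")

# Co-occurrence: one driver gene whose mutations track mtDNA status.
idx = pd.Index(levels.index)
mt_any = levels["any_mt"].to_numpy()
driver = rng.random(len(idx)) < np.where(mt_any, 0.35, 0.15)
nuclear = pd.DataFrame(
    {"TP53": driver, "KRAS": rng.random(len(idx)) < 0.2}, index=idx
)
types = pd.Series(rng.choice(["breast", "colorectal"], size=len(idx)), index=idx)
res = mh.cooccurrence_tests(nuclear, levels, types)
print("\ntop co-occurrence results (chi-squared, 5% prevalence floor):")
cols = ["cancer_type", "gene", "level", "chi2", "odds_ratio", "p", "q"]
print(res.nsmallest(5, "p")[cols].to_string(index=False))
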