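"""Score each ETP sample's lineage bias from the nine-gene hub panel.

Normalizes hub-gene expression to the ETP cohort mean, references it to
PROM1 (Transformed Expression Scores), combines TES values into geometric-
mean lineage scores and assigns every lineage within 10% of the maximum.
Compares assignments against the simulator's latent lineage labels.
"""

import etplineage as el

cfg = el.CohortSimConfig(n_etp=12, n_nonetp=40, n_genes=200, n_up=30,
                         n_down=30, n_variance_inflated=15,
                         lineage_boost=2.0, noise_sd=0.25, seed=5)
expr, labels, truth = el.generate_cohort(cfg)
cards = el.score_cohort(expr, labels, tolerance=0.10)

print("sample    myeloid     B       T    unident.  assigned (planted)")
hits = 0
for card in cards:
    s = card.scores
    planted = truth.sample_lineage[card.sample_id][0]
    hit = planted in card.assigned
    hits += hit
    print(f"{card.sample_id}  {s['myeloid']:7.3f} {s['B']:7.3f} "
          f"{s['T']:7.3f} {s['unidentified']:7.3f}   "
          f"{'+'.join(card.assigned):20s} ({planted}{'' if hit else ' MISS'})")
print(f"\nrecovery: {hits}/{len(cards)} samples contain their planted "
      "lineage in the assigned set")
print("summary:", el.summarize_assignments(cards))
print("-> scores are ratios to the PROM1-referenced cohort mean: 1.0 means "
      "no skew; the 10% window lets genuinely mixed samples carry "
      "multiple lineages.")
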