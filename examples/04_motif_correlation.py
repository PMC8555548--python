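"""Correlate local 5-mer content with readthrough fold change.

For each PAS a window from 200 bases upstream of the nearest 3' splice
site to 200 bases downstream of the PAS is built; overlap-corrected 5-mer
frequencies (a run of six identical bases counts 1.2 events) are paired
with log2 fold change in readthrough and ranked by Spearman correlation.
"""

import polyterm as pt
from polyterm import annotation, motifstats as ms, readthrough as rt

ds = pt.generate(pt.SynthConfig(seed=1))
features = annotation.derive_features(ds.models, ds.genome.lengths())

usage = (ds.counts[ds.counts["sample"].isin(ds.wt_samples)]
         .groupby("pas_id")["up"].mean().to_dict())
sites = rt.collapse_pas(ds.pas_sites, usage)
counts = ds.counts[ds.counts.pas_id.isin({s.pas_id for s in sites})]
table = rt.readthrough_table(counts)
diff = rt.differential(table, ds.mutant_samples, ds.wt_samples)

windows, n_excl = ms.build_pas_windows(
    [s for s in sites if s.pas_id in diff.index], features,
    ds.genome.lengths())
print(f"{len(windows)} analysis windows ({n_excl} PAS without an upstream "
      "3' splice site excluded)")

res = ms.motif_correlation(windows, diff["fold_change"].dropna().to_dict(),
                           ds.genome)
ranked = res.dropna(subset=["spearman_rho"]).sort_values("spearman_rho")
print(f"{int(res.significant.sum())} of 1024 motifs significant "
      "(uncorrected alpha = 0.05)")
print("\nmost negative correlations (motif content suppresses readthrough "
      "in the mutant):")
print(ranked.head(5)[["motif", "normalized_freq", "spearman_rho", "p_value"]]
      .to_string(index=False))
print(f"\nplanted driver TTTTT ranks "
      f"{list(ranked.motif).index('TTTTT') + 1} of {len(ranked)} — the "
      "generator links mutant readthrough loss to planted T-run content.")
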