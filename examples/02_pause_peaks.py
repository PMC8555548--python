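"""Post-process pause-peak summits and rank 3'-flank 5-mers.

Expands unstranded summits to 80 bp, assigns strand by read majority,
filters regions touching internal exons, and compares 3'-half 5-mer
frequencies with random genomic controls.
"""

import polyterm as pt
from polyterm import annotation, peaks

ds = pt.generate(pt.SynthConfig(seed=1))
features = annotation.derive_features(ds.models, ds.genome.lengths())

regions = peaks.expand_and_strand(ds.summits, ds.peak_reads,
                                  ds.genome.lengths())
correct = sum(r.strand == ds.truth.peak_strand[f"peak{i:04d}"]
              for i, r in enumerate(regions))
print(f"strand assignment: {correct}/{len(regions)} match the planted truth")

internal = [iv for _g, iv in features.iter_class("internal_exons")]
kept, removed = peaks.filter_regions(regions, internal, [], ds.genome)
print(f"{len(kept)} regions kept, {len(removed)} removed "
      "(internal-exon overlap)")

enrich = peaks.flank_kmer_enrichment(kept, ds.genome, k=5, n_controls=5,
                                     control_size=1000, seed=0)
top = enrich.sort_values("z", ascending=False).head(5)
print("\nmost enriched 3'-flank 5-mers vs random controls:")
print(top[["motif", "observed_freq", "control_mean", "z"]]
      .to_string(index=False))
print("\nT-rich motifs dominate because the generator plants T runs on the "
      "3' flank of most peaks,\nmirroring the association of pausing with "
      "downstream T-rich sequence.")
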