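"""piRNA target prediction by seed matching and per-TE RPKM.

A piRNA targets a TE wherever the reverse complement of its positions
2-11 occurs exactly in the TE sense sequence; multi-target reads are
split equally over all sites.  Weighted per-TE abundances are then
normalised to RPKM."""

from tepirna.smallrna import (NormalizationTotals, pirna_rpkm,
                              predict_targets)
from tepirna.synth import (ReadPlan, SynthConfig, make_smallrna_reads,
                           make_te_references)

cfg = SynthConfig(seed=19, n_families=3, te_length_range=(2000, 3000))
refs = make_te_references(cfg)
records, _ = make_smallrna_reads(
    cfg, refs, {name: ReadPlan(antisense=200) for name in refs})

weights = predict_targets(records, refs)
totals = NormalizationTotals(pirna_reads=float(len(records)),
                             sirna_te_reads=0.0)
print("per-TE weighted antisense piRNA targeting:")
for name, w in weights.items():
    rpkm = pirna_rpkm(w, len(refs[name]), totals)
    print(f"  {name}: weight={w:8.2f}  RPKM={rpkm:10.1f}")
print("\nWeights sum to the number of reads with at least one seed")
print(f"match (total weight {weights.sum():.2f} of {len(records)} reads);")
print("RPKM scales by TE length and library size.")
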