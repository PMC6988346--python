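# tepirna

Tools for studying the evolutionary arms race between transposable
elements (TEs) and PIWI-interacting RNAs (piRNAs) in *Drosophila
melanogaster* populations: a forward Wright–Fisher simulator of TE:piRNA
coevolution, and the quantification pipeline used to measure the arms
race in population sequencing data — weighted small-RNA assignment,
ping-pong signatures, de novo piRNA signature calling, piRNA target
prediction, coverage-based TE copy number, insertion genotyping and
cross-strain correlation statistics.  Seeded synthetic-data generators
produce every input with known ground truth, so the whole package builds
and tests without downloads.

It is written for population geneticists and small-RNA biologists who
want to simulate TE:piRNA dynamics under explicit parameters, or to run
the quantification steps on their own alignment-derived tables.

## The model

A diploid, panmictic Wright–Fisher population of size *N*<sub>e</sub>
carries TE loci and piRNA-generating loci ("piTEs") on two homologous
chromosomes of length *L*.  piRNAs repress only TEs of their own
sequence subtype *j*, with dosage-dependent kinetics: a TE of subtype
*j* present in *x*<sub>j</sub> copies, matched by *y*<sub>j</sub> piRNA
loci, transposes at rate

&nbsp;&nbsp;&nbsp;&nbsp; *u* / (1 + *R·y*<sub>j</sub>/*x*<sub>j</sub>)

where *R* is the repression efficiency.  Fitness declines with the
effective number of active TEs
*n* = Σ<sub>j</sub> *x*<sub>j</sub>/(1 + *R·y*<sub>j</sub>/*x*<sub>j</sub>)
and with the excess piRNA count *m* = max(0, Σ*y*<sub>j</sub> − *x*<sub>j</sub>)
(off-target cost, penalty coefficient *p*):

&nbsp;&nbsp;&nbsp;&nbsp; *w* = exp(−*s·a·n* − ½*s·b·n*² + *p*(−*s·a·m* − ½*s·b·m*²))

Each generation, parents are sampled in proportion to fitness; TEs
transpose in the parents (a new insertion becomes a piRNA locus with
probability *f*); each parent contributes one gamete formed by
recombination (Poisson(*r·L*) crossovers), excision (*i*), escape to a
new subtype (*e*) and duplication (*d*).  A replicate stops when all
TEs are purged or mean fitness falls below 0.05.

On the quantification side, multimapped small RNAs are equally split
across locations; piRNA-like reads are 23–29 nt (siRNA-like 20–22 nt);
the ping-pong signature is the Z-score of the 10-nt 5′–5′ overlap count
between sense and antisense reads against the other overlap lengths;
piRNA targets are predicted by exact antisense matching of read
positions 2–11; a de novo piRNA signature at a novel insertion requires
≥ 0.5 RPKM in the 2-kb flanks with ≥ 70% of reads antisense upstream /
sense downstream; TE copy number is the median depth over covered sites
normalised by single-copy genes.

## Worked example

```bash
python examples/simulate_arms_race.py
```

```
R= 0.0: stopped 'completed' at generation 2500
        TEs/chromosome=15.9  piTEs/chromosome=21.8  mean fitness=0.529
        last recorded correlations: 0.00 0.21 0.21 0.00 0.00
R=12.0: stopped 'fitness' at generation 2458
        TEs/chromosome=482.0  piTEs/chromosome=482.3  mean fitness=0.050
        last recorded correlations: 0.00 0.28 0.26 0.42 0.00
```

Without repression (R=0) the TE load equilibrates near 16 TEs per
chromosome and the TE:piRNA chromosome correlation (Spearman, clamped
to 0 when P > 0.05) hovers at zero.  Under strong repression (R=12)
piRNAs shelter TEs from selection, loads grow, and positive
correlations between TE and piRNA counts on the same chromosome emerge
in the late generations — the arms-race signature.  The other examples
(`pingpong_signature.py`, `predict_targets.py`, `insertion_spectrum.py`,
`copy_number.py`, `correlate_strains.py`) each build a small synthetic
input, run one pipeline stage and print what the numbers mean.

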