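# Methods

## The coevolution model

The simulator follows a diploid, panmictic, constant-size Wright–Fisher
population with non-overlapping generations.  Each individual carries
two homologous chromosomes of length `L` (default 100 Mb); a locus is
either a transposable element (TE) or a piRNA-generating locus
("piTE"), and carries an integer sequence subtype `j`.  piRNAs repress
only TEs of their own subtype, in a dosage-dependent way: with
`x_j` TE copies and `y_j` matched piRNA loci in an individual (both
homologs pooled — repression is cellular, not chromosomal), each TE of
subtype `j` transposes with probability `u / (1 + R*y_j/x_j)` per
generation.  Only TE loci transpose; a new insertion lands at a uniform
position on a uniform homolog and becomes a piRNA locus with
probability `f`, keeping the parental subtype.

Fitness is an exponential quadratic in the effective TE load
`n = sum_j x_j/(1 + R*y_j/x_j)` and the excess piRNA count
`m = max(0, sum_j y_j - x_j)`:

    w = exp(-s*a*n - 1/2*s*b*n^2 + p*(-s*a*m - 1/2*s*b*m^2))

The excess term models the off-target cost of piRNAs beyond the
matched TE complement.  `m` is computed on global totals by default; a
`per_subtype_excess` switch clamps within each subtype instead (the
two agree whenever a single subtype segregates, which is the case in
every run without escape).

Per generation: two parents are drawn per offspring with probability
proportional to `w` (independently, so selfing is possible at rate
1/Ne); transposition happens in each sampled parent (independently per
use of the parent); each parent yields one gamete via recombination
(Poisson(`r*L`) crossovers at uniform breakpoints, starting homolog
uniform), then excision, escape and duplication; the two gametes form
the offspring.  This event order — sampling, transposition,
recombination, meiotic mutation, union — is fixed for reproducibility;
the model statement constrains only that transposition is premeiotic
and the other events meiotic.

Meiotic events per locus: excision removes a locus with probability
`i`; escape (TE only, probability `e`) rewrites the subtype to a fresh
integer from a global counter, so an escaped TE is matched only by
piRNA loci descending from its own lineage; duplication (probability
`d`, TE and piRNA loci alike) copies the locus to a new uniform
position on the same gamete.

**Excision of piRNA loci.**  Excision applies to piRNA loci as well as
TEs by default (`excise_pirna=True`).  This choice matters: if piRNA
loci can only be gained (by the `f`-flux and duplication at `d` >
`i`), their number ratchets up to the TE count, at which point the
quadratic excess-piRNA penalty makes selection *favour* additional TEs
(they absorb the excess), and the population escalates to a fitness
collapse at every repression strength.  With piRNA-locus excision the
piTE:TE ratio settles near `f*u'/i` and the intermediate-selection
regimes (s = 2, s = 5) equilibrate as expected.  The TE-only variant
remains available for comparison.

**Stopping rules.**  A replicate ends when all TEs are purged from the
population, when mean fitness drops below `fitness_floor` (0.05), or at
`generations`.  Purging is absorbing: no process creates TE loci
de novo.

**The correlation statistic.**  At each recording interval (every 50
generations) the per-chromosome TE and piRNA locus counts (all subtypes
pooled) are collected; `sample_size` chromosomes carrying at least one
TE are sampled without replacement and the Spearman rank correlation is
computed (Pearson available).  A non-significant test (P > 0.05)
reports 0; fewer than `sample_size` qualifying chromosomes report "not
computed".  The threshold counts qualifying chromosomes, matching the
sampling unit.  A replicate's "late-generation correlation" summarised
by experiments is the median of its last five recorded values, which is
robust to the clamp flickering between consecutive recordings.

## Parameters

Defaults are the rates for *D. melanogaster* scaled by 100 to make
desk-scale runs informative: `Ne=5000`, `L=1e8` bp, `u=0.03` per
element per generation, `d=0.003`, `i=0.001`, `e=0` (or 0.001),
`f=0.2` (or 0.05), `r=1e-8` per nucleotide, `p=0.5`, `a=1e-3`,
`b=5e-4`, 15000 generations, 200 replicates, 1000 sampled chromosomes,
10% initial single-TE carriers.  `R` (repression efficiency, 0–20) and
`s` (selection scaling, 0.5–20) are the experimental dials: `R`
controls how strongly matched piRNAs suppress transposition, `s` scales
the whole fitness cost.

Two reduced presets keep experiments single-core: the *desk preset*
(`SimParams.desk()`: Ne=1000, 3000 generations, 20 replicates, 200
sampled chromosomes) for the null-correlation and selection-extreme
experiments, and a further reduced size (Ne=500, 2500 generations, 6
replicates, 150 sampled chromosomes) for the repression/escape ordering
experiments, which spend most of their time at high TE loads (hundreds
of loci per chromosome).  These sizes are the package's chosen problem
sizes for its shipped experiments; the full-scale parameters are a
constructor call away.

At reduced scale two behaviours differ quantitatively from full scale:
selection is less efficient relative to drift, so strong-repression
runs (R=12, s=2) escalate to the fitness floor within ~2500 generations
rather than plateauing; and single replicates occasionally show
transient significant correlations at R=0 (the biogenesis coupling),
which is why the null claim is about the *median* across replicates.

## Implementation notes

The population lives in flat per-locus arrays grouped by individual;
the generation step is a numba kernel.  Determinism: all randomness
derives from one integer seed per replicate; the kernel RNG is
re-seeded each generation from that stream.  When no escape mutation
has ever occurred all loci share subtype 0 and per-parent transposition
counts are drawn binomially; with multiple subtypes the kernel falls
back to per-locus Bernoulli draws.  New-insertion positions are
redrawn on collision with other same-generation insertions; collisions
with existing loci (probability ~ loci/L ≈ 1e-5) are tolerated, as is
the corresponding case for duplications.  The per-individual reference
operations (`transpose`, `recombine`, `mutate_meiotic`,
`step_generation`) implement the same contracts one event at a time in
pure Python and back the unit tests; the kernel is validated against
their statistical expectations (transposition flux, drift variance,
fitness closed forms to 1e-12).

## Quantification pipeline

*Weighted assignment.*  A read mapped to `k` locations carries weight
`1/k` per location; all per-TE counts, profiles and RPKMs use these
split weights, so total weight equals the number of retained reads.

*Classification.*  Reads overlapping rRNA/tRNA/miscRNA/ncRNA/miRNA
annotation on any hit are excluded; the rest are piRNA-like (23–29 nt),
siRNA-like (20–22 nt) or "other".

*Ping-pong.*  For each overlap length o in 1..23, the weighted count of
sense/antisense 5′-pairs overlapping by exactly o nt is accumulated via
5′-end profiles (equivalent to exhaustive pair enumeration, which the
tests verify); Z(o) is computed against the mean and sd of the other
overlap lengths, and flagged undefined when that sd is zero.  The
background range 1..23 spans the minimum piRNA length.

*RPKM.*  `weighted count / reference length * 1e9 / (23-29 nt reads
mapped to genome+TEs + 20-22 nt reads mapped to TEs)`.

*Target prediction.*  Read positions 2–11 (1-based from the 5′ end)
must match a TE sense sequence exactly in antisense orientation; each
read splits its unit weight equally over all matching *sites* (not
references), and per-TE weights sum the site shares.  Reads shorter
than 11 nt are skipped with a warning.

*De novo signature.*  Over the 2-kb flanks (clipped at contig ends) of
a novel insertion, using uniquely mapped 23–29 nt reads: positive iff
RPKM ≥ 0.5 over the combined flanks and (upstream antisense + downstream
sense) ≥ 70% of flank reads, evaluated jointly over both flanks.  Zero
flank reads yield a negative call with diagnostics.

*Insertion calling.*  A known (reference-annotated) insertion is
present in a strain iff some properly paired read spans ≥ 30 bp of a
boundary flank with ≤ 4 mismatches+indels per 100 bp and the site is
not independently called absent.  Novel calls are merged per
chromosome and family when closer than 100 bp (transitively; supports
summed, frequency recomputed as the support-weighted mean — the
alternative "max of constituents" would only matter for heterogeneous
clusters) and retained iff some strain shows both-flank support with
frequency strictly above 0.80.

*Copy number.*  Median depth over covered sites (depth > 0) of the TE
reference, divided by the median of per-gene median depths of
single-copy genes (a pooled-positions variant is available; the
per-gene default is robust to a single aberrant gene).  The P-element's
active part (1-based 819–2527) is sliced out and treated as its own
reference, since internally deleted elements inflate the terminal
coverage only.

*Statistics.*  Per-family Spearman correlations across strains (≥ 4
paired observations required) with Benjamini–Hochberg adjustment across
tested families; cv = sample sd (ddof=1)/mean; spectrum-class
comparisons by two-sided Fisher's exact test; expression fold change as
log2(mean carrier / mean non-carrier expression) with a pseudocount of
1 normalized unit applied (and flagged) only when the non-carrier mean
is zero, and per-category two-sample KS tests (Mann–Whitney alongside).
All tests are two-sided.

## Synthetic data

The generators emulate: TE reference sets (uniform-random sequences,
800–8000 bp); small-RNA libraries with length modes at 25 nt (23–29)
and 21 nt (20–22), a 1U fraction following `u1_bias` (default 0.721)
by rejection-sampling start positions, planted 10-nt 5′–5′ ping-pong
pairs (which skip the 1U constraint, since the overlap geometry fixes
both ends), and natural multimapping (each read is re-searched against
all references); insertion panels whose occupancy follows a
deterministic cycle through `insertion_freq_spectrum` (default skewed
to singletons, as in real spectra under purifying selection);
strand-asymmetric flank reads; and coverage tracks at 12.5x single-copy
depth with multiplicative Gaussian noise (exact when noiseless).

What the generators do *not* emulate — sequencing error, mapping bias,
chimeric reads, reference misassembly, piRNA cluster structure, TE
sequence divergence within a family — bounds what the passing tests
show: the pipeline recovers planted truth under clean conditions and
exact threshold semantics, not robustness to real-library artefacts.

## Numerical choices and degenerate inputs

Spearman/Pearson on constant vectors is treated as non-significant
(correlation 0) in the simulator's clamped statistic, and reported as
missing in the cross-strain layer.  An empty read set is an error for
1U fractions but a negative call for the de novo signature.  Zero
normalization totals and zero gene medians raise.  Fisher's exact
odds ratio may be infinite for degenerate tables and is reported as
such.  Trajectory quantiles across replicates with early stops are
computed over the replicates still running at each recorded
generation.
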