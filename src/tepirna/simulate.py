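"""Forward Wright-Fisher simulation of the TE:piRNA evolutionary arms race.

The model: a diploid, panmictic, constant-size population carries
transposable-element (TE) loci and piRNA-generating loci ("piTEs") on two
homologous chromosomes of length ``L``.  piRNAs repress only TEs of their
own sequence subtype ``j``, with enzymatic, dosage-dependent kinetics: a TE
of subtype ``j`` present in ``x_j`` copies and matched by ``y_j`` piRNA loci
transposes at rate ``u / (1 + R*y_j/x_j)``.  Fitness declines with the
effective number of active TEs

    n = sum_j x_j / (1 + R*y_j/x_j)

and, with penalty coefficient ``p``, with the number of excessive piRNAs
``m = max(0, sum_j y_j - x_j)``:

    w = exp(-s*a*n - 1/2*s*b*n^2 + p*(-s*a*m - 1/2*s*b*m^2))

Each generation, parents are sampled proportionally to fitness; TEs
transpose in the parents (a new insertion becomes a piRNA locus with
probability ``f``); each parent contributes one gamete formed by
recombination (Poisson(r*L) crossovers) followed by excision (``i``),
escape to a fresh subtype (``e``) and duplication (``d``).

Two implementations coexist: per-individual pure-Python operations
(`transpose`, `recombine`, `mutate_meiotic`, `step_generation`) that state
the model one event at a time, and a fused numba kernel (`Population.step`)
used by `run_replicate` / `run_experiment` for full-length runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _kernel

__all__ = [
    "SimParams", "Locus", "Individual", "TrajectoryRecord",
    "effective_load", "excess_pirna", "fitness", "transposition_rate",
    "transpose", "mutate_meiotic", "recombine", "step_generation",
    "Population", "ReplicateResult", "run_replicate",
    "chromosome_correlation", "run_experiment", "NOT_COMPUTED",
]

#: sentinel returned when too few TE-carrying chromosomes exist to sample
NOT_COMPUTED = "not computed"


@dataclass(frozen=True)
class SimParams:
    """Scaled simulation parameters (the D. melanogaster rates scaled x100).

    Defaults are the full-study values; :meth:`desk` gives the reduced
    preset used for routine runs on a single core.
    """

    Ne: int = 5000                 # diploid population size
    L: int = 100_000_000           # chromosome length, bp
    u: float = 0.03                # transposition rate / element / generation
    R: float = 0.0                 # piRNA repression efficiency
    s: float = 2.0                 # selection scaling constant
    a: float = 1e-3                # linear fitness constant
    b: float = 5e-4                # quadratic fitness constant
    p: float = 0.5                 # excessive-piRNA penalty coefficient
    d: float = 0.003               # duplication rate / locus / generation
    i: float = 0.001               # excision rate / TE / generation
    e: float = 0.0                 # escape-to-new-subtype rate / TE
    f: float = 0.2                 # P(new insertion is a piRNA locus)
    r: float = 1e-8                # recombination rate / nucleotide
    generations: int = 15_000
    replicates: int = 200
    sample_size: int = 1000        # chromosomes sampled for the correlation
    fitness_floor: float = 0.05    # mean-fitness stopping threshold
    init_carrier_fraction: float = 0.1
    record_every: int = 50
    per_subtype_excess: bool = False  # m as sum_j max(0, y_j-x_j) instead
    excise_pirna: bool = True      # excision i also removes piRNA loci

    def __post_init__(self):
        for name in ("u", "d", "i", "e", "f", "p",
                     "init_carrier_fraction", "fitness_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("R", "s", "a", "b", "r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")

    @classmethod
    def desk(cls, **overrides) -> "SimParams":
        """Reduced preset: Ne=1000, 3000 generations, 20 replicates, 200
        sampled chromosomes (with the qualifying threshold scaled along)."""
        base = dict(Ne=1000, generations=3000, replicates=20,
                    sample_size=200)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "SimParams":
        return replace(self, **overrides)


class Locus(NamedTuple):
    position: int
    subtype: int
    is_pirna: bool


@dataclass
class Individual:
    """Two homologous chromosomes, each a position-sorted list of loci."""

    chromA: list = field(default_factory=list)
    chromB: list = field(default_factory=list)

    def counts(self):
        """(x, y): per-subtype TE and piRNA locus counts over both homologs."""
        x: dict[int, int] = {}
        y: dict[int, int] = {}
        for loc in self.chromA + self.chromB:
            tgt = y if loc.is_pirna else x
            tgt[loc.subtype] = tgt.get(loc.subtype, 0) + 1
        return x, y


class TrajectoryRecord(NamedTuple):
    generation: int
    te_per_chrom: float        # mean TE loci per chromosome
    pite_per_chrom: float      # mean piRNA-generating loci per chromosome
    eff_per_chrom: float       # mean effective TE load n per chromosome
    mean_fitness: float
    correlation: object        # float, or NOT_COMPUTED sentinel


# ---------------------------------------------------------------------------
# scalar model functions


def effective_load(x: Mapping[int, int], y: Mapping[int, int],
                   R: float) -> float:
    """Effective number of active TEs, n = sum_j x_j / (1 + R*y_j/x_j)."""
    n = 0.0
    for j, xj in x.items():
        if xj < 0 or y.get(j, 0) < 0:
            raise ValueError("counts must be nonnegative")
        if xj == 0:
            continue
        n += xj / (1.0 + R * y.get(j, 0) / xj)
    return n


def excess_pirna(x: Mapping[int, int], y: Mapping[int, int],
                 per_subtype: bool = False) -> float:
    """Number of excessive piRNAs, m = max(0, sum_j y_j - x_j).

    The default reads the sum globally (total piRNA loci minus total TE
    loci); ``per_subtype=True`` clamps within each subtype instead.
    """
    if any(v < 0 for v in x.values()) or any(v < 0 for v in y.values()):
        raise ValueError("counts must be nonnegative")
    if per_subtype:
        subtypes = set(x) | set(y)
        return float(sum(max(0, y.get(j, 0) - x.get(j, 0)) for j in subtypes))
    return float(max(0, sum(y.values()) - sum(x.values())))


def fitness(n: float, m: float, params: SimParams) -> float:
    """w = exp(-s*a*n - 1/2*s*b*n^2 + p*(-s*a*m - 1/2*s*b*m^2))."""
    if n < 0 or m < 0:
        raise ValueError("n and m must be nonnegative")
    s, a, b, p = params.s, params.a, params.b, params.p
    return math.exp(-s * a * n - 0.5 * s * b * n * n
                    + p * (-s * a * m - 0.5 * s * b * m * m))


def transposition_rate(x_j: int, y_j: int, u: float, R: float) -> float:
    """Per-element transposition rate u / (1 + R*y_j/x_j)."""
    if x_j < 1:
        raise ValueError("transposition rate undefined for x_j < 1")
    return min(1.0, u / (1.0 + R * y_j / x_j))


# ---------------------------------------------------------------------------
# per-individual reference operations


def transpose(ind: Individual, params: SimParams,
              rng: np.random.Generator) -> Individual:
    """Each non-piRNA TE locus spawns a new insertion with probability
    equal to its subtype's transposition rate; new insertions land at a
    uniform position on a uniformly chosen homolog and become a piRNA
    locus with probability f.  Parent loci are unchanged."""
    x, y = ind.counts()
    new = Individual(list(ind.chromA), list(ind.chromB))
    chroms = (new.chromA, new.chromB)
    occupied = [{loc.position for loc in c} for c in chroms]
    for loc in ind.chromA + ind.chromB:
        if loc.is_pirna:
            continue
        rate = transposition_rate(x[loc.subtype], y.get(loc.subtype, 0),
                                  params.u, params.R)
        if rng.random() < rate:
            h = int(rng.integers(0, 2))
            pos = int(rng.integers(0, params.L))
            while pos in occupied[h]:
                pos = int(rng.integers(0, params.L))
            occupied[h].add(pos)
            is_pi = bool(rng.random() < params.f)
            chroms[h].append(Locus(pos, loc.subtype, is_pi))
    new.chromA.sort()
    new.chromB.sort()
    return new


def recombine(chromA: Sequence[Locus], chromB: Sequence[Locus],
              r: float, L: int, rng: np.random.Generator) -> list:
    """One gamete: Poisson(r*L) crossovers at uniform breakpoints; segments
    alternate between homologs starting from a uniformly chosen one."""
    nbp = rng.poisson(r * L)
    bps = np.sort(rng.random(nbp) * L)
    h0 = int(rng.integers(0, 2))
    gamete = []
    for h, chrom in enumerate((chromA, chromB)):
        for loc in chrom:
            cnt = int(np.searchsorted(bps, loc.position, side="right"))
            if (h0 + cnt) % 2 == h:
                gamete.append(loc)
    gamete.sort()
    return gamete


def mutate_meiotic(gamete: Sequence[Locus], params: SimParams,
                   rng: np.random.Generator,
                   subtype_counter: Iterable[int] | None = None) -> list:
    """Excision (i; TE loci, and piRNA loci unless ``excise_pirna`` is
    off), escape to a fresh subtype (e, TE only) and duplication to a new
    uniform position (d, TE and piRNA loci)."""
    counter = subtype_counter if subtype_counter is not None else iter(
        range(10**9, 10**9 + 10**6))
    out = []
    occupied = {loc.position for loc in gamete}
    for loc in gamete:
        sj = loc.subtype
        if loc.is_pirna:
            if params.excise_pirna and rng.random() < params.i:
                continue
        else:
            if rng.random() < params.i:
                continue
            if params.e > 0 and rng.random() < params.e:
                sj = next(counter)
        kept = Locus(loc.position, sj, loc.is_pirna)
        out.append(kept)
        if params.d > 0 and rng.random() < params.d:
            pos = int(rng.integers(0, params.L))
            while pos in occupied:
                pos = int(rng.integers(0, params.L))
            occupied.add(pos)
            out.append(Locus(pos, sj, loc.is_pirna))
    out.sort()
    return out


def step_generation(pop: Sequence[Individual], params: SimParams,
                    rng: np.random.Generator,
                    subtype_counter: Iterable[int] | None = None) -> list:
    """One Wright-Fisher generation (reference implementation).

    Raises ``ZeroDivisionError``-free RuntimeError when every individual
    has zero fitness (the simulation-stop signal).
    """
    w = np.empty(len(pop))
    for k, ind in enumerate(pop):
        x, y = ind.counts()
        w[k] = fitness(effective_load(x, y, params.R),
                       excess_pirna(x, y, params.per_subtype_excess), params)
    tot = w.sum()
    if tot <= 0:
        raise RuntimeError("all individuals have zero fitness")
    prob = w / tot
    counter = subtype_counter if subtype_counter is not None else iter(
        range(10**9, 10**9 + 10**6))
    offspring = []
    for _ in range(len(pop)):
        gametes = []
        for parent_idx in rng.choice(len(pop), size=2, p=prob):
            parent = transpose(pop[parent_idx], params, rng)
            gam = recombine(parent.chromA, parent.chromB,
                            params.r, params.L, rng)
            gametes.append(mutate_meiotic(gam, params, rng, counter))
        offspring.append(Individual(gametes[0], gametes[1]))
    return offspring


# ---------------------------------------------------------------------------
# kernel-backed population for full-length replicates


class Population:
    """Flat-array population advanced by the numba kernel."""

    def __init__(self, params: SimParams, seed: int):
        self.params = params
        self.rng = np.random.default_rng(seed)
        Ne, L = params.Ne, params.L
        n_carriers = int(round(params.init_carrier_fraction * Ne))
        carriers = self.rng.choice(Ne, size=n_carriers, replace=False)
        carriers.sort()
        self.pos = self.rng.integers(0, L, size=n_carriers).astype(np.int64)
        self.sub = np.zeros(n_carriers, dtype=np.int64)
        self.pirna = np.zeros(n_carriers, dtype=np.uint8)
        self.homolog = self.rng.integers(
            0, 2, size=n_carriers).astype(np.uint8)
        counts = np.zeros(Ne, dtype=np.int64)
        counts[carriers] = 1
        self.offsets = np.concatenate(
            ([0], np.cumsum(counts))).astype(np.int64)
        self.next_subtype = 1
        self.generation = 0

    @property
    def n_loci(self) -> int:
        return self.pos.shape[0]

    def stats(self):
        """(w, n, m, rate, xcnt, urate) arrays for the current generation."""
        p = self.params
        return _kernel.fitness_rates(
            self.sub, self.pirna, self.offsets,
            float(p.R), float(p.s), float(p.a), float(p.b), float(p.p),
            float(p.u), p.per_subtype_excess)

    def chromosome_counts(self):
        """(te, pite) locus counts per chromosome (2*Ne each)."""
        Ne = self.params.Ne
        owner = np.repeat(np.arange(Ne), np.diff(self.offsets))
        key = owner * 2 + self.homolog
        te = np.bincount(key[self.pirna == 0], minlength=2 * Ne)
        pi = np.bincount(key[self.pirna == 1], minlength=2 * Ne)
        return te, pi

    def step(self, w, rate, xcnt, urate) -> None:
        p = self.params
        cap = max(4 * self.n_loci + 4 * p.Ne + 1024, 8192)
        while True:
            seed = int(self.rng.integers(1, 2**31 - 1))
            res = _kernel.make_offspring(
                self.pos, self.sub, self.pirna, self.homolog, self.offsets,
                w, rate, xcnt, urate,
                np.int64(p.L), float(p.d), float(p.i),
                float(p.i) if p.excise_pirna else 0.0, float(p.e),
                float(p.f), float(p.r) * float(p.L),
                np.int64(self.next_subtype), seed, np.int64(cap))
            status = res[0]
            if status == _kernel.STATUS_OVERFLOW:
                cap *= 2
                continue
            if status == _kernel.STATUS_ZERO_FITNESS:
                raise RuntimeError("all individuals have zero fitness")
            break
        (_, self.pos, self.sub, self.pirna, self.homolog,
         self.offsets, self.next_subtype) = res
        self.generation += 1


@dataclass
class ReplicateResult:
    trajectory: pd.DataFrame   # one row per recorded generation
    stop_reason: str           # "purged" | "fitness" | "completed"
    stop_generation: int

    @property
    def final_correlation(self):
        col = self.trajectory["correlation"]
        return col.iloc[-1]


def chromosome_correlation(te_counts, pi_counts, sample_size: int,
                           rng: np.random.Generator,
                           method: str = "spearman", alpha: float = 0.05):
    """Rank (or Pearson) correlation between per-chromosome TE and piRNA
    locus counts in ``sample_size`` sampled TE-carrying chromosomes.

    Returns 0.0 when the test is not significant (P > alpha), and the
    :data:`NOT_COMPUTED` sentinel when fewer than ``sample_size``
    chromosomes carry a TE.
    """
    te_counts = np.asarray(te_counts)
    pi_counts = np.asarray(pi_counts)
    qualifying = np.flatnonzero(te_counts >= 1)
    if qualifying.size < sample_size:
        return NOT_COMPUTED
    idx = rng.choice(qualifying, size=sample_size, replace=False)
    te, pi = te_counts[idx], pi_counts[idx]
    if np.all(te == te[0]) or np.all(pi == pi[0]):
        return 0.0  # degenerate: no rank variation, never significant
    if method == "spearman":
        rho, pval = sps.spearmanr(te, pi)
    elif method == "pearson":
        rho, pval = sps.pearsonr(te, pi)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(rho) or pval > alpha:
        return 0.0
    return float(rho)


def run_replicate(params: SimParams, seed: int,
                  method: str = "spearman") -> ReplicateResult:
    """Run one replicate to ``params.generations`` or to a stopping rule
    (all TEs purged, or mean fitness below ``params.fitness_floor``)."""
    pop = Population(params, seed)
    corr_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    records = []
    stop_reason = "completed"
    stop_gen = params.generations

    def record(gen):
        w, n, m, rate, xcnt, urate = pop.stats()
        te_tot = int(np.sum(pop.pirna == 0))
        pi_tot = int(np.sum(pop.pirna == 1))
        denom = 2.0 * params.Ne
        te_c, pi_c = pop.chromosome_counts()
        corr = chromosome_correlation(te_c, pi_c, params.sample_size,
                                      corr_rng, method=method)
        records.append(TrajectoryRecord(
            gen, te_tot / denom, pi_tot / denom, float(n.sum()) / denom,
            float(w.mean()), corr))
        return w, rate, te_tot

    gen = 0
    while True:
        w, n, m, rate, xcnt, urate = pop.stats()
        te_tot = int(np.sum(pop.pirna == 0))
        mean_w = float(w.mean())
        if te_tot == 0:
            stop_reason, stop_gen = "purged", gen
            record(gen)
            break
        if mean_w < params.fitness_floor:
            stop_reason, stop_gen = "fitness", gen
            record(gen)
            break
        if gen % params.record_every == 0 or gen == params.generations:
            record(gen)
        if gen >= params.generations:
            break
        pop.step(w, rate, xcnt, urate)
        gen += 1

    traj = pd.DataFrame(records, columns=TrajectoryRecord._fields)
    return ReplicateResult(traj, stop_reason, stop_gen)


def run_experiment(grid: Sequence[SimParams], replicates: int,
                   base_seed: int, method: str = "spearman",
                   quantiles=(0.025, 0.5, 0.975)):
    """Run ``replicates`` per parameter set; returns (tidy, summary).

    ``tidy`` has one row per configuration x replicate x recorded
    generation; ``summary`` holds the median and 2.5/97.5% quantiles of
    every trajectory field per configuration x generation (correlations
    recorded as numbers, with the P>0.05 clamp applied and the
    not-computed sentinel treated as missing).
    """
    if not grid:
        raise ValueError("parameter grid must be nonempty")
    seed_rng = np.random.default_rng(base_seed)
    seeds = seed_rng.integers(1, 2**31 - 1,
                              size=(len(grid), replicates))
    frames = []
    for ci, params in enumerate(grid):
        for rep in range(replicates):
            res = run_replicate(params, int(seeds[ci, rep]), method=method)
            t = res.trajectory.copy()
            t.insert(0, "config", ci)
            t.insert(1, "replicate", rep)
            t["stop_reason"] = res.stop_reason
            frames.append(t)
    tidy = pd.concat(frames, ignore_index=True)
    num = tidy.copy()
    num["correlation"] = pd.to_numeric(
        num["correlation"].where(num["correlation"] != NOT_COMPUTED),
        errors="coerce")
    value_cols = ["te_per_chrom", "pite_per_chrom", "eff_per_chrom",
                  "mean_fitness", "correlation"]
    summary = (num.groupby(["config", "generation"])[value_cols]
               .quantile(list(quantiles)).unstack(level=-1))
    summary.columns = [f"{c}_q{q}" for c, q in summary.columns]
    return tidy, summary.reset_index()
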