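"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the study conditions: a panel of fly strains
carrying known/novel TE insertions at controlled population frequencies;
ovary small-RNA read sets with a 23-29 nt piRNA peak (mode 25 nt) and a
20-22 nt siRNA peak (mode 21 nt), configurable 1U bias, planted 10-nt
5'-5' ping-pong pairs and strand-asymmetric reads in insertion flanks;
and DNA-coverage tracks with known true TE copy number at ~12.5x
single-copy depth.  Ground truth is returned alongside each dataset so
downstream estimators can be scored exactly.  All randomness flows from
the single integer seed of :class:`SynthConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .smallrna import SmallRNARecord, revcomp

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_strains: int = 10
    n_families: int = 5
    te_length_range: tuple = (800, 8000)
    pirna_peak_len: int = 25
    sirna_peak_len: int = 21
    u1_bias: float = 0.721
    pingpong_fraction: float = 0.3
    flank_asymmetry: float = 0.9
    depth_mean: float = 12.5
    insertion_freq_spectrum: tuple = (
        0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2, 0.3, 0.5, 1.0)

    def __post_init__(self):
        for name in ("u1_bias", "pingpong_fraction", "flank_asymmetry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        lo, hi = self.te_length_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"invalid te_length_range {self.te_length_range}")
        if self.n_families < 1 or self.n_strains < 1:
            raise ValueError("n_families and n_strains must be >= 1")
        if self.pirna_peak_len <= 0 or self.sirna_peak_len <= 0:
            raise ValueError("peak lengths must be positive")
        if not self.insertion_freq_spectrum:
            raise ValueError("insertion_freq_spectrum must be nonempty")
        for q in self.insertion_freq_spectrum:
            if not 0.0 < q <= 1.0:
                raise ValueError(f"spectrum frequency {q} not in (0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, stream]))


def make_te_references(cfg: SynthConfig) -> dict:
    """Random nucleotide references TE_1..TE_n with lengths uniform in
    ``te_length_range`` (FASTA-writable; deterministic under the seed)."""
    rng = cfg.rng(1)
    refs = {}
    lo, hi = cfg.te_length_range
    for k in range(cfg.n_families):
        length = int(rng.integers(lo, hi + 1))
        refs[f"TE_{k + 1}"] = "".join(
            NUCLEOTIDES[rng.integers(0, 4, size=length)])
    return refs


@dataclass(frozen=True)
class ReadPlan:
    """Planted per-family read counts for :func:`make_smallrna_reads`."""

    sense: int = 0
    antisense: int = 0
    pingpong_pairs: int = 0
    sirna: int = 0


def _pirna_length(cfg, rng) -> int:
    lens = np.arange(23, 30)
    w = np.exp(-0.5 * ((lens - cfg.pirna_peak_len) / 1.2) ** 2)
    return int(rng.choice(lens, p=w / w.sum()))


def _sirna_length(cfg, rng) -> int:
    lens = np.arange(20, 23)
    w = np.exp(-0.5 * ((lens - cfg.sirna_peak_len) / 0.8) ** 2)
    return int(rng.choice(lens, p=w / w.sum()))


def _draw_start(ref: str, length: int, strand: str, want_u: bool,
                rng, max_tries: int = 200) -> int:
    """Start position such that the read's 5' base is (or is not) U."""
    limit = len(ref) - length
    if limit < 0:
        raise ValueError("read longer than its reference")
    for _ in range(max_tries):
        start = int(rng.integers(0, limit + 1))
        base5 = ref[start] if strand == "+" else ref[start + length - 1]
        is_u = (base5 == "T") if strand == "+" else (base5 == "A")
        if is_u == want_u:
            return start
    return int(rng.integers(0, limit + 1))  # give up; keep it unbiased-ish


def _read_seq(ref: str, start: int, length: int, strand: str) -> str:
    frag = ref[start:start + length]
    return frag if strand == "+" else revcomp(frag)


def _find_hits(seq: str, refs: Mapping[str, str]):
    """All exact occurrences of a read (either orientation) across refs."""
    hits = []
    rc = revcomp(seq)
    for name, ref in refs.items():
        i = ref.find(seq)
        while i != -1:
            hits.append((name, i, "+"))
            i = ref.find(seq, i + 1)
        i = ref.find(rc)
        while i != -1:
            hits.append((name, i, "-"))
            i = ref.find(rc, i + 1)
    return hits


def make_smallrna_reads(cfg: SynthConfig, te_refs: Mapping[str, str],
                        planted: Mapping[str, ReadPlan]):
    """Small-RNA records over TE references with planted structure.

    Per family the plan gives counts of sense piRNAs, antisense piRNAs,
    ping-pong pairs (one sense + one antisense read whose 5' ends overlap
    by exactly 10 nt) and siRNAs.  The 5'-U fraction of unpaired piRNAs
    follows ``cfg.u1_bias`` exactly in expectation; reads are mapped back
    against all references so shared sequences become multimappers.

    Returns (records, truth) where truth holds the planted counts.
    """
    rng = cfg.rng(2)
    records = []
    truth_rows = []
    rid = 0
    for family, plan in planted.items():
        if family not in te_refs:
            raise KeyError(f"unknown family {family!r}")
        ref = te_refs[family]
        if min(plan.sense, plan.antisense, plan.pingpong_pairs,
               plan.sirna) < 0:
            raise ValueError("planted counts must be >= 0")
        for strand, count in (("+", plan.sense), ("-", plan.antisense)):
            for _ in range(count):
                length = _pirna_length(cfg, rng)
                want_u = bool(rng.random() < cfg.u1_bias)
                start = _draw_start(ref, length, strand, want_u, rng)
                seq = _read_seq(ref, start, length, strand)
                hits = _find_hits(seq, te_refs) or [(family, start, strand)]
                records.append(SmallRNARecord(f"r{rid}", seq, hits))
                rid += 1
        for _ in range(plan.pingpong_pairs):
            # sense 5' at s, antisense 5' at s+9: exactly 10 nt overlap
            l1 = _pirna_length(cfg, rng)
            l2 = _pirna_length(cfg, rng)
            if len(ref) < max(l1, l2) + 10:
                raise ValueError("reference too short for a ping-pong pair")
            lo = max(0, l2 - 10)
            hi = len(ref) - max(l1, 10)
            s = int(rng.integers(lo, hi + 1))
            seq_s = _read_seq(ref, s, l1, "+")
            a_start = s + 9 - (l2 - 1)
            seq_a = _read_seq(ref, a_start, l2, "-")
            for seq, start, strand in ((seq_s, s, "+"),
                                       (seq_a, a_start, "-")):
                hits = _find_hits(seq, te_refs) or [(family, start, strand)]
                records.append(SmallRNARecord(f"r{rid}", seq, hits))
                rid += 1
        for _ in range(plan.sirna):
            length = _sirna_length(cfg, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, len(ref) - length + 1))
            seq = _read_seq(ref, start, length, strand)
            hits = _find_hits(seq, te_refs) or [(family, start, strand)]
            records.append(SmallRNARecord(f"r{rid}", seq, hits))
            rid += 1
        truth_rows.append(dict(
            family=family, sense=plan.sense, antisense=plan.antisense,
            pingpong_pairs=plan.pingpong_pairs, sirna=plan.sirna))
    truth = pd.DataFrame(truth_rows)
    return records, truth


def make_flank_reads(cfg: SynthConfig, contig: str, contig_length: int,
                     insertion_pos: int, n_reads: int,
                     asymmetry: float | None = None, flank: int = 2000,
                     stream: int = 5):
    """Uniquely mapped piRNA-like reads in the 2-kb flanks of a novel
    insertion with the de novo strand signature: a fraction ``asymmetry``
    of reads are antisense in the upstream flank or sense in the
    downstream flank (the signature strands); the rest are flipped."""
    rng = cfg.rng(stream)
    if asymmetry is None:
        asymmetry = cfg.flank_asymmetry
    records = []
    for k in range(n_reads):
        length = _pirna_length(cfg, rng)
        upstream = bool(rng.random() < 0.5)
        on_signature = bool(rng.random() < asymmetry)
        if upstream:
            lo = max(0, insertion_pos - flank)
            hi = insertion_pos - length
            strand = "-" if on_signature else "+"
        else:
            lo = insertion_pos
            hi = min(contig_length, insertion_pos + flank) - length
            strand = "+" if on_signature else "-"
        start = int(rng.integers(lo, max(lo + 1, hi)))
        seq = "".join(NUCLEOTIDES[rng.integers(0, 4, size=length)])
        records.append(SmallRNARecord(
            f"fl{insertion_pos}_{k}", seq, [(contig, start, strand)]))
    return records


def make_insertion_panel(cfg: SynthConfig, insertions_per_family: int = 6,
                         chrom: str = "2L", chrom_length: int = 23_000_000):
    """Novel-insertion panel: TEMP-like raw calls plus the truth matrix.

    Each insertion's population frequency is taken from
    ``insertion_freq_spectrum`` (cycled deterministically); carriers are
    drawn without replacement so the realized occupancy is exactly
    round(freq * n_strains) (at least 1).  Raw calls carry both-flank
    support and frequency > 0.8, i.e. they survive the novel-insertion
    filters unchanged.
    """
    rng = cfg.rng(3)
    strains = [f"S{k + 1}" for k in range(cfg.n_strains)]
    spectrum = list(cfg.insertion_freq_spectrum)
    truth = {}
    raw_rows = []
    idx = 0
    for fam in range(cfg.n_families):
        family = f"TE_{fam + 1}"
        for _ in range(insertions_per_family):
            freq = spectrum[idx % len(spectrum)]
            idx += 1
            n_carriers = max(1, int(round(freq * cfg.n_strains)))
            carriers = sorted(rng.choice(cfg.n_strains, size=n_carriers,
                                         replace=False))
            pos = int(rng.integers(1000, chrom_length - 1000))
            name = f"ins_{idx}"
            truth[name] = [k in carriers for k in range(cfg.n_strains)]
            for k in carriers:
                left = int(rng.integers(3, 15))
                right = int(rng.integers(3, 15))
                raw_rows.append(dict(
                    strain=strains[k], chrom=chrom, start=pos,
                    end=pos + int(rng.integers(1, 8)), family=family,
                    left_support=left, right_support=right,
                    frequency=float(rng.uniform(0.85, 1.0))))
    raw = pd.DataFrame(raw_rows)
    truth_matrix = pd.DataFrame.from_dict(
        truth, orient="index", columns=strains)
    return raw, truth_matrix


def make_coverage_tracks(te_copy_truth: Mapping[str, float],
                         depth_mean: float, gene_count: int, seed: int,
                         noise: float = 0.05,
                         te_lengths: Mapping[str, int] | None = None,
                         gene_length: int = 2000):
    """Coverage tracks for TEs with known copy number plus single-copy
    gene tracks.

    TE depth per position is copy * depth_mean (exactly, when noise=0)
    with multiplicative Gaussian noise of relative sd ``noise``; gene
    tracks are built the same way around depth_mean.  Returns
    (te_tracks, gene_tracks).
    """
    from .tequant import CoverageTrack

    if gene_count < 1:
        raise ValueError("gene_count must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    te_tracks = {}
    for name, copy in te_copy_truth.items():
        if copy < 0:
            raise ValueError("copy numbers must be >= 0")
        length = (te_lengths or {}).get(name, 3000)
        base = copy * depth_mean
        depth = np.full(length, base, dtype=float)
        if noise > 0 and base > 0:
            depth *= np.clip(rng.normal(1.0, noise, size=length), 0.0, None)
        te_tracks[name] = CoverageTrack(name, depth)
    gene_tracks = []
    for g in range(gene_count):
        depth = np.full(gene_length, float(depth_mean))
        if noise > 0:
            depth *= np.clip(rng.normal(1.0, noise, size=gene_length),
                             0.0, None)
        gene_tracks.append(CoverageTrack(f"gene_{g + 1}", depth))
    return te_tracks, gene_tracks
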