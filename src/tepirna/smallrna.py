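"""piRNA quantification: read classification, weighted multimapper
assignment, 1U fractions, ping-pong signature, RPKM on TE references,
piRNA target prediction and de novo piRNA-signature calling.

Conventions: piRNA-like reads are 23-29 nt, siRNA-like 20-22 nt.  A read
mapped to several locations is equally split across them (each hit carries
weight 1/|hits|).  Coordinates are 0-based half-open; strand is "+"/"-".
The 5' end of a "+" hit is its start; for a "-" hit it is start+len-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PIRNA_RANGE = (23, 29)
SIRNA_RANGE = (20, 22)

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SmallRNARecord:
    """One mapped small RNA; ``hits`` is a list of (ref, start0, strand)."""

    read_id: str
    sequence: str
    hits: list = field(default_factory=list)

    def __post_init__(self):
        if not self.hits:
            raise ValueError(f"{self.read_id}: a record needs >= 1 hit")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def weight_per_hit(self) -> float:
        return 1.0 / len(self.hits)


@dataclass(frozen=True)
class NormalizationTotals:
    """Library-size totals: 23-29 nt reads mapped to genome+TEs and
    20-22 nt reads mapped to TEs, both used in the RPKM denominator."""

    pirna_reads: float
    sirna_te_reads: float = 0.0

    @property
    def combined(self) -> float:
        return self.pirna_reads + self.sirna_te_reads


@dataclass
class PiRNAProfile:
    """Per-position weighted 5'-end depth on one reference, by strand."""

    reference: str
    length: int
    sense5: np.ndarray
    antisense5: np.ndarray

    @property
    def total(self) -> float:
        return float(self.sense5.sum() + self.antisense5.sum())


def build_profiles(records: Iterable[SmallRNARecord],
                   ref_lengths: Mapping[str, int]) -> dict:
    """Weighted 5'-end profiles per reference from split-weight hits."""
    profiles = {
        name: PiRNAProfile(name, ln, np.zeros(ln), np.zeros(ln))
        for name, ln in ref_lengths.items()
    }
    for rec in records:
        wt = rec.weight_per_hit
        for ref, start, strand in rec.hits:
            if ref not in profiles:
                continue
            prof = profiles[ref]
            if strand == "+":
                five = start
                arr = prof.sense5
            else:
                five = start + rec.length - 1
                arr = prof.antisense5
            if 0 <= five < prof.length:
                arr[five] += wt
    return profiles


def classify_reads(records: Iterable[SmallRNARecord],
                   annotations: Mapping[str, Iterable[tuple]] | None = None):
    """Bin reads into piRNA-like (23-29 nt), siRNA-like (20-22 nt) and
    "other"; any read with a hit overlapping an excluded-class annotation
    interval (rRNA/tRNA/miscRNA/ncRNA/miRNA) goes to "excluded".

    ``annotations`` maps reference name -> iterable of (start0, end0)
    half-open intervals.
    """
    trees: dict[str, IntervalTree] = {}
    if annotations is not None:
        for ref, ivals in annotations.items():
            tree = IntervalTree()
            for start, end in ivals:
                if end > start:
                    tree.addi(start, end)
            trees[ref] = tree
    out = {"piRNA": [], "siRNA": [], "excluded": [], "other": []}
    for rec in records:
        excluded = False
        for ref, start, strand in rec.hits:
            tree = trees.get(ref)
            if tree is not None and tree.overlap(start, start + rec.length):
                excluded = True
                break
        if excluded:
            out["excluded"].append(rec)
        elif PIRNA_RANGE[0] <= rec.length <= PIRNA_RANGE[1]:
            out["piRNA"].append(rec)
        elif SIRNA_RANGE[0] <= rec.length <= SIRNA_RANGE[1]:
            out["siRNA"].append(rec)
        else:
            out["other"].append(rec)
    return out


def first_nt_fractions(reads: Sequence[SmallRNARecord]) -> dict:
    """Fractions of A/C/G/U at the 5'-most read position (per read, not
    per hit; T in input sequences is reported as U)."""
    if not reads:
        raise ValueError("first_nt_fractions: empty read set")
    counts = {"A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0}
    n = 0
    for rec in reads:
        nt = rec.sequence[0].upper().replace("T", "U")
        if nt in counts:
            counts[nt] += 1
            n += 1
    if n == 0:
        raise ValueError("first_nt_fractions: no A/C/G/U starting reads")
    return {k: v / n for k, v in counts.items()}


@dataclass
class PingPongResult:
    overlaps: np.ndarray       # overlap lengths 1..max_overlap
    counts: np.ndarray         # weighted pair counts per overlap
    zscores: np.ndarray        # Z per overlap vs the other overlaps
    z10: float                 # the diagnostic 10-nt value (NaN if undefined)
    defined: bool              # False when the background sd is zero


def pingpong_zscore(records: Iterable[SmallRNARecord],
                    ref_lengths: Mapping[str, int],
                    max_overlap: int = 23) -> PingPongResult:
    """Ping-pong signature: weighted counts of sense/antisense read pairs
    whose 5' ends overlap by exactly o nt (o = 1..max_overlap), and the
    Z-score of each overlap against the remaining overlap lengths.

    A sense 5' end at position s and an antisense 5' end at position
    s + o - 1 overlap by o nt.  Z(o) uses the mean/sd over the other
    overlap lengths; when that sd is zero the result is flagged undefined.
    """
    profiles = build_profiles(records, ref_lengths)
    counts = np.zeros(max_overlap)
    for prof in profiles.values():
        s5, a5 = prof.sense5, prof.antisense5
        L = prof.length
        for o in range(1, max_overlap + 1):
            # antisense 5' at s + o - 1
            shift = o - 1
            if shift < L:
                counts[o - 1] += float(np.dot(s5[:L - shift], a5[shift:]))
    z = np.full(max_overlap, np.nan)
    for o in range(max_overlap):
        others = np.delete(counts, o)
        sd = others.std(ddof=1)
        if sd > 0:
            z[o] = (counts[o] - others.mean()) / sd
    overlaps = np.arange(1, max_overlap + 1)
    idx10 = 9 if max_overlap >= 10 else None
    defined = idx10 is not None and np.isfinite(z[idx10])
    z10 = float(z[idx10]) if defined else float("nan")
    return PingPongResult(overlaps, counts, z, z10, defined)


def pirna_rpkm(weighted_count: float, te_length: int,
               totals: NormalizationTotals) -> float:
    """RPKM = weighted piRNAs / TE length * 1e9 / (23-29 nt reads mapped to
    genome+TEs + 20-22 nt reads mapped to TEs)."""
    if te_length <= 0:
        raise ValueError("te_length must be positive")
    if totals.combined <= 0:
        raise ValueError("normalization totals must be positive")
    return weighted_count / te_length * 1e9 / totals.combined


def profile_rpkm(profile: PiRNAProfile, totals: NormalizationTotals,
                 strand: str = "both") -> float:
    if strand == "sense":
        count = float(profile.sense5.sum())
    elif strand == "antisense":
        count = float(profile.antisense5.sum())
    else:
        count = profile.total
    return pirna_rpkm(count, profile.length, totals)


def predict_targets(pirna_reads: Iterable[SmallRNARecord],
                    te_refs: Mapping[str, str],
                    warn=None) -> pd.Series:
    """Weighted antisense piRNA abundance per TE by seed matching.

    A piRNA targets a TE wherever the reverse complement of its positions
    2-11 (1-based from the 5' end) occurs as an exact substring of the TE
    sense strand.  Each read's unit weight is split equally over all its
    target sites across all TEs; per-TE sums are returned.
    """
    weights = {name: 0.0 for name in te_refs}
    refs = {name: seq.upper().replace("U", "T") for name, seq in
            te_refs.items()}
    for rec in pirna_reads:
        seq = rec.sequence.upper().replace("U", "T")
        if len(seq) < 11:
            if warn is not None:
                warn(f"{rec.read_id}: shorter than 11 nt, skipped")
            continue
        probe = revcomp(seq[1:11])  # positions 2-11, 1-based
        sites = []  # (te, count at te)
        for name, ref in refs.items():
            cnt = 0
            i = ref.find(probe)
            while i != -1:
                cnt += 1
                i = ref.find(probe, i + 1)  # overlapping occurrences count
            if cnt:
                sites.append((name, cnt))
        total_sites = sum(c for _, c in sites)
        if total_sites == 0:
            continue
        for name, cnt in sites:
            weights[name] += cnt / total_sites
    return pd.Series(weights, name="antisense_pirna_weight")


@dataclass
class DeNovoCall:
    positive: bool
    rpkm: float
    asymmetry: float           # NaN when no flank reads at all
    n_reads: float             # weighted read count over both flanks


def denovo_signature(insertion_pos: int,
                     flank_reads: Iterable[SmallRNARecord],
                     contig: str,
                     contig_length: int,
                     totals: NormalizationTotals,
                     flank: int = 2000,
                     min_rpkm: float = 0.5,
                     min_asymmetry: float = 0.70,
                     unique_only: bool = True) -> DeNovoCall:
    """De novo piRNA production signature at a novel TE insertion.

    Positive iff, over the two ``flank``-bp regions (clipped at contig
    ends) around ``insertion_pos``: (1) the piRNA abundance is at least
    ``min_rpkm`` RPKM, and (2) antisense piRNAs upstream plus sense piRNAs
    downstream make up at least ``min_asymmetry`` of all flank piRNAs.
    Only uniquely mapped 23-29 nt reads count unless ``unique_only`` is
    off.  Zero flank reads yield a negative call, not an error.
    """
    up_lo = max(0, insertion_pos - flank)
    up_hi = insertion_pos
    dn_lo = insertion_pos
    dn_hi = min(contig_length, insertion_pos + flank)
    region_len = (up_hi - up_lo) + (dn_hi - dn_lo)
    signature = 0.0
    total = 0.0
    for rec in flank_reads:
        if not PIRNA_RANGE[0] <= rec.length <= PIRNA_RANGE[1]:
            continue
        if unique_only and len(rec.hits) > 1:
            continue
        wt = rec.weight_per_hit
        for ref, start, strand in rec.hits:
            if ref != contig:
                continue
            five = start if strand == "+" else start + rec.length - 1
            if up_lo <= five < up_hi:
                total += wt
                if strand == "-":
                    signature += wt
            elif dn_lo <= five < dn_hi:
                total += wt
                if strand == "+":
                    signature += wt
    if region_len <= 0 or totals.combined <= 0:
        return DeNovoCall(False, 0.0, float("nan"), total)
    rpkm = total / region_len * 1e9 / totals.combined
    asym = signature / total if total > 0 else float("nan")
    positive = (total > 0 and rpkm >= min_rpkm and asym >= min_asymmetry)
    return DeNovoCall(bool(positive), rpkm, asym, total)
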