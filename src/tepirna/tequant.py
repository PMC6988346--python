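"""TE insertion genotyping and copy-number estimation.

Covers: presence calling of reference-annotated ("known") insertions from
flank-spanning paired-end alignments, filtering and merging of novel
insertion calls from a TEMP-like table, insertion frequency spectra, and
coverage-based TE copy number normalised by single-copy genes (with the
P-element's active part, positions 819-2527, handled as its own
reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: minimum read span into the flank (bp) for known-insertion support
MIN_FLANK_SPAN = 30
#: maximum mismatches+indels per 100 bp of mapped sequence
MAX_MISMATCHES = 4
#: calls closer than this (bp) are merged
MERGE_DISTANCE = 100
#: spanning-read frequency must strictly exceed this in >= 1 strain
MIN_FREQUENCY = 0.80


@dataclass(frozen=True)
class FlankAlignment:
    read_id: str
    proper_pair: bool
    span: int              # bp spanning into the flank of the boundary
    mismatches: int        # mismatches + indels per 100 bp


@dataclass(frozen=True)
class InsertionCall:
    strain: str
    chrom: str
    start: int             # 0-based half-open
    end: int
    family: str
    left_support: int
    right_support: int
    frequency: float
    source: str = "novel"  # or "reference-annotated"


def alignment_supports(aln: FlankAlignment) -> bool:
    """Proper pair, span >= 30 bp, and <= 4 mismatches/indels per 100 bp."""
    return (aln.proper_pair and aln.span >= MIN_FLANK_SPAN
            and aln.mismatches <= MAX_MISMATCHES)


def call_known_presence(alignments: Mapping[tuple, Sequence[FlankAlignment]],
                        absence_calls: Iterable[tuple] = ()) -> pd.DataFrame:
    """Present/absent per (strain, insertion).

    ``alignments`` maps (strain, insertion_id) -> flank alignments at the
    insertion's boundaries; an insertion is present in a strain iff at
    least one alignment passes all support filters and the pair is not
    listed in ``absence_calls`` (e.g. TEMP "Absence" results).
    """
    absent = set(absence_calls)
    rows = []
    for (strain, ins), alns in alignments.items():
        ok = (strain, ins) not in absent and any(
            alignment_supports(a) for a in alns)
        rows.append((strain, ins, bool(ok)))
    return pd.DataFrame(rows, columns=["strain", "insertion", "present"])


def _merge_clusters(intervals: Sequence[tuple]) -> list:
    """Transitively merge sorted (start, end, idx) triples whose gap is
    < MERGE_DISTANCE; returns lists of member indices."""
    clusters = []
    cur: list[int] = []
    cur_end = None
    for start, end, idx in intervals:
        if cur and start - cur_end < MERGE_DISTANCE:
            cur.append(idx)
            cur_end = max(cur_end, end)
        else:
            if cur:
                clusters.append(cur)
            cur = [idx]
            cur_end = end
    if cur:
        clusters.append(cur)
    return clusters


def filter_novel_insertions(raw: pd.DataFrame) -> pd.DataFrame:
    """Merge and filter TEMP-like novel insertion calls.

    Same-family calls on one chromosome whose intervals are closer than
    100 bp are merged transitively into one spanning interval per strain
    (flank supports summed, frequency recomputed as a support-weighted
    mean).  A merged site is retained iff in at least one strain it has
    supporting reads on both flanks and a spanning-read frequency
    strictly above 0.80; the returned table keeps one row per retained
    site x strain, plus a ``site`` identifier.

    Expected columns: strain, chrom, start, end, family, left_support,
    right_support, frequency.
    """
    required = {"strain", "chrom", "start", "end", "family",
                "left_support", "right_support", "frequency"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out_rows = []
    site_id = 0
    for (chrom, family), grp in raw.groupby(["chrom", "family"], sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        triples = [(int(r.start), int(r.end), i)
                   for i, r in grp.iterrows()]
        for members in _merge_clusters(triples):
            sub = grp.iloc[members]
            lo, hi = int(sub["start"].min()), int(sub["end"].max())
            per_strain = []
            for strain, ss in sub.groupby("strain"):
                left = int(ss["left_support"].sum())
                right = int(ss["right_support"].sum())
                support = (ss["left_support"] + ss["right_support"])
                wsum = float(support.sum())
                freq = (float((ss["frequency"] * support).sum() / wsum)
                        if wsum > 0 else float(ss["frequency"].mean()))
                per_strain.append((strain, left, right, freq))
            keep = any(left > 0 and right > 0 and freq > MIN_FREQUENCY
                       for _, left, right, freq in per_strain)
            if not keep:
                continue
            for strain, left, right, freq in per_strain:
                out_rows.append(dict(
                    site=site_id, strain=strain, chrom=chrom, start=lo,
                    end=hi, family=family, left_support=left,
                    right_support=right, frequency=freq))
            site_id += 1
    cols = ["site", "strain", "chrom", "start", "end", "family",
            "left_support", "right_support", "frequency"]
    return pd.DataFrame(out_rows, columns=cols)


def frequency_spectrum(presence: pd.DataFrame) -> pd.DataFrame:
    """Occupancy histogram of a boolean insertions x strains matrix.

    Returns one row per occupancy 1..n_strains with counts, percentages
    (summing to 100 over non-empty insertions) and the three-class label
    used for reporting ("1", "2-5", ">5").
    """
    n_strains = presence.shape[1]
    occupancy = presence.sum(axis=1).astype(int)
    occupancy = occupancy[occupancy > 0]
    counts = occupancy.value_counts().reindex(
        range(1, n_strains + 1), fill_value=0)
    total = counts.sum()
    pct = 100.0 * counts / total if total else counts.astype(float)
    labels = ["1" if k == 1 else "2-5" if k <= 5 else ">5"
              for k in counts.index]
    return pd.DataFrame({
        "occupancy": counts.index, "count": counts.values,
        "percent": pct.values, "class": labels,
    }).reset_index(drop=True)


def spectrum_classes(presence: pd.DataFrame) -> pd.Series:
    """Counts of insertions in the 1 / 2-5 / >5 occupancy classes."""
    spec = frequency_spectrum(presence)
    return spec.groupby("class")["count"].sum().reindex(
        ["1", "2-5", ">5"], fill_value=0)


@dataclass
class CoverageTrack:
    """Per-position sequencing depth over one named reference."""

    reference: str
    depth: np.ndarray

    def covered_median(self) -> float:
        """Median depth over covered sites (depth > 0); 0 if none."""
        covered = self.depth[self.depth > 0]
        if covered.size == 0:
            return 0.0
        return float(np.median(covered))


def gene_median(gene_tracks: Sequence[CoverageTrack],
                pooled: bool = False) -> float:
    """Normalising depth from single-copy genes: by default the median of
    per-gene medians (robust to one aberrant gene); ``pooled=True`` takes
    one median over all covered positions of all genes instead."""
    if not gene_tracks:
        raise ValueError("need at least one single-copy gene track")
    if pooled:
        allpos = np.concatenate([t.depth[t.depth > 0] for t in gene_tracks])
        med = float(np.median(allpos)) if allpos.size else 0.0
    else:
        meds = [t.covered_median() for t in gene_tracks]
        med = float(np.median(meds))
    if med <= 0:
        raise ValueError("single-copy gene median depth is zero")
    return med


def te_copy_number(te_track: CoverageTrack,
                   gene_tracks: Sequence[CoverageTrack],
                   pooled_genes: bool = False) -> float:
    """Copy number = median TE depth over covered sites / single-copy-gene
    median depth."""
    return te_track.covered_median() / gene_median(gene_tracks,
                                                   pooled=pooled_genes)


#: 1-based inclusive coordinates of the P-element's active part
PELEMENT_ACTIVE = (819, 2527)


def pelement_active_copy(pelement_track: CoverageTrack,
                         gene_tracks: Sequence[CoverageTrack],
                         pooled_genes: bool = False) -> float:
    """Copy number of the P-element's active part (1-based 819-2527),
    treated as a standalone reference."""
    lo, hi = PELEMENT_ACTIVE
    if pelement_track.depth.size < hi:
        raise ValueError(
            f"P-element reference shorter than {hi} bp "
            f"({pelement_track.depth.size})")
    active = CoverageTrack(f"{pelement_track.reference}:active",
                           pelement_track.depth[lo - 1:hi])
    return te_copy_number(active, gene_tracks, pooled_genes=pooled_genes)
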