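"""On-disk formats: FASTA references (via Biopython), tab-separated tables
for mapped small-RNA records, insertion calls and coverage tracks, and
truth sidecars.  All tables are TSV with a header row, UTF-8, LF,
0-based positions."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .smallrna import SmallRNARecord
from .tequant import CoverageTrack


def write_fasta(refs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in refs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_tsv(records: Iterable[SmallRNARecord], path) -> None:
    """One row per hit: read_id, seq, ref, start0, strand."""
    rows = []
    for rec in records:
        for ref, start, strand in rec.hits:
            rows.append((rec.read_id, rec.sequence, ref, start, strand))
    pd.DataFrame(rows, columns=["read_id", "seq", "ref", "start0",
                                "strand"]).to_csv(path, sep="\t",
                                                  index=False)


def read_reads_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    records = []
    for read_id, grp in df.groupby("read_id", sort=False):
        hits = [(r.ref, int(r.start0), r.strand)
                for r in grp.itertuples()]
        records.append(SmallRNARecord(str(read_id),
                                      str(grp["seq"].iloc[0]), hits))
    return records


def write_coverage_tsv(tracks: Iterable[CoverageTrack], path) -> None:
    """Columns: ref, pos0, depth (covered positions only)."""
    frames = []
    for t in tracks:
        pos = np.flatnonzero(t.depth > 0)
        frames.append(pd.DataFrame({
            "ref": t.reference, "pos0": pos, "depth": t.depth[pos]}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path, lengths: Mapping[str, int] | None = None):
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for ref, grp in df.groupby("ref"):
        length = (lengths or {}).get(ref, int(grp["pos0"].max()) + 1)
        depth = np.zeros(length)
        depth[grp["pos0"].to_numpy()] = grp["depth"].to_numpy()
        tracks[ref] = CoverageTrack(str(ref), depth)
    return tracks


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
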