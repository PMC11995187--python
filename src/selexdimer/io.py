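"""File formats: MEME minimal and JASPAR motifs, FASTA/FASTQ, BED, bedGraph.

All genomic records use 0-based half-open coordinates.  Read input is
gzip-transparent.  Motif dimer annotations round-trip through a comment line
in the MEME file ("# dimer: orientation=ER spacing=1 halfsite_len=7").
"""

from __future__ import annotations

import gzip
import io as _io
import re
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import Motif


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequences(path) -> list[str]:
    """Read FASTA or FASTQ (by extension), returning uppercase sequences."""
    fmt = "fastq" if re.search(r"\.(fastq|fq)(\.gz)?$", str(path)) else "fasta"
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def read_fasta_dict(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered name -> sequence dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, seqs: "dict[str, str] | Iterable[str]", width: int = 80) -> None:
    if not isinstance(seqs, dict):
        seqs = {f"seq{i}": s for i, s in enumerate(seqs)}
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path, seqs: Iterable[str], quality_char: str = "I") -> None:
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@read{i}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def write_meme(path, motifs: Iterable[Motif], background=None) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with _open_text(path, "wt") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            if m.dimer is not None:
                d = m.dimer
                fh.write(
                    f"# dimer: orientation={d.orientation} spacing={d.spacing} "
                    f"halfsite_len={d.halfsite_len}\n"
                )
            nsites = int(m.counts.sum(axis=1).max()) if m.counts is not None else 20
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in m.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[Motif]:
    """Read a MEME minimal file (our dimer comment line is honoured)."""
    from .dimers import DimerConfig  # deferred import avoids a cycle

    motifs: list[Motif] = []
    name = None
    dimer = None
    rows: list[list[float]] = []
    expect = 0

    def flush():
        nonlocal name, dimer, rows, expect
        if name is not None and rows:
            mat = np.asarray(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs.append(Motif(name=name, matrix=mat, source="file", dimer=dimer))
        name, dimer, rows, expect = None, None, [], 0

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1] if len(line.split()) > 1 else "motif"
            elif line.startswith("# dimer:"):
                kv = dict(tok.split("=") for tok in line.split()[2:])
                dimer = DimerConfig(
                    orientation=kv["orientation"],
                    spacing=int(kv["spacing"]),
                    halfsite_len=int(kv["halfsite_len"]),
                )
            elif line.startswith("letter-probability matrix"):
                mm = re.search(r"w=\s*(\d+)", line)
                expect = int(mm.group(1)) if mm else -1
            elif expect and name is not None:
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                    if expect > 0 and len(rows) == expect:
                        expect = 0
    flush()
    return motifs


def read_jaspar_pfm(path) -> list[Motif]:
    """Read JASPAR-style integer PFMs (``>id name`` then four base rows)."""
    motifs = []
    with _open_text(path) as fh:
        text = fh.read()
    blocks = re.split(r"^>", text, flags=re.M)
    for block in blocks:
        if not block.strip():
            continue
        lines = block.strip().splitlines()
        name = lines[0].split()[0]
        counts = {}
        for line in lines[1:]:
            mm = re.match(r"\s*([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$", line)
            if mm:
                counts[mm.group(1)] = [float(x) for x in mm.group(2).split()]
        if set(counts) != set("ACGT"):
            raise ValueError(f"PFM block {name!r} lacks all four base rows")
        c = np.column_stack([counts[b] for b in "ACGT"])
        mat = (c + 1e-9) / (c + 1e-9).sum(axis=1, keepdims=True)
        motifs.append(Motif(name=name, matrix=mat, source="file"))
    return motifs


# ---------------------------------------------------------------------------
# intervals and tracks
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED (3-6 columns) into chrom/start/end[/name/score/strand]."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base arrays (NaN where uncovered)."""
    track = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    for row in df.itertuples(index=False):
        if row.chrom in track:
            track[row.chrom][int(row.start):int(row.end)] = float(row.value)
    return track


def write_bedgraph(path, track: dict[str, np.ndarray]) -> None:
    """Write per-base arrays as run-length-merged bedGraph lines."""
    with _open_text(path, "wt") as fh:
        for chrom, vals in track.items():
            v = np.asarray(vals, dtype=float)
            if len(v) == 0:
                continue
            change = np.nonzero(np.diff(v) != 0)[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                if not np.isnan(v[s]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")
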