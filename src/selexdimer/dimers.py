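"""Homodimeric binding-mode analysis: orientation x spacing enumeration,
configuration enrichment scans, dimer naming, half-site specificity change,
cooperativity, and DNA-shape profiles.

Orientation conventions (fixed for this package, with h the half-site in
monomer orientation and rc its reverse complement):

* ``DR`` (direct repeat):   h  + N^s + h
* ``IR`` (inverted repeat): h  + N^s + rc(h)   (head-to-head)
* ``ER`` (everted repeat):  rc(h) + N^s + h    (tail-to-tail)

Negative spacing means the two half-sites overlap; overlapping IUPAC symbols
are intersected and an empty intersection marks the configuration infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import iupac_intersect, revcomp
from .motifs import Motif, reverse_complement
from .selex import pattern_enrichment

ORIENTATIONS = ("DR", "IR", "ER")


class InfeasibleOverlapError(ValueError):
    """Overlapping half-sites with an empty IUPAC intersection."""

    def __init__(self, position: int):
        self.position = position
        super().__init__(f"incompatible overlap at merged position {position}")


@dataclass(frozen=True)
class DimerConfig:
    """A dimeric binding mode: orientation plus integer spacing."""

    orientation: str
    spacing: int
    halfsite_len: int
    rank_letter: str = ""

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.spacing < -(self.halfsite_len - 1):
            raise ValueError("overlap cannot exceed halfsite_len - 1")

    @property
    def full_length(self) -> int:
        return 2 * self.halfsite_len + self.spacing

    @property
    def name(self) -> str:
        return f"{self.orientation}{self.spacing}{self.rank_letter}"


@dataclass(frozen=True)
class DimerAnnotation:
    """DimerConfig plus half-site boundaries inside a dimeric motif matrix."""

    config: DimerConfig
    left: tuple[int, int]
    right: tuple[int, int]

    @property
    def orientation(self) -> str:
        return self.config.orientation

    @property
    def spacing(self) -> int:
        return self.config.spacing

    @property
    def halfsite_len(self) -> int:
        return self.config.halfsite_len


# ---------------------------------------------------------------------------
# pattern construction
# ---------------------------------------------------------------------------

def _merge_overlap(left: str, right: str, overlap: int) -> str:
    head, a = left[:-overlap], left[-overlap:]
    b, tail = right[:overlap], right[overlap:]
    merged = []
    for i, (x, y) in enumerate(zip(a, b)):
        sym = iupac_intersect(x, y)
        if sym is None:
            raise InfeasibleOverlapError(len(head) + i)
        merged.append(sym)
    return head + "".join(merged) + tail


def build_dimer_pattern(
    half: str, config: DimerConfig, half2: str | None = None
) -> str:
    """IUPAC pattern of a dimeric site from half-site(s) and a configuration.

    ``half2`` (defaulting to ``half``) is the second monomer element, given in
    monomer orientation; it forms the right element for DR/ER and is
    reverse-complemented for IR.
    """
    h1 = half.upper()
    h2 = (half2 or half).upper()
    if config.halfsite_len != len(h1) or len(h1) != len(h2):
        raise ValueError("halfsite_len must equal the half-site pattern length")
    o, s = config.orientation, config.spacing
    if o == "DR":
        left, right = h1, h2
    elif o == "IR":
        left, right = h1, revcomp(h2)
    else:  # ER
        left, right = revcomp(h1), h2
    if s >= 0:
        return left + "N" * s + right
    return _merge_overlap(left, right, -s)


# ---------------------------------------------------------------------------
# configuration enrichment scan
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentMatrix:
    """Fold enrichments of dimeric patterns on an orientation x spacing grid.

    ``folds`` has orientation rows and spacing columns; infeasible
    configurations are NaN ("missing", distinct from a fold of zero).
    """

    folds: pd.DataFrame
    f_signal: pd.DataFrame
    f_background: pd.DataFrame
    half: str
    half2: str | None = None

    def argmax(self) -> tuple[str, int]:
        """(orientation, spacing) of the largest feasible fold."""
        stacked = self.folds.stack()
        if stacked.empty:
            raise ValueError("no feasible configuration in the scan grid")
        o, s = stacked.idxmax()
        return str(o), int(s)

    def top(self, n: int) -> list[tuple[str, int, float]]:
        stacked = self.folds.stack().sort_values(ascending=False)
        return [(str(o), int(s), float(v)) for (o, s), v in stacked.head(n).items()]

    def to_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready table (orientation, spacing, fold, feasible)."""
        rows = []
        for o in self.folds.index:
            for s in self.folds.columns:
                v = self.folds.loc[o, s]
                rows.append(
                    {"orientation": o, "spacing": int(s), "fold": v,
                     "feasible": bool(np.isfinite(v))}
                )
        return pd.DataFrame(rows)


def configuration_scan(
    half: str,
    signal_reads: list[str],
    background_reads: list[str],
    spacings: Sequence[int] = tuple(range(-2, 17)),
    orientations: Sequence[str] = ORIENTATIONS,
    half2: str | None = None,
) -> EnrichmentMatrix:
    """Fold enrichment of every (orientation, spacing) dimeric pattern.

    Each cell is the read-fraction fold enrichment (both-strand exact IUPAC
    matching) of the pattern built by :func:`build_dimer_pattern`; infeasible
    overlaps are recorded as NaN rather than zero.
    """
    folds = pd.DataFrame(np.nan, index=list(orientations), columns=list(spacings))
    fs = folds.copy()
    fb = folds.copy()
    hlen = len(half)
    for o in orientations:
        for s in spacings:
            try:
                cfg = DimerConfig(orientation=o, spacing=int(s), halfsite_len=hlen)
                pattern = build_dimer_pattern(half, cfg, half2)
            except (InfeasibleOverlapError, ValueError):
                continue
            r = pattern_enrichment(pattern, signal_reads, background_reads)
            folds.loc[o, s] = r["fold"]
            fs.loc[o, s] = r["f_signal"]
            fb.loc[o, s] = r["f_background"]
    return EnrichmentMatrix(folds=folds, f_signal=fs, f_background=fb,
                            half=half, half2=half2)


# ---------------------------------------------------------------------------
# configuration inference from a dimeric matrix
# ---------------------------------------------------------------------------

def _placement_corr(dimer: np.ndarray, mono: np.ndarray, offset: int) -> float:
    from .motifs import _column_pearson

    m = len(mono)
    rs = [_column_pearson(dimer[offset + j], mono[j]) for j in range(m)]
    return float(np.mean(rs))


def infer_dimer_config(
    dimer_motif: Motif, monomer_motif: Motif, min_corr: float = 0.3
) -> DimerAnnotation:
    """Locate two monomer placements inside a dimeric matrix.

    The monomer matrix and its reverse complement are slid over the dimer
    matrix; the best two distinct placements (by mean column correlation)
    define the orientation (from their strand pattern) and the spacing (gap
    between them, negative when overlapping).  Ties break leftmost, then "+".
    """
    D, m = dimer_motif.length, monomer_motif.length
    if D < m:
        raise ValueError("dimer motif shorter than the monomer motif")
    mono_f = monomer_motif.matrix
    mono_r = reverse_complement(monomer_motif).matrix
    placements = []
    for off in range(D - m + 1):
        for strand, mono in (("+", mono_f), ("-", mono_r)):
            placements.append((off, strand, _placement_corr(dimer_motif.matrix, mono, off)))
    placements.sort(key=lambda p: (-p[2], p[0], p[1] != "+"))
    best = placements[0]
    if best[2] < min_corr:
        raise ValueError("no half-site found (best placement correlation %.2f)" % best[2])
    second = next((p for p in placements[1:] if p[0] != best[0]), None)
    if second is None or second[2] < min_corr:
        raise ValueError("no second half-site found")
    left, right = sorted([best, second], key=lambda p: p[0])
    strands = (left[1], right[1])
    if strands in (("+", "+"), ("-", "-")):
        orientation = "DR"
    elif strands == ("+", "-"):
        orientation = "IR"
    else:
        orientation = "ER"
    spacing = right[0] - (left[0] + m)
    cfg = DimerConfig(orientation=orientation, spacing=spacing, halfsite_len=m)
    return DimerAnnotation(
        config=cfg, left=(left[0], left[0] + m), right=(right[0], right[0] + m)
    )


def name_dimer_motifs(motifs: list[Motif]) -> list[Motif]:
    """Assign names like ``ER1a``/``ER1b`` to annotated dimeric motifs.

    Motifs sharing (orientation, spacing) get suffix letters in order of
    descending enrichment (ties: total IC, then name) — so the strongest mode
    of a configuration is always the "a" motif.
    """
    groups: dict[tuple[str, int], list[Motif]] = {}
    for m in motifs:
        if m.dimer is None:
            raise ValueError(f"motif {m.name} lacks a dimer annotation")
        key = (m.dimer.orientation, m.dimer.spacing)
        groups.setdefault(key, []).append(m)
    out = []
    for (o, s), group in groups.items():
        group.sort(
            key=lambda m: (
                -(m.enrichment if m.enrichment is not None else float("-inf")),
                -m.ic_bits,
                m.name,
            )
        )
        for i, m in enumerate(group):
            letter = chr(ord("a") + i)
            ann = m.dimer
            cfg = replace(ann.config, rank_letter=letter)
            new_ann = DimerAnnotation(config=cfg, left=ann.left, right=ann.right)
            out.append(replace(m, name=f"{o}{s}{letter}", dimer=new_ann))
    return out


# ---------------------------------------------------------------------------
# half-site specificity change
# ---------------------------------------------------------------------------

def _fixed_offset_distance(a: np.ndarray, b: np.ndarray) -> float:
    from .motifs import _column_pearson

    rs = [_column_pearson(a[i], b[i]) for i in range(len(a))]
    return float(np.clip(1.0 - np.mean(rs), 0.0, 1.0))


def half_site_divergence(
    dimer_motif: Motif,
    monomer_motif: Motif,
    threshold: float = 0.4,
) -> dict[str, float | bool]:
    """Column-wise distance of each half-site from the monomeric motif.

    Each half-site submatrix is oriented into the monomer frame according to
    the dimer's orientation convention and compared column-by-column (no
    offset search).  ``threshold`` flags a half-site as divergent; the default
    is the 95th simulation-null percentile documented in the methods note.
    """
    ann: DimerAnnotation | None = dimer_motif.dimer  # type: ignore[assignment]
    if ann is None:
        ann = infer_dimer_config(dimer_motif, monomer_motif)
    if ann.halfsite_len != monomer_motif.length:
        raise ValueError("half-site length does not match the monomer motif")
    ls, le = ann.left
    rs_, re_ = ann.right
    left_sub = dimer_motif.matrix[ls:le]
    right_sub = dimer_motif.matrix[rs_:re_]
    o = ann.orientation
    flip = lambda m: m[::-1, [3, 2, 1, 0]]
    if o == "IR":
        right_sub = flip(right_sub)
    elif o == "ER":
        left_sub = flip(left_sub)
    left_d = _fixed_offset_distance(left_sub, monomer_motif.matrix)
    right_d = _fixed_offset_distance(right_sub, monomer_motif.matrix)
    return {
        "left_d": left_d,
        "right_d": right_d,
        "left_divergent": left_d > threshold,
        "right_divergent": right_d > threshold,
        "threshold": threshold,
    }


def cooperativity_index(
    dimer_fold: float, left_half_fold: float, right_half_fold: float
) -> float:
    """fold(dimer) / (fold(left half) * fold(right half)).

    Values above 1 indicate that the full dimeric pattern is enriched beyond
    what two independent half-site binding events would explain.
    """
    return dimer_fold / (left_half_fold * right_half_fold)


# ---------------------------------------------------------------------------
# DNA shape profiles
# ---------------------------------------------------------------------------

class ShapeTable:
    """Pentamer -> shape-feature lookup (e.g. minor groove width, Angstrom).

    Missing pentamers resolve to the table default.  TSV format:
    ``pentamer<TAB>feature<TAB>value``.
    """

    def __init__(self, values: dict[str, dict[str, float]], default: float = np.nan):
        for p in values:
            if len(p) != 5 or any(c not in "ACGT" for c in p):
                raise ValueError(f"shape table key {p!r} is not an ACGT 5-mer")
        self.values = values
        self.default = default

    @classmethod
    def from_tsv(cls, path, default: float = np.nan) -> "ShapeTable":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["pentamer", "feature", "value"])
        values: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            values.setdefault(str(row.pentamer).upper(), {})[str(row.feature)] = float(row.value)
        return cls(values, default)

    def lookup(self, pentamer: str, feature: str) -> float:
        return self.values.get(pentamer.upper(), {}).get(feature, self.default)


def shape_profile(
    reads: list[str],
    hits: list[tuple[int, int, str]],
    motif_len: int,
    table: ShapeTable,
    feature: str,
    flank: int = 0,
) -> pd.DataFrame:
    """Per-position mean +/- sd of a pentamer shape feature across motif hits.

    ``hits`` are (read index, start, strand) records; minus-strand hits are
    flipped into motif orientation.  Position p covers [-flank, motif_len +
    flank); a position lacking full pentamer context (or with no table entry)
    is missing for that read.
    """
    if not hits:
        raise ValueError("no matched reads")
    positions = list(range(-flank, motif_len + flank))
    acc: dict[int, list[float]] = {p: [] for p in positions}
    for idx, start, strand in hits:
        read = reads[idx]
        if strand == "-":
            read = revcomp(read)
            start = len(read) - (start + motif_len)
        for p in positions:
            centre = start + p
            if centre - 2 < 0 or centre + 3 > len(read):
                continue
            v = table.lookup(read[centre - 2:centre + 3], feature)
            if np.isfinite(v):
                acc[p].append(v)
    rows = []
    for p in positions:
        vals = np.asarray(acc[p])
        rows.append(
            {"position": p,
             "mean": float(vals.mean()) if vals.size else np.nan,
             "sd": float(vals.std(ddof=0)) if vals.size else np.nan,
             "n": int(vals.size)}
        )
    return pd.DataFrame(rows)


def align_profiles_with_gaps(
    profile: pd.DataFrame, halfsite_len: int, spacing: int, max_spacing: int
) -> pd.DataFrame:
    """Re-index a dimer shape profile so half-sites of different spacings align.

    Gap columns are inserted in the spacer zone (centred) so that profiles of
    modes with different spacings share one half-site-aligned coordinate
    system of width ``2 * halfsite_len + max_spacing``.
    """
    if spacing > max_spacing:
        raise ValueError("spacing exceeds max_spacing")
    pad = max_spacing - spacing
    out = profile.copy()

    def remap(p: int) -> int:
        if p < halfsite_len:
            return p
        if p >= halfsite_len + spacing:
            return p + pad
        return p + pad // 2
    out["aligned_position"] = [remap(int(p)) for p in out["position"]]
    return out
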