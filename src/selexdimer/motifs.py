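"""Motif representation, information content, scanning and comparison.

A motif is a position probability matrix (PPM) over A,C,G,T.  Scanning uses
log2-odds scores against an i.i.d. background, with site significance taken
from the *exact* null distribution of window scores computed by discretised
convolution across columns (the standard dynamic program used by FIMO-style
scanners), so a p-value threshold maps deterministically to a score cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._seq import (
    BASES,
    IUPAC_SETS,
    decode,
    encode,
    revcomp_codes,
    validate_iupac,
    window_scores,
)

UNIFORM_BG = np.full(4, 0.25)

#: default pseudocount added to probabilities inside log-odds ratios
DEFAULT_LOGODDS_PSEUDOCOUNT = 1e-3
#: default discretisation width (bits) of the exact null dynamic program
DEFAULT_BIN_WIDTH = 0.01


@dataclass(frozen=True)
class Motif:
    """A DNA binding motif.

    Attributes
    ----------
    name : identifier.
    matrix : (L, 4) base probabilities in A,C,G,T order; rows sum to 1.
    counts : optional (L, 4) non-negative counts the matrix was derived from.
    pseudocount : the per-cell pseudocount used when normalising ``counts``.
    source : one of ``discovered``, ``consensus``, ``mutated``, ``file``.
    dimer : optional dimer annotation (orientation/spacing/half-site bounds),
        see :mod:`selexdimer.dimers`.
    enrichment : optional fold enrichment recorded at discovery time.
    """

    name: str
    matrix: np.ndarray
    counts: np.ndarray | None = None
    pseudocount: float = 0.0
    source: str = "consensus"
    dimer: object | None = None
    enrichment: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] == 0:
            raise ValueError("motif matrix must be (L, 4) with L >= 1")
        if (m < -1e-12).any():
            raise ValueError("motif matrix entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif matrix rows must each sum to 1")
        object.__setattr__(self, "matrix", m)
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=float)
            if c.shape != m.shape or (c < 0).any():
                raise ValueError("counts must be non-negative and match matrix shape")
            norm = (c + self.pseudocount) / (c + self.pseudocount).sum(axis=1, keepdims=True)
            if not np.allclose(norm, m, atol=1e-6):
                raise ValueError("matrix does not equal pseudocount-normalised counts")
            object.__setattr__(self, "counts", c)

    # -- basic properties -------------------------------------------------
    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.length

    @property
    def ic_bits(self) -> float:
        return information_content(self)[0]

    @property
    def mean_ic(self) -> float:
        return information_content(self)[1]

    @property
    def consensus(self) -> str:
        """IUPAC consensus: at each column keep bases with p >= max(p)/2."""
        out = []
        for row in self.matrix:
            keep = frozenset(BASES[b] for b in range(4) if row[b] >= row.max() / 2 - 1e-12)
            out.append(_set_symbol(keep))
        return "".join(out)

    def with_name(self, name: str) -> "Motif":
        return replace(self, name=name)

    def logodds_lut(
        self,
        background: np.ndarray = UNIFORM_BG,
        pseudocount: float = DEFAULT_LOGODDS_PSEUDOCOUNT,
    ) -> np.ndarray:
        """(L, 5) log2-odds lookup; column 4 (ambiguous base) scores 0."""
        bg = np.asarray(background, dtype=float)
        lut = np.zeros((self.length, 5))
        with np.errstate(divide="ignore"):
            lut[:, :4] = np.log2((self.matrix + pseudocount) / (bg + pseudocount))
        return lut

    def max_score(
        self,
        background: np.ndarray = UNIFORM_BG,
        pseudocount: float = DEFAULT_LOGODDS_PSEUDOCOUNT,
    ) -> float:
        """Best attainable log2-odds window score, in bits."""
        return float(self.logodds_lut(background, pseudocount)[:, :4].max(axis=1).sum())


def _set_symbol(keep: frozenset[str]) -> str:
    from ._seq import SET_TO_IUPAC

    return SET_TO_IUPAC[keep]


# ---------------------------------------------------------------------------
# construction and elementary transforms
# ---------------------------------------------------------------------------

def iupac_to_ppm(consensus: str, name: str | None = None) -> Motif:
    """PPM with equal probability over the bases each IUPAC symbol allows."""
    text = consensus.upper()
    validate_iupac(text)
    m = np.zeros((len(text), 4))
    for i, ch in enumerate(text):
        allowed = IUPAC_SETS[ch]
        for b in allowed:
            m[i, BASES.index(b)] = 1.0 / len(allowed)
    return Motif(name=name or text, matrix=m, source="consensus")


def information_content(motif: Motif) -> tuple[float, float]:
    """Total and per-column-mean information content in bits.

    Per-column IC is 2 + sum_b p_b log2 p_b with 0*log 0 = 0.
    """
    p = motif.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    per_col = 2.0 + plogp.sum(axis=1)
    total = float(per_col.sum())
    return total, total / motif.length


def reverse_complement(motif: Motif) -> Motif:
    """Reverse column order and swap A<->T, C<->G probabilities."""
    m = motif.matrix[::-1, [3, 2, 1, 0]]
    counts = None
    if motif.counts is not None:
        counts = motif.counts[::-1, [3, 2, 1, 0]]
    return Motif(
        name=motif.name + "_rc",
        matrix=m,
        counts=counts,
        pseudocount=motif.pseudocount,
        source=motif.source,
        enrichment=motif.enrichment,
    )


def log_odds_score(
    motif: Motif,
    window: str,
    background: np.ndarray = UNIFORM_BG,
    pseudocount: float = DEFAULT_LOGODDS_PSEUDOCOUNT,
) -> float:
    """Log2-odds score of one window; ambiguous bases contribute 0 bits."""
    if len(window) != motif.length:
        raise ValueError(f"window length {len(window)} != motif length {motif.length}")
    codes = encode(window)
    lut = motif.logodds_lut(background, pseudocount)
    return float(lut[np.arange(motif.length), codes].sum())


def mutate_consensus(target: "Motif | str", edits: Iterable[tuple[int, str]]):
    """Replace columns (or characters) at the listed positions.

    ``edits`` is an iterable of (0-based position, IUPAC symbol).  For a Motif
    the listed columns become the uniform-over-allowed-bases columns of
    :func:`iupac_to_ppm`; anything not listed is untouched.
    """
    edits = list(edits)
    if isinstance(target, str):
        validate_iupac(target) if target else None
        chars = list(target)
        for pos, sym in edits:
            if not 0 <= pos < len(chars):
                raise IndexError(f"edit position {pos} out of range for length {len(chars)}")
            validate_iupac(sym)
            if len(sym) != 1:
                raise ValueError("edit symbol must be a single IUPAC character")
            chars[pos] = sym.upper()
        return "".join(chars)
    m = target.matrix.copy()
    for pos, sym in edits:
        if not 0 <= pos < target.length:
            raise IndexError(f"edit position {pos} out of range for length {target.length}")
        m[pos] = iupac_to_ppm(sym).matrix[0]
    if not edits:
        return target
    return Motif(name=target.name + "_mut", matrix=m, source="mutated", dimer=target.dimer)


# ---------------------------------------------------------------------------
# exact null distribution and scanning
# ---------------------------------------------------------------------------

class ScoreDistribution:
    """Exact null distribution of integer-discretised log-odds window scores.

    Scores are discretised to multiples of ``bin_width`` bits; the null pmf
    under the i.i.d. background model is computed by convolving the per-column
    score distributions, which is exact on the discretised scale.
    """

    def __init__(
        self,
        motif: Motif,
        background: np.ndarray = UNIFORM_BG,
        pseudocount: float = DEFAULT_LOGODDS_PSEUDOCOUNT,
        bin_width: float = DEFAULT_BIN_WIDTH,
    ) -> None:
        self.motif = motif
        self.background = np.asarray(background, dtype=float)
        self.pseudocount = pseudocount
        self.bin_width = bin_width
        lut_bits = motif.logodds_lut(self.background, pseudocount)
        ilut = np.rint(lut_bits / bin_width).astype(np.int64)
        ilut[:, 4] = 0  # ambiguous bases contribute nothing
        self.ilut = ilut
        self._build_null()

    def _build_null(self) -> None:
        pmf = np.ones(1)
        lo = 0
        for j in range(self.motif.length):
            col = self.ilut[j, :4]
            cmin, cmax = int(col.min()), int(col.max())
            new = np.zeros(len(pmf) + cmax - cmin)
            for b in range(4):
                off = int(col[b]) - cmin
                new[off:off + len(pmf)] += self.background[b] * pmf
            pmf = new
            lo += cmin
        self.min_iscore = lo
        self.pmf = pmf
        # tail[i] = P(score >= lo + i)
        self.tail = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, iscore: float) -> float:
        """P(null window score >= iscore), iscore in integer bins."""
        idx = int(np.ceil(iscore)) - self.min_iscore
        if idx <= 0:
            return 1.0
        if idx >= len(self.tail):
            return 0.0
        return float(self.tail[idx])

    def pvalue_bits(self, score_bits: float) -> float:
        return self.pvalue(np.rint(score_bits / self.bin_width))

    def threshold(self, p_value: float) -> int:
        """Smallest integer score whose tail probability is <= p_value."""
        if not 0 < p_value <= 1:
            raise ValueError("p_value_threshold must lie in (0, 1]")
        idx = int(np.searchsorted(-self.tail, -p_value, side="left"))
        return self.min_iscore + idx

    def threshold_bits(self, p_value: float) -> float:
        return self.threshold(p_value) * self.bin_width


@dataclass(frozen=True)
class Site:
    """One motif occurrence: 0-based half-open coordinates on the + axis."""

    start: int
    end: int
    strand: str
    score: float  # bits
    pvalue: float = float("nan")


def scan_sequence(
    motif: Motif,
    sequence: str,
    p_value_threshold: float,
    background: np.ndarray = UNIFORM_BG,
    pseudocount: float = DEFAULT_LOGODDS_PSEUDOCOUNT,
    bin_width: float = DEFAULT_BIN_WIDTH,
    dist: ScoreDistribution | None = None,
) -> list[Site]:
    """Find sites of ``motif`` on both strands above an exact p-value cutoff.

    Windows with more than L/2 ambiguous bases are dropped; other ambiguous
    bases contribute zero bits.  Sites are reported in coordinate order and
    may overlap.
    """
    if dist is None:
        dist = ScoreDistribution(motif, background, pseudocount, bin_width)
    thr = dist.threshold(p_value_threshold)
    codes = encode(sequence)
    L = motif.length
    if len(codes) < L:
        return []
    sites: list[Site] = []
    ilut = dist.ilut.astype(float)
    rc_ilut = ilut[::-1][:, [3, 2, 1, 0, 4]]
    n_counts = window_scores(codes, np.eye(5)[4][None, :].repeat(L, axis=0))
    for strand, lut in (("+", ilut), ("-", rc_ilut)):
        sc = window_scores(codes, lut)
        ok = (sc >= thr) & (n_counts <= L / 2)
        for i in np.nonzero(ok)[0]:
            isc = sc[i]
            sites.append(
                Site(int(i), int(i) + L, strand, float(isc * bin_width), dist.pvalue(isc))
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# motif comparison and embedding
# ---------------------------------------------------------------------------

def _column_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx < 1e-12 and ny < 1e-12:
        return 1.0
    if nx < 1e-12 or ny < 1e-12:
        return 0.0
    return float(xc @ yc / (nx * ny))


def _best_alignment_corr(a: np.ndarray, b: np.ndarray, min_overlap: int) -> float:
    best = -np.inf
    la, lb = len(a), len(b)
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(la, off + lb)
        if hi_a - lo_a < min_overlap:
            continue
        rs = [
            _column_pearson(a[i], b[i - off]) for i in range(lo_a, hi_a)
        ]
        best = max(best, float(np.mean(rs)))
    return best


def motif_distance(a: Motif, b: Motif, min_overlap: int = 4) -> float:
    """1 minus the best mean column Pearson correlation over offsets/strands.

    The orientation of ``b`` is searched (b vs its reverse complement); at
    least ``min_overlap`` aligned columns are required.  Symmetric, zero on
    identical motifs, invariant to reverse-complementing either argument.
    """
    if a.length < min_overlap or b.length < min_overlap:
        raise ValueError(f"motifs must have at least {min_overlap} columns")
    best = max(
        _best_alignment_corr(a.matrix, b.matrix, min_overlap),
        _best_alignment_corr(a.matrix, reverse_complement(b).matrix, min_overlap),
    )
    return float(np.clip(1.0 - best, 0.0, 1.0))


def mds_embed(distance_matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distance matrix and projects on the top
    eigenvectors.  Deterministic up to sign; signs are fixed so the largest-
    magnitude coordinate on each axis is positive.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords
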