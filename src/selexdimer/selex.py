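"""Seed-based motif discovery from cycle-indexed SELEX read libraries.

Reads are tiled into fixed-length segments, enriched k-mers (local maxima in
the Hamming-1 neighbourhood graph) are called as seeds against a background
cycle, and position probability matrices are built by multinomial-1 counting:
column *i* of the matrix counts windows that match the seed everywhere except
possibly at *i*.  Library-level signal is quantified by E-MI, the mutual
information between 3-mer distributions at non-overlapping position pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode_many, revcomp, iupac_regex, validate_iupac
from .motifs import Motif, iupac_to_ppm, motif_distance


@dataclass
class SelexLibrary:
    """Cycle-indexed ligand sequences with provenance.

    ``cycles`` maps cycle index (0 = input library) to a list of reads.
    """

    cycles: dict[int, list[str]]
    ligand_length: int = 101
    meta: dict = field(default_factory=dict)

    def reads(self, cycle: int) -> list[str]:
        return self.cycles[cycle]

    @property
    def final_cycle(self) -> int:
        return max(self.cycles)


@dataclass(frozen=True)
class SeedReport:
    seed: str
    signal_count: int
    background_count: int
    enrichment: float
    locally_maximal: bool = True


# ---------------------------------------------------------------------------
# segmentation and k-mer counting
# ---------------------------------------------------------------------------

def segment_reads(reads: list[str], segment_length: int = 40) -> list[str]:
    """Tile reads into non-overlapping ``segment_length`` windows from 0.

    Trailing remainders (and reads shorter than the window) contribute
    nothing; segment order follows read order.
    """
    if segment_length < 8:
        raise ValueError("segment_length must be >= 8")
    out = []
    for r in reads:
        for i in range(0, len(r) - segment_length + 1, segment_length):
            out.append(r[i:i + segment_length])
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer codes of all k-windows of an (n, L) code matrix.

    Windows containing an ambiguous base get code -1.
    """
    n, L = codes.shape
    W = L - k + 1
    if W <= 0:
        return np.empty((n, 0), dtype=np.int64)
    out = np.zeros((n, W), dtype=np.int64)
    bad = np.zeros((n, W), dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        out = out * 4 + np.where(c[:, j:j + W] < 4, c[:, j:j + W], 0)
        bad |= c[:, j:j + W] >= 4
    out[bad] = -1
    return out


def _rc_code_perm(k: int) -> np.ndarray:
    """Permutation p with p[code] = code of the reverse complement k-mer."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


class KmerCounts:
    """Occurrence counts of every k-mer in a segment set.

    The stored table counts forward-strand windows; ``count(kmer)`` with
    ``both_strands=True`` adds the reverse-complement entry at query time.
    """

    def __init__(self, segments: list[str], k: int):
        if segments and k > min(len(s) for s in segments):
            raise ValueError("k exceeds segment length")
        self.k = k
        self.table = np.zeros(4 ** k, dtype=np.int64)
        self.total_windows = 0
        by_len: dict[int, list[str]] = {}
        for s in segments:
            by_len.setdefault(len(s), []).append(s)
        for L, group in by_len.items():
            codes = _kmer_codes(encode_many(group), k)
            valid = codes[codes >= 0]
            self.table += np.bincount(valid, minlength=4 ** k)
            self.total_windows += codes.size
        self._rc = None

    @property
    def rc_perm(self) -> np.ndarray:
        if self._rc is None:
            self._rc = _rc_code_perm(self.k)
        return self._rc

    def both_strand_table(self) -> np.ndarray:
        return self.table + self.table[self.rc_perm]

    def count(self, kmer: str, both_strands: bool = True) -> int:
        codes = _kmer_codes(encode_many([kmer]), self.k)
        c = int(codes[0, 0])
        n = int(self.table[c])
        if both_strands:
            n += int(self.table[self.rc_perm[c]])
        return n

    def as_dict(self, min_count: int = 1) -> dict[str, int]:
        idx = np.nonzero(self.table >= min_count)[0]
        return {_decode_kmer(int(i), self.k): int(self.table[i]) for i in idx}


def kmer_counts(segments: list[str], k: int, both_strands: bool = True) -> KmerCounts:
    """Count all k-windows of the segments (see :class:`KmerCounts`)."""
    kc = KmerCounts(segments, k)
    kc.both_strands_default = both_strands
    return kc


# ---------------------------------------------------------------------------
# seed discovery
# ---------------------------------------------------------------------------

def _near_duplicate(a: str, b: str, min_overlap: int) -> bool:
    """True if some gapless alignment (either strand) overlaps by at least
    ``min_overlap`` positions and matches at all but (at most) one of them."""
    for bb in (b, revcomp(b)):
        for off in range(-(len(bb) - 1), len(a)):
            lo, hi = max(0, off), min(len(a), off + len(bb))
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            mm = sum(1 for i in range(lo, hi) if a[i] != bb[i - off])
            if mm <= 1:
                return True
    return False


def find_seeds(
    signal_counts: dict[int, KmerCounts],
    background_counts: dict[int, KmerCounts],
    k_range: tuple[int, int] = (8, 10),
    min_enrichment: float = 2.0,
    max_seeds: int = 50,
) -> list[SeedReport]:
    """Call enriched, Hamming-1-locally-maximal k-mers as motif seeds.

    Enrichment of a k-mer is its size-normalised both-strand frequency in the
    signal over the background, with a pseudocount of 1 on counts.  A k-mer is
    a seed iff its enrichment exceeds ``min_enrichment`` and is >= that of all
    3k Hamming-1 neighbours.  Near-duplicate seeds (best gapless alignment
    matching at >= min(k)-2 positions) are merged keeping the higher one.
    """
    candidates: list[SeedReport] = []
    for k in range(k_range[0], k_range[1] + 1):
        if k not in signal_counts or k not in background_counts:
            continue
        sc, bc = signal_counts[k], background_counts[k]
        if sc.total_windows == 0:
            continue
        s_tab = sc.both_strand_table().astype(float)
        b_tab = bc.both_strand_table().astype(float)
        s_freq = (s_tab + 1) / max(sc.total_windows, 1)
        b_freq = (b_tab + 1) / max(bc.total_windows, 1)
        enr = s_freq / b_freq
        idx = np.nonzero(enr > min_enrichment)[0]
        if len(idx) == 0:
            continue
        # keep the top candidates only; local-maximum test prunes the rest
        order = idx[np.argsort(enr[idx])[::-1][: max_seeds * 40]]
        pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for c in order:
            e = enr[c]
            is_max = True
            for j in range(k):
                digit = (c // pow4[j]) % 4
                for b in range(4):
                    if b == digit:
                        continue
                    nb = c + (b - digit) * pow4[j]
                    if enr[nb] > e:
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                candidates.append(
                    SeedReport(
                        seed=_decode_kmer(int(c), k),
                        signal_count=int(s_tab[c]),
                        background_count=int(b_tab[c]),
                        enrichment=float(e),
                    )
                )
    candidates.sort(key=lambda r: (-r.enrichment, r.seed))
    kept: list[SeedReport] = []
    for cand in candidates:
        dup = any(
            _near_duplicate(
                kept_r.seed, cand.seed,
                min(len(kept_r.seed), len(cand.seed)) - 2,
            )
            for kept_r in kept
        )
        if not dup:
            kept.append(cand)
        if len(kept) >= max_seeds:
            break
    return kept


def discover_seeds(
    signal_segments: list[str],
    background_segments: list[str],
    k_range: tuple[int, int] = (8, 10),
    min_enrichment: float = 2.0,
    max_seeds: int = 50,
) -> list[SeedReport]:
    """Convenience wrapper: count k-mers for every k and call seeds."""
    ks = range(k_range[0], k_range[1] + 1)
    sig = {k: KmerCounts(signal_segments, k) for k in ks}
    bg = {k: KmerCounts(background_segments, k) for k in ks}
    return find_seeds(sig, bg, k_range, min_enrichment, max_seeds)


# ---------------------------------------------------------------------------
# multinomial-1 PWM construction
# ---------------------------------------------------------------------------

def _h1_column_counts(win_codes: np.ndarray, seed_codes: np.ndarray) -> np.ndarray:
    """Column counts from windows at Hamming distance <= 1 from the seed."""
    k = len(seed_codes)
    eq = win_codes == seed_codes
    mm = k - eq.sum(axis=1)
    counts = np.zeros((k, 4))
    n_exact = int((mm == 0).sum())
    counts[np.arange(k), seed_codes] += n_exact
    one = np.nonzero(mm == 1)[0]
    if len(one):
        pos = np.argmin(eq[one], axis=1)
        base = win_codes[one, pos]
        ok = base < 4
        np.add.at(counts, (pos[ok], base[ok]), 1)
    return counts


def pwm_from_seed(
    seed: str,
    segments: list[str],
    pseudocount: float = 1.0,
    both_strands: bool = True,
) -> Motif:
    """Multinomial-1 PWM around a seed.

    For each position *i* and base *b*, counts windows equal to the seed with
    position *i* replaced by *b* and every other position matching exactly;
    reverse-complement windows are folded onto the seed orientation when
    ``both_strands``.  Columns are normalised with ``pseudocount``.
    """
    k = len(seed)
    seed_codes = encode_many([seed])[0]
    if (seed_codes >= 4).any():
        raise ValueError("seed must contain only A,C,G,T")
    counts = np.zeros((k, 4))
    by_len: dict[int, list[str]] = {}
    for s in segments:
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(s)
    for L, group in by_len.items():
        codes = encode_many(group)
        strands = [codes]
        if both_strands:
            from ._seq import revcomp_codes

            strands.append(revcomp_codes(codes))
        for mat in strands:
            W = L - k + 1
            wins = np.lib.stride_tricks.sliding_window_view(mat, (1, k))
            wins = wins.reshape(-1, k)
            counts += _h1_column_counts(wins, seed_codes)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError(
            "no Hamming<=1 support at some seed position; a larger library is needed"
        )
    matrix = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    return Motif(
        name=seed, matrix=matrix, counts=counts, pseudocount=pseudocount,
        source="discovered",
    )


def pwm_from_matches(
    pattern: str,
    reads: list[str],
    pseudocount: float = 1.0,
    name: str | None = None,
) -> Motif:
    """PPM from read windows matching an IUPAC pattern (both strands).

    Reads are aligned on every exact pattern match; minus-strand matches are
    reverse-complemented into pattern orientation before column counting.
    Complements multinomial-1 construction for sites longer than seed k-mers.
    """
    validate_iupac(pattern)
    rx = iupac_regex(pattern)
    k = len(pattern)
    windows: list[str] = []
    for r in reads:
        for strand_seq in (r, revcomp(r)):
            for m in rx.finditer(strand_seq):
                windows.append(strand_seq[m.start():m.start() + k])
    if not windows:
        raise ValueError("pattern has no matches in the reads")
    codes = encode_many(windows)
    counts = np.zeros((k, 4))
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    matrix = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    return Motif(
        name=name or pattern, matrix=matrix, counts=counts,
        pseudocount=pseudocount, source="discovered",
    )


def trim_motif(motif: Motif, min_col_ic: float = 0.25) -> Motif:
    """Trim uninformative flanking columns from a discovered motif.

    The motif is cut to the maximal contiguous run of columns with
    information content >= ``min_col_ic`` bits that contains the strongest
    column.  This removes random flanks picked up by seeds longer than the
    binding site, and also detached secondary islands (e.g. the first bases
    of a dimer partner half-site bleeding into the flank columns).  Raises if
    nothing informative remains.
    """
    p = motif.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    col_ic = 2.0 + plogp.sum(axis=1)
    if (col_ic < min_col_ic).all():
        raise ValueError("no informative columns to keep")
    peak = int(np.argmax(col_ic))
    lo = peak
    while lo > 0 and col_ic[lo - 1] >= min_col_ic:
        lo -= 1
    hi = peak + 1
    while hi < motif.length and col_ic[hi] >= min_col_ic:
        hi += 1
    if lo == 0 and hi == motif.length:
        return motif
    counts = motif.counts[lo:hi] if motif.counts is not None else None
    return Motif(
        name=motif.name, matrix=motif.matrix[lo:hi], counts=counts,
        pseudocount=motif.pseudocount, source=motif.source,
        enrichment=motif.enrichment,
    )


# ---------------------------------------------------------------------------
# motif-set filtering
# ---------------------------------------------------------------------------

def filter_motifs(
    motifs: list[Motif],
    min_total_ic: float = 1.0,
    duplicate_distance: float = 0.05,
    run_fraction: float = 0.8,
) -> tuple[list[Motif], list[tuple[str, str]]]:
    """Drop low-IC motifs, single-nucleotide runs, and near-duplicates.

    Returns (survivors, removal log of (name, reason)).  A motif is a run if
    >= ``run_fraction`` of its columns share the same top base.  Duplicates
    (motif_distance < ``duplicate_distance``) keep the higher-enrichment
    member, ties broken lexicographically by name.
    """
    log: list[tuple[str, str]] = []
    stage: list[Motif] = []
    for m in motifs:
        if m.ic_bits < min_total_ic:
            log.append((m.name, "total IC < %.3g bits" % min_total_ic))
            continue
        top = m.matrix.argmax(axis=1)
        frac = np.bincount(top, minlength=4).max() / m.length
        if frac >= run_fraction:
            log.append((m.name, "single-nucleotide run"))
            continue
        stage.append(m)

    def rank(m: Motif):
        e = m.enrichment if m.enrichment is not None else float("-inf")
        return (-e, m.name)

    stage.sort(key=rank)
    kept: list[Motif] = []
    for m in stage:
        dup_of = next(
            (k.name for k in kept if motif_distance(k, m) < duplicate_distance), None
        )
        if dup_of is not None:
            log.append((m.name, f"duplicate of {dup_of}"))
        else:
            kept.append(m)
    return kept, log


# ---------------------------------------------------------------------------
# E-MI library QC
# ---------------------------------------------------------------------------

@dataclass
class EMIReport:
    """Pairwise mutual information between k-mer positions, in bits."""

    mi: np.ndarray  # (P, P), NaN where windows overlap
    kmer_len: int
    n_reads: int
    summary: float  # mean of the top-n pair MIs
    top_n: int


def emi(
    reads: list[str],
    kmer_len: int = 3,
    top_n: int = 10,
    position_stride: int = 1,
    max_reads: int | None = None,
    rng: np.random.Generator | None = None,
) -> EMIReport:
    """E-MI: mutual information of k-mer identities at position pairs.

    For every ordered pair of non-overlapping ``kmer_len`` windows (i, j) the
    MI (bits) of the joint distribution of the two k-mers across reads is
    computed, with the Miller-Madow small-sample bias correction (the plug-in
    MI of a 64 x 64 joint is biased upward by roughly (Kx-1)(Ky-1)/(2N ln 2));
    the summary score is the mean of the ``top_n`` largest pair MIs.
    """
    if len(reads) < 100:
        raise ValueError("E-MI requires at least 100 reads")
    if max_reads is not None and len(reads) > max_reads:
        rng = rng or np.random.default_rng(0)
        reads = [reads[i] for i in rng.choice(len(reads), max_reads, replace=False)]
    L = min(len(r) for r in reads)
    if any(len(r) != L for r in reads):
        warnings.warn(f"reads of unequal length; using common prefix of {L} bp")
        reads = [r[:L] for r in reads]
    codes = encode_many(reads)
    ids = _kmer_codes(codes, kmer_len)
    n, P = ids.shape
    positions = list(range(0, P, position_stride))
    mi = np.full((P, P), np.nan)
    n_states = 4 ** kmer_len
    for ai, i in enumerate(positions):
        vi = ids[:, i]
        for j in positions[ai + 1:]:
            if j - i < kmer_len:
                continue
            ok = (vi >= 0) & (ids[:, j] >= 0)
            joint = np.bincount(
                vi[ok] * n_states + ids[ok, j], minlength=n_states ** 2
            ).reshape(n_states, n_states).astype(float)
            tot = joint.sum()
            if tot == 0:
                continue
            joint /= tot
            px = joint.sum(axis=1, keepdims=True)
            py = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(joint > 0, joint * np.log2(joint / (px * py)), 0.0)
            plugin = float(terms.sum())
            # Miller-Madow bias correction on the three plug-in entropies
            kx = int((px > 0).sum())
            ky = int((py > 0).sum())
            kxy = int((joint > 0).sum())
            correction = (kx - 1 + ky - 1 - (kxy - 1)) / (2 * tot * np.log(2))
            mi[i, j] = mi[j, i] = plugin + correction
    vals = mi[np.isfinite(mi)]
    top = np.sort(vals)[::-1][:top_n] if vals.size else np.array([0.0])
    return EMIReport(mi=mi, kmer_len=kmer_len, n_reads=n,
                     summary=float(top.mean()), top_n=top_n)


# ---------------------------------------------------------------------------
# pattern enrichment
# ---------------------------------------------------------------------------

def pattern_match_fraction(pattern: str, reads: list[str]) -> float:
    """Fraction of reads with >= 1 exact IUPAC match on either strand."""
    if not reads:
        raise ValueError("empty read set")
    fwd = iupac_regex(pattern)
    rev = iupac_regex(revcomp(pattern))
    n = sum(1 for r in reads if fwd.search(r) or rev.search(r))
    return n / len(reads)


def pattern_enrichment(
    pattern: str, signal_reads: list[str], background_reads: list[str]
) -> dict[str, float]:
    """Fold enrichment of an IUPAC pattern in signal over background reads.

    ``fold = (f_signal + eps) / (f_background + eps)`` with
    ``eps = 1 / (n_background + 1)``; a pattern absent from both sets thus has
    fold 1.
    """
    f_sig = pattern_match_fraction(pattern, signal_reads)
    f_bg = pattern_match_fraction(pattern, background_reads)
    eps = 1.0 / (len(background_reads) + 1)
    return {
        "f_signal": f_sig,
        "f_background": f_bg,
        "fold": (f_sig + eps) / (f_bg + eps),
    }
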