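"""Ground-truth generators: simulated SELEX libraries and planted genomes.

The SELEX simulator draws the sequenced reads of cycle *k* exactly from the
occupancy model's post-selection distribution

    p_k(x)  proportional to  p0(x) * s(x)^k,
    s(x) = min(1, capture_scale * w(x)  +  nonspecific_rate),
    w(x) = sum over modes, windows, strands of
           omega_mode * exp(activity_mode * logodds_score),

where p0 is the i.i.d. background.  Sampling uses self-normalised importance
resampling from a planted-site mixture proposal, which emulates selection
from an effectively infinite initial pool (bench SELEX starts from ~10^12
molecules, so every strong site exists in the pool even though a desk-scale
finite sample of the background would contain none).  Cycle 0 reads are
literal i.i.d. background draws.  All outputs are pure functions of
(parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import IUPAC_SETS, BASES, decode, window_scores
from .dimers import DimerAnnotation, DimerConfig, build_dimer_pattern
from .genome import GenomicAnnotation
from .motifs import Motif, UNIFORM_BG, iupac_to_ppm
from .selex import SelexLibrary

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class BindingMode:
    """One binding mode: a motif with activity and (dimeric) cooperativity."""

    motif: Motif
    activity: float  # lambda, multiplies the log2-odds score inside exp()
    cooperativity: float = 1.0  # omega, >= 1; meaningful for dimeric modes
    name: str = ""

    def full_site_weight(self) -> float:
        """exp(activity * best score), excluding cooperativity."""
        return float(np.exp(self.activity * self.motif.max_score()))


@dataclass
class BindingModel:
    """Mixture of monomeric/dimeric PWM modes driving ligand selection."""

    modes: list[BindingMode]
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    capture_scale: float | None = None  # None -> calibrated at simulate time
    nonspecific_rate: float = 0.002  # selection probability floor
    saturation_target: float = 0.1  # full-site selection prob. when calibrated

    def __post_init__(self):
        if not self.modes:
            raise ValueError("model needs at least one mode")

    def resolved_capture_scale(self) -> float:
        """capture_scale, defaulting so the weakest mode's full site is
        selected with probability ``saturation_target`` per cycle."""
        if self.capture_scale is not None:
            return self.capture_scale
        return self.saturation_target / min(m.full_site_weight() for m in self.modes)

    def snapshot(self) -> dict:
        return {
            "modes": [
                {"name": m.name or m.motif.name, "length": m.motif.length,
                 "consensus": m.motif.consensus, "activity": m.activity,
                 "cooperativity": m.cooperativity}
                for m in self.modes
            ],
            "capture_scale": self.resolved_capture_scale(),
            "nonspecific_rate": self.nonspecific_rate,
        }


@dataclass
class SyntheticTruth:
    """Planted-site records plus the generating model and seed."""

    records: pd.DataFrame  # seq_id/chrom, start, end, strand, mode
    model: dict
    seed: int


# ---------------------------------------------------------------------------
# SELEX simulation
# ---------------------------------------------------------------------------

def _sample_site(rng: np.random.Generator, motif: Motif, n: int) -> np.ndarray:
    """Draw n encoded site sequences from a motif's PPM."""
    L = motif.length
    out = np.empty((n, L), dtype=np.int8)
    for j in range(L):
        out[:, j] = rng.choice(4, size=n, p=motif.matrix[j])
    return out


def _mode_tables(mode: BindingMode, background: np.ndarray):
    """(selection lut, exact-ratio lut) pairs for both strands."""
    sel = mode.motif.logodds_lut(background)  # pseudocounted, bits
    with np.errstate(divide="ignore"):
        exact = np.log2(mode.motif.matrix / background)
    exact = np.where(np.isfinite(exact), exact, -1e6)
    ex = np.zeros((mode.motif.length, 5))
    ex[:, :4] = exact
    ex[:, 4] = -1e6
    def rc(lut):
        return lut[::-1][:, [3, 2, 1, 0, 4]]
    return (sel, rc(sel)), (ex, rc(ex))


def simulate_selex(
    model: BindingModel,
    n_ligands: int = 50_000,
    length: int = 101,
    cycles: int = 3,
    seed: int = 0,
    proposal_factor: int = 4,
    plant_fraction: float = 0.3,
) -> tuple[SelexLibrary, SyntheticTruth]:
    """Simulate an HT-SELEX experiment for a PWM-mixture binding model.

    Returns a library with cycle 0 (input) plus ``cycles`` enrichment cycles
    of ``n_ligands`` reads each, and the ground-truth records of planted mode
    sites present in the returned reads.
    """
    if n_ligands < 1000:
        raise ValueError("n_ligands must be >= 1000")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    rng = np.random.default_rng(seed)
    bg = model.background
    cs = model.resolved_capture_scale()
    n_modes = len(model.modes)
    alpha_m = plant_fraction / n_modes
    alpha_0 = 1.0 - plant_fraction

    # ----- cycle 0: literal i.i.d. background reads
    cyc0 = rng.choice(4, size=(n_ligands, length), p=bg).astype(np.int8)
    cycles_out: dict[int, list[str]] = {0: [decode(row) for row in cyc0]}

    # ----- proposal: background reads, a fraction carrying one planted site
    N = proposal_factor * n_ligands
    prop = rng.choice(4, size=(N, length), p=bg).astype(np.int8)
    assign = rng.choice(n_modes + 1, size=N,
                        p=[alpha_0] + [alpha_m] * n_modes)
    planted_mode = np.full(N, -1, dtype=int)
    planted_start = np.full(N, -1, dtype=int)
    planted_strand = np.full(N, 0, dtype=int)  # 0 '+', 1 '-'
    for mi, mode in enumerate(model.modes):
        rows = np.nonzero(assign == mi + 1)[0]
        if len(rows) == 0:
            continue
        m_len = mode.motif.length
        sites = _sample_site(rng, mode.motif, len(rows))
        starts = rng.integers(0, length - m_len + 1, size=len(rows))
        strands = rng.integers(0, 2, size=len(rows))
        flip = strands == 1
        from ._seq import revcomp_codes

        sites[flip] = revcomp_codes(sites[flip])
        for r, s0, site in zip(rows, starts, sites):
            prop[r, s0:s0 + m_len] = site
        planted_mode[rows] = mi
        planted_start[rows] = starts
        planted_strand[rows] = strands

    # ----- per-read selection weight w and proposal density ratio
    w = np.zeros(N)
    dens_ratio = np.full(N, alpha_0)
    for mi, mode in enumerate(model.modes):
        (sel_f, sel_r), (ex_f, ex_r) = _mode_tables(mode, bg)
        W = length - mode.motif.length + 1
        mode_w = np.zeros(N)
        mode_r = np.zeros(N)
        for lut_sel, lut_ex in ((sel_f, ex_f), (sel_r, ex_r)):
            sc = window_scores(prop, lut_sel)
            mode_w += np.exp(np.clip(mode.activity * sc, -700, 700)).sum(axis=1)
            ratio = np.exp2(np.clip(window_scores(prop, lut_ex), -1000, 300))
            mode_r += ratio.sum(axis=1)
        w += mode.cooperativity * mode_w
        dens_ratio += alpha_m * mode_r / (2 * W)
    s = np.minimum(1.0, model.nonspecific_rate + cs * w)
    bg_rows = assign == 0
    if bg_rows.any() and (s[bg_rows] >= 1.0).mean() > 0.5:
        warnings.warn("capture_scale too high: selection saturates for most ligands")

    # ----- per-cycle importance resampling
    records = []
    for k in range(1, cycles + 1):
        wt = s ** k / dens_ratio
        wt_sum = wt.sum()
        if wt_sum <= 0:
            raise RuntimeError("degenerate selection weights")
        idx = rng.choice(N, size=n_ligands, replace=True, p=wt / wt_sum)
        cycles_out[k] = [decode(prop[i]) for i in idx]
        for j, i in enumerate(idx):
            if planted_mode[i] >= 0:
                mode = model.modes[planted_mode[i]]
                records.append({
                    "seq_id": f"cycle{k}_read{j}",
                    "cycle": k,
                    "start": int(planted_start[i]),
                    "end": int(planted_start[i]) + mode.motif.length,
                    "strand": "-" if planted_strand[i] else "+",
                    "mode": mode.name or mode.motif.name,
                })
    lib = SelexLibrary(
        cycles=cycles_out, ligand_length=length,
        meta={"provenance": "simulation", "seed": seed},
    )
    truth = SyntheticTruth(
        records=pd.DataFrame(records), model=model.snapshot(), seed=seed,
    )
    return lib, truth


# ---------------------------------------------------------------------------
# the planted specificity-change model
# ---------------------------------------------------------------------------

def make_er1a_like_model(
    base_half: str = "ACCTAAY",
    modified_half: str = "CACGTGG",
    spacing: int = 1,
    orientation: str = "ER",
    distant_spacing: int = 8,
    distant_orientation: str = "ER",
    monomer_selection: float = 0.01,
    distant_selection: float = 0.5,
    close_selection: float = 0.9,
    cooperativity: float = 4.0,
    capture_scale: float = 1e-5,
    nonspecific_rate: float = 0.002,
) -> BindingModel:
    """Binding model with a planted half-site specificity change.

    Modes: (a) the monomer from ``base_half``; (b) a distant homodimer
    (default ER spacing 8) from two base halves — the unchanged control; (c) a
    close dimer (default ER spacing 1) whose *right* half derives from
    ``modified_half`` — the planted specificity change.

    Mode activities are set from per-cycle capture probabilities of one full
    consensus site (``*_selection``); the defaults make the dimeric modes the
    dominant drivers of enrichment, emulating a factor whose homodimeric
    binding carries the library — which is the regime where a half-site
    specificity change is observable at all.  A fully degenerate base half
    would otherwise swamp the changed mode: a site of the changed dimer is
    intrinsically ~4x rarer per degenerate base-half position in random
    sequence.
    """
    if len(base_half) != len(modified_half):
        raise ValueError("half-sites must have equal length")
    h = len(base_half)
    monomer = iupac_to_ppm(base_half, name="monomer")

    def dimer_motif(name, orient, sp, half2):
        cfg = DimerConfig(orientation=orient, spacing=sp, halfsite_len=h)
        pattern = build_dimer_pattern(base_half, cfg, half2=half2)
        # boundaries: left element occupies [0, h), right [h + sp, 2h + sp)
        ann = DimerAnnotation(config=cfg, left=(0, h), right=(h + sp, 2 * h + sp))
        return replace(iupac_to_ppm(pattern, name=name), dimer=ann)

    distant = dimer_motif(
        f"{distant_orientation}{distant_spacing}", distant_orientation,
        distant_spacing, base_half,
    )
    close = dimer_motif(
        f"{orientation}{spacing}mod", orientation, spacing, modified_half,
    )

    def activity(motif, target, omega):
        # omega * exp(activity * max_score) * capture_scale == target
        return float(np.log(target / (capture_scale * omega)) / motif.max_score())

    modes = [
        BindingMode(motif=monomer, name="monomer",
                    activity=activity(monomer, monomer_selection, 1.0)),
        BindingMode(motif=distant, name=distant.name, cooperativity=cooperativity,
                    activity=activity(distant, distant_selection, cooperativity)),
        BindingMode(motif=close, name=close.name, cooperativity=cooperativity,
                    activity=activity(close, close_selection, cooperativity)),
    ]
    return BindingModel(modes=modes, capture_scale=capture_scale,
                        nonspecific_rate=nonspecific_rate)


# ---------------------------------------------------------------------------
# planted genomes
# ---------------------------------------------------------------------------

def _realise_pattern(rng: np.random.Generator, pattern: str) -> str:
    """One concrete ACGT sample of an IUPAC pattern (uniform over allowed)."""
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in pattern
    )


def soften_motif(motif: Motif, soft: float = 0.1, name: str | None = None) -> Motif:
    """Mix a PPM with the uniform distribution: (1-soft)*p + soft/4.

    Turns hard 0/1 consensus matrices into graded motifs whose sampled sites
    span a range of scores, as discovered motifs do.
    """
    m = (1.0 - soft) * motif.matrix + soft / 4.0
    return Motif(name=name or motif.name, matrix=m, source=motif.source,
                 dimer=motif.dimer)


def _sample_from(rng: np.random.Generator, spec: "str | Motif") -> str:
    if isinstance(spec, Motif):
        return decode(_sample_site(rng, spec, 1)[0])
    return _realise_pattern(rng, spec)


def _spec_len(spec: "str | Motif") -> int:
    return spec.length if isinstance(spec, Motif) else len(spec)


class _Occupancy:
    """Per-chromosome interval bookkeeping with rejection placement."""

    def __init__(self, chrom_sizes: dict[str, int], rng: np.random.Generator):
        self.taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
        self.sizes = chrom_sizes
        self.rng = rng

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(e <= start or end <= s for s, e in self.taken[chrom])

    def place(self, width: int, chrom: str | None = None,
              lo: int | None = None, hi: int | None = None,
              budget: int = 10) -> tuple[str, int]:
        chroms = list(self.sizes)
        for _ in range(budget):
            c = chrom or chroms[self.rng.integers(len(chroms))]
            a = 0 if lo is None else max(0, lo)
            b = self.sizes[c] if hi is None else min(self.sizes[c], hi)
            if b - a < width:
                continue
            start = int(self.rng.integers(a, b - width + 1))
            if self._free(c, start, start + width):
                self.taken[c].append((start, start + width))
                return c, start
        raise RuntimeError("could not place interval within the rejection budget")


def plant_genome(
    patterns: "dict[str, str | Motif]",
    seed: int = 0,
    genome_length: int = 2_000_000,
    n_chroms: int = 2,
    n_peaks: int = 500,
    peak_width: int = 200,
    peak_pattern_fractions: dict[str, float] | None = None,
    rank_planted_first: bool = True,
    n_tss: int = 1_000,
    tss_cre_fractions: dict[str, float] | None = None,
    promoter_offset_range: tuple[int, int] = (-1000, 0),
    background_sites_per_pattern: int = 0,
    conservation_base: float = 0.1,
    conservation_boost: float = 0.7,
    background: np.ndarray = UNIFORM_BG,
) -> tuple[GenomicAnnotation, SyntheticTruth]:
    """Synthetic genome with planted CREs, peaks, TSSs and conservation.

    Peaks are non-overlapping; ``peak_pattern_fractions`` assigns each pattern
    a fraction of peaks that receive one planted site (an exact-consensus
    sample for IUPAC-string patterns, a PPM-sampled site for Motif patterns)
    (remaining peaks stay empty).  A fraction of TSSs get a promoter CRE at an
    offset drawn in ``promoter_offset_range`` (strand-aware, gene strand).
    Conservation equals ``conservation_base`` everywhere plus
    ``conservation_boost`` exactly over planted footprints.
    """
    rng = np.random.default_rng(seed)
    chrom_len = genome_length // n_chroms
    chroms = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    genome_codes = {
        c: rng.choice(4, size=n, p=background).astype(np.int8)
        for c, n in chroms.items()
    }
    occ = _Occupancy(chroms, rng)
    records: list[dict] = []

    def plant(chrom: str, start: int, pattern_name: str, strand: str, where: str):
        site = _sample_from(rng, patterns[pattern_name])
        if strand == "-":
            from ._seq import revcomp

            site = revcomp(site)
        from ._seq import encode

        genome_codes[chrom][start:start + len(site)] = encode(site)
        records.append({"chrom": chrom, "start": start, "end": start + len(site),
                        "strand": strand, "mode": pattern_name, "where": where})

    # ----- peaks
    peak_rows = []
    for _ in range(n_peaks):
        c, s0 = occ.place(peak_width, budget=10 * n_peaks)
        peak_rows.append({"chrom": c, "start": s0, "end": s0 + peak_width})
    fractions = peak_pattern_fractions or {}
    assignment: list[str | None] = []
    for name, frac in fractions.items():
        assignment += [name] * int(round(frac * n_peaks))
    assignment += [None] * (n_peaks - len(assignment))
    if len(assignment) != n_peaks:
        raise ValueError("peak_pattern_fractions sum to more than 1")
    perm = rng.permutation(n_peaks)
    margin = 10
    for pi, ai in enumerate(perm):
        name = assignment[ai]
        row = peak_rows[pi]
        row["planted"] = name
        if name is None:
            continue
        w = _spec_len(patterns[name])
        off = int(rng.integers(margin, peak_width - w - margin + 1))
        strand = "+-"[rng.integers(2)]
        plant(row["chrom"], row["start"] + off, name, strand, "peak")
    # rank scores: planted peaks first (they emulate the strongest binding)
    order = np.arange(n_peaks)
    if rank_planted_first:
        planted_flag = np.array([r["planted"] is not None for r in peak_rows])
        order = np.concatenate([
            rng.permutation(np.nonzero(planted_flag)[0]),
            rng.permutation(np.nonzero(~planted_flag)[0]),
        ])
    scores = np.empty(n_peaks)
    scores[order] = np.arange(n_peaks, 0, -1)
    peaks = pd.DataFrame(peak_rows).drop(columns="planted")
    peaks["name"] = [f"peak{i}" for i in range(n_peaks)]
    peaks["score"] = scores

    # ----- TSSs and promoter CREs
    tss_rows = []
    cre_fracs = tss_cre_fractions or {}
    cre_names = list(cre_fracs)
    cre_probs = [cre_fracs[n] for n in cre_names]
    if sum(cre_probs) > 1 + 1e-9:
        raise ValueError("tss_cre_fractions sum to more than 1")
    for ti in range(n_tss):
        c, p0 = occ.place(1, lo=1100, hi=chrom_len - 1100,
                          budget=10 * n_tss)
        strand = "+-"[rng.integers(2)]
        tss_rows.append({"chrom": c, "pos": p0, "strand": strand,
                         "gene": f"gene{ti}"})
        u = rng.random()
        acc = 0.0
        chosen = None
        for nm, pr in zip(cre_names, cre_probs):
            acc += pr
            if u < acc:
                chosen = nm
                break
        if chosen is not None:
            w = _spec_len(patterns[chosen])
            off = int(rng.integers(promoter_offset_range[0],
                                   promoter_offset_range[1] - w + 1))
            start = p0 + off if strand == "+" else p0 - off - w
            occ.taken[c].append((start, start + w))
            plant(c, start, chosen, strand, "promoter")
    tss = pd.DataFrame(tss_rows)

    # ----- free background sites
    for name in (patterns if background_sites_per_pattern else ()):
        w = _spec_len(patterns[name])
        for _ in range(background_sites_per_pattern):
            c, s0 = occ.place(w, budget=100)
            plant(c, s0, name, "+-"[rng.integers(2)], "background")

    genome = {c: decode(codes) for c, codes in genome_codes.items()}
    conservation = {
        c: np.full(n, float(conservation_base)) for c, n in chroms.items()
    }
    for r in records:
        conservation[r["chrom"]][r["start"]:r["end"]] += conservation_boost
    annotation = GenomicAnnotation(
        genome=genome, peaks=peaks, tss=tss, conservation=conservation,
    )
    truth = SyntheticTruth(
        records=pd.DataFrame(records),
        model={"patterns": {k: (v.consensus if isinstance(v, Motif) else v)
                    for k, v in patterns.items()}, "n_peaks": n_peaks,
               "peak_width": peak_width, "n_tss": n_tss,
               "conservation_base": conservation_base,
               "conservation_boost": conservation_boost},
        seed=seed,
    )
    return annotation, truth
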