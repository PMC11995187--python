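"""Virtual-TF SELEX: retain random ligands that score above a cutoff.

Used to diagnose false-positive pattern enrichments: a library retained on a
*degenerate* motif also enriches every stricter sub-pattern contained in the
motif's consensus set, so pattern enrichment alone cannot prove an extra
binding mode (the in-silico control logic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, window_scores
from .motifs import Motif, UNIFORM_BG
from .selex import pattern_enrichment


@dataclass
class VirtualLibrary:
    """Reads retained by a virtual TF (best window log2-odds > threshold)."""

    reads: list[str]
    n_generated: int
    length: int
    score_threshold: float
    motif_name: str
    seed: int

    @property
    def retention(self) -> float:
        return len(self.reads) / self.n_generated if self.n_generated else 0.0

    def manifest(self) -> dict:
        return {
            "motif": self.motif_name,
            "n_generated": self.n_generated,
            "length": self.length,
            "score_threshold": self.score_threshold,
            "n_retained": len(self.reads),
            "retention": self.retention,
            "seed": self.seed,
        }


def simulate_virtual_tf_library(
    motif: Motif,
    n: int = 10_000_000,
    length: int = 101,
    threshold: float = 10.0,
    seed: int = 0,
    background: np.ndarray = UNIFORM_BG,
    batch_size: int = 100_000,
) -> VirtualLibrary:
    """Generate i.i.d. background reads and keep those the motif binds.

    Per-read score is the max log2-odds over all windows and both strands;
    reads with score strictly above ``threshold`` (bits) are retained.
    Generation is streamed in batches so memory is independent of ``n``.
    """
    if length < motif.length:
        raise ValueError("read length shorter than the motif")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=float)
    lut = motif.logodds_lut(bg)
    rc_lut = lut[::-1][:, [3, 2, 1, 0, 4]]
    kept: list[str] = []
    done = 0
    while done < n:
        b = min(batch_size, n - done)
        codes = rng.choice(4, size=(b, length), p=bg).astype(np.int8)
        best = np.maximum(
            window_scores(codes, lut).max(axis=1),
            window_scores(codes, rc_lut).max(axis=1),
        )
        for i in np.nonzero(best > threshold)[0]:
            kept.append(decode(codes[i]))
        done += b
    if not kept:
        warnings.warn("no reads passed the score threshold; empty virtual library")
    return VirtualLibrary(
        reads=kept, n_generated=n, length=length,
        score_threshold=threshold, motif_name=motif.name, seed=seed,
    )


def false_positive_diagnosis(
    library: VirtualLibrary,
    query_patterns: dict[str, str],
    background_reads: list[str],
    flag_fold: float = 2.0,
) -> pd.DataFrame:
    """Enrichment of query IUPAC patterns in the retained virtual library.

    A pattern enriched here is enriched *solely* through the retained motif's
    own preference — evidence that its enrichment in a real library need not
    reflect a distinct binding mode.  Rows flag folds above ``flag_fold``.
    """
    if not library.reads:
        raise ValueError("empty virtual library")
    rows = []
    for name, pattern in query_patterns.items():
        r = pattern_enrichment(pattern, library.reads, background_reads)
        rows.append(
            {"pattern_name": name, "pattern": pattern, **r,
             "flagged_false_positive": r["fold"] > flag_fold}
        )
    return pd.DataFrame(rows)
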