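"""Position weight matrices and conservation-aware promoter scanning.

PWMs from JASPAR or TRANSFAC text collections are turned into log-odds
matrices (bits) against a background base composition.  Promoters are
scored either by the best conservation-eligible hit (a window is eligible
only when every base reaches the conservation threshold) or, with no
conservation requirement, by the mean of the three highest-scoring hits.
Both strands are always scanned.

Scores handed to the enrichment stage are min-max normalised per PWM
(0 = worst possible window, 1 = consensus) so that score thresholds are
comparable across motifs of different widths and information content.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .promoters import Promoter

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: conservation thresholds used for masked scanning; None = unmasked top-3 mode
CONSERVATION_MODES = (0.7, 0.8, 0.9, 1.0, None)

__all__ = [
    "PWM",
    "parse_pwm_collection",
    "best_hit",
    "top3_mean",
    "scan_promoters",
    "MotifHit",
    "PromoterScore",
    "CONSERVATION_MODES",
]


@dataclass
class PWM:
    """A named position count matrix with background model.

    counts is a 4 x width array in A, C, G, T row order.  TRANSFAC-style
    frequency matrices (columns summing to ~1) are rescaled to a nominal
    total of 100 at parse time, so `counts` is always on a count scale.
    """

    motif_id: str
    counts: np.ndarray
    source: str = ""
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.25

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if self.width < 1:
            raise ValueError("PWM width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 strictly positive frequencies")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.pseudocount == 0 and np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("zero column sum requires a positive pseudocount")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        """Per-column base probabilities after pseudocount smoothing."""
        col = self.counts.sum(axis=0) + 4 * self.pseudocount
        return (self.counts + self.pseudocount) / col

    def log_odds(self) -> np.ndarray:
        """4 x width log2 odds matrix against the background."""
        return np.log2(self.frequencies() / self.background[:, None])

    def score_range(self) -> tuple[float, float]:
        """(min, max) achievable raw window scores."""
        lo = self.log_odds()
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds().argmax(axis=0))

    def normalize(self, raw: float) -> float:
        """Map a raw window score onto [0, 1] by the achievable range."""
        smin, smax = self.score_range()
        if smax == smin:  # zero-information matrix
            return 0.0
        return (raw - smin) / (smax - smin)


@dataclass
class MotifHit:
    promoter_id: str
    motif_id: str
    offset: int  # 0-based, promoter orientation
    strand: str  # match strand relative to the promoter, '+' or '-'
    score_bits: float


@dataclass
class PromoterScore:
    promoter_id: str
    motif_id: str
    mode: float | None  # conservation threshold, or None for top-3 mode
    score: float  # min-max normalised to [0, 1]
    eligible: bool


def _validate_bio_motif(m, source: str) -> PWM:
    counts = np.array([m.counts[b] for b in BASES], dtype=float)
    colsums = counts.sum(axis=0)
    # TRANSFAC collections mix count and frequency conventions; frequency
    # columns (sum ~ 1) are rescaled to a nominal count of 100
    if np.all(colsums > 0) and np.all(np.abs(colsums - 1.0) < 0.02):
        counts = counts * 100.0
    motif_id = m.matrix_id if getattr(m, "matrix_id", None) else m.name
    if not motif_id:
        motif_id = getattr(m, "base_id", "") or "motif"
    return PWM(motif_id=str(motif_id), counts=counts, source=source)


def parse_pwm_collection(text: str, format: str) -> list[PWM]:
    """Parse a JASPAR (multi-record PFM) or TRANSFAC matrix collection.

    Counts are preserved exactly; negative values or ragged rows raise.
    """
    fmt = format.lower()
    if fmt not in {"jaspar", "transfac"}:
        raise ValueError(f"unknown PWM format: {format!r}")
    handle = _io.StringIO(text)
    try:
        records = bio_motifs.parse(handle, "jaspar" if fmt == "jaspar" else "TRANSFAC")
        parsed = list(records)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed {fmt} matrix file: {exc}") from exc
    if not parsed:
        raise ValueError(f"no motifs found in {fmt} input")
    return [_validate_bio_motif(m, fmt) for m in parsed]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT bases become 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _window_scores(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Raw log-odds score of every window of width w on one strand.

    Windows containing ambiguous bases score the matrix column minimum at
    those positions (worst case), keeping every offset defined.
    """
    w = lo.shape[1]
    n = encoded.size - w + 1
    if n <= 0:
        return np.empty(0)
    # pad the score table with a worst-case row for non-ACGT codes
    table = np.vstack([lo, lo.min(axis=0)])
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    return table[windows, np.arange(w)].sum(axis=1)


def _revcomp_matrix(lo: np.ndarray) -> np.ndarray:
    return lo[::-1, ::-1]


def _both_strand_scores(encoded: np.ndarray, lo: np.ndarray):
    """(forward, reverse) raw scores at every offset of the promoter."""
    return _window_scores(encoded, lo), _window_scores(encoded, _revcomp_matrix(lo))


def _eligible_offsets(conservation: np.ndarray, width: int, threshold: float) -> np.ndarray:
    """Offsets whose whole window has conservation >= threshold."""
    n = conservation.size - width + 1
    if n <= 0:
        return np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(conservation, width)
    return windows.min(axis=1) >= threshold


def best_hit(
    promoter: Promoter, pwm: PWM, cons_threshold: float
) -> tuple[PromoterScore, MotifHit | None]:
    """Best conservation-eligible hit of a PWM in one promoter.

    Scans every offset on both strands; a window is eligible iff every
    base position has conservation >= ``cons_threshold``.  Ties are broken
    by smallest offset, then + strand.
    """
    if len(promoter.sequence) < pwm.width:
        raise ValueError("promoter shorter than motif")
    encoded = encode_sequence(promoter.sequence)
    fwd, rev = _both_strand_scores(encoded, pwm.log_odds())
    ok = _eligible_offsets(
        np.asarray(promoter.conservation, dtype=float), pwm.width, cons_threshold
    )
    if not ok.any():
        return (
            PromoterScore(promoter.gene_id, pwm.motif_id, cons_threshold, 0.0, False),
            None,
        )
    fwd_m = np.where(ok, fwd, -np.inf)
    rev_m = np.where(ok, rev, -np.inf)
    per_offset = np.maximum(fwd_m, rev_m)
    offset = int(per_offset.argmax())  # argmax takes the smallest offset on ties
    raw = float(per_offset[offset])
    strand = "+" if fwd_m[offset] >= rev_m[offset] else "-"
    hit = MotifHit(promoter.gene_id, pwm.motif_id, offset, strand, raw)
    return (
        PromoterScore(
            promoter.gene_id, pwm.motif_id, cons_threshold, pwm.normalize(raw), True
        ),
        hit,
    )


def top3_mean(promoter: Promoter, pwm: PWM) -> PromoterScore:
    """Unmasked promoter score: mean of the three highest window scores.

    All offsets on both strands are candidates; if fewer than three exist
    the available ones are averaged.
    """
    if len(promoter.sequence) < pwm.width:
        raise ValueError("promoter shorter than motif")
    encoded = encode_sequence(promoter.sequence)
    fwd, rev = _both_strand_scores(encoded, pwm.log_odds())
    candidates = np.concatenate([fwd, rev])
    k = min(3, candidates.size)
    top = np.sort(np.partition(candidates, candidates.size - k)[-k:])[::-1]
    return PromoterScore(
        promoter.gene_id, pwm.motif_id, None, pwm.normalize(float(top.mean())), True
    )


def scan_promoters(
    promoters: Sequence[Promoter],
    pwms: Sequence[PWM],
    modes: Iterable[float | None] = CONSERVATION_MODES,
) -> pd.DataFrame:
    """Score every promoter against every PWM under every conservation mode.

    Returns a long-form frame ``promoter_id, motif_id, mode, score,
    eligible`` with mode "none" for the unmasked top-3 scoring.  Raw
    log-odds are computed once per (promoter, PWM, strand) and reused
    across modes.
    """
    modes = list(modes)
    # per-PWM precomputation shared across promoters
    prepped = []
    for pwm in pwms:
        lo = pwm.log_odds()
        smin, smax = pwm.score_range()
        span = (smax - smin) or 1.0
        fwd_table = np.vstack([lo, lo.min(axis=0)])
        rc = _revcomp_matrix(lo)
        rev_table = np.vstack([rc, rc.min(axis=0)])
        prepped.append((pwm, fwd_table, rev_table, smin, span, np.arange(pwm.width)))

    rows: list[tuple] = []
    for prom in promoters:
        encoded = encode_sequence(prom.sequence)
        cons = np.asarray(prom.conservation, dtype=float)
        win_min_cache: dict[int, np.ndarray] = {}
        for pwm, fwd_table, rev_table, smin, span, cols in prepped:
            if encoded.size < pwm.width:
                raise ValueError(
                    f"promoter {prom.gene_id} shorter than motif {pwm.motif_id}"
                )
            windows = np.lib.stride_tricks.sliding_window_view(encoded, pwm.width)
            fwd = fwd_table[windows, cols].sum(axis=1)
            rev = rev_table[windows, cols].sum(axis=1)
            per_offset = np.maximum(fwd, rev)
            if pwm.width not in win_min_cache:
                win_min_cache[pwm.width] = (
                    np.lib.stride_tricks.sliding_window_view(cons, pwm.width).min(axis=1)
                    if cons.size >= pwm.width
                    else np.empty(0)
                )
            win_min = win_min_cache[pwm.width]
            for mode in modes:
                if mode is None:
                    candidates = np.concatenate([fwd, rev])
                    k = min(3, candidates.size)
                    top = np.sort(
                        np.partition(candidates, candidates.size - k)[-k:]
                    )[::-1]
                    norm = (float(top.mean()) - smin) / span
                    rows.append((prom.gene_id, pwm.motif_id, "none", norm, True))
                else:
                    ok = win_min >= mode
                    if ok.any():
                        norm = (float(per_offset[ok].max()) - smin) / span
                        rows.append((prom.gene_id, pwm.motif_id, mode, norm, True))
                    else:
                        rows.append((prom.gene_id, pwm.motif_id, mode, 0.0, False))
    return pd.DataFrame(
        rows, columns=["promoter_id", "motif_id", "mode", "score", "eligible"]
    )
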