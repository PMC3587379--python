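"""Position-weight-matrix scanning with core/matrix similarity scores.

Scoring follows the classic information-weighted scheme: each matrix
position i carries an information value

    I(i) = sum_b f(i,b) * ln(4 f(i,b))

(0 for a uniform column, ln 4 for a one-hot column), and a candidate site is
scored by ``Current = sum_i I(i) f(i, site_i)``, min-max normalised as

    score = (Current - Min) / (Max - Min)

where Max/Min substitute the per-position best/worst base.  The **matrix
similarity score** uses all positions; the **core score** uses only the five
consecutive positions with the highest summed information (leftmost on
ties).  Default scan cutoffs are core >= 1.0 and matrix >= 0.7; both strands
are scanned, the reverse strand by scoring the reverse complement of each
window at the same forward-strand coordinate.

TATA-, CCAAT- and GC-box annotation reuses the same scanner with bundled
consensus-derived matrices restricted to conventional upstream windows.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .seqio import (
    GenomicSequence,
    PromoterRecord,
    RelativeWindow,
    encode_sequence,
    rel_to_index,
)

CORE_LENGTH = 5


@dataclass(frozen=True)
class PWM:
    """A position frequency matrix over {A,C,G,T} (columns in that order)."""

    id: str
    name: str
    freq: np.ndarray                   # (L, 4), rows sum to 1
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise ValueError("freq must be an (L, 4) matrix with L >= 1")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"matrix {self.id!r}: rows must sum to 1")
        object.__setattr__(self, "freq", freq)

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @functools.cached_property
    def info(self) -> np.ndarray:
        return information_vector(self)

    @functools.cached_property
    def core_idx(self) -> np.ndarray:
        """The min(5, L) consecutive positions with maximal summed
        information; leftmost window on ties."""
        L = self.length
        c = min(CORE_LENGTH, L)
        sums = np.convolve(self.info, np.ones(c), mode="valid")
        start = int(np.argmax(sums))  # argmax returns the first maximum
        return np.arange(start, start + c)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.freq.argmax(axis=1))


def information_vector(pwm: PWM) -> np.ndarray:
    """Per-position information I(i) = sum_b f ln(4f), with 0 ln 0 = 0."""
    f = pwm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return term.sum(axis=1)


@dataclass(frozen=True)
class TFBSHit:
    seq_id: str
    matrix_id: str
    start: int                 # 0-based on the forward strand
    end: int                   # half-open; end - start == matrix length
    strand: str                # '+' or '-'
    core_score: float
    matrix_score: float


@dataclass(frozen=True)
class BoxAnnotation:
    seq_id: str
    box_type: str              # TATA, CCAAT or GC
    start: int
    end: int
    strand: str
    score: float               # matrix similarity score

    @property
    def matrix_score(self) -> float:
        return self.score


def _score_bounds(pwm: PWM, idx: np.ndarray) -> tuple[float, float]:
    w = pwm.info[idx, None] * pwm.freq[idx]
    return float(w.max(axis=1).sum()), float(w.min(axis=1).sum())


def match_scores(pwm: PWM, site: str) -> tuple[float, float]:
    """(core_score, matrix_score) of one candidate site of length L."""
    site = site.upper()
    if len(site) != pwm.length:
        raise ValueError(f"site length {len(site)} != matrix length {pwm.length}")
    codes = encode_sequence(site)
    if (codes < 0).any():
        raise ValueError("site contains N or non-ACGT characters")
    scores = []
    for idx in (pwm.core_idx, np.arange(pwm.length)):
        vmax, vmin = _score_bounds(pwm, idx)
        if vmax - vmin <= 0:
            warnings.warn(
                f"matrix {pwm.id!r}: uninformative positions; score defined as 1.0"
            )
            scores.append(1.0)
            continue
        cur = float((pwm.info[idx] * pwm.freq[idx, codes[idx]]).sum())
        scores.append((cur - vmin) / (vmax - vmin))
    return scores[0], scores[1]


def _scan_strand(
    pwm: PWM, windows: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (core, matrix) scores for an array of encoded windows."""
    L = pwm.length
    pos = np.arange(L)
    contrib = pwm.info[None, :] * pwm.freq[pos, np.maximum(windows, 0)]
    out = []
    for idx in (pwm.core_idx, pos):
        vmax, vmin = _score_bounds(pwm, idx)
        cur = contrib[:, idx].sum(axis=1)
        if vmax - vmin <= 0:
            s = np.ones(len(windows))
        else:
            s = (cur - vmin) / (vmax - vmin)
        out.append(np.where(valid, s, -np.inf))
    return out[0], out[1]


def scan(
    seqs,
    pwms,
    core_cut: float = 1.0,
    mss_cut: float = 0.7,
    both_strands: bool = True,
) -> list[TFBSHit]:
    """Scan sequences with matrices; report hits passing both cutoffs.

    Windows containing N are skipped.  Hits are sorted by
    (seq_id, start, matrix_id, strand).
    """
    if not 0 <= core_cut <= 1 or not 0 <= mss_cut <= 1:
        raise ValueError("cutoffs must lie in [0, 1]")
    if isinstance(seqs, (GenomicSequence, PromoterRecord, str)):
        seqs = [seqs]
    if isinstance(pwms, PWM):
        pwms = [pwms]
    hits: list[TFBSHit] = []
    for s in seqs:
        seq_id = getattr(s, "id", getattr(s, "gene_id", "seq"))
        seq = s.seq if hasattr(s, "seq") else str(s).upper()
        codes = encode_sequence(seq)
        for pwm in pwms:
            L = pwm.length
            if len(codes) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, L)
            valid = (win >= 0).all(axis=1)
            strands = [("+", win)]
            if both_strands:
                strands.append(("-", 3 - win[:, ::-1]))
            for strand, w in strands:
                core, mss = _scan_strand(pwm, w, valid)
                keep = np.flatnonzero((core >= core_cut) & (mss >= mss_cut))
                hits.extend(
                    TFBSHit(
                        seq_id, pwm.id, int(i), int(i) + L, strand,
                        float(core[i]), float(mss[i]),
                    )
                    for i in keep
                )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.matrix_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# TATA / CCAAT / GC box annotation
# ---------------------------------------------------------------------------

#: conventional upstream search windows (TSS-relative, inclusive endpoints)
DEFAULT_BOX_WINDOWS: dict[str, RelativeWindow] = {
    "TATA": RelativeWindow(-100, -1),
    "CCAAT": RelativeWindow(-200, -1),
    "GC": RelativeWindow(-200, -1),
}


def load_box_pwms() -> dict[str, PWM]:
    """Bundled consensus-derived matrices for the TATA, CCAAT and GC boxes.

    These are synthetic smoothed-consensus matrices (TATAWAW, CCAAT, GGGCGG),
    not database profiles; substitute real matrices for production scans.
    """
    from .seqio import parse_transfac_matrices

    path = resources.files("promin.data") / "box_matrices.transfac"
    with resources.as_file(path) as p:
        pwms = parse_transfac_matrices(p)
    return {pwm.name: pwm for pwm in pwms}


def annotate_boxes(
    record,
    box_pwms: dict[str, PWM] | None = None,
    tss_index: int | None = None,
    windows: dict[str, RelativeWindow] | None = None,
    core_cut: float = 0.85,
    mss_cut: float = 0.8,
) -> list[BoxAnnotation]:
    """Annotate TATA/CCAAT/GC boxes within conventional upstream windows.

    ``record`` may be a PromoterRecord (TSS declared) or any sequence with an
    explicit ``tss_index``.  Returned starts are absolute 0-based indices.
    """
    if box_pwms is None:
        box_pwms = load_box_pwms()
    if windows is None:
        windows = DEFAULT_BOX_WINDOWS
    if isinstance(record, PromoterRecord):
        seq, tss = record.seq, record.tss_index
        seq_id = record.gene_id
    else:
        seq = record.seq if hasattr(record, "seq") else str(record).upper()
        seq_id = getattr(record, "id", "seq")
        tss = tss_index
    if tss is None:
        raise ValueError("annotate_boxes needs a declared TSS")
    annotations: list[BoxAnnotation] = []
    for box_type, pwm in box_pwms.items():
        window = windows.get(box_type)
        if window is None:
            continue
        start, end = rel_to_index(window, tss, seq_len=len(seq))
        sub = GenomicSequence(seq_id, seq[start:end])
        for h in scan(sub, pwm, core_cut=core_cut, mss_cut=mss_cut):
            annotations.append(
                BoxAnnotation(
                    seq_id, box_type, h.start + start, h.end + start,
                    h.strand, h.matrix_score,
                )
            )
    annotations.sort(key=lambda a: (a.start, a.box_type))
    return annotations
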