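"""DNA duplex stability (nearest-neighbor free energy) and GC-content profiles.

The stability of a DNA duplex is approximated by summing standard free
energies of formation (ΔG°37, kcal/mol) over the overlapping dinucleotide
steps of the sequence, using the unified nearest-neighbor parameter set for
the ten unique duplex steps (AA/TT, AT/TA, TA/AT, CA/GT, GT/CA, CT/GA,
GA/CT, CG/GC, GC/CG, GG/CC).  Less negative ΔG means a less stable duplex;
promoters typically show a stability maximum (ΔG peak) just upstream of the
TSS where the AT-rich TATA region sits.

Profiles slide a fixed window (default 15 nt) along the sequence and report
the per-window step sum.  Initiation/terminal corrections are omitted by
default: every window has the same length, so constant terms cancel when
windows are compared; ``duplex_delta_g`` exposes ``include_initiation`` for
standalone thermodynamic use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import GenomicSequence, PromoterRecord, encode_sequence, pos_to_rel

#: Unified nearest-neighbor ΔG°37 (kcal/mol) for the ten unique duplex steps,
#: keyed by the top-strand dinucleotide.
DELTA_G_UNIFIED: dict[str, float] = {
    "AA": -1.00,  # AA/TT
    "AT": -0.88,  # AT/TA
    "TA": -0.58,  # TA/AT
    "CA": -1.45,  # CA/GT
    "GT": -1.44,  # GT/CA
    "CT": -1.28,  # CT/GA
    "GA": -1.30,  # GA/CT
    "CG": -2.17,  # CG/GC
    "GC": -2.24,  # GC/CG
    "GG": -1.84,  # GG/CC
}

#: Duplex initiation penalty per terminal base pair (kcal/mol).
INITIATION = {"A": 1.03, "T": 1.03, "C": 0.98, "G": 0.98}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc2(step: str) -> str:
    return _COMP[step[1]] + _COMP[step[0]]


def load_nn_table() -> dict[str, float]:
    """Return ΔG°37 for all 16 dinucleotide steps.

    The ten canonical values are closed under reverse complement (a step and
    its reverse complement describe the same duplex), so e.g.
    ``ΔG("TT") == ΔG("AA")`` and ``ΔG("AC") == ΔG("GT")``.
    """
    table = dict(DELTA_G_UNIFIED)
    for step, dg in DELTA_G_UNIFIED.items():
        table.setdefault(_rc2(step), dg)
    assert len(table) == 16
    return table


_NN_TABLE = load_nn_table()

#: ΔG indexed by 4*code(first) + code(second); order A,C,G,T.
_STEP_DG = np.array(
    [_NN_TABLE[a + b] for a in "ACGT" for b in "ACGT"], dtype=float
)


def duplex_delta_g(seq: str, include_initiation: bool = False) -> float:
    """Nearest-neighbor ΔG°37 (kcal/mol) of a duplex, from its top strand.

    The value is the sum over the ``len(seq) - 1`` overlapping dinucleotide
    steps; ``include_initiation`` adds the two terminal initiation penalties.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("duplex_delta_g needs at least 2 bases")
    codes = encode_sequence(seq)
    if (codes < 0).any():
        raise ValueError("sequence contains N or non-ACGT characters")
    dg = float(_STEP_DG[4 * codes[:-1] + codes[1:]].sum())
    if include_initiation:
        dg += INITIATION[seq[0]] + INITIATION[seq[-1]]
    return dg


@dataclass(frozen=True)
class StabilityProfile:
    """Sliding-window ΔG profile; ``positions`` are window starts (TSS-relative
    when a TSS was declared, else 0-based).  Windows containing N are NaN."""

    positions: np.ndarray
    values: np.ndarray
    window: int


@dataclass(frozen=True)
class GCProfile:
    positions: np.ndarray
    values: np.ndarray
    window: int


def _positions(n: int, tss_index: int | None) -> np.ndarray:
    idx = np.arange(n)
    if tss_index is None:
        return idx
    return np.where(idx >= tss_index, idx - tss_index + 1, idx - tss_index)


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of length-w windows; NaNs propagate to every window
    containing them."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    sums = c[w:] - c[:-w]
    if np.isnan(x).any():
        bad = np.concatenate([[0.0], np.cumsum(np.isnan(x).astype(float))])
        sums = np.where((bad[w:] - bad[:-w]) > 0, np.nan, sums)
    return sums


def _resolve(seq_or_record) -> tuple[str, int | None]:
    if isinstance(seq_or_record, PromoterRecord):
        return seq_or_record.seq, seq_or_record.tss_index
    if isinstance(seq_or_record, GenomicSequence):
        return seq_or_record.seq, None
    return str(seq_or_record).upper(), None


def stability_profile(
    seq_or_record, window: int = 15, tss_index: int | None = None
) -> StabilityProfile:
    """ΔG of every length-``window`` subsequence (step 1).

    Value *i* is :func:`duplex_delta_g` of the window starting at position
    *i*; profile length is ``len(seq) - window + 1``.  Windows touching an N
    base get NaN and are excluded from downstream averaging.
    """
    seq, tss = _resolve(seq_or_record)
    if tss_index is not None:
        tss = tss_index
    if window < 2:
        raise ValueError("stability window must be >= 2")
    if len(seq) < window:
        raise ValueError("sequence shorter than window")
    codes = encode_sequence(seq)
    step_dg = np.where(
        (codes[:-1] >= 0) & (codes[1:] >= 0),
        _STEP_DG[4 * np.maximum(codes[:-1], 0) + np.maximum(codes[1:], 0)],
        np.nan,
    )
    values = _window_sums(step_dg, window - 1)
    return StabilityProfile(_positions(len(values), tss), values, window)


def gc_profile(
    seq_or_record, window: int = 15, tss_index: int | None = None
) -> GCProfile:
    """GC fraction of every length-``window`` subsequence (NaN where N)."""
    seq, tss = _resolve(seq_or_record)
    if tss_index is not None:
        tss = tss_index
    if window < 1:
        raise ValueError("gc window must be >= 1")
    if len(seq) < window:
        raise ValueError("sequence shorter than window")
    codes = encode_sequence(seq)
    gc = np.where(codes >= 0, ((codes == 1) | (codes == 2)).astype(float), np.nan)
    values = _window_sums(gc, window) / window
    return GCProfile(_positions(len(values), tss), values, window)
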