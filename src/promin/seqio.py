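"""Sequence and matrix input/output plus the TSS-relative coordinate convention.

Coordinates are handled in two frames:

* **internal** — 0-based, half-open, the usual Python/BED convention;
* **user-facing** — relative to the transcriptional start site (TSS), where
  the TSS base is position +1, the base immediately upstream is -1, and
  *there is no position 0*.  This matches how promoter windows are quoted in
  the literature ("-200 to +100"); such a window covers 200 upstream bases
  plus 100 downstream bases = 300 bp, with both endpoints inclusive.

All sequences are uppercase over the alphabet {A, C, G, T, N}; anything else
is rejected on load.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base -> integer code used throughout the package (N and friends -> -1)
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0 C=1 G=2 T=3; N (or any other
    character) becomes -1 so downstream windows can mask it out."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _validate_alphabet(seq: str, name: str) -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(
            f"record {name!r} contains characters outside A/C/G/T/N: "
            f"{sorted(bad)}"
        )


class CpGClass(enum.Enum):
    WITH_CPG = "with_cpg"
    WITHOUT_CPG = "without_cpg"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence (uppercase, {A,C,G,T,N})."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        _validate_alphabet(self.seq, self.id)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PromoterRecord:
    """A training sequence with a declared TSS.

    ``tss_index`` is the 0-based index of the TSS base (user-facing position
    +1) within ``seq``.  ``cpg_class`` records whether the promoter carries a
    CpG island, the stratification used by the two SVM branches.
    """

    gene_id: str
    seq: str
    tss_index: int
    cpg_class: CpGClass = CpGClass.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        _validate_alphabet(self.seq, self.gene_id)
        if not 0 <= self.tss_index < len(self.seq):
            raise ValueError(
                f"tss_index {self.tss_index} out of bounds for "
                f"{self.gene_id!r} (length {len(self.seq)})"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def window_seq(self, window: "RelativeWindow") -> str:
        start, end = rel_to_index(window, self.tss_index, seq_len=len(self.seq))
        return self.seq[start:end]


@dataclass(frozen=True)
class RelativeWindow:
    """A TSS-relative window with inclusive, nonzero endpoints."""

    start_rel: int
    end_rel: int

    def __post_init__(self) -> None:
        if self.start_rel == 0 or self.end_rel == 0:
            raise ValueError("TSS-relative positions are nonzero (TSS is +1)")
        if self.start_rel > self.end_rel:
            raise ValueError(
                f"start_rel {self.start_rel} must not follow end_rel {self.end_rel}"
            )

    @property
    def length(self) -> int:
        span = self.end_rel - self.start_rel + 1
        if self.start_rel < 0 < self.end_rel:
            span -= 1  # no position 0
        return span

    def __str__(self) -> str:  # "-200..+100"
        return f"{self.start_rel:+d}..{self.end_rel:+d}"


def rel_to_pos(rel: int, tss_index: int) -> int:
    """Map one TSS-relative position (no 0) to a 0-based index."""
    if rel == 0:
        raise ValueError("position 0 does not exist in TSS-relative coordinates")
    return tss_index + rel - 1 if rel > 0 else tss_index + rel


def pos_to_rel(idx: int, tss_index: int) -> int:
    """Inverse of :func:`rel_to_pos`."""
    return idx - tss_index + 1 if idx >= tss_index else idx - tss_index


def rel_to_index(
    window: RelativeWindow, tss_index: int, seq_len: int | None = None
) -> tuple[int, int]:
    """Resolve a relative window to internal 0-based half-open indices.

    ``window(-200, +100)`` at ``tss_index=3000`` resolves to ``(2800, 3100)``
    (length 300).  When ``seq_len`` is given, out-of-bounds windows raise.
    """
    start = rel_to_pos(window.start_rel, tss_index)
    end = rel_to_pos(window.end_rel, tss_index) + 1
    if start < 0 or (seq_len is not None and end > seq_len):
        raise ValueError(
            f"window {window} at tss_index {tss_index} falls outside the "
            f"sequence (resolved {start}:{end}, length {seq_len})"
        )
    return start, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a (multi-)FASTA file into :class:`GenomicSequence` records.

    Sequences are uppercased; characters outside {A,C,G,T,N} raise a
    ``ValueError`` naming the offending record.  An empty file raises.
    """
    records = [
        GenomicSequence(rec.id, str(rec.seq))
        for rec in _BioSeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    _BioSeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TRANSFAC flat-file matrices
# ---------------------------------------------------------------------------

def parse_transfac_matrices(path: str | Path):
    """Parse a TRANSFAC flat-file of count (or frequency) matrices.

    Blocks are delimited by ``//``; each block carries ``ID``/``NA`` lines and
    a ``P0  A C G T`` header followed by numbered rows.  Count matrices
    (row sums > 1.5) are converted to frequencies with a small pseudocount of
    ``0.01 * (row_total + 1) / 4`` per cell, then renormalised, so one-hot
    columns never produce log(0) in information vectors.

    Returns a list of :class:`promin.pwmscan.PWM`.
    """
    from .pwmscan import PWM  # deferred: avoids a circular import

    text = Path(path).read_text()
    blocks: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.startswith("//"):
            blocks.append([])
        else:
            blocks[-1].append(line.rstrip())

    pwms = []
    for block in blocks:
        if not any(l.strip() for l in block):
            continue
        mat_id = name = None
        order: list[str] | None = None
        rows: list[list[float]] = []
        for line in block:
            tokens = line.split()
            if not tokens:
                continue
            tag = tokens[0]
            if tag in ("ID", "AC") and mat_id is None and len(tokens) > 1:
                mat_id = tokens[1]
            elif tag == "NA" and len(tokens) > 1:
                name = " ".join(tokens[1:])
            elif tag in ("P0", "PO"):
                order = [t.upper() for t in tokens[1:5]]
                if sorted(order) != ["A", "C", "G", "T"]:
                    raise ValueError(
                        f"bad P0 column header in matrix {mat_id!r}: {order}"
                    )
            elif tag.isdigit() and order is not None:
                vals = [float(t) for t in tokens[1:5]]
                if len(vals) != 4:
                    raise ValueError(
                        f"matrix {mat_id!r} row {tag} has {len(vals)} values"
                    )
                rows.append(vals)
        if order is None:
            raise ValueError(f"matrix block {mat_id!r} lacks a P0 header")
        if not rows:
            raise ValueError(f"matrix {mat_id!r} has zero length")
        counts = np.array(rows, dtype=float)
        # reorder columns to A,C,G,T
        counts = counts[:, [order.index(b) for b in "ACGT"]]
        totals = counts.sum(axis=1)
        spread = totals.max() - totals.min()
        if totals.max() > 1.5 and spread > 0.05 * max(totals.mean(), 1.0):
            warnings.warn(
                f"matrix {mat_id!r}: row totals vary ({totals.min():g}"
                f"-{totals.max():g}); treating rows independently"
            )
        pseudo = 0.01 * (totals[:, None] + 1.0) / 4.0
        freq = (counts + pseudo) / (counts + pseudo).sum(axis=1, keepdims=True)
        pwms.append(
            PWM(
                id=mat_id or f"M{len(pwms):05d}",
                name=name or (mat_id or ""),
                freq=freq,
                counts=counts,
            )
        )
    if not pwms:
        raise ValueError(f"no matrices found in {path}")
    return pwms


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------

def write_hits_bed(hits: Sequence, path: str | Path, header: str | None = None) -> None:
    """Write scan hits as BED6 (score = matrix score scaled to 0-1000)."""
    lines = []
    if header:
        lines.append(f"# {header}")
    for h in hits:
        start, end = int(h.start), int(h.end)
        if end <= start:
            raise ValueError(f"hit with end {end} <= start {start}")
        score = getattr(h, "matrix_score", getattr(h, "score", 0.0))
        name = getattr(h, "matrix_id", getattr(h, "box_type", "hit"))
        strand = getattr(h, "strand", ".")
        lines.append(
            f"{h.seq_id}\t{start}\t{end}\t{name}\t"
            f"{int(round(1000 * min(max(score, 0.0), 1.0)))}\t{strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
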