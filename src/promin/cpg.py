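"""CpG island detection.

Islands are the classic criteria: length >= 500 bp, G+C fraction >= 0.5, and
observed/expected CpG ratio >= 0.6, where

    obs/exp = (#CG dinucleotides * region length) / (#C * #G)

Detection seeds every minimum-length window satisfying all three criteria,
merges overlapping seeds into maximal regions, and trims a merged region
from its ends (rarely needed) until the region itself satisfies the
criteria.  N bases count as neither C nor G and break CpG dinucleotides.

Island presence around the candidate window is what routes a sequence to the
with-CpG or without-CpG branch of the promoter classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import PromoterRecord, RelativeWindow, rel_to_index


@dataclass(frozen=True)
class CpGIsland:
    start: int          # 0-based, half-open
    end: int
    gc: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start

    # duck-typing for write_hits_bed
    @property
    def seq_id(self) -> str:
        return getattr(self, "_seq_id", "seq")

    @property
    def score(self) -> float:
        return min(self.obs_exp / 2.0, 1.0)

    @property
    def box_type(self) -> str:
        return "CpG_island"

    strand = "."


def _region_stats(cum_c, cum_g, cum_cg, start: int, end: int) -> tuple[float, float]:
    w = end - start
    n_c = cum_c[end] - cum_c[start]
    n_g = cum_g[end] - cum_g[start]
    # a CG dinucleotide at position i (i, i+1) belongs to [start, end) iff
    # start <= i <= end - 2
    n_cg = cum_cg[max(end - 1, start)] - cum_cg[start]
    gc = (n_c + n_g) / w
    oe = (n_cg * w) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    seq: str,
    min_length: int = 500,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
) -> list[CpGIsland]:
    """Maximal non-overlapping CpG islands of a sequence (case-insensitive)."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    seq = (seq.seq if hasattr(seq, "seq") else str(seq)).upper()
    L = len(seq)
    if L < min_length:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cg = np.zeros(L, dtype=bool)
    is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    w = min_length
    starts = np.arange(L - w + 1)
    n_c = cum_c[starts + w] - cum_c[starts]
    n_g = cum_g[starts + w] - cum_g[starts]
    n_cg = cum_cg[starts + w - 1] - cum_cg[starts]
    gc = (n_c + n_g) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cg * w / (n_c * n_g), 0.0)
    passing = starts[(gc >= gc_min) & (oe >= oe_min)]
    if len(passing) == 0:
        return []

    # merge overlapping seed windows [s, s + w)
    merged: list[list[int]] = [[int(passing[0]), int(passing[0]) + w]]
    for s in passing[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = int(s) + w
        else:
            merged.append([int(s), int(s) + w])

    islands = []
    for start, end in merged:
        gc_r, oe_r = _region_stats(cum_c, cum_g, cum_cg, start, end)
        # trim ends until the merged region itself meets the criteria
        while (gc_r < gc_min or oe_r < oe_min) and end - start > min_length:
            gc_l, oe_l = _region_stats(cum_c, cum_g, cum_cg, start + 1, end)
            gc_t, oe_t = _region_stats(cum_c, cum_g, cum_cg, start, end - 1)
            if min(gc_l - gc_min, oe_l - oe_min) >= min(gc_t - gc_min, oe_t - oe_min):
                start += 1
                gc_r, oe_r = gc_l, oe_l
            else:
                end -= 1
                gc_r, oe_r = gc_t, oe_t
        if gc_r >= gc_min and oe_r >= oe_min:
            islands.append(CpGIsland(start, end, gc_r, oe_r))
    return islands


def has_cpg_island(
    record: PromoterRecord,
    window: RelativeWindow,
    islands: list[CpGIsland] | None = None,
    **kwargs,
) -> bool:
    """True iff a detected CpG island overlaps the resolved window by >= 1 bp."""
    start, end = rel_to_index(window, record.tss_index, seq_len=len(record.seq))
    if islands is None:
        islands = find_cpg_islands(record.seq, **kwargs)
    return any(isl.start < end and isl.end > start for isl in islands)
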