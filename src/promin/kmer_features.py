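"""Nucleotide-composition profiling and over-represented oligonucleotides.

Three related feature families live here:

* positional **k-mer occurrence-rate profiles** (k = 1, 2, 3) in a 20-bp
  window sliding along TSS-aligned training sequences, plus their Pearson
  clustering into an adenine-like and a guanine-like group (a diagnostic of
  the two dominant compositional trends around mammalian TSSs);
* **hexamer Z-scores**: each of the 4096 hexamers is counted (overlapping)
  in a pool of promoter windows and compared with its expected frequency
  under a background model, ``z = (n - Np) / sqrt(Np(1-p))`` — the top-z
  hexamers become SVM features;
* general **over-represented oligonucleotides** (6-12 bp, Z > 5 by default)
  reported as promoter annotations.

The genome-wide background of the original analysis is replaced by a Markov
background model (order 0-2) fitted to a user-supplied background sequence
set, the closest estimable surrogate.  Occurrences are pooled across
windows, and self-overlap variance inflation is deliberately not corrected.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import GenomicSequence, PromoterRecord, encode_sequence

BASES = "ACGT"


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def count_overlapping(seq: str, word: str) -> int:
    """Number of (possibly overlapping) occurrences of word in seq."""
    count = start = 0
    while True:
        i = seq.find(word, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each overlapping k-mer; -1 where any base is N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        out = out * 4 + np.maximum(c, 0)
        bad |= c < 0
    out[bad] = -1
    return out


# ---------------------------------------------------------------------------
# Background models
# ---------------------------------------------------------------------------

class BackgroundModel:
    """Markov background model (order 0, 1 or 2) over {A,C,G,T}.

    ``prob(word)`` returns the stationary probability of observing ``word``
    at a fixed position: the empirical frequency of its leading context
    times the product of transition probabilities.
    """

    def __init__(self, order: int, context_probs: np.ndarray, trans: np.ndarray):
        if order < 0 or order > 2:
            raise ValueError("background order must be 0, 1 or 2")
        self.order = order
        self._ctx = context_probs          # shape (4**order,)
        self._trans = trans                # shape (4**order, 4)

    @classmethod
    def from_base_probs(cls, probs) -> "BackgroundModel":
        """Order-0 model from explicit base probabilities (A, C, G, T)."""
        p = np.asarray(probs, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("need 4 base probabilities summing to 1")
        return cls(0, np.ones(1), p[None, :])

    @classmethod
    def fit(cls, seqs, order: int = 0) -> "BackgroundModel":
        """Fit from sequences (strings, GenomicSequence or PromoterRecord)."""
        ctx_counts = np.zeros(4 ** order, dtype=float)
        trans_counts = np.zeros((4 ** order, 4), dtype=float)
        for s in seqs:
            seq = s.seq if hasattr(s, "seq") else str(s).upper()
            codes = encode_sequence(seq)
            kcodes = _kmer_codes(codes, order + 1)
            valid = kcodes[kcodes >= 0]
            np.add.at(trans_counts, (valid // 4, valid % 4), 1.0)
        ctx_counts = trans_counts.sum(axis=1)
        if ctx_counts.sum() == 0:
            raise ValueError("no usable (N-free) positions in background")
        ctx = ctx_counts / ctx_counts.sum()
        with np.errstate(invalid="ignore"):
            trans = trans_counts / np.where(
                ctx_counts[:, None] > 0, ctx_counts[:, None], 1.0
            )
        trans[ctx_counts == 0] = 0.25  # unseen context: uniform
        return cls(order, ctx, trans)

    def prob(self, word: str) -> float:
        """Probability of observing ``word`` at a position under the model."""
        codes = encode_sequence(word.upper())
        if (codes < 0).any():
            raise ValueError("word contains non-ACGT characters")
        if len(word) <= self.order:
            # marginalise the context distribution
            p = 0.0
            m = self.order
            for ctx_code in range(4 ** m):
                digits = [(ctx_code // 4 ** (m - 1 - j)) % 4 for j in range(m)]
                if digits[: len(codes)] == list(codes):
                    p += self._ctx[ctx_code]
            return float(p)
        ctx_code = 0
        for c in codes[: self.order]:
            ctx_code = ctx_code * 4 + int(c)
        p = float(self._ctx[ctx_code]) if self.order else 1.0
        for c in codes[self.order :]:
            p *= float(self._trans[ctx_code, int(c)])
            ctx_code = (ctx_code * 4 + int(c)) % (4 ** self.order) if self.order else 0
        return p


# ---------------------------------------------------------------------------
# Positional k-mer rate profiles and their clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerRateProfile:
    k: int
    window: int
    positions: np.ndarray           # TSS-relative window starts
    rates: np.ndarray               # (n_positions, 4**k), averaged over records
    labels: tuple[str, ...]

    def profile(self, kmer: str) -> np.ndarray:
        return self.rates[:, self.labels.index(kmer.upper())]


def kmer_rate_profile(
    records, k: int, window: int = 20, step: int = 1
) -> KmerRateProfile:
    """Average positional occurrence rates of all 4**k k-mers.

    Rate of k-mer *w* in a window = occurrences of *w* among the
    ``window - k + 1`` overlapping positions divided by that position count;
    rates are averaged across records position-wise.  Records must share a
    length and (when present) a TSS index so position grids align.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if window < k:
        raise ValueError("window smaller than k")
    records = list(records)
    if not records:
        raise ValueError("no records")
    lengths = {len(r.seq) if hasattr(r, "seq") else len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError("records must share one length")
    L = lengths.pop()
    tss = {r.tss_index for r in records if isinstance(r, PromoterRecord)}
    if len(tss) > 1:
        raise ValueError("records must share one TSS index")
    tss_index = tss.pop() if tss else None

    nk = 4 ** k
    per_win = window - k + 1
    starts = np.arange(0, L - window + 1, step)
    total = np.zeros((len(starts), nk))
    nvalid = np.zeros(len(starts))
    for r in records:
        seq = r.seq if hasattr(r, "seq") else str(r).upper()
        kcodes = _kmer_codes(encode_sequence(seq), k)
        M = np.zeros((nk + 1, len(kcodes)))
        M[np.where(kcodes >= 0, kcodes, nk), np.arange(len(kcodes))] = 1.0
        csum = np.concatenate(
            [np.zeros((nk + 1, 1)), np.cumsum(M, axis=1)], axis=1
        )
        counts = csum[:, starts + per_win] - csum[:, starts]
        ok = counts[nk] == 0  # no N anywhere in the window
        total[ok] += counts[:nk, ok].T / per_win
        nvalid += ok
    with np.errstate(invalid="ignore"):
        rates = total / np.where(nvalid[:, None] > 0, nvalid[:, None], np.nan)
    positions = starts if tss_index is None else np.where(
        starts >= tss_index, starts - tss_index + 1, starts - tss_index
    )
    return KmerRateProfile(k, window, positions, rates, tuple(all_kmers(k)))


@dataclass(frozen=True)
class ProfileClusters:
    """The 84 mono/di/tri-mer profiles split into an adenine-anchored and a
    guanine-anchored group by Pearson correlation with the two anchors."""

    group_A: tuple[str, ...]
    group_G: tuple[str, ...]
    correlations: pd.DataFrame      # index kmer, columns r_A, r_G


def cluster_profiles(profiles: dict[str, np.ndarray]) -> ProfileClusters:
    """Assign each k-mer profile to the anchor (A or G mononucleotide
    profile) it correlates with more strongly."""
    for anchor in ("A", "G"):
        if anchor not in profiles:
            raise ValueError(f"anchor profile {anchor!r} missing")
    a, g = np.asarray(profiles["A"]), np.asarray(profiles["G"])
    rows, grp_a, grp_g = {}, [], []
    for kmer in sorted(profiles, key=lambda w: (len(w), w)):
        v = np.asarray(profiles[kmer], dtype=float)
        if np.nanstd(v) == 0:
            gc = sum(b in "GC" for b in kmer) / len(kmer)
            r_a = r_g = np.nan
            target = grp_g if gc >= 0.5 else grp_a
            warnings.warn(f"constant profile for {kmer}; assigned by GC content")
        else:
            r_a = _pearson(v, a)
            r_g = _pearson(v, g)
            if r_a == r_g:
                warnings.warn(f"correlation tie for {kmer}; assigned to group A")
            target = grp_a if r_a >= r_g else grp_g
        target.append(kmer)
        rows[kmer] = (r_a, r_g)
    corr = pd.DataFrame.from_dict(rows, orient="index", columns=["r_A", "r_G"])
    return ProfileClusters(tuple(grp_a), tuple(grp_g), corr)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


# ---------------------------------------------------------------------------
# Over-represented words
# ---------------------------------------------------------------------------

def _pooled_counts(windows, k: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    n_positions = 0
    for w in windows:
        seq = w.seq if hasattr(w, "seq") else str(w).upper()
        kcodes = _kmer_codes(encode_sequence(seq), k)
        valid = kcodes[kcodes >= 0]
        counts.update(valid.tolist())
        n_positions += len(valid)
    return counts, n_positions


def _zscore(n: np.ndarray, N: int, p: np.ndarray) -> np.ndarray:
    expected = N * p
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (n - expected) / np.sqrt(expected * (1.0 - p))
    z = np.where((p <= 0) & (n == 0), 0.0, z)
    z = np.where((p <= 0) & (n > 0), np.inf, z)
    return z


def hexamer_zscores(promoter_windows, background: BackgroundModel) -> pd.DataFrame:
    """Z-scores of all 4096 hexamers in a pool of promoter windows.

    n = pooled overlapping occurrences, N = pooled scanned positions,
    p = background probability; z = (n - Np)/sqrt(Np(1-p)).  A hexamer with
    background probability 0 but nonzero count gets z = +inf (flagged by the
    ``p_zero`` column).
    """
    counts, N = _pooled_counts(promoter_windows, 6)
    hexamers = all_kmers(6)
    n = np.array([counts.get(i, 0) for i in range(4096)], dtype=float)
    p = np.array([background.prob(w) for w in hexamers])
    z = _zscore(n, N, p)
    return pd.DataFrame(
        {"n": n.astype(int), "p": p, "expected": N * p, "z": z,
         "p_zero": p <= 0},
        index=pd.Index(hexamers, name="hexamer"),
    )


def top_hexamers(stats: pd.DataFrame, n: int = 100) -> list[str]:
    """The n highest-z hexamers, ties broken lexicographically."""
    finite = stats[np.isfinite(stats["z"])]
    if n > len(finite):
        raise ValueError(f"asked for {n} hexamers but only {len(finite)} have finite z")
    # stable sort on a lexicographically pre-sorted index implements the
    # "ties break alphabetically" rule regardless of input order
    order = finite.sort_index().sort_values(
        by="z", ascending=False, kind="mergesort"
    )
    return list(order.index[:n])


@dataclass(frozen=True)
class OverrepOligo:
    oligo: str
    n: int
    p: float
    z: float


def overrep_oligos(
    promoter_regions,
    background: BackgroundModel,
    kmin: int = 6,
    kmax: int = 12,
    zthresh: float = 5.0,
) -> pd.DataFrame:
    """Over-represented oligonucleotides of length kmin..kmax (z > zthresh).

    Only oligos actually observed in the regions can exceed the threshold,
    so counting is restricted to observed words.
    """
    if kmin > kmax:
        raise ValueError("kmin > kmax")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    rows = []
    for k in range(kmin, kmax + 1):
        counts, N = _pooled_counts(promoter_regions, k)
        if N == 0:
            continue
        codes = np.array(sorted(counts), dtype=np.int64)
        n = np.array([counts[c] for c in codes], dtype=float)
        words = ["".join(BASES[(c >> (2 * (k - 1 - j))) & 3] for j in range(k))
                 for c in codes]
        p = np.array([background.prob(w) for w in words])
        z = _zscore(n, N, p)
        for w, ni, pi, zi in zip(words, n, p, z):
            if zi > zthresh:
                rows.append((w, k, int(ni), pi, zi))
    df = pd.DataFrame(rows, columns=["oligo", "k", "n", "p", "z"])
    return df.sort_values(["z", "oligo"], ascending=[False, True]).reset_index(
        drop=True
    )
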