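"""Synthetic promoter-like data with controllable planted structure.

Every generator is a pure function of its seed, so all tests and benchmarks
run without external sequence databases.  The promoter generator emulates
the structure of mammalian TSS-flanking training data:

* i.i.d. background flanks at a mammalian-like GC content (0.41 by default)
  extending ``flank`` bp (default 3000) on each side of the TSS;
* a TATA-box cassette sampled from the TATAWAW consensus at a configurable
  per-base strength, planted at -31..-25;
* a set of promoter-typical hexamers overwritten at random positions within
  -200..+100 at a configurable embedding rate (default 0.8);
* for WITH_CPG records, a 700-bp GC-rich segment (P(C)=P(G)=0.33) spanning
  the TSS, which makes G+C ~0.66 and CpG obs/exp ~1 — comfortably above the
  island detector's thresholds;
* a TA-repeat-like -45..-15 segment ("stability dip"): TA/AT steps carry
  the weakest nearest-neighbor free energies, so the segment raises the ΔG
  profile (least-negative free energy) just upstream of the TSS above
  anything background stretches produce.

Gene-group generation plants a jointly embedded TF consensus set in the
observed promoters and sprinkles the same TFs independently at a low rate
into a background panel, mimicking a co-regulated gene group against a
genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pwmscan import PWM
from .seqio import CpGClass, GenomicSequence, PromoterRecord, rel_to_pos

BASES = np.array(list("ACGT"))

DEFAULT_HEXAMERS = (
    "TATAAA", "CCAATC", "GGGCGG", "CACGTG",
    "TGACTC", "GCCACG", "CTGCGC", "AATAAA",
)

TATA_CONSENSUS = "TATAWAW"


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def gen_background(
    n: int, length: int, gc: float = 0.41, seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[GenomicSequence]:
    """n i.i.d. background sequences with P(G)+P(C) = gc."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly within (0, 1)")
    rng = rng or np.random.default_rng(seed)
    probs = _base_probs(gc)
    return [
        GenomicSequence(f"bg{i:04d}", _random_seq(rng, length, probs))
        for i in range(n)
    ]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic promoter generator (defaults are the study
    conditions: strongly separable planted structure)."""

    seed: int = 0
    n_records: int = 50
    flank: int = 3000                      # bp each side of the TSS
    gc: float = 0.41
    cpg_class: CpGClass = CpGClass.WITHOUT_CPG
    planted_hexamers: tuple[str, ...] = DEFAULT_HEXAMERS
    embedding_rate: float = 0.8            # per-hexamer, per-record
    hexamer_window: tuple[int, int] = (-200, 100)
    tata_start: int = -31                  # TSS-relative start of TATAWAW
    tata_strength: float = 0.9             # per-base consensus probability
    stability_dip: bool = True
    dip_window: tuple[int, int] = (-45, -15)
    dip_strength: float = 0.95             # per-base TA-pattern probability
    cpg_span: tuple[int, int] = (-350, 350)
    cpg_gc: float = 0.66

    def __post_init__(self) -> None:
        for p in (self.embedding_rate, self.tata_strength):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.flank < 400:
            raise ValueError("flank must cover the largest candidate window")


def _sample_tata(rng: np.random.Generator, strength: float) -> str:
    out = []
    for c in TATA_CONSENSUS:
        if rng.random() < strength:
            out.append("AT"[rng.integers(2)] if c == "W" else c)
        else:
            out.append(BASES[rng.integers(4)])
    return "".join(out)


def _overwrite(seq: list[str], start: int, insert: str) -> None:
    if start < 0 or start + len(insert) > len(seq):
        raise ValueError("planted element overlaps a sequence end")
    seq[start : start + len(insert)] = list(insert)


def gen_promoters(config: GeneratorConfig) -> list[PromoterRecord]:
    """Promoter records of length 2*flank + 1 with TSS at index flank."""
    rng = np.random.default_rng(config.seed)
    probs = _base_probs(config.gc)
    tss = config.flank
    length = 2 * config.flank + 1
    records = []
    for i in range(config.n_records):
        seq = list(_random_seq(rng, length, probs))
        used: list[tuple[int, int]] = []
        if config.cpg_class is CpGClass.WITH_CPG:
            a = rel_to_pos(config.cpg_span[0], tss)
            b = rel_to_pos(config.cpg_span[1], tss) + 1
            _overwrite(seq, a, _random_seq(rng, b - a, _base_probs(config.cpg_gc)))
        if config.stability_dip:
            a = rel_to_pos(config.dip_window[0], tss)
            b = rel_to_pos(config.dip_window[1], tss) + 1
            dip = [
                "TA"[j % 2]
                if rng.random() < config.dip_strength
                else BASES[rng.integers(4)]
                for j in range(b - a)
            ]
            _overwrite(seq, a, "".join(dip))
            used.append((a, b))
        tata_idx = rel_to_pos(config.tata_start, tss)
        _overwrite(seq, tata_idx, _sample_tata(rng, config.tata_strength))
        used.append((tata_idx, tata_idx + len(TATA_CONSENSUS)))
        lo = rel_to_pos(config.hexamer_window[0], tss)
        hi = rel_to_pos(config.hexamer_window[1], tss) + 1
        for hexamer in config.planted_hexamers:
            if rng.random() >= config.embedding_rate:
                continue
            for _ in range(100):
                p = int(rng.integers(lo, hi - 6))
                if all(p + 6 <= s or p >= e for s, e in used):
                    _overwrite(seq, p, hexamer)
                    used.append((p, p + 6))
                    break
        records.append(
            PromoterRecord(f"syn{i:04d}", "".join(seq), tss, config.cpg_class)
        )
    return records


def gen_pwm(
    length: int, informativeness: float, seed: int | None = 0,
    rng: np.random.Generator | None = None, pwm_id: str = "SYN",
) -> PWM:
    """A synthetic PWM: Dirichlet columns interpolated toward a random
    consensus; informativeness 1 gives one-hot columns, 0 near-uniform."""
    if length < 4:
        raise ValueError("pwm length must be >= 4")
    if not 0.0 <= informativeness <= 1.0:
        raise ValueError("informativeness must lie in [0, 1]")
    rng = rng or np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=length)
    freq = rng.dirichlet(np.ones(4), size=length)
    onehot = np.eye(4)[consensus]
    f = informativeness * onehot + (1.0 - informativeness) * freq
    f /= f.sum(axis=1, keepdims=True)
    return PWM(id=pwm_id, name=pwm_id, freq=f)


def gen_gene_group(
    pwms: list[PWM],
    co_set: list[str],
    n_genes: int = 10,
    embed_prob: float = 0.9,
    background_n: int = 100,
    bg_embed_rate: float = 0.05,
    decoy_rate: float = 0.3,
    length: int = 500,
    gc: float = 0.41,
    seed: int = 0,
) -> tuple[list[GenomicSequence], list[GenomicSequence]]:
    """(observed, background) promoter panels with a planted co-occurring
    TF set.

    Observed promoters embed one consensus site of *every* co_set TF jointly
    with probability ``embed_prob``; other TFs appear as decoys at
    ``decoy_rate``.  Background promoters embed each TF independently at
    ``bg_embed_rate``.
    """
    ids = {p.id for p in pwms}
    if not set(co_set) <= ids:
        raise ValueError("co_set must be a subset of the provided matrices")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0.0 < embed_prob <= 1.0:
        raise ValueError("embed_prob must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    probs = _base_probs(gc)
    by_id = {p.id: p for p in pwms}

    def plant(seq: list[str], pwm: PWM, used: list[tuple[int, int]]) -> None:
        for _ in range(100):
            p = int(rng.integers(0, len(seq) - pwm.length + 1))
            if all(p + pwm.length <= s or p >= e for s, e in used):
                _overwrite(seq, p, pwm.consensus)
                used.append((p, p + pwm.length))
                return

    observed = []
    for i in range(n_genes):
        seq = list(_random_seq(rng, length, probs))
        used: list[tuple[int, int]] = []
        if rng.random() < embed_prob:
            for tf in co_set:
                plant(seq, by_id[tf], used)
        for pwm in pwms:
            if pwm.id not in co_set and rng.random() < decoy_rate:
                plant(seq, pwm, used)
        observed.append(GenomicSequence(f"obs{i:04d}", "".join(seq)))
    background = []
    for i in range(background_n):
        seq = list(_random_seq(rng, length, probs))
        used = []
        for pwm in pwms:
            if rng.random() < bg_embed_rate:
                plant(seq, pwm, used)
        background.append(GenomicSequence(f"bgp{i:04d}", "".join(seq)))
    return observed, background
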