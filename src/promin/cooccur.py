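"""Co-occurrence mining of TF binding sites in a gene group.

Each promoter of the group becomes a *transaction*: the set of TF matrix
identifiers with at least one binding-site hit in that promoter.  Frequent
TF combinations are mined levelwise (Apriori) under user-set support and
confidence thresholds (defaults 0.9/0.9), and every combination of size >= 2
is tested for enrichment against a background promoter set scanned with the
same parameters, using the hypergeometric upper tail

    P(t) = sum_{i=t}^{min(T,k)} C(T,i) C(K-T, k-i) / C(K,k)

where K = background promoters, T = observed promoters, k = background
promoters containing the combination, t = observed promoters containing it.
Small P marks combinations unexpectedly frequent in the observed group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy import stats as _stats


@dataclass(frozen=True)
class Transaction:
    promoter_id: str
    items: frozenset


def build_transactions(hits, promoter_ids=None) -> list[Transaction]:
    """One transaction per promoter; items are the distinct matrix ids hit.

    ``promoter_ids`` lists promoters to retain even with zero hits (their
    transactions are empty); defaults to the ids present in ``hits``.
    """
    by_prom: dict[str, set] = {}
    if promoter_ids is not None:
        for pid in promoter_ids:
            by_prom[pid] = set()
    for h in hits:
        by_prom.setdefault(h.seq_id, set()).add(h.matrix_id)
    return [Transaction(pid, frozenset(items)) for pid, items in by_prom.items()]


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float


def _normalize_frac(x: float, name: str) -> float:
    """Accept percent-style (90) or fractional (0.9) thresholds."""
    if x > 1.0:
        if x > 100.0:
            raise ValueError(f"{name} must be <= 100")
        x = x / 100.0
    if not 0.0 < x <= 1.0:
        raise ValueError(f"{name} must lie in (0, 1] (or (0, 100] as percent)")
    return x


def _itemset_key(s: frozenset):
    return (len(s), tuple(sorted(s)))


def apriori(
    transactions,
    min_support: float = 0.9,
    min_confidence: float = 0.9,
) -> tuple[dict[frozenset, float], list[AssociationRule]]:
    """Levelwise frequent-itemset mining plus association rules.

    Returns ``(supports, rules)``: supports maps each frequent itemset to
    its support (fraction of transactions containing it); rules are all
    A => B with frequent A ∪ B and confidence support(A∪B)/support(A) >=
    min_confidence.  Ordering is deterministic: itemsets by (size, support
    desc, lexical); rules likewise by their underlying itemset.
    """
    min_support = _normalize_frac(min_support, "min_support")
    min_confidence = _normalize_frac(min_confidence, "min_confidence")
    txns = [t.items if isinstance(t, Transaction) else frozenset(t) for t in transactions]
    n = len(txns)
    if n == 0:
        return {}, []

    def support_count(itemset: frozenset) -> int:
        return sum(1 for t in txns if itemset <= t)

    supports: dict[frozenset, float] = {}
    # level 1
    items = sorted({i for t in txns for i in t})
    level = []
    for it in items:
        s = support_count(frozenset([it]))
        if s / n >= min_support:
            fs = frozenset([it])
            supports[fs] = s / n
            level.append(fs)
    # levelwise join + prune
    k = 2
    while level:
        prev = {tuple(sorted(s)) for s in level}
        candidates = set()
        level_sorted = sorted(prev)
        for a, b in combinations(level_sorted, 2):
            if a[:-1] == b[:-1]:
                cand = tuple(sorted(set(a) | set(b)))
                if all(
                    tuple(sorted(set(cand) - {x})) in prev for x in cand
                ):
                    candidates.add(frozenset(cand))
        level = []
        for cand in candidates:
            s = support_count(cand)
            if s / n >= min_support:
                supports[cand] = s / n
                level.append(cand)
        k += 1

    rules: list[AssociationRule] = []
    for itemset in sorted(supports, key=_itemset_key):
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(sorted(itemset), r):
                a = frozenset(ante)
                conf = supports[itemset] / supports[a]
                if conf >= min_confidence:
                    rules.append(
                        AssociationRule(a, itemset - a, supports[itemset], conf)
                    )
    ordered = dict(
        sorted(supports.items(), key=lambda kv: (len(kv[0]), -kv[1], tuple(sorted(kv[0]))))
    )
    return ordered, rules


# ---------------------------------------------------------------------------
# Hypergeometric significance
# ---------------------------------------------------------------------------

def hypergeom_p(K: int, T: int, k: int, t: int, exact: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= t).

    X counts observed promoters carrying the combination when T promoters
    are drawn from a background of K of which k carry it.  ``exact=True``
    computes the tail in rational arithmetic (small inputs).
    """
    if not (0 <= t <= T <= K):
        raise ValueError(f"need 0 <= t <= T <= K, got t={t} T={T} K={K}")
    if not 0 <= k <= K:
        raise ValueError(f"need 0 <= k <= K, got k={k} K={K}")
    if t > k:
        raise ValueError(f"t={t} cannot exceed k={k}")
    if t == 0:
        return 1.0
    if exact:
        num = sum(
            math.comb(T, i) * math.comb(K - T, k - i)
            for i in range(t, min(T, k) + 1)
            if k - i <= K - T
        )
        return float(Fraction(num, math.comb(K, k)))
    # scipy parameterisation: population K, k successes, T draws
    return float(_stats.hypergeom.sf(t - 1, K, k, T))


@dataclass(frozen=True)
class AssociationResult:
    itemset: frozenset
    support: float
    t: int
    k: int
    T: int
    K: int
    p_value: float
    q_value: float | None = None
    rules: tuple[AssociationRule, ...] = ()


def evaluate_combinations(
    frequent_itemsets: dict[frozenset, float],
    observed_transactions,
    background_transactions,
    adjust: str | None = None,
    min_size: int = 2,
    rules: list[AssociationRule] | None = None,
) -> list[AssociationResult]:
    """Score each frequent combination against the background.

    The background must be scanned with the same cutoffs as the observed
    group.  When the observed promoters are part of the background, k counts
    them too so k >= t is guaranteed.  Returns results sorted by p-value
    (ascending); ``adjust='bh'`` adds Benjamini-Hochberg q-values.
    """
    obs = [
        t.items if isinstance(t, Transaction) else frozenset(t)
        for t in observed_transactions
    ]
    bg = [
        t.items if isinstance(t, Transaction) else frozenset(t)
        for t in background_transactions
    ]
    T, K = len(obs), len(bg)
    if K < T:
        raise ValueError(f"background size K={K} smaller than observed T={T}")
    results = []
    for itemset, support in frequent_itemsets.items():
        if len(itemset) < min_size:
            continue
        t = sum(1 for x in obs if itemset <= x)
        k = sum(1 for x in bg if itemset <= x)
        # combination absent from the background but present in the observed
        # group: clamp k so the tail is defined (worst case, fully enriched)
        k_eff = max(k, t)
        p = hypergeom_p(K, T, k_eff, t)
        my_rules = tuple(
            r for r in (rules or []) if r.antecedent | r.consequent == itemset
        )
        results.append(
            AssociationResult(itemset, support, t, k, T, K, p, rules=my_rules)
        )
    results.sort(key=lambda r: (r.p_value, _itemset_key(r.itemset)))
    if adjust == "bh" and results:
        qs = _stats.false_discovery_control(
            np.array([r.p_value for r in results]), method="bh"
        )
        results = [
            AssociationResult(
                r.itemset, r.support, r.t, r.k, r.T, r.K, r.p_value,
                float(q), r.rules,
            )
            for r, q in zip(results, qs)
        ]
    elif adjust not in (None, "none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results
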