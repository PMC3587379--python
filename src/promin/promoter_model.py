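"""CpG-stratified RBF-SVM identification of proximal promoter regions.

The classifier decides whether a fixed-length window (default -200..+100
around a putative TSS) looks like a proximal promoter.  Each window is
represented by a 204-dimensional fused feature vector:

* **OR** (100 dims) — overlapping-count density of the 100 most
  over-represented hexamers of the training promoters (selected by
  background-corrected Z-score on the training folds only);
* **NC** (84 dims)  — window-wide occurrence rates of every mono-, di- and
  tri-nucleotide (three simplices, so the block sums to 3);
* **DS** (20 dims)  — the 15-nt nearest-neighbor ΔG profile of the window
  aggregated into 20 equal-width positional bins (mean per bin, kcal/mol).

Two branches are trained — promoters with and without a CpG island — and at
prediction time each candidate window is routed to the branch matching its
own CpG-island status.  Feature subsets (OR+NC, OR+DS, NC+DS, OR+NC+DS) are
selectable for ablation studies.

Negatives are windows of the same length sampled from the training flanks
with zero overlap with the positive window, one per record, so classes stay
balanced.  Performance is reported by record-level k-fold cross-validation
with Precision = TP/(TP+FP), Sensitivity = TP/(TP+FN), Specificity =
TN/(TN+FP) and Accuracy = (TP+TN)/(TP+FP+TN+FN).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cpg import find_cpg_islands, has_cpg_island
from .kmer_features import (
    BackgroundModel,
    _kmer_codes,
    all_kmers,
    hexamer_zscores,
    top_hexamers,
)
from .seqio import (
    CpGClass,
    GenomicSequence,
    PromoterRecord,
    RelativeWindow,
    encode_sequence,
    rel_to_index,
)
from .stability import stability_profile

#: the five candidate proximal-promoter windows
CANDIDATE_WINDOWS: tuple[RelativeWindow, ...] = (
    RelativeWindow(-60, 20),
    RelativeWindow(-100, 50),
    RelativeWindow(-200, 100),
    RelativeWindow(-300, 150),
    RelativeWindow(-400, 200),
)

DEFAULT_WINDOW = RelativeWindow(-200, 100)

N_TOP_HEXAMERS = 100
N_DS_BINS = 20
ALL_FEATURE_SETS = ("OR", "NC", "DS")

#: hyperparameter grid for the RBF kernel (inner 3-fold selection)
PARAM_GRID = {
    "C": [2.0 ** e for e in range(-3, 8, 2)],
    "gamma": [2.0 ** e for e in range(-9, 2, 2)],
}

#: sequence context (bp) added on each side of a candidate window when
#: deciding its CpG-island status at prediction time
CPG_CONTEXT_PAD = 500


# ---------------------------------------------------------------------------
# Training-set construction
# ---------------------------------------------------------------------------

def build_training_set(
    records,
    window: RelativeWindow = DEFAULT_WINDOW,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 100,
) -> tuple[list[str], list[str], list[PromoterRecord]]:
    """One positive window plus one random non-overlapping negative window
    per record.

    Negatives are drawn uniformly from the record outside the positive
    window; records whose positive window contains N, or that cannot host an
    N-free non-overlapping negative, are dropped with a warning.  Returns
    (positives, negatives, kept_records).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    wlen = window.length
    positives, negatives, kept = [], [], []
    for rec in records:
        try:
            ps, pe = rel_to_index(window, rec.tss_index, seq_len=len(rec.seq))
        except ValueError:
            warnings.warn(f"{rec.gene_id}: window {window} out of bounds; dropped")
            continue
        pos = rec.seq[ps:pe]
        if "N" in pos:
            warnings.warn(f"{rec.gene_id}: positive window contains N; dropped")
            continue
        candidates = [
            i
            for i in range(0, len(rec.seq) - wlen + 1)
            if i + wlen <= ps or i >= pe
        ]
        if not candidates:
            warnings.warn(f"{rec.gene_id}: no room for a negative window; dropped")
            continue
        neg = None
        for _ in range(max_attempts):
            i = int(rng.choice(candidates))
            cand = rec.seq[i : i + wlen]
            if "N" not in cand:
                neg = cand
                break
        if neg is None:
            warnings.warn(f"{rec.gene_id}: no N-free negative window; dropped")
            continue
        positives.append(pos)
        negatives.append(neg)
        kept.append(rec)
    return positives, negatives, kept


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    schema: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def feature_schema(
    top_hexamers_: list[str], feature_sets=ALL_FEATURE_SETS
) -> tuple[str, ...]:
    names: list[str] = []
    if "OR" in feature_sets:
        names += [f"or_{h}" for h in top_hexamers_]
    if "NC" in feature_sets:
        for k in (1, 2, 3):
            names += [f"nc_{w}" for w in all_kmers(k)]
    if "DS" in feature_sets:
        names += [f"ds_bin{i:02d}" for i in range(N_DS_BINS)]
    return tuple(names)


def assemble_features(
    window_seq: str,
    top_hexamers_: list[str],
    feature_sets=ALL_FEATURE_SETS,
) -> FeatureVector:
    """Fuse the OR/NC/DS blocks of one N-free candidate window."""
    window_seq = window_seq.upper()
    codes = encode_sequence(window_seq)
    if (codes < 0).any():
        raise ValueError("window contains N; pre-filter before featurizing")
    L = len(window_seq)
    blocks: list[np.ndarray] = []
    if "OR" in feature_sets:
        hexcodes = Counter(_kmer_codes(codes, 6).tolist())
        idx = {h: _word_code(h) for h in top_hexamers_}
        blocks.append(
            np.array([hexcodes.get(idx[h], 0) / L for h in top_hexamers_])
        )
    if "NC" in feature_sets:
        for k in (1, 2, 3):
            kc = Counter(_kmer_codes(codes, k).tolist())
            denom = L - k + 1
            blocks.append(
                np.array([kc.get(c, 0) / denom for c in range(4 ** k)])
            )
    if "DS" in feature_sets:
        prof = stability_profile(window_seq, window=15).values
        blocks.append(
            np.array([chunk.mean() for chunk in np.array_split(prof, N_DS_BINS)])
        )
    values = np.concatenate(blocks)
    return FeatureVector(values, feature_schema(top_hexamers_, feature_sets))


def _word_code(word: str) -> int:
    code = 0
    for b in word:
        code = code * 4 + "ACGT".index(b)
    return code


def feature_matrix(
    windows: list[str], top_hexamers_: list[str], feature_sets=ALL_FEATURE_SETS
) -> np.ndarray:
    return np.vstack(
        [assemble_features(w, top_hexamers_, feature_sets).values for w in windows]
    )


# ---------------------------------------------------------------------------
# Training and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class BranchModel:
    scaler: StandardScaler
    svc: SVC
    top_hexamers: list[str]
    feature_sets: tuple[str, ...] = ALL_FEATURE_SETS

    def decision_scores(self, windows: list[str]) -> np.ndarray:
        X = feature_matrix(windows, self.top_hexamers, self.feature_sets)
        return self.svc.decision_function(self.scaler.transform(X))


def train(
    X: np.ndarray,
    y: np.ndarray,
    C: float | None = None,
    gamma: float | None = None,
    seed: int = 0,
) -> tuple[StandardScaler, SVC]:
    """Standardize and fit an RBF-kernel SVM.

    When C/gamma are not given they are selected by an inner 3-fold grid
    search on the training data.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if C is None or gamma is None:
        inner = StratifiedKFold(3, shuffle=True, random_state=seed)
        search = GridSearchCV(
            SVC(kernel="rbf"), PARAM_GRID, cv=inner, n_jobs=1
        ).fit(Xs, y)
        C, gamma = search.best_params_["C"], search.best_params_["gamma"]
    svc = SVC(kernel="rbf", C=C, gamma=gamma).fit(Xs, y)
    return scaler, svc


@dataclass
class CVReport:
    """Per-fold and pooled confusion counts with the four derived metrics."""

    folds: list[dict]
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    def summary(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
        }


def _select_hexamers(
    positive_windows: list[str], background: BackgroundModel, n: int
) -> list[str]:
    stats = hexamer_zscores(positive_windows, background)
    return top_hexamers(stats, n=n)


def cross_validate(
    records,
    window: RelativeWindow = DEFAULT_WINDOW,
    k: int = 5,
    seed: int = 0,
    feature_sets=ALL_FEATURE_SETS,
    C: float | None = None,
    gamma: float | None = None,
    background: BackgroundModel | None = None,
) -> CVReport:
    """Record-level k-fold cross-validation of one branch.

    A record's positive and negative window always share a fold; fold sizes
    differ by at most one.  Hexamer selection, the background model (order-0
    over the full training flanks, unless supplied) and feature scaling are
    all fitted on the training folds only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    pos, neg, kept = build_training_set(records, window, seed=rng)
    if len(kept) < k:
        raise ValueError(f"need at least {k} usable records, got {len(kept)}")
    order = rng.permutation(len(kept))
    fold_idx = np.array_split(order, k)
    folds = []
    tp = fp = tn = fn = 0
    for fold, test_idx in enumerate(fold_idx):
        test_mask = np.zeros(len(kept), dtype=bool)
        test_mask[test_idx] = True
        train_i = np.flatnonzero(~test_mask)
        test_i = np.flatnonzero(test_mask)
        bg = background or BackgroundModel.fit([kept[i] for i in train_i])
        hx = (
            _select_hexamers([pos[i] for i in train_i], bg, N_TOP_HEXAMERS)
            if "OR" in feature_sets
            else []
        )
        windows_train = [pos[i] for i in train_i] + [neg[i] for i in train_i]
        y_train = np.r_[np.ones(len(train_i)), np.zeros(len(train_i))]
        windows_test = [pos[i] for i in test_i] + [neg[i] for i in test_i]
        y_test = np.r_[np.ones(len(test_i)), np.zeros(len(test_i))]
        X_train = feature_matrix(windows_train, hx, feature_sets)
        X_test = feature_matrix(windows_test, hx, feature_sets)
        scaler, svc = train(X_train, y_train, C=C, gamma=gamma, seed=seed)
        y_hat = svc.predict(scaler.transform(X_test))
        f_tp = int(((y_hat == 1) & (y_test == 1)).sum())
        f_fp = int(((y_hat == 1) & (y_test == 0)).sum())
        f_tn = int(((y_hat == 0) & (y_test == 0)).sum())
        f_fn = int(((y_hat == 0) & (y_test == 1)).sum())
        folds.append({"fold": fold, "tp": f_tp, "fp": f_fp, "tn": f_tn, "fn": f_fn})
        tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
    return CVReport(folds, tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# Model bundle and prediction
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """The deployable pair of branch models sharing one window spec."""

    window: RelativeWindow
    branches: dict[str, BranchModel]          # keys: with_cpg / without_cpg
    feature_sets: tuple[str, ...] = ALL_FEATURE_SETS
    threshold: float = 0.0
    version: str = "1"

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def _branch_key(record: PromoterRecord, window: RelativeWindow) -> str:
    if record.cpg_class is CpGClass.WITH_CPG:
        return "with_cpg"
    if record.cpg_class is CpGClass.WITHOUT_CPG:
        return "without_cpg"
    return "with_cpg" if has_cpg_island(record, window) else "without_cpg"


def train_bundle(
    records,
    window: RelativeWindow = DEFAULT_WINDOW,
    seed: int = 0,
    feature_sets=ALL_FEATURE_SETS,
    C: float | None = None,
    gamma: float | None = None,
) -> ModelBundle:
    """Train the with-CpG and without-CpG branches from labelled records.

    Records with cpg_class UNKNOWN are routed by detecting islands around
    their own window.  A branch with no records (or a single class) is
    omitted with a warning; prediction then falls back to the other branch.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[PromoterRecord]] = {"with_cpg": [], "without_cpg": []}
    for rec in records:
        groups[_branch_key(rec, window)].append(rec)
    branches: dict[str, BranchModel] = {}
    for key, recs in groups.items():
        if len(recs) < 2:
            warnings.warn(f"branch {key}: {len(recs)} record(s); branch skipped")
            continue
        pos, neg, kept = build_training_set(recs, window, seed=rng)
        if not kept:
            warnings.warn(f"branch {key}: no usable records; branch skipped")
            continue
        bg = BackgroundModel.fit(kept)
        hx = (
            _select_hexamers(pos, bg, N_TOP_HEXAMERS)
            if "OR" in feature_sets
            else []
        )
        X = feature_matrix(pos + neg, hx, feature_sets)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        scaler, svc = train(X, y, C=C, gamma=gamma, seed=seed)
        branches[key] = BranchModel(scaler, svc, hx, tuple(feature_sets))
    if not branches:
        raise ValueError("no branch could be trained")
    return ModelBundle(window, branches, tuple(feature_sets))


@dataclass(frozen=True)
class PredictedRegion:
    seq_id: str
    start: int
    end: int
    branch: str
    score: float

    # duck-typing for write_hits_bed
    @property
    def matrix_id(self) -> str:
        return f"promoter_{self.branch}"

    @property
    def matrix_score(self) -> float:
        return 1.0 / (1.0 + np.exp(-self.score))

    strand = "."


def predict_promoters(
    seq: GenomicSequence,
    bundle: ModelBundle,
    stride: int = 10,
) -> list[PredictedRegion]:
    """Slide the model window along a novel sequence and report promoter-like
    regions.

    Each candidate window is routed to the branch matching the CpG-island
    status of its padded context; windows whose decision score exceeds the
    bundle threshold are merged into maximal regions keeping the best score.
    """
    if not bundle.branches:
        raise ValueError("bundle has no trained branches")
    wlen = bundle.window.length
    L = len(seq.seq)
    if L < wlen:
        raise ValueError(f"sequence shorter than model window ({wlen} bp)")
    islands = find_cpg_islands(seq.seq)
    starts = list(range(0, L - wlen + 1, max(stride, 1)))
    routed: dict[str, list[int]] = {k: [] for k in bundle.branches}
    fallback = next(iter(bundle.branches))
    for i in starts:
        if "N" in seq.seq[i : i + wlen]:
            continue
        lo, hi = i - CPG_CONTEXT_PAD, i + wlen + CPG_CONTEXT_PAD
        overlaps = any(isl.start < hi and isl.end > lo for isl in islands)
        key = "with_cpg" if overlaps else "without_cpg"
        if key not in bundle.branches:
            key = fallback
        routed[key].append(i)
    hits: list[tuple[int, str, float]] = []
    for key, idxs in routed.items():
        if not idxs:
            continue
        branch = bundle.branches[key]
        scores = branch.decision_scores([seq.seq[i : i + wlen] for i in idxs])
        hits.extend(
            (i, key, float(s))
            for i, s in zip(idxs, scores)
            if s > bundle.threshold
        )
    hits.sort()
    regions: list[PredictedRegion] = []
    for i, key, s in hits:
        if regions and i < regions[-1].end:
            prev = regions[-1]
            best = max(prev.score, s)
            regions[-1] = PredictedRegion(
                seq.id, prev.start, i + wlen,
                key if s > prev.score else prev.branch, best,
            )
        else:
            regions.append(PredictedRegion(seq.id, i, i + wlen, key, s))
    return regions
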