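"""Pseudopopulation construction, cross-odour distance geometry, and the
subsampled PCA + Gaussian-model leave-one-trial-out odour decoder.

Population vectors are per-trial spike counts in the odour window (0 to
+0.5 s), with units pooled across sessions and aligned by within-odour trial
index.  The Euclidean geometry of those vectors quantifies odour
separability: within-odour distance distributions capture trial-to-trial
variability, cross-odour distributions capture representational distance,
and a Welch ANOVA with Games-Howell post-hocs compares them.

The decoder repeatedly (default 500 iterations per population size, sizes in
steps of 10) draws random unit subsamples, holds out one random trial,
jointly reduces the training vectors to four principal components, fits one
multivariate Gaussian per odour class (equal priors, full covariance with
small diagonal regularization) and scores the held-out trial.  Accuracy per
size is the fraction of correct iterations, tested one-sided against the
chance level 1/6 with an exact binomial test.  A kNN-based error-correcting
output-codes (ECOC) classifier is available as a control model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import multivariate_normal
from sklearn.decomposition import PCA
from sklearn.neighbors import KNeighborsClassifier

from .stats import (
    TestResult,
    binomial_test_one_sided,
    games_howell,
    two_proportion_test,
    welch_anova,
)
from .similarity import sidak_adjust

CHANCE = {6: 1.0 / 6.0}


@dataclass
class PopulationMatrix:
    counts: np.ndarray  # (n_trials_total, n_units) spike counts
    labels: np.ndarray  # odour carbon per row
    unit_ids: list[str]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class DistanceSummary:
    group_labels: list[str]
    distances: dict  # label -> 1-D array of distances
    omnibus: TestResult | None
    posthoc_p: np.ndarray | None  # Games-Howell matrix over group_labels
    degenerate: bool = False


@dataclass
class DecodingCurve:
    classifier: str
    sizes: np.ndarray
    outcomes: np.ndarray  # (n_sizes, iters) bool
    accuracy: np.ndarray  # per size
    chance: float
    binom_p: np.ndarray  # one-sided vs chance, per size
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "accuracy": self.accuracy,
                "binom_p": self.binom_p,
                "iters": self.outcomes.shape[1],
                "classifier": self.classifier,
            }
        )


def build_pseudopopulation(sessions, n_trials: int = 19,
                           window: tuple[float, float] = (0.0, 0.5)) -> PopulationMatrix:
    """Pool units of (deduplicated) sessions into one trials × units matrix.

    Row r of odour o combines each session's r-th trial of odour o.  Every
    session must have at least ``n_trials`` trials of every odour; extra
    trials are truncated so each odour contributes exactly ``n_trials`` rows.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions")
    carbons = sessions[0].odour_carbons
    blocks, unit_ids, labels = [], [], None
    for s in sessions:
        if s.odour_carbons != carbons:
            raise ValueError(f"session {s.session_id} has a different odour set")
        cols = []
        row_labels = []
        for c in carbons:
            m = s.trials["odour_carbon"] == c
            onsets = s.trials.loc[m, "onset_s"].to_numpy()[:n_trials]
            if onsets.size < n_trials:
                raise ValueError(
                    f"session {s.session_id} has only {onsets.size} trials of odour {c}"
                )
            counts = np.stack(
                [
                    np.searchsorted(u.spike_times, onsets + window[1])
                    - np.searchsorted(u.spike_times, onsets + window[0])
                    for u in s.units
                ],
                axis=1,
            )
            cols.append(counts)
            row_labels.extend([c] * n_trials)
        blocks.append(np.concatenate(cols, axis=0))
        unit_ids.extend(f"{s.session_id}/{u.unit_id}" for u in s.units)
        labels = np.array(row_labels)
    counts = np.concatenate(blocks, axis=1)
    return PopulationMatrix(counts=counts.astype(int), labels=labels, unit_ids=unit_ids)


def cross_odour_distances(pop: PopulationMatrix) -> DistanceSummary:
    """Within- and cross-odour Euclidean distance distributions + tests.

    Groups: one within-odour distribution per odour (all C(n,2) trial pairs)
    and one cross distribution per odour pair (all n × n combinations).
    Omnibus: Welch ANOVA over all groups; post-hoc: Games-Howell matrix.
    """
    classes = pop.classes
    if classes.size < 2:
        raise ValueError("need >= 2 odours")
    D = squareform(pdist(pop.counts.astype(float)))
    groups, labels = [], []
    for c in classes:
        idx = np.flatnonzero(pop.labels == c)
        if idx.size < 2:
            raise ValueError(f"odour {c} has < 2 trials")
        sub = D[np.ix_(idx, idx)]
        groups.append(sub[np.triu_indices(idx.size, k=1)])
        labels.append(f"within:{c}")
    for a, b in itertools.combinations(classes, 2):
        ia = np.flatnonzero(pop.labels == a)
        ib = np.flatnonzero(pop.labels == b)
        groups.append(D[np.ix_(ia, ib)].ravel())
        labels.append(f"cross:{a}-{b}")
    distances = dict(zip(labels, groups))
    if all(np.all(g == 0) for g in groups):
        return DistanceSummary(labels, distances, None, None, degenerate=True)
    try:
        omnibus = welch_anova(groups)
        posthoc = games_howell(groups)
    except ValueError:
        return DistanceSummary(labels, distances, None, None, degenerate=True)
    return DistanceSummary(labels, distances, omnibus, posthoc)


def posthoc_grid(summary: DistanceSummary, classes) -> pd.DataFrame:
    """Within-vs-cross post-hoc p for each (row odour A, column odour B).

    Mirrors the off-diagonal tiles of the distance figures: entry (A, B)
    compares the within-A distribution against the cross-(A,B) distribution.
    """
    classes = list(classes)
    labels = summary.group_labels
    P = summary.posthoc_p
    rows = []
    for a in classes:
        i = labels.index(f"within:{a}")
        for b in classes:
            if a == b:
                continue
            key = f"cross:{min(a, b)}-{max(a, b)}"
            j = labels.index(key)
            rows.append(dict(row_odour=a, col_odour=b,
                             p=np.nan if P is None else float(P[i, j])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classifiers


class GaussianClassifier:
    """One full-covariance multivariate Gaussian per odour class.

    Equal priors; prediction is the class of maximal likelihood.  Diagonal
    regularization ε = 1e-6 × mean variance keeps covariances invertible.
    Ties break toward the lowest carbon number (classes are kept sorted).
    """

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.dists_ = []
        mean_var = max(float(X.var(axis=0).mean()), 1e-12)
        eps = self.reg * mean_var
        for c in self.classes_:
            Xc = X[y == c]
            if Xc.shape[0] < d + 2:
                raise ValueError(
                    f"class {c}: need >= {d + 2} training rows to estimate a covariance"
                )
            cov = np.cov(Xc, rowvar=False) + eps * np.eye(d)
            try:
                self.dists_.append(multivariate_normal(Xc.mean(axis=0), cov))
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise ValueError(f"singular covariance for class {c}") from e
        return self

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([d.logpdf(X).reshape(X.shape[0]) for d in self.dists_], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        ll = self.log_likelihoods(X)
        return self.classes_[np.argmax(ll, axis=1)]  # argmax -> lowest carbon on ties


class KnnEcocClassifier:
    """One-vs-one ECOC with k-nearest-neighbour binary learners.

    15 binary learners for 6 classes; decoding minimizes Hamming loss over
    the coding matrix (for one-vs-one this reduces to pairwise voting);
    ties break toward the lowest carbon number.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.pairs_ = list(itertools.combinations(range(self.classes_.size), 2))
        self.learners_ = []
        for i, j in self.pairs_:
            m = (y == self.classes_[i]) | (y == self.classes_[j])
            if self.k > m.sum():
                raise ValueError("k exceeds the training size of a binary problem")
            knn = KNeighborsClassifier(n_neighbors=self.k, metric="euclidean")
            knn.fit(X[m], (y[m] == self.classes_[j]).astype(int))
            self.learners_.append(knn)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_classes = self.classes_.size
        loss = np.zeros((X.shape[0], n_classes))
        for (i, j), knn in zip(self.pairs_, self.learners_):
            pred = knn.predict(X)  # 1 -> class j, 0 -> class i
            loss[:, i] += pred
            loss[:, j] += 1 - pred
        return self.classes_[np.argmin(loss, axis=1)]


def fit_gaussian_classifier(X, y, reg: float = 1e-6) -> GaussianClassifier:
    return GaussianClassifier(reg=reg).fit(X, y)


def fit_knn_ecoc(X, y, k: int = 5) -> KnnEcocClassifier:
    return KnnEcocClassifier(k=k).fit(X, y)


# ---------------------------------------------------------------------------
# subsampled leave-one-trial-out decoding


def _loto_iteration(counts, labels, size, rng, classifier, pca_dim, joint_pca, k):
    n_trials, n_units = counts.shape
    units = rng.choice(n_units, size=size, replace=False)
    test_idx = rng.integers(n_trials)
    X = counts[:, units].astype(float)
    train = np.ones(n_trials, dtype=bool)
    train[test_idx] = False
    dim = min(pca_dim, size)
    pca = PCA(n_components=dim)
    if joint_pca:
        Z = pca.fit_transform(X)
        Ztr, Zte = Z[train], Z[~train]
    else:
        Ztr = pca.fit_transform(X[train])
        Zte = pca.transform(X[~train])
    if classifier == "gaussian":
        model = GaussianClassifier().fit(Ztr, labels[train])
    elif classifier == "knn_ecoc":
        model = KnnEcocClassifier(k=k).fit(Ztr, labels[train])
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return model.predict(Zte)[0] == labels[test_idx]


def decode_accuracy(
    pop: PopulationMatrix,
    classifier: str = "gaussian",
    sizes=None,
    iters: int = 500,
    pca_dim: int = 4,
    seed: int = 0,
    joint_pca: bool = False,
    k: int = 5,
) -> DecodingCurve:
    """Leave-one-trial-out decoding accuracy across subsampled sizes.

    Per size, per iteration: draw ``size`` units without replacement, hold
    out one random trial, reduce the training rows to ``pca_dim`` principal
    components (``joint_pca=True`` reproduces the literal reduce-all-then-
    hold-out reading), fit the classifier, score the held-out trial.
    Deterministic given ``seed``.
    """
    n_trials, n_units = pop.counts.shape
    if sizes is None:
        sizes = np.arange(10, n_units + 1, 10)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0 or sizes.max() > n_units:
        raise ValueError(f"sizes must be non-empty and <= {n_units} units")
    rng = np.random.default_rng(seed)
    chance = 1.0 / pop.classes.size
    outcomes = np.zeros((sizes.size, iters), dtype=bool)
    for si, size in enumerate(sizes):
        for it in range(iters):
            outcomes[si, it] = _loto_iteration(
                pop.counts, pop.labels, size, rng, classifier, pca_dim, joint_pca, k
            )
    accuracy = outcomes.mean(axis=1)
    binom_p = np.array(
        [
            binomial_test_one_sided(int(o.sum()), iters, chance, "greater").p
            for o in outcomes
        ]
    )
    return DecodingCurve(classifier, sizes, outcomes, accuracy, chance, binom_p, seed)


def compare_decoding_curves(curve_a: DecodingCurve, curve_b: DecodingCurve) -> pd.DataFrame:
    """Per-size accuracy difference with Šídák-adjusted two-proportion tests."""
    if not np.array_equal(curve_a.sizes, curve_b.sizes):
        raise ValueError("curves have mismatched sizes")
    if curve_a.outcomes.shape != curve_b.outcomes.shape:
        raise ValueError("curves have mismatched iteration counts")
    n = curve_a.outcomes.shape[1]
    rows = []
    for i, size in enumerate(curve_a.sizes):
        ka = int(curve_a.outcomes[i].sum())
        kb = int(curve_b.outcomes[i].sum())
        res = two_proportion_test(ka, n, kb, n)
        rows.append(dict(size=int(size),
                         accuracy_a=ka / n, accuracy_b=kb / n,
                         diff=(ka - kb) / n, z=res.statistic, p_raw=res.p))
    df = pd.DataFrame(rows)
    df["p_adj"] = sidak_adjust(df["p_raw"].to_numpy(), len(df))
    return df
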