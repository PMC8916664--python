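"""Few-shot open-set recognition on embedded unit steps.

Subjects are partitioned into *training*, *known* and *unknown* groups
(default 20/10/10).  The encoder is trained on the training group; for
each known subject only n (=10) randomly reserved *shot* steps are used to
compute a centroid D_a (mean embedding) and fit a one-class SVM boundary.
A query embedding v is provisionally assigned to the nearest centroid p
and accepted iff the decision value

    h_p(v) = sum_i alpha_i K(v_i,p, v) - delta_p  >=  tau,

with radial kernel K(v, v') = exp(-gamma ||v - v'||^2), multipliers alpha
solving the one-class dual

    min_alpha 1/2 sum_ii' alpha_i alpha_i' K(v_i, v_i')
    s.t.      0 <= alpha_i <= 1/(nu n),  sum_i alpha_i = 1,

and offset delta_p = sum_i alpha_i K(v_i, v_h) for a margin support vector
h (0 < alpha_h < 1/(nu n)).  A known-test step counts as a true positive
only when it is accepted *and* assigned to its true subject; an
unknown-test step counts as a true negative when rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import OneClassSVM

KKT_TOL = 1e-8


@dataclass
class SplitSpec:
    """Subject partition and shot protocol for one experiment."""

    n_train: int = 20
    n_known: int = 10
    n_unknown: int = 10
    n_shots: int = 10
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_known, self.n_unknown) < 1:
            raise ValueError("all group sizes must be positive")
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")


@dataclass
class Split:
    """Step indices of one repetition's partition (values are (n, T, 28) arrays)."""

    train: dict[int, np.ndarray]
    shots: dict[int, np.ndarray]
    known_test: dict[int, np.ndarray]
    unknown_test: dict[int, np.ndarray]
    repetition: int = 0

    def manifest(self) -> dict:
        return {
            "repetition": self.repetition,
            "training_subjects": sorted(self.train),
            "known_subjects": sorted(self.shots),
            "unknown_subjects": sorted(self.unknown_test),
        }


def split_dataset(dataset, spec: SplitSpec, repetition: int = 0) -> Split:
    """Randomly partition subjects and reserve the n shot steps per known subject.

    The partition is a deterministic function of (spec.seed, repetition).
    """
    subjects = dataset.subjects
    need = spec.n_train + spec.n_known + spec.n_unknown
    if len(subjects) < need:
        raise ValueError(f"need {need} subjects, dataset has {len(subjects)}")
    rng = np.random.default_rng([spec.seed, repetition])
    perm = rng.permutation(len(subjects))
    train_ids = [subjects[i] for i in perm[: spec.n_train]]
    known_ids = [subjects[i] for i in perm[spec.n_train : spec.n_train + spec.n_known]]
    unknown_ids = [subjects[i] for i in perm[spec.n_train + spec.n_known : need]]
    shots, known_test = {}, {}
    for a in known_ids:
        arr = dataset.steps[a]
        if arr.shape[0] <= spec.n_shots:
            raise ValueError(
                f"subject {a} has {arr.shape[0]} steps; needs > {spec.n_shots}"
            )
        idx = rng.permutation(arr.shape[0])
        shots[a] = arr[np.sort(idx[: spec.n_shots])]
        known_test[a] = arr[np.sort(idx[spec.n_shots :])]
    return Split(
        train={a: dataset.steps[a] for a in train_ids},
        shots=shots,
        known_test=known_test,
        unknown_test={a: dataset.steps[a] for a in unknown_ids},
        repetition=repetition,
    )


# ---------------------------------------------------------------------------
# Centroids and one-class SVM
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    """A unit-norm encoder output tagged with its subject and step index."""

    vector: np.ndarray
    subject: int = 0
    index: int = 0


@dataclass
class Centroid:
    subject: int
    vector: np.ndarray


def compute_centroid(embeddings, subject: int = 0) -> Centroid:
    """Arithmetic mean of the n shot embeddings (not re-normalized).

    Accepts an (n, d) array or a list of :class:`Embedding`; a list mixing
    subjects is rejected.
    """
    if isinstance(embeddings, (list, tuple)) and embeddings and \
            isinstance(embeddings[0], Embedding):
        subjects = {e.subject for e in embeddings}
        if len(subjects) > 1:
            raise ValueError(f"centroid shots mix subjects: {sorted(subjects)}")
        subject = embeddings[0].subject
        embeddings = np.stack([e.vector for e in embeddings])
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[0] < 1:
        raise ValueError("need an (n, d) array with n >= 1")
    return Centroid(subject, embeddings.mean(axis=0))


def rbf_kernel(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """K(x, y) = exp(-gamma ||x - y||^2), pairwise."""
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-gamma * d2)


@dataclass
class OSVMModel:
    """Fitted one-class boundary for one subject's shot embeddings."""

    subject: int
    support: np.ndarray        # (n, d) shot embeddings
    alphas: np.ndarray         # (n,), 0 <= alpha_i <= 1/(nu n), sum = 1
    gamma: float
    nu: float
    delta: float               # offset delta_p

    @property
    def box(self) -> float:
        return 1.0 / (self.nu * len(self.alphas))

    def margin_support_indices(self, rtol: float = 1e-6) -> np.ndarray:
        box = self.box
        return np.flatnonzero(
            (self.alphas > rtol * box) & (self.alphas < box * (1 - rtol))
        )


def _kkt_polish(K: np.ndarray, alpha: np.ndarray, box: float) -> np.ndarray:
    """Exact equality-constrained solve on the free set of a box-QP solution.

    Given a near-optimal alpha for  min 1/2 a'Ka  s.t. 0<=a<=box, sum a=1,
    re-solves the stationarity system (Ka)_f = rho on the free variables,
    driving KKT residuals to numerical precision.
    """
    n = len(alpha)
    tol = 1e-6 * box
    free = np.flatnonzero((alpha > tol) & (alpha < box - tol))
    if len(free) == 0:
        return alpha
    bound = np.setdiff1d(np.arange(n), free)
    at_box = bound[alpha[bound] > box / 2] if len(bound) else np.array([], dtype=int)
    a = np.zeros(n)
    a[at_box] = box
    rhs_sum = 1.0 - box * len(at_box)
    nf = len(free)
    A = np.zeros((nf + 1, nf + 1))
    A[:nf, :nf] = K[np.ix_(free, free)]
    A[:nf, nf] = -1.0
    A[nf, :nf] = 1.0
    rhs = np.zeros(nf + 1)
    if len(at_box):
        rhs[:nf] = -K[np.ix_(free, at_box)] @ a[at_box]
    rhs[nf] = rhs_sum
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return alpha
    a[free] = sol[:nf]
    # keep the polished point only if it stays feasible
    if a.min() < -1e-12 or a.max() > box * (1 + 1e-12):
        return alpha
    return np.clip(a, 0.0, box)


def fit_osvm(embeddings: np.ndarray, gamma: float, nu: float,
             subject: int = 0) -> OSVMModel:
    """Solve the one-class dual for one subject's shot embeddings.

    The libsvm solver (via scikit-learn) provides the active set; its
    multipliers are rescaled from the libsvm convention (box 1, sum nu*n)
    to the convention here (box 1/(nu n), sum 1) and polished by an exact
    solve on the free set so KKT residuals reach ~1e-12.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2:
        raise ValueError("embeddings must be an (n, d) array")
    n = embeddings.shape[0]
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not 0 < nu <= 1:
        raise ValueError(
            f"nu must be in (0, 1]: nu={nu} makes the constraint set infeasible"
        )
    K = rbf_kernel(embeddings, embeddings, gamma)
    box = 1.0 / (nu * n)
    if n == 1:
        # sum alpha = 1 forces alpha_1 = 1; delta = K(v1, v1) = 1
        return OSVMModel(subject, embeddings, np.array([1.0]), gamma, nu, 1.0)
    svm = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu, tol=1e-9)
    svm.fit(embeddings)
    alpha = np.zeros(n)
    alpha[svm.support_] = svm.dual_coef_.ravel() / (nu * n)
    alpha = _kkt_polish(K, alpha, box)
    margin = np.flatnonzero((alpha > 1e-6 * box) & (alpha < box * (1 - 1e-6)))
    if len(margin):
        h = margin[0]
        delta = float(alpha @ K[:, h])
    else:
        sv = np.flatnonzero(alpha > 1e-6 * box)
        delta = float(np.mean([alpha @ K[:, j] for j in sv]))
    return OSVMModel(subject, embeddings, alpha, gamma, nu, float(delta))


def decision_value(model: OSVMModel, v: np.ndarray) -> float:
    """h_p(v) = sum_i alpha_i K(v_i, v) - delta_p."""
    k = rbf_kernel(model.support, np.asarray(v, dtype=float)[None], model.gamma)
    return float(model.alphas @ k[:, 0] - model.delta)


def decision_values(model: OSVMModel, V: np.ndarray) -> np.ndarray:
    k = rbf_kernel(model.support, V, model.gamma)
    return model.alphas @ k - model.delta


# ---------------------------------------------------------------------------
# Recognition and metrics
# ---------------------------------------------------------------------------

@dataclass
class RecognitionResult:
    provisional: int
    decision: float
    accepted: bool
    tau: float


def recognize(v: np.ndarray, centroids: list[Centroid],
              models: dict[int, OSVMModel], tau: float) -> RecognitionResult:
    """Nearest-centroid provisional assignment, then one-class acceptance.

    Only the provisional subject's model is evaluated; centroid-distance
    ties break to the smallest subject id.
    """
    if not centroids:
        raise ValueError("empty known set: no centroids to match against")
    order = sorted(centroids, key=lambda c: c.subject)
    d2 = [float(((c.vector - v) ** 2).sum()) for c in order]
    p = order[int(np.argmin(d2))].subject
    h = decision_value(models[p], v)
    return RecognitionResult(p, h, h >= tau, tau)


def recognize_batch(V: np.ndarray, centroids: list[Centroid],
                    models: dict[int, OSVMModel], tau: float):
    """Vectorized recognition: (assigned subject, decision value, accepted)."""
    if not centroids:
        raise ValueError("empty known set: no centroids to match against")
    order = sorted(centroids, key=lambda c: c.subject)
    C = np.stack([c.vector for c in order])
    ids = np.array([c.subject for c in order])
    d2 = ((V[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # ties -> lowest index -> smallest id
    assigned = ids[nearest]
    decisions = np.empty(len(V))
    for j, a in enumerate(ids):
        mask = nearest == j
        if mask.any():
            decisions[mask] = decision_values(models[a], V[mask])
    return assigned, decisions, decisions >= tau


@dataclass
class MetricsReport:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def tnr(self) -> float:
        if self.tn + self.fp == 0:
            warnings.warn("empty unknown test set: TNR is undefined", RuntimeWarning)
            return float("nan")
        return self.tn / (self.tn + self.fp)

    @property
    def acc(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")

    def as_dict(self) -> dict:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return {
                "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
                "TPR": self.tpr, "TNR": self.tnr, "ACC": self.acc,
            }


def evaluate(known_emb: dict[int, np.ndarray], unknown_emb: np.ndarray,
             centroids: list[Centroid], models: dict[int, OSVMModel],
             tau: float) -> MetricsReport:
    """Score one repetition's known- and unknown-test embeddings.

    A known-test step is a TP only if accepted and assigned to its true
    subject; misidentification and rejection both count FN.  An accepted
    unknown-test step is an FP regardless of which subject it matched.
    """
    tp = fn = tn = fp = 0
    for true_subject, V in known_emb.items():
        if len(V) == 0:
            continue
        assigned, _, accepted = recognize_batch(V, centroids, models, tau)
        good = accepted & (assigned == true_subject)
        tp += int(good.sum())
        fn += int(len(V) - good.sum())
    if len(unknown_emb):
        _, _, accepted = recognize_batch(unknown_emb, centroids, models, tau)
        fp += int(accepted.sum())
        tn += int(len(unknown_emb) - accepted.sum())
    return MetricsReport(tp, fn, tn, fp)


@dataclass
class MetricsSummary:
    """Per-repetition reports and their mean metrics."""

    reports: list[MetricsReport] = field(default_factory=list)

    def mean(self) -> dict:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keys = ("TPR", "TNR", "ACC")
            rows = [r.as_dict() for r in self.reports]
            return {k: float(np.mean([row[k] for row in rows])) for k in keys}
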