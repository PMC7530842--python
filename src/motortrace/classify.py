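"""Monte-Carlo-averaged linear-SVM severity scoring (Motor Error Scores).

A subject's epochs ("symptomatic") are classified against pooled control
epochs ("non-symptomatic").  Because the control pool dwarfs a single
subject's data, each of ``n_iter`` Monte-Carlo iterations subsamples the
control pool without replacement down to the subject's epoch count (1:1
balance), splits the balanced set 80/20 stratified, fits a linear SVM on the
80 % and scores the held-out 20 %.  The final hyperplane is the arithmetic
mean of the per-iteration coefficient vectors (intercept included),
orientation-corrected so the symptomatic side is positive.

The **Motor Error Score** of an epoch with (standardized) metric vector m is
its signed Euclidean distance to the averaged hyperplane,

    MES(m) = (h_{1:n} . m + h_0) / |h_{1:n}|,

positive meaning more motor dysfunction.  The **weight** of metric i,

    w_i = h_i^2 / sum_j h_j^2,

is its relative contribution to the classification.  MES defaults to a
"full-data" hyperplane averaged over fits on 100 % of each balanced
subsample (no held-out fifth), maximizing data yield, while accuracies come
from the held-out splits.

Features are z-scored against the control pool (stored inside the
hyperplane, so scoring is self-contained); SVM hyperparameters are fixed a
priori (linear kernel, C = 1, no class weighting).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score, train_test_split
from sklearn.svm import SVC

from .metrics import METRIC_NAMES

__all__ = [
    "Hyperplane",
    "ClassifierReport",
    "TwoStateReport",
    "fit_mes_classifier",
    "mes",
    "mes_series",
    "metric_weights",
    "shuffled_label_control",
    "control_split_null",
    "metric_excluded_fit",
    "two_state_classifier",
]

MIN_EPOCHS = 30


@dataclass
class Hyperplane:
    """Averaged separating hyperplane with its feature scaling.

    ``coef``/``intercept`` live in standardized feature space; ``scale_mean``
    and ``scale_sd`` map raw metric vectors into it, so :meth:`mes` is
    self-contained.  Orientation is patient-positive.
    """

    intercept: float
    coef: np.ndarray
    metric_names: tuple[str, ...]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    n_iterations: int = 1
    averaging: str = "raw"

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.scale_mean = np.asarray(self.scale_mean, dtype=float)
        self.scale_sd = np.asarray(self.scale_sd, dtype=float)
        if len(self.coef) != len(self.metric_names):
            raise ValueError("coefficient vector and metric names disagree in length")
        if np.linalg.norm(self.coef) == 0:
            raise ValueError("hyperplane has a zero coefficient vector")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.scale_mean) / self.scale_sd

    def mes(self, m) -> np.ndarray | float:
        """Signed distance of raw metric vector(s) to the hyperplane."""
        m = np.asarray(m, dtype=float)
        if m.shape[-1] != len(self.metric_names):
            raise ValueError(
                f"metric vector has {m.shape[-1]} entries; hyperplane expects "
                f"{len(self.metric_names)} ({self.metric_names})"
            )
        z = self.standardize(m)
        d = (z @ self.coef + self.intercept) / np.linalg.norm(self.coef)
        return float(d) if d.ndim == 0 else d

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "metric_names": list(self.metric_names),
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "n_iterations": self.n_iterations,
            "averaging": self.averaging,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperplane":
        return cls(
            intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], dtype=float),
            metric_names=tuple(d["metric_names"]),
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_sd=np.asarray(d["scale_sd"], dtype=float),
            n_iterations=int(d.get("n_iterations", 1)),
            averaging=d.get("averaging", "raw"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Hyperplane":
        return cls.from_dict(json.loads(text))


@dataclass
class ClassifierReport:
    """Outcome of one Monte-Carlo classification run."""

    accuracies: np.ndarray          # held-out accuracy per iteration
    hyperplane: Hyperplane          # averaged over the 80 %-trained fits
    mes_hyperplane: Hyperplane      # averaged over full-subsample fits
    class_counts: list[tuple[int, int]]  # (n_patient, n_control) per iteration
    n_iter: int
    C: float
    test_fraction: float
    train_cv_accuracies: np.ndarray | None = None  # optional inner-CV diagnostics

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "n_iter": self.n_iter,
            "C": self.C,
            "test_fraction": self.test_fraction,
            "metric_names": list(self.hyperplane.metric_names),
        }


@dataclass
class TwoStateReport:
    """Within-subject two-state discrimination plus its shuffled-label null."""

    report: ClassifierReport
    shuffled: ClassifierReport


def _as_matrix(data, metric_names=None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Accept a tidy metric DataFrame or a plain (n, d) array."""
    if isinstance(data, pd.DataFrame):
        cols = [m for m in (metric_names or METRIC_NAMES) if m in data.columns]
        if not cols:
            raise ValueError("no metric columns found in DataFrame")
        sub = data[cols]
        keep = [c for c in cols if len(sub) == 0 or not sub[c].isna().all()]
        dropped = sorted(set(cols) - set(keep))
        if dropped:
            warnings.warn(f"dropping all-NaN metric columns: {dropped}")
        x = data[keep].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("metric table contains NaNs in retained columns")
        return x, tuple(keep)
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D array of epoch metric vectors")
    names = tuple(metric_names) if metric_names else tuple(f"m{i}" for i in range(x.shape[1]))
    if len(names) != x.shape[1]:
        raise ValueError("metric_names length does not match data width")
    return x, names


def _control_scaler(x: np.ndarray, names) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        bad = [names[i] for i in zero]
        raise ValueError(f"zero-variance metrics in the reference pool: {bad}")
    return mu, sd


def _orient(intercept: float, coef: np.ndarray, zp: np.ndarray, zc: np.ndarray):
    """Flip the plane if it scores patients below controls on average."""
    mp = (zp @ coef + intercept).mean()
    mc = (zc @ coef + intercept).mean()
    if mp < mc:
        return -intercept, -coef
    return intercept, coef


def _mc_fit(
    zp: np.ndarray,
    zc: np.ndarray,
    names: tuple[str, ...],
    mu: np.ndarray,
    sd: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    C: float,
    test_fraction: float,
    subsample_size: int | None,
    averaging: str,
    inner_cv: bool,
) -> ClassifierReport:
    n_p, n_c = len(zp), len(zc)
    size = n_p if subsample_size is None else subsample_size
    if size > n_c:
        warnings.warn(
            f"control pool ({n_c}) smaller than requested subsample ({size}); using full pool"
        )
        size = n_c
    accs = np.empty(n_iter)
    cv_accs = np.empty(n_iter) if inner_cv else None
    coefs80, coefs_full = [], []
    counts = []
    for i in range(n_iter):
        idx = rng.choice(n_c, size=size, replace=False)
        x = np.vstack([zp, zc[idx]])
        y = np.concatenate([np.ones(n_p), np.zeros(size)])
        counts.append((n_p, size))
        xtr, xte, ytr, yte = train_test_split(
            x,
            y,
            test_size=test_fraction,
            stratify=y,
            random_state=int(rng.integers(2**31)),
        )
        clf = SVC(kernel="linear", C=C).fit(xtr, ytr)
        accs[i] = clf.score(xte, yte)
        coefs80.append((clf.intercept_[0], clf.coef_[0].copy()))
        if inner_cv:
            cv_accs[i] = cross_val_score(SVC(kernel="linear", C=C), xtr, ytr, cv=10).mean()
        clf_full = SVC(kernel="linear", C=C).fit(x, y)
        coefs_full.append((clf_full.intercept_[0], clf_full.coef_[0].copy()))

    def average(pairs) -> tuple[float, np.ndarray]:
        b = np.array([p[0] for p in pairs])
        w = np.array([p[1] for p in pairs])
        if averaging == "normalized":
            norms = np.linalg.norm(w, axis=1, keepdims=True)
            w = w / norms
            b = b / norms[:, 0]
        elif averaging != "raw":
            raise ValueError("averaging must be 'raw' or 'normalized'")
        return float(b.mean()), w.mean(axis=0)

    planes = []
    for pairs in (coefs80, coefs_full):
        b0, w0 = average(pairs)
        b0, w0 = _orient(b0, w0, zp, zc)
        planes.append(
            Hyperplane(
                intercept=b0,
                coef=w0,
                metric_names=names,
                scale_mean=mu,
                scale_sd=sd,
                n_iterations=n_iter,
                averaging=averaging,
            )
        )
    return ClassifierReport(
        accuracies=accs,
        hyperplane=planes[0],
        mes_hyperplane=planes[1],
        class_counts=counts,
        n_iter=n_iter,
        C=C,
        test_fraction=test_fraction,
        train_cv_accuracies=cv_accs,
    )


def fit_mes_classifier(
    patient_vectors,
    control_pool,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    C: float = 1.0,
    test_fraction: float = 0.2,
    metric_names=None,
    subsample_factor: float | None = None,
    averaging: str = "raw",
    inner_cv: bool = False,
    min_epochs: int = MIN_EPOCHS,
) -> ClassifierReport:
    """Monte-Carlo-averaged linear SVM of one subject against a control pool.

    ``patient_vectors`` and ``control_pool`` are tidy metric DataFrames (or
    (n, d) arrays with ``metric_names``).  Control epochs are subsampled
    without replacement to the patient epoch count each iteration (1:1); the
    literal divide-the-pool-by-a-constant protocol is available through
    ``subsample_factor``.  Features are z-scored against the control pool.
    """
    rng = np.random.default_rng(rng)
    xp, names_p = _as_matrix(patient_vectors, metric_names)
    xc, names_c = _as_matrix(control_pool, metric_names)
    if names_p != names_c:
        raise ValueError(f"metric sets differ: {names_p} vs {names_c}")
    if len(xp) == 0 or len(xc) == 0:
        raise ValueError("both classes need at least one epoch (single-class input)")
    if len(xp) > len(xc):
        raise ValueError(
            f"patient pool ({len(xp)}) larger than control pool ({len(xc)}); swap the "
            "arguments or subsample the patient epochs to at most the pool size"
        )
    if len(xp) < min_epochs:
        raise ValueError(f"need at least {min_epochs} patient epochs, got {len(xp)}")
    mu, sd = _control_scaler(xc, names_c)
    zp = (xp - mu) / sd
    zc = (xc - mu) / sd
    size = None if subsample_factor is None else max(1, int(round(len(xc) / subsample_factor)))
    return _mc_fit(
        zp, zc, names_p, mu, sd, n_iter, rng, C, test_fraction, size, averaging, inner_cv
    )


def mes(vector, plane: Hyperplane):
    """Motor Error Score: signed distance from metric vector(s) to the plane."""
    return plane.mes(vector)


def mes_series(table: pd.DataFrame, plane: Hyperplane) -> pd.DataFrame:
    """MES per epoch for a tidy metric table, keyed by subject/trial/epoch."""
    x = table[list(plane.metric_names)].to_numpy(dtype=float)
    out = table[[c for c in ("subject_id", "group", "trial", "epoch") if c in table.columns]].copy()
    out["mes"] = plane.mes(x)
    return out


def metric_weights(plane: Hyperplane) -> pd.Series:
    """Relative contribution of each metric: w_i = h_i^2 / sum_j h_j^2."""
    h = plane.coef
    ss = float(np.sum(h**2))
    if ss == 0:
        raise ValueError("zero coefficient vector has no defined weights")
    return pd.Series(h**2 / ss, index=list(plane.metric_names), name="weight")


def shuffled_label_control(
    patient_vectors,
    control_pool,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    permutation: np.ndarray | None = None,
    **kwargs,
) -> ClassifierReport:
    """The classification pipeline re-run with epoch labels permuted.

    All patient and control epochs are pooled, the class labels permuted
    (one draw per call; pass ``permutation`` explicitly for a deterministic
    test hook, e.g. the identity), and the permuted classes sent through
    :func:`fit_mes_classifier` unchanged.  For exchangeable data the mean
    accuracy sits at chance.
    """
    rng = np.random.default_rng(rng)
    mn = kwargs.pop("metric_names", None)
    xp, names_p = _as_matrix(patient_vectors, mn)
    xc, names_c = _as_matrix(control_pool, mn)
    if names_p != names_c:
        raise ValueError(f"metric sets differ: {names_p} vs {names_c}")
    x = np.vstack([xp, xc])
    y = np.concatenate([np.ones(len(xp)), np.zeros(len(xc))])
    perm = rng.permutation(len(y)) if permutation is None else np.asarray(permutation)
    y = y[perm]  # labels move, epochs stay
    return fit_mes_classifier(
        x[y == 1], x[y == 0], n_iter=n_iter, rng=rng, metric_names=names_p, **kwargs
    )


def control_split_null(
    control_pool,
    n_patient_epochs: int,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> ClassifierReport:
    """Exchangeable null: a random epoch split of the control pool vs itself."""
    rng = np.random.default_rng(rng)
    xc, names = _as_matrix(control_pool, kwargs.pop("metric_names", None))
    if n_patient_epochs >= len(xc):
        raise ValueError("pseudo-patient split must leave a larger control remainder")
    perm = rng.permutation(len(xc))
    fake = xc[perm[:n_patient_epochs]]
    rest = xc[perm[n_patient_epochs:]]
    return fit_mes_classifier(fake, rest, n_iter=n_iter, rng=rng, metric_names=names, **kwargs)


def metric_excluded_fit(
    patient_vectors,
    control_pool,
    excluded: str,
    **kwargs,
) -> ClassifierReport:
    """Re-run the classification with one metric removed from the space."""
    mn = kwargs.pop("metric_names", None)
    xp, names = _as_matrix(patient_vectors, mn)
    xc, names_c = _as_matrix(control_pool, mn)
    if names != names_c:
        raise ValueError(f"metric sets differ: {names} vs {names_c}")
    if excluded not in names:
        raise ValueError(f"unknown metric {excluded!r}; available: {names}")
    if len(names) < 3:
        raise ValueError("at least 2 metrics must remain after exclusion")
    keep = [i for i, nm in enumerate(names) if nm != excluded]
    kept_names = tuple(nm for nm in names if nm != excluded)
    return fit_mes_classifier(
        xp[:, keep], xc[:, keep], metric_names=kept_names, **kwargs
    )


def two_state_classifier(
    state_a_vectors,
    state_b_vectors,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    C: float = 1.0,
    test_fraction: float = 0.2,
    metric_names=None,
    averaging: str = "raw",
    min_epochs: int = MIN_EPOCHS,
) -> TwoStateReport:
    """Within-subject discrimination of two states (e.g. DBS On vs Off).

    Same Monte-Carlo protocol with the two states as the classes (the larger
    class subsampled to the smaller each iteration); features are z-scored
    against the pooled two-state data.  A shuffled-label null run is
    included in the report.  State A is the positive (higher-MES) class by
    orientation convention.
    """
    rng = np.random.default_rng(rng)
    xa, names_a = _as_matrix(state_a_vectors, metric_names)
    xb, names_b = _as_matrix(state_b_vectors, metric_names)
    if names_a != names_b:
        raise ValueError(f"metric sets differ: {names_a} vs {names_b}")
    if min(len(xa), len(xb)) < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs per state")
    pool = np.vstack([xa, xb])
    mu, sd = _control_scaler(pool, names_a)
    za, zb = (xa - mu) / sd, (xb - mu) / sd
    if len(za) > len(zb):  # subsample the larger state down each iteration
        zp, zc = zb, za
        flip = True
    else:
        zp, zc = za, zb
        flip = False
    report = _mc_fit(
        zp, zc, names_a, mu, sd, n_iter, rng, C, test_fraction, None, averaging, False
    )
    if flip:
        # keep state A on the positive side regardless of which was subsampled
        for plane in (report.hyperplane, report.mes_hyperplane):
            plane.intercept = -plane.intercept
            plane.coef = -plane.coef

    # shuffled-label null: reshuffle epochs across the two states, same counts
    zall = np.vstack([zp, zc])
    zs = zall[rng.permutation(len(zall))]
    shuffled = _mc_fit(
        zs[: len(zp)], zs[len(zp) :], names_a, mu, sd, n_iter, rng, C,
        test_fraction, None, averaging, False,
    )
    return TwoStateReport(report=report, shuffled=shuffled)
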