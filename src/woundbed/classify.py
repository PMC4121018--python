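"""Tissue classifiers: Gaussian naive Bayes and kernel SVM.

Both learners consume the retained feature columns, z-scored with training
statistics baked into the model so raw queries are standardized
transparently.  The Bayes classifier models each feature with a per-class
normal marginal (variances floored at 1e-9) and picks the maximum
posterior; the SVM is a soft-margin one-vs-one machine with linear,
polynomial (degree 2 or 3, K = (gamma x.y + 1)^d) or RBF kernels.  Class
ties break in the fixed order granulation < slough < necrotic.

Models serialize to JSON: distribution parameters for Bayes; kernel spec,
support vectors and dual coefficients for the SVM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.svm import SVC

from .features import LABELS, META_COLUMNS
from .selection import SelectionResult

VAR_FLOOR = 1e-9
KERNELS = ("linear", "poly2", "poly3", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel configuration; `name` fixes the polynomial degree."""

    name: str = "poly3"
    C: float = 1.0
    gamma: float | str = "scale"  # "scale" = 1 / (n_features * var(X))
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.name!r}")

    @property
    def degree(self) -> int:
        return {"poly2": 2, "poly3": 3}.get(self.name, 3)

    @property
    def sklearn_kernel(self) -> str:
        return {"linear": "linear", "poly2": "poly", "poly3": "poly", "rbf": "rbf"}[self.name]


@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray  # zero-variance columns get scale 1

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale


def _design(table: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
    x = table[columns].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    return x, y


def _resolve_columns(table: pd.DataFrame, selection: SelectionResult | None) -> list[str]:
    if selection is not None:
        if not selection.retained:
            raise ValueError("selection retained no features")
        return list(selection.retained)
    return [c for c in table.columns if c not in META_COLUMNS]


def _present_classes(y: np.ndarray) -> list[str]:
    classes = [c for c in LABELS if (y == c).sum() > 0]
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training rows")
    return classes


# ---------------------------------------------------------------- naive Bayes


@dataclass
class BayesModel:
    classes: list[str]
    priors: np.ndarray            # (k,), sums to 1
    means: np.ndarray             # (k, d) on standardized features
    variances: np.ndarray         # (k, d), floored
    columns: list[str]
    standardizer: Standardizer = field(repr=False, default=None)  # type: ignore[assignment]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": "gaussian-naive-bayes",
            "classes": self.classes,
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "columns": self.columns,
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "scale": self.standardizer.scale.tolist(),
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "BayesModel":
        obj = json.loads(Path(path).read_text())
        if obj.get("kind") != "gaussian-naive-bayes":
            raise ValueError("not a Bayes model file")
        return cls(
            classes=list(obj["classes"]),
            priors=np.asarray(obj["priors"]),
            means=np.asarray(obj["means"]),
            variances=np.asarray(obj["variances"]),
            columns=list(obj["columns"]),
            standardizer=Standardizer(
                mean=np.asarray(obj["standardizer"]["mean"]),
                scale=np.asarray(obj["standardizer"]["scale"]),
            ),
        )


def fit_bayes(table: pd.DataFrame, selection: SelectionResult | None = None) -> BayesModel:
    """Maximum-likelihood per-class normal marginals on standardized features."""
    columns = _resolve_columns(table, selection)
    x, y = _design(table, columns)
    classes = _present_classes(y)
    std = Standardizer.fit(x)
    xs = std.transform(x)
    priors = np.array([(y == c).mean() for c in classes])
    means = np.stack([xs[y == c].mean(axis=0) for c in classes])
    variances = np.stack([xs[y == c].var(axis=0) for c in classes])
    variances = np.maximum(variances, VAR_FLOOR)
    return BayesModel(classes, priors, means, variances, columns, std)


def bayes_posteriors(model: BayesModel, x: np.ndarray) -> np.ndarray:
    """Posterior matrix (n, k); rows sum to 1.  Computed in the log domain."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != len(model.columns):
        raise ValueError("query width does not match the model's feature manifest")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite query values")
    xs = model.standardizer.transform(x)
    ll = -0.5 * (
        np.log(2.0 * np.pi * model.variances)[None, :, :]
        + (xs[:, None, :] - model.means[None, :, :]) ** 2 / model.variances[None, :, :]
    ).sum(axis=2)
    logpost = ll + np.log(model.priors)[None, :]
    return np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))


def predict_bayes(model: BayesModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Label and posterior triple for one query vector."""
    post = bayes_posteriors(model, x)[0]
    return model.classes[int(np.argmax(post))], post


def predict_bayes_table(model: BayesModel, table: pd.DataFrame) -> np.ndarray:
    x = table[model.columns].to_numpy(dtype=np.float64)
    post = bayes_posteriors(model, x)
    return np.asarray(model.classes)[np.argmax(post, axis=1)]


# ----------------------------------------------------------------------- SVM


@dataclass
class SvmModel:
    kernel: KernelSpec
    classes: list[str]
    columns: list[str]
    standardizer: Standardizer = field(repr=False)
    gamma_value: float = 1.0
    support_vectors: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    dual_coef: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    intercepts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    n_support: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": "ovo-kernel-svm",
            "kernel": {"name": self.kernel.name, "C": self.kernel.C,
                       "coef0": self.kernel.coef0, "gamma": self.gamma_value},
            "classes": self.classes,
            "columns": self.columns,
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "scale": self.standardizer.scale.tolist(),
            },
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercepts": self.intercepts.tolist(),
            "n_support": self.n_support.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SvmModel":
        obj = json.loads(Path(path).read_text())
        if obj.get("kind") != "ovo-kernel-svm":
            raise ValueError("not an SVM model file")
        k = obj["kernel"]
        return cls(
            kernel=KernelSpec(name=k["name"], C=k["C"], gamma=k["gamma"], coef0=k["coef0"]),
            classes=list(obj["classes"]),
            columns=list(obj["columns"]),
            standardizer=Standardizer(
                mean=np.asarray(obj["standardizer"]["mean"]),
                scale=np.asarray(obj["standardizer"]["scale"]),
            ),
            gamma_value=float(k["gamma"]),
            support_vectors=np.asarray(obj["support_vectors"]),
            dual_coef=np.asarray(obj["dual_coef"]),
            intercepts=np.asarray(obj["intercepts"]),
            n_support=np.asarray(obj["n_support"], dtype=np.int64),
        )


def _kernel_matrix(spec: KernelSpec, gamma: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if spec.name == "linear":
        return a @ b.T
    if spec.name in ("poly2", "poly3"):
        return (gamma * (a @ b.T) + spec.coef0) ** spec.degree
    # rbf
    sq = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-gamma * sq)


def fit_svm(
    table: pd.DataFrame,
    selection: SelectionResult | None = None,
    kernel: KernelSpec | None = None,
) -> SvmModel:
    """Train the soft-margin one-vs-one SVM on standardized retained features."""
    kernel = kernel or KernelSpec()
    columns = _resolve_columns(table, selection)
    x, y = _design(table, columns)
    classes = _present_classes(y)
    std = Standardizer.fit(x)
    xs = std.transform(x)
    y_idx = np.array([classes.index(c) for c in y])

    clf = SVC(
        kernel=kernel.sklearn_kernel,
        degree=kernel.degree,
        gamma=kernel.gamma,
        coef0=kernel.coef0,
        C=kernel.C,
    )
    clf.fit(xs, y_idx)
    dual_coef = clf.dual_coef_.copy()
    intercepts = clf.intercept_.copy()
    if len(classes) == 2:
        # sklearn inverts the binary decision function relative to its own
        # one-vs-one layout; normalize so positive always favors the first
        # class of the pair
        dual_coef, intercepts = -dual_coef, -intercepts
    return SvmModel(
        kernel=kernel,
        classes=classes,
        columns=columns,
        standardizer=std,
        gamma_value=float(clf._gamma),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=dual_coef,
        intercepts=intercepts,
        n_support=clf.n_support_.copy(),
    )


def svm_decision_ovo(model: SvmModel, x: np.ndarray) -> np.ndarray:
    """Pairwise decision values, one column per class pair (i < j).

    Positive favors the earlier class.  Computed from the stored support
    vectors and dual coefficients, so a deserialized model predicts
    identically to a freshly trained one.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != len(model.columns):
        raise ValueError("query width does not match the model's feature manifest")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite query values")
    xs = model.standardizer.transform(x)
    k = len(model.classes)
    starts = np.concatenate([[0], np.cumsum(model.n_support)])
    kmat = _kernel_matrix(model.kernel, model.gamma_value, xs, model.support_vectors)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out = np.empty((xs.shape[0], len(pairs)))
    for pidx, (i, j) in enumerate(pairs):
        ci = model.dual_coef[j - 1, starts[i]:starts[i + 1]]
        cj = model.dual_coef[i, starts[j]:starts[j + 1]]
        out[:, pidx] = (
            kmat[:, starts[i]:starts[i + 1]] @ ci
            + kmat[:, starts[j]:starts[j + 1]] @ cj
            + model.intercepts[pidx]
        )
    return out


def predict_svm(model: SvmModel, x: np.ndarray) -> np.ndarray:
    """One-vs-one vote; ties resolved by the fixed class order."""
    dec = svm_decision_ovo(model, x)
    k = len(model.classes)
    votes = np.zeros((dec.shape[0], k), dtype=np.int64)
    pidx = 0
    for i in range(k):
        for j in range(i + 1, k):
            win = np.where(dec[:, pidx] > 0, i, j)
            votes[np.arange(dec.shape[0]), win] += 1
            pidx += 1
    return np.asarray(model.classes)[np.argmax(votes, axis=1)]


def predict_svm_table(model: SvmModel, table: pd.DataFrame) -> np.ndarray:
    return predict_svm(model, table[model.columns].to_numpy(dtype=np.float64))
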