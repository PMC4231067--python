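"""Soft-margin kernel SVMs composed into a one-against-others ensemble.

The binary machines solve the usual soft-margin dual (here via scikit-learn's
libsvm backend); the contribution of this module is the surrounding contract:
a genome-driven kernel/penalty assignment per class, a shared feature mask,
decision values reconstructed *from the stored support vectors and dual
coefficients* (so a serialized model predicts identically after reload), and
deterministic argmax aggregation over the m one-against-others members.

Kernels (x, y already masked):

    linear       x . y
    quadratic    (x . y + 1)^2
    polynomial   (x . y + 1)^u
    rbf          exp(-||x - y||^2 / (2 sigma^2))
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import InputError, InvalidGenomeError, TrainingError
from .genome import ClassifierGenes, Genome


@dataclass(frozen=True)
class KernelSpec:
    """A kernel kind plus exactly the parameter that kind requires."""

    kind: str
    u: int | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic", "polynomial", "rbf"):
            raise InputError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and (self.u is None or self.u < 1):
            raise InputError("polynomial kernel needs integer degree u >= 1")
        if self.kind == "rbf" and (self.sigma is None or self.sigma <= 0):
            raise InputError("rbf kernel needs width sigma > 0")

    @classmethod
    def from_genes(cls, genes: ClassifierGenes) -> "KernelSpec":
        return cls(kind=genes.kind, u=genes.u, sigma=genes.sigma)


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Y[j]) for masked feature matrices."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise InputError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.kind == "linear":
        return X @ Y.T
    if spec.kind in ("quadratic", "polynomial"):
        degree = 2 if spec.kind == "quadratic" else int(spec.u)  # type: ignore[arg-type]
        return (X @ Y.T + 1.0) ** degree
    # rbf
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * (X @ Y.T)
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * spec.sigma**2))  # type: ignore[operator]


def kernel_eval(spec: KernelSpec, x: Sequence[float], y: Sequence[float]) -> float:
    """Scalar kernel evaluation k(x, y)."""
    return float(kernel_matrix(spec, np.atleast_2d(x), np.atleast_2d(y))[0, 0])


def _svc_params(spec: KernelSpec) -> dict:
    if spec.kind == "linear":
        return {"kernel": "linear"}
    if spec.kind in ("quadratic", "polynomial"):
        degree = 2 if spec.kind == "quadratic" else int(spec.u)  # type: ignore[arg-type]
        return {"kernel": "poly", "degree": degree, "gamma": 1.0, "coef0": 1.0}
    return {"kernel": "rbf", "gamma": 1.0 / (2.0 * spec.sigma**2)}  # type: ignore[operator]


@dataclass
class BinarySVM:
    """One trained soft-margin machine, self-contained for prediction.

    ``decision`` is computed from the stored fields only:
    f(x) = sum_i alpha_i k(sv_i, x) + b, with sign(f) the predicted label.
    """

    support_vectors: np.ndarray  # (n_sv, n_masked_features)
    dual_coef: np.ndarray  # (n_sv,), alpha_i * y_i
    bias: float
    kernel: KernelSpec
    C: float
    positive_class: str

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.dual_coef = np.asarray(self.dual_coef, dtype=np.float64)
        if self.dual_coef.size != self.support_vectors.shape[0]:
            raise InputError("one dual coefficient per support vector required")

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Decision values f(X) for masked inputs (positive -> positive class)."""
        K = kernel_matrix(self.kernel, np.atleast_2d(X), self.support_vectors)
        return K @ self.dual_coef + self.bias


def train_binary_svm(
    X: np.ndarray,
    y: Sequence[int],
    kernel: KernelSpec,
    C: float,
    positive_class: str = "+1",
) -> BinarySVM:
    """Fit one soft-margin machine on labels in {-1, +1}."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if C <= 0:
        raise TrainingError(f"penalty C must be positive, got {C}")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise TrainingError(
            f"both labels must be present: {n_pos} positive, {n_neg} negative samples"
        )
    svc = SVC(C=C, **_svc_params(kernel))
    svc.fit(X, y)
    # libsvm orders classes as [-1, +1]; decision_function > 0 predicts +1,
    # matching f(x) = dual_coef . k(sv, x) + intercept directly.
    return BinarySVM(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        kernel=kernel,
        C=float(C),
        positive_class=positive_class,
    )


@dataclass
class OvREnsemble:
    """m one-against-others machines sharing one feature mask."""

    members: list[BinarySVM]
    class_order: list[str]
    feature_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.class_order):
            raise InputError("one member per class required")

    @property
    def n_classes(self) -> int:
        return len(self.members)

    def _masked(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.feature_mask):
            raise InputError(
                f"expected {len(self.feature_mask)}-dimensional features, got {X.shape[1]}"
            )
        return X[:, np.asarray(self.feature_mask, dtype=bool)]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, m) matrix of per-member decision values."""
        Xm = self._masked(X)
        return np.column_stack([m.decision(Xm) for m in self.members])

    def predict(self, X: np.ndarray) -> list[str]:
        """argmax over members' decision values; ties break to the lowest class index."""
        D = self.decision_values(X)
        return [self.class_order[i] for i in np.argmax(D, axis=1)]

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "feature_mask": [bool(b) for b in self.feature_mask],
            "members": [
                {
                    "positive_class": m.positive_class,
                    "kernel": {"kind": m.kernel.kind, "u": m.kernel.u, "sigma": m.kernel.sigma},
                    "C": m.C,
                    "support_vectors": m.support_vectors.tolist(),
                    "dual_coef": m.dual_coef.tolist(),
                    "bias": m.bias,
                }
                for m in self.members
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OvREnsemble":
        members = [
            BinarySVM(
                support_vectors=np.asarray(md["support_vectors"], dtype=np.float64),
                dual_coef=np.asarray(md["dual_coef"], dtype=np.float64),
                bias=float(md["bias"]),
                kernel=KernelSpec(
                    kind=md["kernel"]["kind"],
                    u=md["kernel"]["u"],
                    sigma=md["kernel"]["sigma"],
                ),
                C=float(md["C"]),
                positive_class=md["positive_class"],
            )
            for md in d["members"]
        ]
        return cls(
            members=members,
            class_order=list(d["class_order"]),
            feature_mask=tuple(bool(b) for b in d["feature_mask"]),
        )


def train_ovr_ensemble(
    X: np.ndarray,
    y: Sequence[str],
    genome: Genome,
    class_order: Sequence[str] | None = None,
) -> OvREnsemble:
    """Train one binary machine per class under the genome's shared mask.

    Member i is trained on labels (+1 for class i, -1 for the rest) with the
    genome's kernel_i, parameter_i and C_i.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    genome.validate()
    if X.shape[1] != genome.n_features:
        raise InputError(
            f"genome mask covers {genome.n_features} features, data has {X.shape[1]}"
        )
    classes = list(class_order) if class_order is not None else sorted(set(y))
    if len(classes) != genome.n_classes:
        raise InvalidGenomeError(
            f"genome carries {genome.n_classes} classifiers for {len(classes)} classes"
        )
    for c in classes:
        if int(np.sum(y == c)) == 0:
            raise TrainingError(f"class {c!r} has no training samples")
    mask = np.asarray(genome.mask, dtype=bool)
    Xm = X[:, mask]
    members = []
    for cls_label, genes in zip(classes, genome.classifiers):
        yi = np.where(y == cls_label, 1, -1)
        members.append(
            train_binary_svm(
                Xm, yi, KernelSpec.from_genes(genes), genes.C, positive_class=str(cls_label)
            )
        )
    return OvREnsemble(members=members, class_order=[str(c) for c in classes], feature_mask=genome.mask)


def predict(ensemble: OvREnsemble, feature_vector: np.ndarray) -> str:
    """Predicted class of one unmasked feature vector."""
    return ensemble.predict(np.atleast_2d(feature_vector))[0]


def count_support_vectors(ensemble: OvREnsemble) -> int:
    """Total support vectors across all members (model-complexity proxy)."""
    return int(sum(m.n_support for m in ensemble.members))


def save_model(ensemble: OvREnsemble, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize an ensemble (plus optional preprocessing metadata) to JSON."""
    doc = {"ensemble": ensemble.to_dict(), "metadata": metadata or {}}
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[OvREnsemble, dict]:
    doc = json.loads(Path(path).read_text())
    return OvREnsemble.from_dict(doc["ensemble"]), doc.get("metadata", {})
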