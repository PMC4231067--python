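"""Model-selection genome shared by the SVM ensemble and the search optimizer.

A genome fixes everything the one-against-others ensemble needs beyond the
training data: which LPC coefficients are fed to the classifiers (a shared
boolean feature mask) and, for each of the m binary classifiers, a kernel
kind, its parameter, and the soft-margin penalty C.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidGenomeError

KERNEL_KINDS: tuple[str, ...] = ("linear", "quadratic", "polynomial", "rbf")

#: admissible decoded ranges (log2 space for sigma and C)
U_RANGE = (1, 6)
SIGMA_LOG2_RANGE = (-10.0, 3.0)
C_LOG2_RANGE = (-5.0, 15.0)


@dataclass(frozen=True)
class ClassifierGenes:
    """Kernel kind, kernel parameter, and penalty of one binary classifier."""

    kind: str
    u: int | None = None  # polynomial degree (quadratic fixes u = 2)
    sigma: float | None = None  # RBF width
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise InvalidGenomeError(f"unknown kernel kind {self.kind!r}")
        if self.C <= 0:
            raise InvalidGenomeError(f"penalty C must be positive, got {self.C}")
        if self.kind == "polynomial" and (self.u is None or self.u < 1):
            raise InvalidGenomeError("polynomial kernel needs integer degree u >= 1")
        if self.kind == "rbf" and (self.sigma is None or self.sigma <= 0):
            raise InvalidGenomeError("rbf kernel needs width sigma > 0")

    @property
    def degree(self) -> int:
        """Effective polynomial degree (2 for the quadratic kind)."""
        if self.kind == "quadratic":
            return 2
        if self.kind == "polynomial":
            return int(self.u)  # type: ignore[arg-type]
        raise InvalidGenomeError(f"{self.kind} kernel has no degree")


@dataclass(frozen=True)
class Genome:
    """One candidate model: feature mask + per-classifier kernel/penalty genes."""

    mask: tuple[bool, ...]
    classifiers: tuple[ClassifierGenes, ...]

    @property
    def n_features(self) -> int:
        return len(self.mask)

    @property
    def n_selected(self) -> int:
        return sum(self.mask)

    @property
    def n_classes(self) -> int:
        return len(self.classifiers)

    def validate(self) -> None:
        if self.n_selected == 0:
            raise InvalidGenomeError("genome selects no features")


def fixed_kernel_genome(
    n_classes: int,
    kind: str,
    u: int | None = None,
    sigma: float | None = None,
    C: float = 1.0,
    n_features: int = 24,
) -> Genome:
    """A baseline genome: full feature mask, one kernel shared by all members."""
    genes = ClassifierGenes(kind=kind, u=u, sigma=sigma, C=C)
    return Genome(mask=(True,) * n_features, classifiers=(genes,) * n_classes)
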