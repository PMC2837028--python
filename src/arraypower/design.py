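"""Study design parameters and the multiple-testing outcome table.

A two-group differential-expression study screens ``m`` genes of which
``m1`` are truly differentially expressed with standardized effect sizes
``delta_i`` (difference in group means per within-group standard
deviation).  The investigator fixes an FDR target ``q*``, a sensitivity
target ``lambda0`` (the fraction of the ``m1`` genes the study should
detect) and, for the 95%-probability formulation, a confidence target
``phi0`` with which that sensitivity must be attained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDesignError

__all__ = ["StudyDesign", "OutcomeCounts"]


@dataclass(frozen=True)
class StudyDesign:
    """Planning parameters for a two-group, equal-allocation study.

    Parameters
    ----------
    m : int
        Total number of genes on the array.
    m1 : int
        Number of truly differentially expressed genes (0 < m1 < m).
        May be given instead as ``pi1 = m1 / m`` via :meth:`from_pi1`.
    effect_sizes : float or array-like
        Standardized effect size(s) ``delta``.  A scalar is broadcast to
        all ``m1`` genes; a vector must have length ``m1``.
    fdr_target : float
        FDR level ``q*`` in (0, 1) at which discoveries will be called.
    sensitivity_target : float
        Desired sensitivity ``lambda0`` in (0, 1).
    confidence_target : float
        Probability ``phi0`` with which the sensitivity must be reached
        under the 95%-probability formulation (default 0.95).
    """

    m: int
    m1: int
    effect_sizes: object
    fdr_target: float
    sensitivity_target: float
    confidence_target: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.m1 < self.m):
            raise InvalidDesignError(f"require 0 < m1 < m, got m1={self.m1}, m={self.m}")
        deltas = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        if deltas.size not in (1, self.m1):
            raise InvalidDesignError(
                f"effect_sizes must be scalar or length m1={self.m1}, got length {deltas.size}"
            )
        if not np.all(deltas > 0):
            raise InvalidDesignError("all effect sizes must be > 0")
        if not (0 < self.fdr_target < 1):
            raise InvalidDesignError(f"fdr_target must be in (0,1), got {self.fdr_target}")
        if not (0 < self.sensitivity_target < 1):
            raise InvalidDesignError(
                f"sensitivity_target must be in (0,1), got {self.sensitivity_target}"
            )
        if not (0.5 <= self.confidence_target < 1):
            raise InvalidDesignError(
                f"confidence_target must be in [0.5,1), got {self.confidence_target}"
            )

    @classmethod
    def from_pi1(cls, m: int, pi1: float, effect_sizes, fdr_target: float,
                 sensitivity_target: float, confidence_target: float = 0.95) -> "StudyDesign":
        """Build a design from the differential proportion ``pi1 = m1/m``."""
        m1 = int(round(m * pi1))
        return cls(m=m, m1=m1, effect_sizes=effect_sizes, fdr_target=fdr_target,
                   sensitivity_target=sensitivity_target, confidence_target=confidence_target)

    @property
    def m0(self) -> int:
        return self.m - self.m1

    @property
    def pi1(self) -> float:
        return self.m1 / self.m

    @property
    def deltas(self) -> np.ndarray:
        """Per-gene standardized effect sizes, broadcast to length ``m1``."""
        d = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        return np.broadcast_to(d, (self.m1,)) if d.size == 1 else d

    @property
    def alpha(self) -> float:
        """Per-comparison significance level implied by the FDR target."""
        from .power import percomparison_alpha

        return percomparison_alpha(self.m0, self.m1, self.sensitivity_target, self.fdr_target)


@dataclass(frozen=True)
class OutcomeCounts:
    """The 2x2 decision table of one multiple-testing run.

    ``V`` false positives, ``S`` true negatives (V + S = m0);
    ``U`` true positives, ``T`` false negatives (U + T = m1);
    ``R = V + U`` total rejections.
    """

    V: int
    U: int
    m0: int
    m1: int
    S: int = field(init=False)
    T: int = field(init=False)

    def __post_init__(self) -> None:
        if min(self.V, self.U, self.m0, self.m1) < 0:
            raise ValueError("counts must be non-negative")
        if self.V > self.m0 or self.U > self.m1:
            raise ValueError("V <= m0 and U <= m1 required")
        object.__setattr__(self, "S", self.m0 - self.V)
        object.__setattr__(self, "T", self.m1 - self.U)

    @property
    def R(self) -> int:
        return self.V + self.U

    @property
    def fdr_realization(self) -> float:
        """V / max(R, 1) -- the realized false discovery proportion."""
        return self.V / max(self.R, 1)

    @property
    def sensitivity(self) -> float:
        """U / m1 -- the realized true positive rate."""
        return self.U / self.m1
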