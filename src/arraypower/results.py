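"""Results containers with statsmodels-style ``summary()`` tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = ["SampleSizeResult"]


@dataclass
class SampleSizeResult:
    """Outcome of a sample-size solver.

    Attributes
    ----------
    n : int
        Estimated per-group sample size.
    method : str
        One of ``average_univariate``, ``confidence_binomial``,
        ``confidence_permutation``, ``confidence_permutation_unadjusted``.
    alpha : float
        Per-comparison significance level used.
    achieved_sensitivity : float
        Expected sensitivity (average per-gene power) at ``n``; for the
        permutation method, the mean of u_b / m1 at the accepted ``n``.
    achieved_confidence : float
        Probability of reaching the sensitivity target at ``n`` for the
        analytic methods; ``u* / m1`` for the permutation method.
    trace : list of (n, criterion value)
        One entry per candidate sample size visited, in increasing order
        of ``n``.
    n_initial : int, optional
        Starting candidate (permutation method only).
    f_trace : list of (n, f1, f2), optional
        Adjustment factors per candidate (permutation method only).
    seed : int, optional
        RNG seed used (stochastic methods only).
    monte_carlo_relabelings : bool
        True when the relabeling ensemble was subsampled rather than
        fully enumerated.
    """

    n: int
    method: str
    alpha: float
    achieved_sensitivity: float
    achieved_confidence: float
    trace: Sequence[Tuple[int, float]] = field(default_factory=list)
    n_initial: Optional[int] = None
    f_trace: Sequence[Tuple[int, float, float]] = field(default_factory=list)
    seed: Optional[int] = None
    monte_carlo_relabelings: bool = False

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "method": self.method,
            "alpha": float(self.alpha),
            "achieved_sensitivity": float(self.achieved_sensitivity),
            "achieved_confidence": float(self.achieved_confidence),
            "trace": [[int(a), float(b)] for a, b in self.trace],
            "n_initial": None if self.n_initial is None else int(self.n_initial),
            "f_trace": [[int(a), float(b), float(c)] for a, b, c in self.f_trace],
            "seed": self.seed,
            "monte_carlo_relabelings": bool(self.monte_carlo_relabelings),
        }

    def summary(self) -> str:
        lines = [
            "Sample Size Estimate",
            "=" * 44,
            f"{'method':<28}{self.method:>16}",
            f"{'per-group sample size n':<28}{self.n:>16d}",
            f"{'per-comparison alpha':<28}{self.alpha:>16.6g}",
            f"{'achieved sensitivity':<28}{self.achieved_sensitivity:>16.4f}",
            f"{'achieved confidence':<28}{self.achieved_confidence:>16.4f}",
        ]
        if self.n_initial is not None:
            lines.append(f"{'initial candidate n':<28}{self.n_initial:>16d}")
        if self.seed is not None:
            lines.append(f"{'seed':<28}{self.seed:>16d}")
        lines.append("=" * 44)
        if self.trace:
            lines.append("candidate trace (n, criterion):")
            for cand, val in self.trace:
                lines.append(f"  n={cand:<5d} {val:.4f}")
        return "\n".join(lines)
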