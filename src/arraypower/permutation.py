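"""Pilot-data permutation estimator of sample size.

The estimator answers: given a small pilot expression matrix (>= 4
samples per group recommended), how many arrays per group are needed so
that at least a fraction ``lambda0`` of the ``m1`` differential genes is
detected with 95% probability at the per-comparison level implied by the
FDR target?  Because critical values and the sensitivity distribution
are taken from relabelings of the observed pilot, the estimate inherits
the pilot's gene-gene correlation and variance structure without
modeling either.

Sketch of the procedure, for a candidate per-group size ``n``:

1. enumerate all N = C(n0p + n1p, n0p) relabelings of the pooled pilot
   samples and compute per-gene pooled-variance t-statistics;
2. shrink every t by the adjustment factor ``f = f1 * f2`` -- ``f1``
   maps pilot-df t quantiles onto target-df quantiles, ``f2`` undoes the
   maximum-likelihood variance convention -- so the permutation null
   mimics the spread expected at the target size;
3. per relabeling, designate ``m1`` random genes as differential and add
   to each the t-scale effect ``delta_i * sqrt(n/2) / s_i`` (``s_i`` the
   pilot's pooled standard deviation under the original labeling);
4. pool the non-designated statistics into an empirical null, take its
   alpha/2 and 1 - alpha/2 quantiles as critical values, and count the
   designated genes detected, ``u_b``, per relabeling;
5. accept ``n`` when the 5th percentile ``u*`` of the ``u_b`` reaches
   ``m1 * lambda0``; otherwise increase ``n`` and repeat from 2.

The unadjusted mode forces ``f = 1`` (the classical pilot-permutation
recipe); it overestimates the needed size when the pilot is much smaller
than the target because small-sample t-statistics are overdispersed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .design import StudyDesign
from .errors import DataError, NonConvergenceError
from .power import sample_size_confidence
from .results import SampleSizeResult

__all__ = [
    "PilotDataset",
    "PermutationEnsemble",
    "AdjustmentFactors",
    "enumerate_relabelings",
    "gene_t_statistics",
    "adjustment_factors",
    "build_ensemble",
    "build_shifted_statistics",
    "null_critical_values",
    "count_detected",
    "PermutationSampleSize",
    "estimate_sample_size",
]

#: enumeration guard: C(20, 10) = 184,756 relabelings
DEFAULT_MAX_SAMPLES = 20


@dataclass
class PilotDataset:
    """Pilot expression matrix with two-group sample labels.

    ``values`` is genes x samples; ``group_labels`` assigns each column
    to one of exactly two groups (the first label encountered is taken
    as the control group).  Groups need at least 3 samples; fewer than 4
    triggers a warning.
    """

    values: np.ndarray
    gene_ids: Sequence[str]
    group_labels: Sequence[str]
    drop_degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("pilot matrix must be 2-dimensional (genes x samples)")
        m, ntot = self.values.shape
        if len(self.gene_ids) != m:
            raise DataError("gene_ids length must match the number of rows")
        labels = np.asarray(self.group_labels)
        if labels.size != ntot:
            raise DataError("group_labels length must match the number of columns")
        uniq = list(dict.fromkeys(labels.tolist()))
        if len(uniq) != 2:
            raise DataError(f"exactly two groups required, found {uniq}")
        self._groups = uniq
        n0p = int(np.sum(labels == uniq[0]))
        n1p = int(np.sum(labels == uniq[1]))
        for name, count in ((uniq[0], n0p), (uniq[1], n1p)):
            if count < 3:
                raise DataError(f"group {name!r} has {count} samples; at least 3 required")
            if count < 4:
                warnings.warn(
                    f"group {name!r} has only {count} samples; at least 4 per group "
                    "is recommended for the permutation estimator",
                    stacklevel=2,
                )
        constant = np.ptp(self.values, axis=1) == 0
        if np.any(constant):
            if self.drop_degenerate:
                kept = ~constant
                warnings.warn(
                    f"dropping {int(constant.sum())} constant gene row(s) with zero variance",
                    stacklevel=2,
                )
                self.values = self.values[kept]
                self.gene_ids = [g for g, k in zip(self.gene_ids, kept) if k]
            else:
                bad = [g for g, c in zip(self.gene_ids, constant) if c]
                raise DataError(
                    f"gene row(s) with zero variance: {bad[:5]}; remove them or pass "
                    "drop_degenerate=True"
                )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n0p(self) -> int:
        return int(np.sum(np.asarray(self.group_labels) == self._groups[0]))

    @property
    def n1p(self) -> int:
        return int(np.sum(np.asarray(self.group_labels) == self._groups[1]))

    @property
    def control_columns(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.group_labels) == self._groups[0])

    @property
    def ordered_values(self) -> np.ndarray:
        """Matrix with control columns first, then treatment columns."""
        labels = np.asarray(self.group_labels)
        order = np.concatenate([
            np.flatnonzero(labels == self._groups[0]),
            np.flatnonzero(labels == self._groups[1]),
        ])
        return self.values[:, order]


@dataclass
class AdjustmentFactors:
    """Scale factors mapping pilot t-statistics to the target size.

    ``f1`` is the ratio of upper alpha/2 central-t quantiles at the
    target df (2n - 2) over the pilot df (n0p + n1p - 2); ``f2`` =
    sqrt(Np / (Np - 2)) converts the maximum-likelihood variance
    convention to the pooled-df one.  Both tend to 1 as the pilot grows.
    """

    f1: float
    f2: float

    @property
    def f(self) -> float:
        return self.f1 * self.f2


@dataclass
class PermutationEnsemble:
    """All relabelings of a pilot with per-gene statistics.

    ``t`` and ``sd`` are (N, m) arrays, one row per relabeling in
    deterministic lexicographic order (original labeling first).  After
    :func:`build_shifted_statistics`, ``alt_index_sets`` (N, m1) holds
    the designated differential genes per relabeling and ``s0`` / ``s1``
    the shifted null and alternative statistics.
    """

    assignments: List[Tuple[int, ...]]
    t: np.ndarray
    sd: np.ndarray
    monte_carlo: bool = False
    alt_index_sets: Optional[np.ndarray] = None
    s0: Optional[np.ndarray] = None
    s1: Optional[np.ndarray] = None

    @property
    def N(self) -> int:
        return len(self.assignments)

    @property
    def sd_original(self) -> np.ndarray:
        """Pooled per-gene standard deviations under the original labeling."""
        return self.sd[0]


def enumerate_relabelings(n0p: int, n1p: int,
                          max_samples: int = DEFAULT_MAX_SAMPLES) -> List[Tuple[int, ...]]:
    """All C(n0p+n1p, n0p) assignments of pooled samples to pseudo-control.

    Lexicographic order; the original labeling (first n0p columns) comes
    first.  Raises for combined sizes above ``max_samples`` -- use the
    Monte-Carlo option of :class:`PermutationSampleSize` instead.
    """
    if n0p < 3 or n1p < 3:
        raise DataError("each pilot group needs at least 3 samples")
    ntot = n0p + n1p
    if ntot > max_samples:
        raise DataError(
            f"{ntot} pooled samples give C({ntot},{n0p}) = {math.comb(ntot, n0p)} "
            f"relabelings (cap {max_samples} samples); use Monte-Carlo subsampling "
            "(max_relabelings option)"
        )
    return list(combinations(range(ntot), n0p))


def gene_t_statistics(values: np.ndarray, assignment: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t and pooled sd per gene row.

    ``assignment`` lists the pseudo-control columns; the remaining
    columns form the pseudo-treatment group.  The statistic is
    pseudo-treatment minus pseudo-control over the pooled standard
    error, df = n0p + n1p - 2.
    """
    values = np.asarray(values, dtype=float)
    ntot = values.shape[1]
    ctrl = np.asarray(assignment, dtype=int)
    trt = np.setdiff1d(np.arange(ntot), ctrl)
    if ctrl.size < 2 or trt.size < 2:
        raise DataError("each pseudo-group needs at least 2 samples")
    x0, x1 = values[:, ctrl], values[:, trt]
    df = ntot - 2
    ss = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sd = np.sqrt(ss / df)
    if np.any(sd == 0):
        raise DataError("zero pooled variance encountered in a gene row")
    t = (x1.mean(axis=1) - x0.mean(axis=1)) / (sd * math.sqrt(1 / ctrl.size + 1 / trt.size))
    return t, sd


def adjustment_factors(n_target: int, n0p: int, n1p: int, alpha: float) -> AdjustmentFactors:
    """Adjustment factor f = f1 * f2 for a candidate target size."""
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    np_ = n0p + n1p
    if np_ <= 2:
        raise DataError("pilot too small: f2 undefined for n0p + n1p <= 2")
    q = 1.0 - alpha / 2.0
    f1 = float(stats.t.ppf(q, 2 * n_target - 2) / stats.t.ppf(q, np_ - 2))
    f2 = math.sqrt(np_ / (np_ - 2))
    return AdjustmentFactors(f1=f1, f2=f2)


def build_ensemble(pilot: PilotDataset, max_samples: int = DEFAULT_MAX_SAMPLES,
                   max_relabelings: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None) -> PermutationEnsemble:
    """Compute t and sd vectors for all (or a subsample of) relabelings."""
    values = pilot.ordered_values
    n0p, n1p = pilot.n0p, pilot.n1p
    monte_carlo = False
    try:
        assigns = enumerate_relabelings(n0p, n1p, max_samples=max_samples)
    except DataError:
        if max_relabelings is None:
            raise
        assigns = None
    if assigns is not None and max_relabelings is not None and len(assigns) > max_relabelings:
        assigns = None
    if assigns is None:
        if rng is None:
            raise DataError("Monte-Carlo subsampling of relabelings requires an rng")
        ntot = n0p + n1p
        seen = {tuple(range(n0p))}  # keep the original labeling
        while len(seen) < max_relabelings:
            seen.add(tuple(sorted(rng.choice(ntot, size=n0p, replace=False).tolist())))
        assigns = sorted(seen)
        assigns.remove(tuple(range(n0p)))
        assigns.insert(0, tuple(range(n0p)))
        monte_carlo = True
    N, m = len(assigns), pilot.m
    t = np.empty((N, m))
    sd = np.empty((N, m))
    for b, ctrl in enumerate(assigns):
        t[b], sd[b] = gene_t_statistics(values, ctrl)
    return PermutationEnsemble(assignments=assigns, t=t, sd=sd, monte_carlo=monte_carlo)


def build_shifted_statistics(ensemble: PermutationEnsemble, f: float, design: StudyDesign,
                             n_target: int, rng: np.random.Generator) -> PermutationEnsemble:
    """Populate s0/s1: scaled null statistics and spiked alternatives.

    Per relabeling, ``m1`` designated genes are drawn uniformly without
    replacement; their statistics receive the t-scale shift
    ``delta_i * sqrt(n_target / 2) / s_i`` with ``s_i`` the pilot pooled
    standard deviation under the original labeling.
    """
    N, m = ensemble.t.shape
    m1 = design.m1
    if m1 >= m:
        raise DataError(f"design m1={m1} must be smaller than the pilot gene count {m}")
    alt = np.empty((N, m1), dtype=int)
    for b in range(N):
        # sorted so row order matches the boolean-mask extraction below
        alt[b] = np.sort(rng.choice(m, size=m1, replace=False))
    mask = np.zeros((N, m), dtype=bool)
    mask[np.repeat(np.arange(N), m1), alt.ravel()] = True
    scaled = f * ensemble.t
    shift = design.deltas[None, :] * math.sqrt(n_target / 2.0) / ensemble.sd_original[alt]
    ensemble.alt_index_sets = alt
    ensemble.s0 = scaled[~mask].reshape(N, m - m1)
    ensemble.s1 = scaled[mask].reshape(N, m1) + shift
    return ensemble


def null_critical_values(s0_pool: np.ndarray, alpha: float) -> Tuple[float, float]:
    """Empirical alpha/2 and 1 - alpha/2 quantiles, nearest-rank rule.

    Ranks ceil((alpha/2) * P) and ceil((1 - alpha/2) * P) of the sorted
    pool of size P (1-based).
    """
    pool = np.asarray(s0_pool, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("empty null pool")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if pool.size < 2.0 / alpha:
        warnings.warn(
            f"null pool of size {pool.size} poorly resolves alpha = {alpha:.3g} quantiles",
            stacklevel=2,
        )
    pool = np.sort(pool)
    p = pool.size
    lo = pool[max(math.ceil(alpha / 2.0 * p), 1) - 1]
    hi = pool[max(math.ceil((1.0 - alpha / 2.0) * p), 1) - 1]
    return float(lo), float(hi)


def count_detected(s1b: np.ndarray, lower: float, upper: float) -> int:
    """Number of alternative statistics outside the acceptance interval."""
    s = np.asarray(s1b, dtype=float)
    return int(np.sum((s < lower) | (s > upper)))


class PermutationSampleSize:
    """Sample-size model fitted to a pilot expression dataset.

    Parameters
    ----------
    pilot : PilotDataset
        Pilot expression matrix with two-group labels.
    design : StudyDesign
        Planning parameters (m1, effect sizes, q*, lambda0, phi0).  The
        design's ``m``/``m1`` must refer to the pilot's gene count.
    mode : {"adjusted", "unadjusted"}
        ``adjusted`` applies f = f1 * f2; ``unadjusted`` forces f = 1
        (the classical pilot-permutation recipe).
    n_max : int
        Candidate-size cap before declaring non-convergence.
    max_relabelings : int, optional
        Monte-Carlo subsample size when full enumeration is infeasible.
    """

    def __init__(self, pilot: PilotDataset, design: StudyDesign, mode: str = "adjusted",
                 n_max: int = 1000, max_samples: int = DEFAULT_MAX_SAMPLES,
                 max_relabelings: Optional[int] = None) -> None:
        if mode not in ("adjusted", "unadjusted"):
            raise ValueError("mode must be 'adjusted' or 'unadjusted'")
        if design.m != pilot.m:
            raise DataError(
                f"design m={design.m} does not match the pilot gene count {pilot.m}"
            )
        self.pilot = pilot
        self.design = design
        self.mode = mode
        self.n_max = n_max
        self.max_samples = max_samples
        self.max_relabelings = max_relabelings

    def fit(self, seed: Optional[int] = None) -> SampleSizeResult:
        """Run the iterative search; deterministic for a fixed seed."""
        design = self.design
        rng = np.random.default_rng(seed)
        alpha = design.alpha
        n_init = sample_size_confidence(design).n
        ensemble = build_ensemble(self.pilot, max_samples=self.max_samples,
                                  max_relabelings=self.max_relabelings, rng=rng)
        N = ensemble.N
        n0p, n1p = self.pilot.n0p, self.pilot.n1p
        need = design.m1 * design.sensitivity_target
        k_star = max(math.ceil(0.05 * N), 1)  # nearest-rank 5th percentile
        trace, f_trace = [], []
        for n in range(n_init, self.n_max + 1):
            if self.mode == "adjusted":
                factors = adjustment_factors(n, n0p, n1p, alpha)
                f = factors.f
                f_trace.append((n, factors.f1, factors.f2))
            else:
                f = 1.0
                f_trace.append((n, 1.0, 1.0))
            build_shifted_statistics(ensemble, f, design, n, rng)
            lo, hi = null_critical_values(ensemble.s0, alpha)
            u = np.sort(np.array([count_detected(ensemble.s1[b], lo, hi) for b in range(N)]))
            u_star = int(u[k_star - 1])
            trace.append((n, u_star))
            if u_star >= need:
                method = ("confidence_permutation" if self.mode == "adjusted"
                          else "confidence_permutation_unadjusted")
                return SampleSizeResult(
                    n=n, method=method, alpha=alpha,
                    achieved_sensitivity=float(np.mean(u) / design.m1),
                    achieved_confidence=u_star / design.m1,
                    trace=trace, n_initial=n_init, f_trace=f_trace, seed=seed,
                    monte_carlo_relabelings=ensemble.monte_carlo,
                )
        raise NonConvergenceError(
            f"permutation search did not reach u* >= {need:.1f} by n = {self.n_max}"
        )


def estimate_sample_size(pilot: PilotDataset, design: StudyDesign, mode: str = "adjusted",
                         rng_seed: Optional[int] = None, **kwargs) -> SampleSizeResult:
    """Functional wrapper around :class:`PermutationSampleSize`."""
    return PermutationSampleSize(pilot, design, mode=mode, **kwargs).fit(seed=rng_seed)
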