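"""Simulation harness validating the sample-size formulations.

Two evaluation pipelines:

* :func:`empirical_performance` -- the independent-model protocol: genes
  are independent normals, the ``m1`` differential genes have mean shift
  ``delta0`` in the treatment group, pooled-t p-values are screened by
  the known-m0 step-up rule, and the empirical FDR, average sensitivity
  and confidence (fraction of replicates reaching the sensitivity
  target) are tallied over replicates.

* :func:`spike_in_resampling_eval` -- the resampling protocol for an
  arbitrary source matrix (e.g. a real dataset with correlated genes):
  columns are resampled, group labels permuted to remove any true
  difference, effects spiked into random genes, and per-gene
  permutation-test p-values screened the same way.

Per-replicate randomness is derived from the master seed by
counter-based spawning, so results do not depend on any execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .design import OutcomeCounts, StudyDesign
from .errors import DataError
from .permutation import PilotDataset

__all__ = [
    "SimulationSummary",
    "generate_independent_dataset",
    "generate_pilot",
    "fdr_call",
    "empirical_performance",
    "spike_in_resampling_eval",
]


@dataclass
class SimulationSummary:
    """Aggregate of per-replicate outcome tables."""

    reps: int
    empirical_fdr: float
    empirical_sensitivity: float
    empirical_confidence: float
    per_replicate_counts: List[OutcomeCounts]
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "empirical_fdr": self.empirical_fdr,
            "empirical_sensitivity": self.empirical_sensitivity,
            "empirical_confidence": self.empirical_confidence,
            "seed": self.seed,
        }

    def summary(self) -> str:
        return "\n".join([
            "Simulation Summary",
            "=" * 40,
            f"{'replicates':<28}{self.reps:>12d}",
            f"{'empirical FDR':<28}{self.empirical_fdr:>12.4f}",
            f"{'empirical sensitivity':<28}{self.empirical_sensitivity:>12.4f}",
            f"{'empirical confidence':<28}{self.empirical_confidence:>12.4f}",
            "=" * 40,
        ])


def _summarize(counts: List[OutcomeCounts], lam0: float, reps: int,
               seed: Optional[int]) -> SimulationSummary:
    fdr = float(np.mean([c.fdr_realization for c in counts]))
    sens = float(np.mean([c.sensitivity for c in counts]))
    conf = float(np.mean([c.U >= c.m1 * lam0 for c in counts]))
    return SimulationSummary(reps=reps, empirical_fdr=fdr, empirical_sensitivity=sens,
                             empirical_confidence=conf, per_replicate_counts=counts,
                             seed=seed)


def generate_independent_dataset(m: int, m1: int, delta0, n: int,
                                 rng_seed=None) -> Tuple[np.ndarray, np.ndarray]:
    """Independent-normal expression matrix with a known truth set.

    Returns an (m, 2n) matrix -- first n columns control ~ N(0,1), last
    n columns treatment ~ N(delta_i, 1) for the first ``m1`` gene rows
    (the truth set) and N(0,1) otherwise -- and the truth index vector.
    """
    if not (0 <= m1 < m):
        raise ValueError("require 0 <= m1 < m")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    x = rng.standard_normal((m, 2 * n))
    deltas = np.broadcast_to(np.atleast_1d(np.asarray(delta0, dtype=float)), (m1,))
    x[:m1, n:] += deltas[:, None]
    return x, np.arange(m1)


def generate_pilot(m: int, m1: int, delta0, n0p: int, n1p: int,
                   rng_seed=None, gene_prefix: str = "g") -> PilotDataset:
    """Synthetic pilot dataset from the independent-normal model."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    x = rng.standard_normal((m, n0p + n1p))
    deltas = np.broadcast_to(np.atleast_1d(np.asarray(delta0, dtype=float)), (m1,))
    x[:m1, n0p:] += deltas[:, None]
    return PilotDataset(
        values=x,
        gene_ids=[f"{gene_prefix}{i}" for i in range(m)],
        group_labels=["control"] * n0p + ["treatment"] * n1p,
    )


def fdr_call(p_values: np.ndarray, m0_true: int, q_star: float) -> np.ndarray:
    """Oracle-adaptive step-up rejection at FDR level ``q*``.

    Sorts p-values ascending (ties broken by gene index) and rejects the
    largest prefix k* with p_(k) <= k * q* / m0_true.  Using the true m0
    rather than m makes the rule exactly adaptive in simulations.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * q_star / m0_true
    passing = np.nonzero(p[order] <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def _pooled_t_pvalues(x: np.ndarray, n0: int) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values per gene row."""
    x0, x1 = x[:, :n0], x[:, n0:]
    n1 = x1.shape[1]
    df = n0 + n1 - 2
    ss = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    t = (x1.mean(axis=1) - x0.mean(axis=1)) / np.sqrt(ss / df * (1 / n0 + 1 / n1))
    return 2.0 * stats.t.sf(np.abs(t), df)


def empirical_performance(design: StudyDesign, n: int, reps: int,
                          rng_seed: Optional[int] = None) -> SimulationSummary:
    """Empirical FDR / sensitivity / confidence under the independent model.

    Per replicate: generate an independent dataset at per-group size
    ``n``, compute two-sided pooled-t p-values, call discoveries with
    the known-m0 step-up rule at ``q*``, and tally the outcome table.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(reps)
    counts: List[OutcomeCounts] = []
    for child in children:
        rng = np.random.default_rng(child)
        x, truth = generate_independent_dataset(design.m, design.m1, design.deltas, n, rng)
        reject = fdr_call(_pooled_t_pvalues(x, n), design.m0, design.fdr_target)
        u = int(reject[truth].sum())
        counts.append(OutcomeCounts(V=int(reject.sum()) - u, U=u,
                                    m0=design.m0, m1=design.m1))
    return _summarize(counts, design.sensitivity_target, reps, rng_seed)


def _permutation_pvalues(x: np.ndarray, n0: int, perm_reps: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-gene permutation-test p-values from random relabelings.

    The observed statistic joins the null set:
    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + perm_reps).
    """
    ntot = x.shape[1]
    x0, x1 = x[:, :n0], x[:, n0:]
    n1 = ntot - n0
    df = ntot - 2

    def tstat(a, b):
        ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
            + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        return (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(ss / df * (1 / n0 + 1 / n1))

    t_obs = np.abs(tstat(x0, x1))
    exceed = np.zeros(x.shape[0], dtype=np.int64)
    for _ in range(perm_reps):
        perm = rng.permutation(ntot)
        exceed += np.abs(tstat(x[:, perm[:n0]], x[:, perm[n0:]])) >= t_obs
    return (1.0 + exceed) / (1.0 + perm_reps)


def spike_in_resampling_eval(source_matrix: np.ndarray, design: StudyDesign, n: int,
                             outer_reps: int, perm_reps: int,
                             rng_seed: Optional[int] = None) -> SimulationSummary:
    """Spike-in resampling evaluation on an arbitrary source matrix.

    Per outer replicate: draw 2n columns without replacement, permute
    the column labels (removing any true group difference while keeping
    gene-gene correlation), add the design's effect sizes to ``m1``
    randomly chosen genes in the pseudo-treatment group (scaled by each
    gene's pooled standard deviation so effects stay standardized),
    compute per-gene permutation p-values from ``perm_reps`` random
    relabelings and call discoveries with the known-m0 step-up rule.
    """
    x_src = np.asarray(source_matrix, dtype=float)
    if x_src.shape[1] < 2 * n:
        raise DataError(
            f"source matrix has {x_src.shape[1]} columns; need at least {2 * n}"
        )
    if perm_reps < 100:
        raise ValueError("perm_reps must be >= 100")
    m = x_src.shape[0]
    if design.m != m:
        raise DataError(f"design m={design.m} does not match source gene count {m}")
    children = np.random.SeedSequence(rng_seed).spawn(outer_reps)
    counts: List[OutcomeCounts] = []
    for child in children:
        rng = np.random.default_rng(child)
        cols = rng.choice(x_src.shape[1], size=2 * n, replace=False)
        x = x_src[:, rng.permutation(cols)].copy()
        truth = rng.choice(m, size=design.m1, replace=False)
        x0, x1 = x[:, :n], x[:, n:]
        ss = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
            + ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        pooled_sd = np.sqrt(ss / (2 * n - 2))
        x[truth, n:] += (design.deltas * pooled_sd[truth])[:, None]
        pvals = _permutation_pvalues(x, n, perm_reps, rng)
        reject = fdr_call(pvals, design.m0, design.fdr_target)
        u = int(reject[truth].sum())
        counts.append(OutcomeCounts(V=int(reject.sum()) - u, U=u,
                                    m0=design.m0, m1=design.m1))
    return _summarize(counts, design.sensitivity_target, outer_reps, rng_seed)
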