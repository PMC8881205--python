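"""Statistical layer: correlations of TE-associated-gene burden with
genome size and repeat abundance, and per-clade group summaries.

Because the unit of observation is a species and comparative designs of
this kind have small n, significance is assessed by a seeded
label-permutation test rather than asymptotic formulas:
p = (1 + #{permuted |r*| >= |r_obs|}) / (n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ParameterError


class DegenerateInputError(ParameterError):
    """A constant vector makes the correlation coefficient undefined."""


@dataclass(frozen=True)
class AssociationResult:
    x_label: str
    y_label: str
    method: str
    coefficient: float
    p_perm: float
    n: int
    n_permutations: int
    seed: int


@dataclass
class GroupSummary:
    groups: List[str]
    n: Dict[str, int]
    mean: Dict[str, float]
    sd: Dict[str, float]
    median: Dict[str, float]
    q1: Dict[str, float]
    q3: Dict[str, float]

    def fold(self, numerator: str, denominator: str) -> float:
        return self.mean[numerator] / self.mean[denominator]

    def pairwise_folds(self) -> Dict[Tuple[str, str], float]:
        return {
            (a, b): self.fold(a, b)
            for a in self.groups
            for b in self.groups
            if a != b
        }


def _coefficient(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ParameterError(f"unknown method {method!r}")


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    n_permutations: int = 9999,
    seed: int = 0,
    x_label: str = "x",
    y_label: str = "y",
) -> AssociationResult:
    """Correlation with a two-sided label-permutation p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    if xv.size < 3:
        raise ParameterError("need n >= 3")
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ParameterError("missing values are not allowed")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("constant vector: coefficient undefined")
    if method == "spearman":
        # ranking once makes each permuted coefficient a plain Pearson
        # correlation of ranks, which vectorizes cleanly
        xv = stats.rankdata(xv)
        yv = stats.rankdata(yv)
        base_method = "pearson"
    else:
        base_method = method
    observed = _coefficient(xv, yv, base_method)
    rng = np.random.default_rng(seed)
    xs = (xv - xv.mean()) / xv.std()
    ys = (yv - yv.mean()) / yv.std()
    n = xv.size
    perms = rng.permuted(
        np.broadcast_to(ys, (n_permutations, n)).copy(), axis=1
    )
    r_null = perms @ xs / n
    n_extreme = int((np.abs(r_null) >= abs(observed) - 1e-12).sum())
    p_perm = (1 + n_extreme) / (n_permutations + 1)
    return AssociationResult(
        x_label=x_label,
        y_label=y_label,
        method=method,
        coefficient=observed,
        p_perm=p_perm,
        n=n,
        n_permutations=n_permutations,
        seed=seed,
    )


def group_summary(
    values: Sequence[float], groups: Sequence[str]
) -> GroupSummary:
    """Per-group n / mean / sample SD (and quartiles for boxplot export)."""
    vv = np.asarray(values, dtype=float)
    gg = list(groups)
    if vv.size != len(gg):
        raise ParameterError("values and groups must have equal length")
    if vv.size == 0:
        raise ParameterError("empty input")
    order = list(dict.fromkeys(gg))
    out = GroupSummary(order, {}, {}, {}, {}, {}, {})
    for g in order:
        sel = vv[np.array([x == g for x in gg])]
        if sel.size == 0:
            raise ParameterError(f"empty group {g!r}")
        out.n[g] = int(sel.size)
        out.mean[g] = float(sel.mean())
        out.sd[g] = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
        out.median[g] = float(np.median(sel))
        out.q1[g] = float(np.percentile(sel, 25))
        out.q3[g] = float(np.percentile(sel, 75))
    return out
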