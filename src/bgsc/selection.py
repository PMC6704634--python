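"""Target selection and reporting for one pattern group.

Genes assigned to the group of interest (group c for the EGFR design) are
turned into :class:`TargetCall` records carrying the group posterior, the
log2-fold change ``mu1 - mu0``, its Welch–Satterthwaite standard error, and
up/down/none direction calls.  Selection is posterior-only (strictly above
the threshold, 0.75 by default); the fold-change cut only sets direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import GeneClassification, GroupFit

__all__ = [
    "TargetCall",
    "log2_fold_change",
    "satterthwaite_se",
    "select_targets",
    "foldchange_agreement",
]


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    posterior: float
    log2fc: float
    se: float
    direction: str  # "up", "down" or "none"
    selected: bool


def log2_fold_change(fit: GroupFit) -> float:
    """Regulated-minus-baseline class mean difference, ``mu1 - mu0``."""
    if fit.mu1 is None:
        raise ValueError(
            f"group {fit.group_label!r} has a single mean; fold change undefined"
        )
    return fit.mu1 - fit.mu0


def satterthwaite_se(
    values0: Sequence[float], values1: Sequence[float]
) -> tuple[float, float]:
    """Standard error and degrees of freedom of a two-class mean difference.

    With at least two values per class this is the Welch–Satterthwaite
    approximation: ``se = sqrt(s0^2/n0 + s1^2/n1)`` with

        df = (s0^2/n0 + s1^2/n1)^2 / [ (s0^2/n0)^2/(n0-1) + (s1^2/n1)^2/(n1-1) ]

    If either class holds a single value its variance is undefined, so the
    pooled-variance fallback is used: ``se = s_p * sqrt(1/n0 + 1/n1)`` with
    ``s_p^2`` the residual variance around both class means (denominator
    ``n0 + n1 - 2``) and ``df = n0 + n1 - 2``.
    """
    x0 = np.asarray(values0, dtype=float)
    x1 = np.asarray(values1, dtype=float)
    n0, n1 = x0.size, x1.size
    if n0 < 1 or n1 < 1:
        raise ValueError("both classes need at least one value")
    if n0 < 2 or n1 < 2:
        ss = float(np.sum((x0 - x0.mean()) ** 2) + np.sum((x1 - x1.mean()) ** 2))
        df = n0 + n1 - 2
        pooled = ss / df if df > 0 else 0.0
        return float(np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))), float(max(df, 1))
    v0 = float(np.var(x0, ddof=1)) / n0
    v1 = float(np.var(x1, ddof=1)) / n1
    se = float(np.sqrt(v0 + v1))
    denom = v0**2 / (n0 - 1) + v1**2 / (n1 - 1)
    df = (v0 + v1) ** 2 / denom if denom > 0 else float(n0 + n1 - 2)
    return se, float(df)


def _direction(log2fc: float, fc_threshold: float) -> str:
    if log2fc > fc_threshold:
        return "up"
    if log2fc < -fc_threshold:
        return "down"
    return "none"


def select_targets(
    classifications: Sequence[GeneClassification],
    group: str,
    pattern_indicator: Sequence[int],
    posterior_threshold: float = 0.75,
    fc_threshold: float = 0.5,
) -> list[TargetCall]:
    """One TargetCall per gene assigned to ``group``.

    ``selected`` is True iff the group posterior strictly exceeds
    ``posterior_threshold``; genes inside the fold-change band stay selected
    but get direction ``"none"``.  Output is sorted by descending posterior,
    then descending |log2fc|, then gene id.
    """
    if not any(group in c.fits for c in classifications) and classifications:
        raise KeyError(f"group {group!r} absent from classifications")
    g = np.asarray(pattern_indicator, dtype=bool)
    calls = []
    for c in classifications:
        if c.assigned_group != group:
            continue
        fit = c.fits[group]
        fc = log2_fold_change(fit)
        se, _ = satterthwaite_se(c.values[~g], c.values[g])
        calls.append(
            TargetCall(
                gene_id=c.gene_id,
                posterior=fit.posterior,
                log2fc=fc,
                se=se,
                direction=_direction(fc, fc_threshold),
                selected=fit.posterior > posterior_threshold,
            )
        )
    calls.sort(key=lambda t: (-t.posterior, -abs(t.log2fc), t.gene_id))
    return calls


def foldchange_agreement(
    fc_platform1: Sequence[float], fc_platform2: Sequence[float]
) -> tuple[float, int]:
    """Pearson correlation of matched per-gene fold changes across platforms.

    Used to compare microarray-derived log2-fold changes against an
    independent assay (e.g. qPCR) on the same genes.
    """
    x = np.asarray(fc_platform1, dtype=float)
    y = np.asarray(fc_platform2, dtype=float)
    if x.size != y.size:
        raise ValueError(f"mismatched vectors ({x.size} vs {y.size})")
    if x.size < 3:
        raise ValueError("need at least 3 paired fold changes")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance in a platform")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(x.size)
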