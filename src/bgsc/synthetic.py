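"""Synthetic expression matrices with known group labels.

The generator reads the classification model forward: per gene, draw a
pattern group from configurable proportions, a baseline level mu0, a signed
effect size delta (zero for the unresponsive group), then independent normal
noise around ``mu0 + delta * g_n`` with one shared standard deviation.  The
defaults mirror the study conditions: 70% unregulated genes, 10% in each
responsive group, log2 effects of 1–2 against noise_sd 0.2 on a baseline
typical of normalized log2 microarray intensities.

What this emulates — and what it does not: profiles follow the fitted model
exactly (independent homoscedastic normals), so recovery results here bound
what is attainable, not what probe-level artifacts, correlated noise or
heavy tails would yield on real arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import PatternGroup
from .model import GeneClassification

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "RecoverySummary",
    "simulate",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults reproduce the study's assumed conditions.

    ``group_proportions`` maps pattern labels to sampling probabilities; when
    ``None``, 0.70 goes to the all-zero group and the rest is split equally.
    ``baseline_mean``/``baseline_sd`` locate the per-gene baseline mu0 (log2
    scale).  ``effect_low``/``effect_high`` bound |delta|, the regulated-class
    mean shift; its sign is equiprobable.  ``noise_sd`` is the shared
    within-gene standard deviation.
    """

    n_genes: int = 10_000
    group_proportions: dict[str, float] | None = None
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    effect_low: float = 1.0
    effect_high: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.effect_low <= self.effect_high):
            raise ValueError("need 0 <= effect_low <= effect_high")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")
        if self.group_proportions is not None:
            props = self.group_proportions
            if any(p < 0 for p in props.values()):
                raise ValueError(f"negative proportion in {props}")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"proportions {props} do not sum to 1")


@dataclass
class SimulatedDataset:
    """Matrix plus per-gene ground truth (group, mu0, delta, sigma)."""

    matrix: pd.DataFrame
    truth: pd.DataFrame


def _resolved_proportions(
    config: SimulationConfig, patterns: Sequence[PatternGroup]
) -> dict[str, float]:
    if config.group_proportions is None:
        n_rest = sum(not p.is_null for p in patterns)
        rest = 0.30 / n_rest if n_rest else 0.0
        return {p.label: (0.70 if p.is_null else rest) for p in patterns}
    props = dict(config.group_proportions)
    unknown = set(props) - {p.label for p in patterns}
    if unknown:
        raise ValueError(f"proportions name unknown groups {sorted(unknown)}")
    return {p.label: props.get(p.label, 0.0) for p in patterns}


def simulate(
    config: SimulationConfig, patterns: Sequence[PatternGroup]
) -> SimulatedDataset:
    """Draw a gene x condition matrix with known generating groups."""
    props = _resolved_proportions(config, patterns)
    labels = [p.label for p in patterns]
    indicators = {p.label: np.asarray(p.indicator, dtype=float) for p in patterns}
    n_cond = len(patterns[0].indicator)

    rng = np.random.default_rng(config.seed)
    groups = rng.choice(labels, size=config.n_genes, p=[props[l] for l in labels])
    mu0 = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    magnitude = rng.uniform(config.effect_low, config.effect_high, size=config.n_genes)
    is_null = np.array([indicators[g].sum() == 0 for g in groups])
    delta = np.where(is_null, 0.0, sign * magnitude)

    g_rows = np.vstack([indicators[g] for g in groups])
    means = mu0[:, None] + delta[:, None] * g_rows
    x = rng.normal(means, config.noise_sd)

    ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    cols = [f"x{j+1}" for j in range(n_cond)]
    matrix = pd.DataFrame(x, index=pd.Index(ids, name="gene_id"), columns=cols)
    truth = pd.DataFrame(
        {
            "group": groups,
            "mu0": mu0,
            "delta": delta,
            "sigma": np.full(config.n_genes, config.noise_sd),
        },
        index=matrix.index,
    )
    return SimulatedDataset(matrix=matrix, truth=truth)


@dataclass
class RecoverySummary:
    """Classification accuracy against simulation truth."""

    accuracy: float
    per_group_accuracy: dict[str, float]
    confusion: pd.DataFrame  # rows = truth, columns = assigned
    calibration: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def evaluate_recovery(
    dataset: SimulatedDataset, classifications: Sequence[GeneClassification]
) -> RecoverySummary:
    """Confusion table, per-group accuracy, and posterior calibration deciles.

    Calibration bins genes by the posterior of their assigned group into ten
    equal-width bins and compares the bin's mean posterior with its empirical
    accuracy — for a well-calibrated classifier the two agree up to binomial
    sampling error.
    """
    if len(classifications) != dataset.truth.shape[0]:
        raise ValueError(
            f"{len(classifications)} classifications for "
            f"{dataset.truth.shape[0]} simulated genes"
        )
    truth = dataset.truth["group"].to_numpy()
    assigned = np.array([c.assigned_group for c in classifications])
    post = np.array([c.assigned_posterior for c in classifications])
    correct = truth == assigned

    groups = sorted(set(truth) | set(assigned))
    confusion = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, a in zip(truth, assigned):
        confusion.loc[t, a] += 1
    per_group = {
        g: float(correct[truth == g].mean()) for g in groups if (truth == g).any()
    }

    edges = np.linspace(0.0, 1.0, 11)
    bin_idx = np.clip(np.digitize(post, edges[1:-1]), 0, 9)
    rows = []
    for b in range(10):
        mask = bin_idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(mask.sum()),
                "mean_posterior": float(post[mask].mean()),
                "accuracy": float(correct[mask].mean()),
            }
        )
    calibration = pd.DataFrame(rows)
    return RecoverySummary(
        accuracy=float(correct.mean()),
        per_group_accuracy=per_group,
        confusion=confusion,
        calibration=calibration,
    )
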