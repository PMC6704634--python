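"""Per-gene normal pattern models, BIC marginal likelihoods, and posteriors.

Each gene contributes one log2 expression value per experimental condition
(six for the EGFR design).  Under pattern group ``z`` the values are modeled
as independent normals sharing one variance, with a single mean for the
all-zero group and two class means (indicator 0 vs 1) otherwise:

    p(x | z, theta_z) = prod_n N(x_n | mu_{z g_n}, sigma_z)

The maximized likelihood is penalized into an approximate marginal likelihood
via the Bayesian Information Criterion,

    p(x | z)  ∝  p(x | z, theta_hat_z) / sqrt(n) ** |theta_z|,

with |theta_z| = 2 for the all-zero group and 3 otherwise, and the posterior
p(z | x) follows from Bayes' formula with user-supplied group priors.  Genes
are assigned to the posterior-maximizing group.

Variance estimators use the moment denominators n-1 (one mean) and n-2 (two
means) rather than the 1/n maximum-likelihood normalization; the likelihood
is evaluated at these estimates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import PatternGroup

__all__ = [
    "ExpressionProfile",
    "Priors",
    "GroupFit",
    "GeneClassification",
    "VARIANCE_FLOOR",
    "default_priors",
    "fit_group",
    "bic_log_marginal",
    "posteriors",
    "classify_gene",
    "classify_matrix",
]

logger = logging.getLogger(__name__)

#: Variance below this is treated as degenerate (likelihood unbounded).
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's log2 expression values across the design's conditions."""

    gene_id: str
    values: np.ndarray
    condition_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError(f"gene {self.gene_id}: expression values must be 1-D")
        if self.condition_labels is not None and len(self.condition_labels) != len(values):
            raise ValueError(
                f"gene {self.gene_id}: {len(self.condition_labels)} condition labels "
                f"for {len(values)} values"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"gene {self.gene_id}: non-finite expression values at positions "
                f"{np.where(~np.isfinite(values))[0].tolist()}"
            )


@dataclass(frozen=True)
class Priors:
    """Prior probability per pattern group; must sum to one."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        probs = {str(k): float(v) for k, v in self.probs.items()}
        object.__setattr__(self, "probs", probs)
        if not probs:
            raise ValueError("priors are empty")
        if any(p < 0 for p in probs.values()):
            raise ValueError(f"negative prior in {probs}")
        total = sum(probs.values())
        if total <= 0:
            raise ValueError("all priors are zero")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"priors sum to {total!r}, not 1")

    def __getitem__(self, group: str) -> float:
        return self.probs[group]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.probs)


def default_priors(patterns: Sequence[PatternGroup], null_prior: float = 0.70) -> Priors:
    """70% prior mass on the unresponsive group, the rest shared equally.

    Encodes the working assumption that most genes are not regulated by the
    stimulus; with the four EGFR groups this is (0.70, 0.1, 0.1, 0.1).
    """
    n_rest = sum(not p.is_null for p in patterns)
    if n_rest == 0:
        return Priors({patterns[0].label: 1.0})
    rest = (1.0 - null_prior) / n_rest
    return Priors(
        {p.label: (null_prior if p.is_null else rest) for p in patterns}
    )


@dataclass
class GroupFit:
    """Fitted parameters and (marginal) likelihood of one pattern group.

    ``mu0`` is the mean of indicator-0 conditions (for the all-zero group, the
    single overall mean); ``mu1`` is the indicator-1 class mean, ``None`` for
    the all-zero group.  ``sigma2`` is the shared variance with denominator
    ``n - n_means``.  ``n_params`` counts free parameters (means + variance).
    """

    group_label: str
    mu0: float
    mu1: float | None
    sigma2: float
    n_params: int
    log_likelihood: float
    log_marginal: float = math.nan
    posterior: float = math.nan
    degenerate: bool = False


@dataclass
class GeneClassification:
    """All per-group fits of one gene plus the posterior-maximizing group."""

    gene_id: str
    fits: dict[str, GroupFit]
    assigned_group: str
    degenerate_flag: bool = False
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def posteriors(self) -> dict[str, float]:
        return {g: f.posterior for g, f in self.fits.items()}

    @property
    def assigned_posterior(self) -> float:
        return self.fits[self.assigned_group].posterior


def _normal_loglik(x: np.ndarray, means: np.ndarray, sigma2: float) -> float:
    n = x.size
    resid = x - means
    return float(-0.5 * n * math.log(2.0 * math.pi * sigma2)
                 - 0.5 * np.dot(resid, resid) / sigma2)


def fit_group(
    profile: ExpressionProfile,
    pattern: PatternGroup,
    variance_floor: float = VARIANCE_FLOOR,
) -> GroupFit:
    """Maximum-likelihood fit of one pattern group to one gene.

    All-zero pattern: one mean over all ``n`` values; variance with
    denominator ``n-1``.  Other patterns: class means over indicator-0 and
    indicator-1 positions; pooled variance with denominator ``n-2``.  The log
    likelihood is the sum of normal log densities at the fitted parameters.

    A variance below ``variance_floor`` marks the fit degenerate and is
    clamped to the floor so downstream marginals remain finite.
    """
    x = profile.values
    g = np.asarray(pattern.indicator, dtype=bool)
    if x.size != g.size:
        raise ValueError(
            f"gene {profile.gene_id}: profile has {x.size} values but pattern "
            f"{pattern.label!r} expects {g.size}"
        )
    n = x.size
    if pattern.is_null:
        mu0 = float(x.mean())
        mu1 = None
        ss = float(np.sum((x - mu0) ** 2))
        denom = n - 1
        means = np.full(n, mu0)
        n_params = 2
    else:
        if not (g.any() and (~g).any()):
            raise ValueError(
                f"pattern {pattern.label!r} must have both indicator classes nonempty"
            )
        mu0 = float(x[~g].mean())
        mu1 = float(x[g].mean())
        ss = float(np.sum((x[~g] - mu0) ** 2) + np.sum((x[g] - mu1) ** 2))
        denom = n - 2
        means = np.where(g, mu1, mu0)
        n_params = 3
    sigma2 = ss / denom
    degenerate = sigma2 < variance_floor
    sigma2_eval = max(sigma2, variance_floor)
    ll = _normal_loglik(x, means, sigma2_eval)
    return GroupFit(
        group_label=pattern.label,
        mu0=mu0,
        mu1=mu1,
        sigma2=sigma2,
        n_params=n_params,
        log_likelihood=ll,
        degenerate=degenerate,
    )


def bic_log_marginal(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """BIC approximation of the log marginal likelihood.

    Divides the maximized likelihood by ``sqrt(n_obs) ** n_params``, i.e.
    returns ``log_likelihood - (n_params / 2) * log(n_obs)``.
    """
    if n_obs < 1:
        raise ValueError(f"n_obs must be >= 1, got {n_obs}")
    if n_params < 0:
        raise ValueError(f"n_params must be >= 0, got {n_params}")
    return log_likelihood - 0.5 * n_params * math.log(n_obs)


def posteriors(
    log_marginals: Mapping[str, float], priors: Priors
) -> dict[str, float]:
    """Posterior group probabilities via Bayes' formula, in log space.

    Uses max-subtracting normalization (logsumexp) over ``log p(x|z) +
    log p(z)`` at full floating precision; never normalize pre-rounded
    marginals — the worked examples are only reproduced at full precision.
    """
    groups = tuple(log_marginals)
    if set(groups) != set(priors.groups):
        raise ValueError(
            f"marginal groups {sorted(groups)} != prior groups {sorted(priors.groups)}"
        )
    with np.errstate(divide="ignore"):  # log(0) -> -inf for zero priors
        scores = np.array(
            [log_marginals[g] + np.log(priors[g]) for g in groups], dtype=float
        )
    log_norm = logsumexp(scores)
    post = np.exp(scores - log_norm)
    return dict(zip(groups, post.tolist()))


def _assign(fits: Mapping[str, GroupFit]) -> str:
    """Argmax posterior; ties prefer fewer parameters, then alphabetical label."""
    best = max(f.posterior for f in fits.values())
    tied = [f for f in fits.values() if f.posterior == best]
    tied.sort(key=lambda f: (f.n_params, f.group_label))
    return tied[0].group_label


def classify_gene(
    profile: ExpressionProfile,
    patterns: Sequence[PatternGroup],
    priors: Priors,
    variance_floor: float = VARIANCE_FLOOR,
) -> GeneClassification:
    """Fit every pattern group, compute posteriors, assign the best group.

    A profile whose total variance is below the floor carries no evidence of
    regulation: it is assigned the all-zero group with posterior 1 and the
    ``degenerate_flag`` set.  If only some group fits are degenerate, their
    variances are clamped to the floor (with a logged warning) and the
    posterior computation proceeds.
    """
    n = profile.values.size
    fits = {p.label: fit_group(profile, p, variance_floor) for p in patterns}
    null_label = next(p.label for p in patterns if p.is_null)

    total_var = float(np.var(profile.values, ddof=1)) if n > 1 else 0.0
    if total_var < variance_floor:
        for label, fit in fits.items():
            fit.log_marginal = bic_log_marginal(fit.log_likelihood, fit.n_params, n)
            fit.posterior = 1.0 if label == null_label else 0.0
        return GeneClassification(
            gene_id=profile.gene_id,
            fits=fits,
            assigned_group=null_label,
            degenerate_flag=True,
            values=profile.values,
        )

    if any(f.degenerate for f in fits.values()):
        warnings.warn(
            f"gene {profile.gene_id}: variance clamped to {variance_floor:g} for "
            f"groups {[g for g, f in fits.items() if f.degenerate]}",
            RuntimeWarning,
            stacklevel=2,
        )
    for fit in fits.values():
        fit.log_marginal = bic_log_marginal(fit.log_likelihood, fit.n_params, n)
    post = posteriors({g: f.log_marginal for g, f in fits.items()}, priors)
    for g, p in post.items():
        fits[g].posterior = p
    return GeneClassification(
        gene_id=profile.gene_id,
        fits=fits,
        assigned_group=_assign(fits),
        degenerate_flag=False,
        values=profile.values,
    )


def classify_matrix(
    matrix: pd.DataFrame,
    patterns: Sequence[PatternGroup],
    priors: Priors,
    variance_floor: float = VARIANCE_FLOOR,
) -> list[GeneClassification]:
    """Row-wise classification of a gene x condition table, order preserved.

    Duplicate gene ids are disambiguated with ``.1``, ``.2`` ... suffixes and
    a warning, so every classification keeps a unique id.
    """
    if matrix.shape[0] < 1:
        raise ValueError("expression matrix has no gene rows")
    ids = [str(i) for i in matrix.index]
    if len(set(ids)) != len(ids):
        warnings.warn("duplicate gene ids; disambiguating with numeric suffixes",
                      UserWarning, stacklevel=2)
        seen: dict[str, int] = {}
        unique = []
        for gid in ids:
            if gid in seen:
                seen[gid] += 1
                unique.append(f"{gid}.{seen[gid]}")
            else:
                seen[gid] = 0
                unique.append(gid)
        ids = unique
    labels = tuple(str(c) for c in matrix.columns)
    values = matrix.to_numpy(dtype=float)
    out = []
    for gid, row in zip(ids, values):
        profile = ExpressionProfile(gid, row, labels)
        out.append(classify_gene(profile, patterns, priors, variance_floor))
    counts: dict[str, int] = {}
    for c in out:
        counts[c.assigned_group] = counts.get(c.assigned_group, 0) + 1
    logger.info(
        "classified %d genes: %s", len(out),
        ", ".join(f"{g}={counts[g]}" for g in sorted(counts)),
    )
    return out
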