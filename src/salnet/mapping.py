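"""Per-subject network maps: empirical-Bayes shrinkage, vertex-wise
membership inference, and the expansion / connectivity summary metrics.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import (
    AtlasSpec,
    BoldRun,
    EngagementMap,
    MembershipMask,
    NetworkMetrics,
    PosteriorMap,
    PriorMaps,
)

__all__ = [
    "fit_posterior_map",
    "test_membership",
    "expansion",
    "connectivity",
    "compute_network_metrics",
]


def fit_posterior_map(
    raw: EngagementMap,
    prior: PriorMaps,
    se_floor: float = 1e-6,
) -> PosteriorMap:
    """Vertex-wise conjugate-normal update of a subject's engagement map.

    posterior mean = (prior.mean / tau2 + raw / s2) / (1/tau2 + 1/s2) and
    posterior variance = 1 / (1/tau2 + 1/s2), where tau2 is the prior
    between-subject variance and s2 the raw estimate's sampling variance.
    The degree of shrinkage is thus set automatically by the two variances:

    * tau2 = 0 (dogmatic prior) — posterior equals the prior mean, with
      ``se_floor`` as its standard error;
    * s2 = inf (no data, e.g. a dropped network) — posterior equals the
      prior mean with the prior variance;
    * tau2 = inf (uninformative prior) — posterior equals the raw estimate.
    """
    if raw.values.shape != prior.mean.shape:
        raise ValueError(
            f"map shape {raw.values.shape} does not match prior {prior.mean.shape}"
        )
    tau2 = prior.between_var
    s2 = raw.sampling_var
    dogmatic = tau2 == 0          # prior pins the value
    no_data = np.isinf(s2)        # dropped network / no usable estimate
    flat_prior = np.isinf(tau2)
    perfect = s2 == 0

    general = ~(dogmatic | no_data | flat_prior | perfect)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(general, 1.0 / np.where(tau2 > 0, tau2, 1.0)
                        + 1.0 / np.where(s2 > 0, s2, 1.0), 1.0)
        var = 1.0 / prec
        num = np.where(general,
                       prior.mean / np.where(tau2 > 0, tau2, 1.0)
                       + raw.values / np.where(s2 > 0, s2, 1.0), 0.0)
        mean = num * var

    mean = np.where(flat_prior | perfect, raw.values, mean)
    var = np.where(flat_prior, np.where(np.isfinite(s2), s2, np.inf), var)
    var = np.where(perfect, 0.0, var)
    mean = np.where(no_data & ~flat_prior, prior.mean, mean)
    var = np.where(no_data & ~flat_prior, tau2, var)
    mean = np.where(dogmatic, prior.mean, mean)
    var = np.where(dogmatic, se_floor**2, var)

    se = np.sqrt(np.maximum(var, se_floor**2))
    return PosteriorMap(mean=mean, se=se)


def test_membership(
    posterior: PosteriorMap,
    network: int,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    two_sided: bool = False,
) -> MembershipMask:
    """Vertex-wise test of positive engagement in ``network`` (1-based).

    A vertex is a member iff its posterior mean is positive and its normal
    p-value falls below alpha divided by the number of vertices (Bonferroni
    across ALL V vertices; ``correction="none"`` skips the division). The
    default is a one-sided test of positive engagement; ``two_sided=True``
    tests two-sided then drops negatives.
    """
    K = posterior.mean.shape[1]
    if not 1 <= network <= K:
        raise ValueError(f"network {network} outside 1..{K}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    mean = posterior.mean[:, network - 1]
    se = posterior.se[:, network - 1]
    V = mean.shape[0]
    z = np.divide(mean, se, out=np.zeros_like(mean), where=se > 0)
    if two_sided:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = stats.norm.sf(z)
    threshold = alpha / V if correction == "bonferroni" else alpha
    mask = (mean > 0) & (p < threshold)
    return MembershipMask(mask=mask, alpha=alpha, n_tests=V)


def expansion(mask: MembershipMask) -> float:
    """Fraction of all vertices that are significant members (in [0, 1])."""
    return float(mask.mask.mean())


def connectivity(bold: BoldRun, mask: MembershipMask) -> float:
    """Mean Pearson correlation over all unordered member-vertex pairs.

    Expects the nuisance-regressed full-length session. Returns NaN when
    fewer than two member vertices exist or any member vertex has zero
    temporal variance (the caller marks such subjects metric-invalid).

    Computed without forming the pairwise loop: with z_v the standardized
    time series scaled to unit norm, sum_{v<u} r_vu = (||sum_v z_v||^2 - m)/2.
    """
    if mask.mask.shape[0] != bold.V:
        raise ValueError("mask length does not match BOLD vertex count")
    members = bold.data[mask.mask]
    m = members.shape[0]
    if m < 2:
        return float("nan")
    centered = members - members.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        return float("nan")
    z = centered / norms[:, None]
    s = z.sum(axis=0)
    pair_sum = (s @ s - m) / 2.0
    return float(pair_sum / (m * (m - 1) / 2.0))


def compute_network_metrics(
    bold: BoldRun,
    posterior: PosteriorMap,
    network: int,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    invalid: bool = False,
) -> NetworkMetrics:
    """Expansion and connectivity for one subject's chosen network.

    ``invalid`` marks subjects failed by the low-variance vertex guard;
    their metrics are reported but flagged unusable.
    """
    mask = test_membership(posterior, network, alpha=alpha, correction=correction)
    conn = connectivity(bold, mask)
    valid = bool(not invalid and np.isfinite(conn))
    return NetworkMetrics(expansion=expansion(mask), connectivity=conn, valid=valid)
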