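"""Population prior construction from pseudo test-retest engagement maps.

Each session is split down the middle into two pseudo-sessions; each half
yields a parcel-seeded dual-regression engagement map. Across sessions the
half-map pairs separate measurement noise (from the within-session
disagreement) from genuine between-subject variability via a
method-of-moments decomposition, producing the prior mean and
between-subject variance maps used for empirical-Bayes shrinkage.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import AtlasSpec, BoldRun, EngagementMap, PriorMaps

__all__ = [
    "split_halves",
    "parcel_dual_regression",
    "normalize_engagement",
    "estimate_prior",
]

logger = logging.getLogger(__name__)


def split_halves(bold: BoldRun) -> tuple[BoldRun, BoldRun]:
    """Split a run into first floor(T/2) frames and the remainder.

    Concatenating the halves reproduces the input exactly.
    """
    if bold.T < 4:
        raise ValueError(f"run too short to split: T={bold.T} < 4")
    half = bold.T // 2
    return (
        BoldRun(data=bold.data[:, :half], tr=bold.tr),
        BoldRun(data=bold.data[:, half:], tr=bold.tr),
    )


def parcel_dual_regression(bold: BoldRun, atlas: AtlasSpec) -> EngagementMap:
    """Two-stage parcel-seeded dual regression.

    Stage 1 averages the time series over the vertices of each of the K
    parcels; stage 2 regresses every vertex's time series on the K parcel
    time courses jointly (with an intercept), giving a (V, K) engagement
    map with vertex-wise OLS sampling variances.

    A parcel whose mean time course is identically zero is dropped from the
    regression; its engagement column is 0 with infinite sampling variance.
    Duplicated (perfectly correlated) parcel time courses raise a
    rank-deficiency error naming the offending parcels.

    After global-signal regression the parcel-size-weighted sum of all K
    mean time courses is exactly zero, so the stage-2 design always loses
    one degree of freedom. The fit therefore uses the minimum-norm
    (pseudoinverse) least-squares solution, truncating singular values
    below a relative tolerance; sampling variances come from the same
    truncated decomposition.
    """
    if bold.V != atlas.V:
        raise ValueError(
            f"BOLD has {bold.V} vertices but atlas expects {atlas.V}"
        )
    K, T = atlas.K, bold.T
    courses = np.zeros((K, T))
    for k in range(1, K + 1):
        courses[k - 1] = bold.data[atlas.vertices_in(k)].mean(axis=0)

    zero = np.all(courses == 0.0, axis=1)
    active = np.flatnonzero(~zero)
    Xk = courses[active].T  # (T, k_active)
    X = np.column_stack([np.ones(T), Xk])
    p = X.shape[1]
    if p > T:
        raise ValueError("more parcel regressors than frames")

    # duplicated parcel courses are a user error worth naming explicitly
    if len(active) >= 2:
        sd = Xk.std(axis=0)
        ok = sd > 0
        if ok.sum() >= 2:
            corr = np.corrcoef(Xk[:, ok], rowvar=False)
            dup = np.argwhere(np.triu(np.abs(corr), 1) > 1 - 1e-10)
            if dup.size:
                idx = np.flatnonzero(ok)
                bad = sorted({int(active[idx[i]]) + 1 for pair in dup for i in pair})
                raise ValueError(
                    f"collinear parcel time courses for parcels {bad}"
                )

    # minimum-norm solution via truncated SVD (one direction is lost to
    # global-signal regression by construction)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-10
    r = int(keep.sum())
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    beta = Vt.T @ ((U.T @ bold.data.T) / s[:, None])  # (p, V)
    resid = bold.data.T - X @ beta
    dof = max(T - r, 1)
    sigma2 = np.sum(resid**2, axis=0) / dof  # (V,)
    coef_var = np.sum((Vt.T / s) ** 2, axis=1)[1:]  # skip intercept

    values = np.zeros((bold.V, K))
    sampling_var = np.full((bold.V, K), np.inf)
    values[:, active] = beta[1:].T
    sampling_var[:, active] = np.outer(sigma2, coef_var)
    return EngagementMap(values=values, sampling_var=sampling_var)


def normalize_engagement(emap: EngagementMap) -> EngagementMap:
    """Scale each network column to unit across-vertex SD.

    Dual regression leaves each network's engagement scale indeterminate
    (it depends on the parcel time-course amplitude); normalizing per map
    and per network puts all maps on one scale before prior estimation and
    shrinkage. Sampling variances are rescaled accordingly.
    """
    sd = emap.values.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return EngagementMap(
        values=emap.values / sd,
        sampling_var=emap.sampling_var / sd**2,
    )


def estimate_prior(
    pairs: list[tuple[EngagementMap, EngagementMap]],
) -> PriorMaps:
    """Method-of-moments prior from half-session engagement map pairs.

    For half-maps (a, b) of each session, per (vertex, network):

    * prior mean — grand mean of the session averages (a+b)/2;
    * within-session noise w — mean of (a-b)^2/2 over sessions, the
      sampling variance of a single half-map;
    * between-subject variance — sample variance of the session averages
      minus w/2 (the noise left in an average of two halves), floored at 0.

    The fraction of floored entries is logged.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 sessions to estimate between-subject variance")
    shapes = {(a.values.shape, b.values.shape) for a, b in pairs}
    if len(shapes) != 1:
        raise ValueError("inconsistent engagement map dimensions across sessions")

    avg = np.stack([(a.values + b.values) / 2.0 for a, b in pairs])  # (n, V, K)
    diff = np.stack([(a.values - b.values) for a, b in pairs])
    w = np.mean(diff**2 / 2.0, axis=0)
    mean = avg.mean(axis=0)
    total = avg.var(axis=0, ddof=1)
    between = total - w / 2.0
    floored = between < 0
    frac = float(floored.mean())
    if frac:
        logger.info("between-subject variance floored at 0 for %.1f%% of entries",
                    100 * frac)
    between = np.where(floored, 0.0, between)
    return PriorMaps(
        mean=mean,
        between_var=between,
        n_sessions_used=len(pairs),
        floor_fraction=frac,
    )
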