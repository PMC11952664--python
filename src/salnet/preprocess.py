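"""Nuisance processing for surface BOLD runs.

The recipe is a single simultaneous least-squares regression per vertex
against: the six rigid-body motion parameters and the global signal, their
backward-difference derivatives, squares, and squared derivatives (28
columns); a discrete-cosine high-pass basis (0.01 Hz via 12 bases at the
default acquisition length); and one spike regressor per DVARS-flagged
frame. White-matter and CSF signals are deliberately absent: they are
highly collinear with the global signal and excluded from this recipe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BoldRun

__all__ = [
    "NuisanceDesign",
    "dct_basis_count",
    "dct_highpass_bases",
    "dvars_outliers",
    "build_nuisance_design",
    "regress_nuisance",
    "low_variance_vertices",
]

logger = logging.getLogger(__name__)


@dataclass
class NuisanceDesign:
    """A (T, p) nuisance design with a role label per column."""

    columns: np.ndarray
    column_roles: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2:
            raise ValueError("design must be 2-D (T, p)")
        if self.columns.shape[1] != len(self.column_roles):
            raise ValueError("one role per column required")

    @property
    def T(self) -> int:
        return self.columns.shape[0]

    @property
    def p(self) -> int:
        return self.columns.shape[1]


def dct_basis_count(T: int, TR: float, cutoff_hz: float = 0.01) -> int:
    """Number of DCT bases with frequency below ``cutoff_hz``: floor(2*T*TR*f_c)."""
    return int(np.floor(2.0 * T * TR * cutoff_hz))


def dct_highpass_bases(T: int, TR: float | None = None, cutoff_hz: float = 0.01,
                       n_bases: int | None = 12) -> np.ndarray:
    """Unit-normalized discrete cosine drift bases, shape (T, n_bases).

    Basis j (1-indexed) is cos(pi*j*(t+1/2)/T), t = 0..T-1 — the DCT-II
    family without the constant term. ``n_bases=None`` derives the count
    from the cutoff frequency (requires TR).
    """
    if n_bases is None:
        if TR is None:
            raise ValueError("TR required to derive the basis count from the cutoff")
        n_bases = dct_basis_count(T, TR, cutoff_hz)
    if n_bases < 0:
        raise ValueError("n_bases must be nonnegative")
    if n_bases > T:
        raise ValueError(f"cannot build {n_bases} DCT bases from {T} frames")
    t = np.arange(T)
    js = np.arange(1, n_bases + 1)
    basis = np.cos(np.pi * np.outer(t + 0.5, js) / T)
    if n_bases:
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def dvars_outliers(bold: BoldRun, practical_cutoff_pct: float = 5.0,
                   alpha: float = 0.05) -> np.ndarray:
    """Dual-cutoff DVARS outlier flags (boolean, length T; frame 0 never flagged).

    DVARS^2 at frame t is the across-vertex mean squared backward difference.
    A frame is flagged only when BOTH cutoffs are exceeded:

    * practical — the excess of DVARS^2 over its robust null center (median),
      as a percentage of the mean temporal variance of the data, is above
      ``practical_cutoff_pct``;
    * statistical — a one-sided p-value from a moment-matched chi-square
      null (center = median, spread from the IQR) falls below
      ``alpha`` Bonferroni-corrected across the T-1 frame differences.

    Constant-in-time data legally produce zero flags.
    """
    if bold.T < 3:
        raise ValueError("DVARS needs at least 3 frames")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    diffs = np.diff(bold.data, axis=1)  # (V, T-1)
    d2 = np.mean(diffs**2, axis=0)  # DVARS^2 per frame transition
    flags = np.zeros(bold.T, dtype=bool)

    mu0 = float(np.median(d2))
    iqr = float(np.subtract(*np.percentile(d2, [75, 25])))
    sigma0 = iqr / 1.349
    if mu0 <= 0 or sigma0 <= 0:
        return flags

    avar = float(np.mean(np.var(bold.data, axis=1)))
    if avar <= 0:
        return flags
    delta_pct = 100.0 * (d2 - mu0) / avar

    nu = 2.0 * mu0**2 / sigma0**2
    pvals = stats.chi2.sf(d2 * nu / mu0, df=nu)
    n_tests = bold.T - 1
    stat_hit = pvals < alpha / n_tests
    prac_hit = delta_pct > practical_cutoff_pct
    flags[1:] = stat_hit & prac_hit
    return flags


def build_nuisance_design(motion: np.ndarray, bold: BoldRun, flags: np.ndarray,
                          dct: np.ndarray) -> NuisanceDesign:
    """Assemble the full nuisance design for one run.

    Columns, in order: raw motion (6) and global signal (1); their
    backward-difference derivatives (leading 0); squares; squared
    derivatives; the DCT columns; one one-hot spike column per flagged
    frame. Zero or linearly dependent columns are dropped with a warning.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (T, 6)")
    T = bold.T
    flags = np.asarray(flags, dtype=bool)
    dct = np.asarray(dct, dtype=np.float64).reshape(T, -1) if np.size(dct) else np.zeros((T, 0))
    if motion.shape[0] != T or flags.shape[0] != T or dct.shape[0] != T:
        raise ValueError("motion, flags, and dct must share the BOLD frame count")

    global_sig = bold.data.mean(axis=0)
    base = np.column_stack([motion, global_sig])  # (T, 7)
    deriv = np.vstack([np.zeros((1, 7)), np.diff(base, axis=0)])

    cols: list[np.ndarray] = []
    roles: list[str] = []

    def add(block: np.ndarray, block_roles: list[str]) -> None:
        cols.append(block)
        roles.extend(block_roles)

    motion_roles = ["motion"] * 6 + ["global"]
    add(base, motion_roles)
    add(deriv, ["motion-derivative"] * 6 + ["global-derivative"])
    add(base**2, ["motion-square"] * 6 + ["global-square"])
    add(deriv**2, ["derivative-square"] * 7)
    if dct.shape[1]:
        add(dct, ["dct"] * dct.shape[1])
    for frame in np.flatnonzero(flags):
        spike = np.zeros(T)
        spike[frame] = 1.0
        add(spike[:, None], ["spike"])

    X = np.column_stack(cols)
    all_roles = roles

    # Drop zero columns, then any column not adding rank (QR with pivoting).
    nonzero = np.linalg.norm(X, axis=0) > 1e-12
    dropped = [all_roles[i] for i in np.flatnonzero(~nonzero)]
    X = X[:, nonzero]
    kept_roles = [r for r, keep in zip(all_roles, nonzero) if keep]

    if X.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int(np.sum(diag > tol))
        keep_idx = np.sort(piv[:rank])
        if rank < X.shape[1]:
            dropped += [kept_roles[i] for i in piv[rank:]]
        X = X[:, keep_idx]
        kept_roles = [kept_roles[i] for i in keep_idx]

    if dropped:
        logger.warning("dropped %d degenerate nuisance columns: %s",
                       len(dropped), sorted(set(dropped)))
    return NuisanceDesign(columns=X, column_roles=kept_roles)


def regress_nuisance(bold: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Residualize every vertex against the whole design in one joint projection.

    A constant term is always part of the projection (the design's 28+12
    convention does not carry one), so residuals are orthogonal to each
    design column and to the constant, and per-vertex variance can only
    decrease.
    """
    if design.T != bold.T:
        raise ValueError("design and BOLD frame counts differ")
    p = design.p + 1  # implicit intercept
    if p >= bold.T:
        raise ValueError(
            f"rank-deficient regression: {p} regressors for {bold.T} frames"
        )
    X = np.column_stack([np.ones(bold.T), design.columns])
    beta, *_ = np.linalg.lstsq(X, bold.data.T, rcond=None)
    resid = bold.data.T - X @ beta
    return BoldRun(data=resid.T, tr=bold.tr)


def low_variance_vertices(bold: BoldRun, threshold: float = 1e-10) -> np.ndarray:
    """Boolean mask of vertices whose post-regression variance is below threshold.

    A subject with any flagged vertex is marked metric-invalid downstream,
    mirroring the exclusion of subjects whose near-constant vertices make
    the network metrics meaningless.
    """
    return np.var(bold.data, axis=1) < threshold
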