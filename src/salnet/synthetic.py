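"""Synthetic cohort generator: surface-style BOLD sessions and phenotypes.

Everything downstream of acquisition is testable against this module: it
draws subject-level network engagement maps around a configurable population
prior, renders BOLD sessions as maps x time-courses plus structured nuisance
(drift, motion-coupled artifact, spikes, white noise), and generates
phenotype tables from the moderated linear-model equations the analysis
battery estimates, with violence counts as sex-specific negative binomials.

The atlas is index-contiguous (no surface mesh): every metric downstream
depends only on vertex labels, not geometry.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AtlasSpec, BoldRun

__all__ = [
    "SubjectTruth",
    "NuisanceMagnitudes",
    "PhenotypeSettings",
    "make_parcel_atlas",
    "default_prior_truth",
    "simulate_subject_engagement",
    "simulate_bold_session",
    "simulate_phenotypes",
    "default_phenotype_coeffs",
]

# Analysis-sample composition and violence-count moments (per-sex mean / SD
# of past-year exposure counts in the cohort the generator emulates).
FEMALE_FRACTION = 141 / 220
VIOLENCE_MEANS = (1.16, 2.95)  # (female, male)
VIOLENCE_SDS = (2.37, 5.05)
DEPRESSION_MEAN, DEPRESSION_SD = 8.8, 5.29

INDICATOR_COLUMNS = ("sex", "black", "white", "hispanic")


def _nb_size(mean: float, sd: float) -> float:
    """Negative-binomial size r solving Var = mu + mu^2/r for the given moments."""
    excess = sd**2 - mean
    if excess <= 0:
        raise ValueError("negative binomial requires SD^2 > mean")
    return mean**2 / excess


@dataclass
class SubjectTruth:
    """Latent truth for one simulated subject: the maps downstream stages estimate."""

    maps: np.ndarray  # (V, K) true engagement
    sessions: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (V, K)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class NuisanceMagnitudes:
    """Scales of the structured nuisance added to a synthetic BOLD session.

    All magnitudes are in units of the network-signal amplitude; zero for all
    fields reproduces the pure maps x time-courses product exactly.
    """

    drift: float = 0.0
    motion: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    noise_sd: float = 0.0


def make_parcel_atlas(V: int, K: int, seed: int = 0, salience_index: int | None = None) -> AtlasSpec:
    """Partition V vertices into K index-contiguous network blocks.

    Block sizes are drawn (deterministically for a given seed) from a flat
    Dirichlet so parcels differ in size, with every network receiving at
    least one vertex. ``salience_index`` defaults to network 8 when K >= 8
    (the salience / ventral-attention B slot of the 17-network ordering),
    else network 1.
    """
    if K < 1 or V < 1:
        raise ValueError("V and K must be positive")
    if K > V:
        raise ValueError(f"cannot split {V} vertices into {K} networks")
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.ones(K))
    # Largest-remainder apportionment of the V - K spare vertices.
    spare = V - K
    raw = weights * spare
    sizes = np.floor(raw).astype(int)
    remainder = spare - sizes.sum()
    if remainder > 0:
        order = np.argsort(-(raw - sizes))
        sizes[order[:remainder]] += 1
    sizes += 1
    labels = np.repeat(np.arange(1, K + 1), sizes)
    if salience_index is None:
        salience_index = 8 if K >= 8 else 1
    return AtlasSpec(labels=labels, K=K, salience_index=salience_index)


def default_prior_truth(
    atlas: AtlasSpec,
    in_mean: float = 1.0,
    out_mean: float = 0.0,
    in_between_sd: float = 0.25,
    out_between_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Population truth maps implied by a hard parcellation.

    The true mean engagement of network k is ``in_mean`` on the vertices the
    atlas assigns to k and ``out_mean`` elsewhere; between-subject SD is
    larger inside the network than outside. Returns (prior_mean_truth,
    prior_var_truth), each (V, K).
    """
    inside = np.stack([atlas.labels == k for k in range(1, atlas.K + 1)], axis=1)
    mean = np.where(inside, in_mean, out_mean).astype(np.float64)
    var = np.where(inside, in_between_sd**2, out_between_sd**2).astype(np.float64)
    return mean, var


def simulate_subject_engagement(
    atlas: AtlasSpec,
    prior_mean_truth: np.ndarray,
    prior_var_truth: np.ndarray,
    n_subjects: int,
    seed: int = 0,
    sessions: int = 2,
    noise_sd: float = 1.0,
) -> list[SubjectTruth]:
    """Draw each subject's true map at (v, k) ~ Normal(mean, var), independently."""
    mean = np.asarray(prior_mean_truth, dtype=np.float64)
    var = np.asarray(prior_var_truth, dtype=np.float64)
    if mean.shape != (atlas.V, atlas.K) or var.shape != (atlas.V, atlas.K):
        raise ValueError("truth maps must be (V, K) matching the atlas")
    if np.any(var < 0):
        raise ValueError("prior_var_truth must be nonnegative")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(var)
    subjects = []
    for i in range(n_subjects):
        maps = mean + sd * rng.standard_normal(mean.shape)
        subjects.append(
            SubjectTruth(maps=maps, sessions=sessions, noise_sd=noise_sd, seed=seed + i)
        )
    return subjects


def _network_timecourses(K: int, T: int, rng: np.random.Generator, ar: float = 0.6) -> np.ndarray:
    """AR(1)-smoothed Gaussian network time courses, mutually decorrelated.

    Rows are orthogonalized (QR) then rescaled to unit temporal variance, so
    the network signals are exactly uncorrelated with each other and with the
    constant — convenient for dual-regression recovery at modest T.
    """
    raw = rng.standard_normal((K, T))
    for t in range(1, T):
        raw[:, t] = ar * raw[:, t - 1] + np.sqrt(1 - ar**2) * raw[:, t]
    centered = raw - raw.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(centered.T)  # (T, K), orthonormal columns
    courses = q.T
    courses = courses - courses.mean(axis=1, keepdims=True)
    sd = courses.std(axis=1, keepdims=True)
    return courses / sd


def simulate_bold_session(
    subject: SubjectTruth,
    atlas: AtlasSpec,
    T: int,
    TR: float,
    nuisance: NuisanceMagnitudes | None = None,
    seed: int = 0,
    signal_amplitude: float = 1.0,
) -> tuple[BoldRun, pd.DataFrame]:
    """Render one BOLD session: Y = maps @ timecourses + structured nuisance.

    Returns the (V, T) run and a 6-column motion-parameter table (translations
    in mm, rotations in radians; AR(1) random walks scaled by the motion
    magnitude). With all nuisance magnitudes zero the output equals the exact
    signal product.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    nuisance = nuisance or NuisanceMagnitudes()
    for name in ("drift", "motion", "spike_rate", "spike_amplitude", "noise_sd"):
        if getattr(nuisance, name) < 0:
            raise ValueError(f"nuisance magnitude {name} must be nonnegative")
    V, K = subject.maps.shape
    if V != atlas.V or K != atlas.K:
        raise ValueError("subject maps do not match atlas dimensions")
    rng = np.random.default_rng(seed)

    courses = _network_timecourses(K, T, rng)
    Y = signal_amplitude * (subject.maps @ courses)

    motion = np.zeros((T, 6))
    if nuisance.motion > 0:
        steps = rng.standard_normal((T, 6)) * 0.05
        motion = nuisance.motion * np.cumsum(steps, axis=0)
        loadings = rng.standard_normal((V, 6)) * 0.3
        Y = Y + loadings @ motion.T

    if nuisance.drift > 0:
        t = np.arange(T) / T
        slow = np.stack([t, t**2, np.cos(np.pi * t)], axis=0)
        Y = Y + nuisance.drift * rng.standard_normal((V, 3)) @ slow

    if nuisance.spike_rate > 0 and nuisance.spike_amplitude > 0:
        n_spikes = rng.binomial(T, nuisance.spike_rate)
        frames = rng.choice(T, size=min(n_spikes, T), replace=False)
        for f in frames:
            Y[:, f] += nuisance.spike_amplitude * rng.standard_normal(V)

    if nuisance.noise_sd > 0:
        Y = Y + nuisance.noise_sd * rng.standard_normal((V, T))

    motion_df = pd.DataFrame(
        motion, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    )
    return BoldRun(data=Y, tr=TR), motion_df


# --- phenotypes ------------------------------------------------------------


def default_phenotype_coeffs() -> dict[int, dict[str, float]]:
    """Generating coefficients for the moderated-model equations, on the
    standardized scale the analysis battery reports.

    Keys are the equation indices of the battery (2: depression on sex,
    violence, and their interaction; 3: expansion; 4: connectivity; 5-8:
    depression on sex and a network metric, optionally adjusting violence).
    Nonzero values are the cohort's reported standardized effects: the
    female indicator and sex-by-violence interaction on depression, and a
    lower female within-network connectivity; exposure effects on the
    network metrics are null, matching the cohort's findings.
    """
    return {
        2: {"b0": 0.0, "b1": 0.399, "b2": 0.102, "b3": 0.337},
        3: {"b0": 0.0, "b1": 0.0, "b2": 0.0, "b3": 0.0},
        4: {"b0": 0.0, "b1": -0.25, "b2": 0.0, "b3": 0.0},
        5: {"b0": 0.0, "b1": 0.242, "b4": 0.3, "b5": -0.2},
        6: {"b0": 0.0, "b1": 0.238, "b4": 0.3, "b5": -0.326},
        7: {"b0": 0.0, "b1": 0.3, "b2": 0.1, "b4": 0.25, "b5": -0.2},
        8: {"b0": 0.0, "b1": 0.3, "b2": 0.1, "b4": 0.25, "b5": -0.2},
    }


@dataclass
class PhenotypeSettings:
    """Configuration of the phenotype generator.

    ``violence_means_by_sex``/``violence_sds_by_sex`` are (female, male)
    moments of past-year violence-exposure counts; the negative-binomial size
    is derived from them. ``depression_equation`` selects which battery
    equation generates the outcome (2 by default; 5-8 let recovery tests
    exercise the metric models). ``noise_sd`` of None calibrates the
    depression residual so the standardized outcome has unit population
    variance, making the standardized generating coefficients directly
    recoverable.
    """

    coeffs: dict[int, dict[str, float]] = field(default_factory=default_phenotype_coeffs)
    violence_means_by_sex: tuple[float, float] = VIOLENCE_MEANS
    violence_sds_by_sex: tuple[float, float] = VIOLENCE_SDS
    sex_fraction_female: float = FEMALE_FRACTION
    noise_sd: float | None = None
    metric_noise_sd: float = 1.0
    depression_equation: int = 2
    lag_correlation: float = 0.5
    missing_t1_fraction: float = 0.0
    discretize: bool = False


def _violence_mixture_moments(settings: PhenotypeSettings) -> tuple[float, float, tuple[float, float]]:
    f = settings.sex_fraction_female
    mu_f, mu_m = settings.violence_means_by_sex
    sd_f, sd_m = settings.violence_sds_by_sex
    var_f, var_m = sd_f**2, sd_m**2
    mu = f * mu_f + (1 - f) * mu_m
    var = f * var_f + (1 - f) * var_m + f * (1 - f) * (mu_f - mu_m) ** 2
    return mu, np.sqrt(var), (var_f, var_m)


def _calibrated_noise_sd(settings: PhenotypeSettings) -> float:
    """Residual SD giving the standardized depression equation unit variance.

    Closed form for equation 2 (sex, standardized violence, interaction)
    from the negative-binomial mixture moments. Used only when the outcome
    is generated from equation 2; other equations fall back to leaving
    roughly unit total variance given the standardized mediators.
    """
    c = settings.coeffs[2]
    f = settings.sex_fraction_female
    mu_f, mu_m = settings.violence_means_by_sex
    mu, sd, (var_f, var_m) = _violence_mixture_moments(settings)
    zf, zm = (mu_f - mu) / sd, (mu_m - mu) / sd
    vf, vm = var_f / sd**2, var_m / sd**2
    el_f = c["b1"] + (c["b2"] + c["b3"]) * zf
    el_m = c["b2"] * zm
    vl_f = (c["b2"] + c["b3"]) ** 2 * vf
    vl_m = c["b2"] ** 2 * vm
    el = f * el_f + (1 - f) * el_m
    var_lin = (
        f * vl_f
        + (1 - f) * vl_m
        + f * (el_f - el) ** 2
        + (1 - f) * (el_m - el) ** 2
    )
    if var_lin >= 1.0:
        return 0.0
    return float(np.sqrt(1.0 - var_lin))


def simulate_phenotypes(
    n: int,
    settings: PhenotypeSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an n-subject phenotype table with the analysis's structure.

    Columns: sex (1 female), violence (past-year count), depression,
    expansion, connectivity, demographics (age, black, white, hispanic,
    bmi_pct, puberty, ipr), and time-1 variants (depression_t1, expansion_t1,
    connectivity_t1, violence_t1). Continuous phenotypes are affine maps of
    standardized latents with the cohort's observed moments; depression stays
    continuous unless ``discretize`` rounds/clips it to the 0-33 survey scale.
    """
    settings = copy.deepcopy(settings) if settings is not None else PhenotypeSettings()
    if n < 4:
        raise ValueError("need n >= 4 subjects")
    if min(settings.violence_means_by_sex) < 0:
        raise ValueError("violence means must be nonnegative")
    rng = np.random.default_rng(seed)

    f = settings.sex_fraction_female
    sex = (rng.random(n) < f).astype(np.int64)  # 1 = female
    mu_f, mu_m = settings.violence_means_by_sex
    sd_f, sd_m = settings.violence_sds_by_sex
    size = np.where(sex == 1, _nb_size(mu_f, sd_f), _nb_size(mu_m, sd_m))
    mean = np.where(sex == 1, mu_f, mu_m)
    violence = rng.negative_binomial(size, size / (size + mean))

    mu, sd, _ = _violence_mixture_moments(settings)
    z = (violence - mu) / sd  # population-standardized exposure
    x1 = sex.astype(np.float64)

    def eq(idx: int, z2: np.ndarray, m: np.ndarray | None = None) -> np.ndarray:
        c = settings.coeffs[idx]
        out = c.get("b0", 0.0) + c.get("b1", 0.0) * x1 + c.get("b2", 0.0) * z2
        out = out + c.get("b3", 0.0) * x1 * z2
        if m is not None:
            out = out + c.get("b4", 0.0) * m + c.get("b5", 0.0) * x1 * m
        return out

    m_noise = settings.metric_noise_sd
    m1 = eq(3, z) + (rng.standard_normal(n) * m_noise if m_noise > 0 else 0.0)
    m2 = eq(4, z) + (rng.standard_normal(n) * m_noise if m_noise > 0 else 0.0)

    noise_sd = settings.noise_sd
    if noise_sd is None:
        noise_sd = _calibrated_noise_sd(settings)
    k = settings.depression_equation
    if k == 2:
        y = eq(2, z)
    elif k in (5, 6):
        y = eq(k, z, m1 if k == 5 else m2)
    elif k in (7, 8):
        y = eq(k, z, m1 if k == 7 else m2)
    else:
        raise ValueError("depression_equation must be one of 2, 5, 6, 7, 8")
    if noise_sd > 0:
        y = y + rng.standard_normal(n) * noise_sd

    rho = settings.lag_correlation
    lag = lambda x: rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)  # noqa: E731

    depression = DEPRESSION_MEAN + DEPRESSION_SD * y
    if settings.discretize:
        depression = np.clip(np.round(depression), 0, 33)
    expansion = 0.05 + 0.015 * m1
    connectivity = 0.25 + 0.08 * m2

    depression_t1 = DEPRESSION_MEAN - 0.8 + DEPRESSION_SD * lag(y)
    expansion_t1 = 0.05 + 0.015 * lag(m1)
    connectivity_t1 = 0.25 + 0.08 * lag(m2)
    violence_t1 = rng.negative_binomial(size, size / (size + mean))

    age = rng.normal(16.06, 0.566, n)
    bmi_pct = np.clip(rng.normal(72.0, 24.9, n), 1.0, 99.7)
    puberty_mean = np.where(sex == 1, 4.43, 3.68)
    puberty = np.clip(np.round(rng.normal(puberty_mean, 0.6)), 1, 5)
    shape = (3.95 / 5.03) ** 2
    ipr = rng.gamma(shape, 3.95 / shape, n)

    table = pd.DataFrame(
        {
            "sex": sex,
            "violence": violence,
            "depression": depression,
            "expansion": expansion,
            "connectivity": connectivity,
            "age": age,
            "black": (rng.random(n) < 0.377).astype(np.int64),
            "white": (rng.random(n) < 0.436).astype(np.int64),
            "hispanic": (rng.random(n) < 0.295).astype(np.int64),
            "bmi_pct": bmi_pct,
            "puberty": puberty,
            "ipr": ipr,
            "depression_t1": depression_t1,
            "expansion_t1": expansion_t1,
            "connectivity_t1": connectivity_t1,
            "violence_t1": violence_t1,
        }
    )
    if settings.missing_t1_fraction > 0:
        n_missing = int(round(settings.missing_t1_fraction * n))
        idx = rng.choice(n, size=n_missing, replace=False)
        table.loc[idx, ["expansion_t1", "connectivity_t1"]] = np.nan
    return table
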