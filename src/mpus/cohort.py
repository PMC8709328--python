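"""Seeded synthetic cohorts of inconclusive focal liver lesions.

The generator emulates the statistical structure the downstream pipeline
assumes, so every stage is testable without clinical data:

* a 91-lesion census across twelve reference diagnoses (34 HCC, 13
  metastases, ...), with a 34/91 cirrhotic fraction assigned preferentially
  to HCC and regenerative nodules;
* class-conditional lesion AREA distributions (malignant -25.08 +/- 37.98 dB,
  benign -7.08 +/- 42.6 dB) linked to the parenchyma AREA through the linear
  relation y = -12.21 + 0.16 x;
* arterial enhancement patterns drawn from each diagnosis's canonical pattern
  and corrupted with a configurable confusion rate, mimicking lesions whose
  pattern was unreadable at CEUS;
* late-phase (120-300 s) time-intensity curves synthesised from the washout
  model A*exp(-kt)+B with additive Gaussian noise in dB, the amplitude A
  solved analytically so each curve's true AREA equals its drawn value.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .lesions import (
    DEFAULT_MALIGNANCY,
    DEFAULT_TYPE_PATTERN,
    EnhancementPattern,
    LesionRecord,
    LesionType,
)
from .washout import TICSeries, area_factor


def default_composition() -> dict[LesionType, int]:
    """The default 91-lesion census by reference diagnosis."""
    return {
        LesionType.HCC: 34,
        LesionType.METASTASIS: 13,
        LesionType.HAEMANGIOMA: 7,
        LesionType.REGENERATIVE_NODULE: 7,
        LesionType.FOCAL_FATTY_ALTERATION: 5,
        LesionType.FATTY_FREE_AREA: 3,
        LesionType.CHOLANGIOCARCINOMA: 4,
        LesionType.ABSCESS: 2,
        LesionType.ADENOMA: 5,
        LesionType.COMPLEX_BILIARY_CYST: 4,
        LesionType.PARENCHYMAL_INFARCTION: 5,
        LesionType.VASCULAR_ABNORMALITY: 2,
    }


@dataclass(frozen=True)
class TICParams:
    """Washout-model parameters of one synthetic curve."""

    A: float  # dB
    B: float  # dB
    k: float  # 1/s
    t0: float = 0.0  # start-frame time, s

    def __post_init__(self) -> None:
        for v in (self.A, self.B, self.k, self.t0):
            if not np.isfinite(v):
                raise ValueError("TIC parameters must be finite")
        if self.k < 0:
            raise ValueError("decay rate k must be >= 0")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``composition`` maps lesion types either to integer counts summing to
    ``n`` (count mode) or to probabilities summing to 1 (probability mode).
    AREA moments are in dB; draws are upper-truncated at
    ``area_upper_bound`` (mean-matched, so configured class means are hit
    exactly in expectation).
    """

    n: int = 91
    composition: dict[LesionType, float] = field(default_factory=default_composition)
    cirrhotic_fraction: float = 34 / 91
    area_mean_malignant: float = -25.08
    area_sd_malignant: float = 37.98
    area_mean_benign: float = -7.08
    area_sd_benign: float = 42.6
    area_mean_parenchyma: float = -7.0
    area_sd_parenchyma: float = 42.6
    regression_intercept: float = -12.21
    regression_slope: float = 0.16
    area_upper_bound: float = 30.0
    k_decay: float = 0.02  # 1/s
    baseline_B: float = -57.3  # dB
    noise_sd: float = 1.0  # dB
    window_start: float = 120.0  # s (late phase starts at 120 s)
    window_end: float = 300.0  # s
    sample_interval: float = 1.0  # s
    pattern_confusion_rate: float = 0.5
    malignant_overrides: dict[LesionType, bool] = field(default_factory=dict)
    seed: int = 0

    def malignancy_map(self) -> dict[LesionType, bool]:
        m = dict(DEFAULT_MALIGNANCY)
        m.update(self.malignant_overrides)
        return m

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not self.composition:
            raise ValueError("composition must not be empty")
        vals = np.array(list(self.composition.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("composition values must be non-negative")
        total = vals.sum()
        is_counts = np.allclose(vals, np.round(vals)) and np.isclose(total, self.n)
        is_probs = np.isclose(total, 1.0)
        if not (is_counts or is_probs):
            raise ValueError(
                f"composition must sum to n={self.n} (counts) or 1 (probabilities); got {total}"
            )
        if not 0.0 <= self.cirrhotic_fraction <= 1.0:
            raise ValueError("cirrhotic_fraction must be in [0, 1]")
        if not 0.0 <= self.pattern_confusion_rate <= 1.0:
            raise ValueError("pattern_confusion_rate must be in [0, 1]")
        for name in ("area_sd_malignant", "area_sd_benign", "area_sd_parenchyma", "noise_sd", "k_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.window_end > self.window_start >= 120.0):
            raise ValueError("need window_end > window_start >= 120 s (late phase)")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        n_samples = int(np.floor((self.window_end - self.window_start) / self.sample_interval)) + 1
        if n_samples < 4:
            raise ValueError("sampling grid must contain at least 4 frames")

    def grid(self) -> np.ndarray:
        """The sampling time grid (absolute seconds) of this configuration."""
        m = int(np.floor((self.window_end - self.window_start) / self.sample_interval)) + 1
        return self.window_start + np.arange(m) * self.sample_interval


def params_from_area(
    target_area: float, k: float, B: float, window_length: float, t0: float = 0.0
) -> TICParams:
    """Invert the AREA definition: amplitude A whose curve has the given AREA.

    For F(t) = A*exp(-kt)+B over a window of length T, the time-averaged
    deviation from the start-frame value is A*[(1-e^{-kT})/(kT) - 1], so
    A = target_area / that factor.  Degenerate when kT -> 0 (a flat
    exponential cannot produce a nonzero AREA).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if target_area == 0.0:
        return TICParams(A=0.0, B=B, k=k, t0=t0)
    denom = area_factor(k, window_length)
    if abs(denom) < 1e-12:
        raise ValueError("degenerate window: k * window_length too close to 0")
    return TICParams(A=target_area / denom, B=B, k=k, t0=t0)


def simulate_tic(
    params: TICParams,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: Union[int, np.random.Generator, None] = None,
    lesion_id: str = "sim",
    roi: str = "lesion",
) -> TICSeries:
    """Sample the washout model on a time grid with i.i.d. Gaussian noise (dB)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty sampling grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = params.A * np.exp(-params.k * (grid - params.t0)) + params.B
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=grid.shape)
    return TICSeries(lesion_id=lesion_id, roi=roi, times=grid, intensities=y)


# ---------------------------------------------------------------------------
# mean-matched upper-truncated normal draws
# ---------------------------------------------------------------------------


def _mills(beta: np.ndarray) -> np.ndarray:
    # phi(beta)/Phi(beta), numerically stable for all beta
    return np.exp(norm.logpdf(beta) - norm.logcdf(beta))


def _matched_location(target: np.ndarray, sd: np.ndarray, upper: float) -> np.ndarray:
    """Location mu such that an upper-truncated N(mu, sd) has mean ``target``.

    Solves target = mu - sd * lambda((upper - mu)/sd) by damped Newton; the
    mean of the truncated distribution is strictly increasing in mu, so the
    root is unique for any target < upper.
    """
    target = np.asarray(target, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), target.shape).copy()
    mu = target.astype(float).copy()
    live = sd > 0
    if np.any(target[live] >= upper):
        raise ValueError("truncated-mean target must lie below the upper bound")
    for _ in range(100):
        beta = (upper - mu[live]) / sd[live]
        lam = _mills(beta)
        f = mu[live] - sd[live] * lam - target[live]
        fp = np.maximum(1.0 - beta * lam - lam**2, 1e-10)
        step = f / fp
        step = np.clip(step, -10.0 * sd[live], 10.0 * sd[live])
        mu[live] = mu[live] - step
        if np.max(np.abs(step)) < 1e-12 * max(1.0, np.max(sd)):
            break
    return mu


def _truncated_var(loc: float, sd: float, upper: float) -> float:
    """Variance of an upper-truncated normal with the given location."""
    if sd == 0:
        return 0.0
    beta = (upper - loc) / sd
    lam = float(_mills(np.asarray(beta)))
    return sd**2 * (1.0 - beta * lam - lam**2)


def _draw_truncated(
    rng: np.random.Generator, target_mean: np.ndarray, sd: np.ndarray, upper: float
) -> np.ndarray:
    """Upper-truncated normal draws whose expectation equals ``target_mean``."""
    target_mean = np.asarray(target_mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), target_mean.shape)
    out = np.minimum(target_mean, upper)  # sd == 0 -> deterministic
    live = sd > 0
    if np.any(live):
        loc = _matched_location(target_mean, sd, upper)
        beta = (upper - loc[live]) / sd[live]
        u = np.clip(rng.random(int(live.sum())), 1e-15, 1.0 - 1e-15)
        out = out.copy()
        out[live] = loc[live] + sd[live] * ndtri(u * ndtr(beta))
    return out


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _expand_composition(config: CohortConfig, rng: np.random.Generator) -> list[LesionType]:
    vals = np.array(list(config.composition.values()), dtype=float)
    types = list(config.composition.keys())
    if np.isclose(vals.sum(), 1.0) and not np.isclose(vals.sum(), config.n):
        counts = rng.multinomial(config.n, vals / vals.sum())
    else:
        counts = np.round(vals).astype(int)
        if counts.sum() != config.n:
            raise ValueError("composition counts do not sum to n")
    expanded: list[LesionType] = []
    for t, c in zip(types, counts):
        expanded.extend([t] * int(c))
    order = rng.permutation(config.n)
    return [expanded[i] for i in order]


#: Relative odds of a cirrhotic liver background by lesion type: HCC and
#: regenerative nodules arise almost exclusively in cirrhosis.
_CIRRHOSIS_WEIGHT = {LesionType.HCC: 5.0, LesionType.REGENERATIVE_NODULE: 5.0}


def sample_cohort(config: CohortConfig, include_tics: bool = True) -> list[LesionRecord]:
    """Generate one seeded cohort of lesion records.

    The exact census follows ``composition`` (count mode); exactly
    ``round(n * cirrhotic_fraction)`` lesions are cirrhotic, selected by
    weighted sampling without replacement favouring HCC and regenerative
    nodules.  Parenchyma AREA is drawn first from its marginal (independently
    of class, so the cohort-wide regression slope is the configured one);
    the lesion AREA is drawn around the configured line plus a class shift
    calibrated so the malignant/benign class means equal their configured
    targets exactly in expectation.  With ``include_tics`` each record also
    carries a lesion and a parenchyma TIC whose noiseless AREA equals the
    drawn value.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    types = _expand_composition(config, rng)
    malignancy = config.malignancy_map()
    truth_mal = np.array([malignancy[t] for t in types], dtype=bool)

    # fibrosis: exact cirrhotic count, weighted without replacement
    n_cir = int(round(config.cirrhotic_fraction * n))
    weights = np.array([_CIRRHOSIS_WEIGHT.get(t, 1.0) for t in types])
    keys = rng.random(n) ** (1.0 / weights)
    cirrhotic = np.zeros(n, dtype=bool)
    if n_cir > 0:
        cirrhotic[np.argsort(keys)[-n_cir:]] = True

    # AREA draws
    upper = config.area_upper_bound
    a, b = config.regression_intercept, config.regression_slope
    x = _draw_truncated(
        rng,
        np.full(n, config.area_mean_parenchyma),
        np.full(n, config.area_sd_parenchyma),
        upper,
    )
    if config.area_sd_parenchyma > 0:
        loc_p = float(
            _matched_location(
                np.array([config.area_mean_parenchyma]), np.array([config.area_sd_parenchyma]), upper
            )[0]
        )
        var_x = _truncated_var(loc_p, config.area_sd_parenchyma, upper)
    else:
        var_x = 0.0
    shift_mal = config.area_mean_malignant - (a + b * config.area_mean_parenchyma)
    shift_ben = config.area_mean_benign - (a + b * config.area_mean_parenchyma)
    sd_resid_mal = np.sqrt(max(config.area_sd_malignant**2 - b**2 * var_x, 0.0))
    sd_resid_ben = np.sqrt(max(config.area_sd_benign**2 - b**2 * var_x, 0.0))
    cond_mean = a + b * x + np.where(truth_mal, shift_mal, shift_ben)
    sd_resid = np.where(truth_mal, sd_resid_mal, sd_resid_ben)
    y = _draw_truncated(rng, cond_mean, sd_resid, upper)

    # arterial patterns with confusion noise
    all_patterns = list(EnhancementPattern)
    patterns: list[EnhancementPattern] = [DEFAULT_TYPE_PATTERN[t] for t in types]
    confused = rng.random(n) < config.pattern_confusion_rate
    picks = rng.integers(0, len(all_patterns) - 1, size=n)
    for i in range(n):
        if confused[i]:
            others = [p for p in all_patterns if p is not patterns[i]]
            patterns[i] = others[int(picks[i])]

    grid = config.grid()
    T = config.window_end - config.window_start
    records: list[LesionRecord] = []
    for i in range(n):
        lesion_id = f"L{i + 1:05d}"
        les_series = par_series = None
        if include_tics:
            p_les = params_from_area(float(y[i]), config.k_decay, config.baseline_B, T, t0=config.window_start)
            p_par = params_from_area(float(x[i]), config.k_decay, config.baseline_B, T, t0=config.window_start)
            les_series = simulate_tic(p_les, grid, config.noise_sd, rng, lesion_id, "lesion")
            par_series = simulate_tic(p_par, grid, config.noise_sd, rng, lesion_id, "parenchyma")
        records.append(
            LesionRecord(
                lesion_id=lesion_id,
                cirrhotic=bool(cirrhotic[i]),
                pattern=patterns[i],
                lesion_series=les_series,
                parenchyma_series=par_series,
                truth_type=types[i],
                truth_malignant=bool(truth_mal[i]),
                area_lesion_true=float(y[i]),
                area_parenchyma_true=float(x[i]),
            )
        )
    return records


def separable_config(seed: int = 0) -> CohortConfig:
    """A noise-free, confusion-free configuration with zero within-class variance.

    Class AREA means sit on opposite sides of the -19.3 dB cutoff, so a
    correct pipeline must classify malignancy perfectly (separability limit).
    """
    return CohortConfig(
        area_sd_malignant=0.0,
        area_sd_benign=0.0,
        area_sd_parenchyma=0.0,
        noise_sd=0.0,
        pattern_confusion_rate=0.0,
        seed=seed,
    )


def consistent_regression_config(seed: int = 0, n: int = 10_000) -> CohortConfig:
    """Configuration whose class means lie exactly on the configured line.

    Used for regression parameter recovery: with both class means equal to
    intercept + slope * E[parenchyma AREA], the class shifts vanish and the
    cohort-wide OLS line is an unbiased estimate of the configured
    (intercept, slope).  Composition switches to probability mode so any n
    can be drawn.
    """
    base = CohortConfig()
    on_line = base.regression_intercept + base.regression_slope * base.area_mean_parenchyma
    comp = {t: c / 91.0 for t, c in default_composition().items()}
    return replace(
        base,
        n=n,
        composition=comp,
        area_mean_malignant=on_line,
        area_mean_benign=on_line,
        seed=seed,
    )
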