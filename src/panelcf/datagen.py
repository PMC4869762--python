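"""Synthetic panel generation.

Two generators live here:

* :func:`generate_panel` draws balanced panels from the Monte Carlo
  data-generating process used throughout the simulation study,

  .. math::

     Y_{it} = X_{1,it}\\beta_1 + X_{2,it}\\beta_2 + \\lambda_t \\mu_i
              + D_{it}\\tau + \\varepsilon_{it},

  where :math:`\\mu_i` is a time-invariant unobserved confounder whose
  effect :math:`\\lambda_t` may drift over time (breaking parallel trends),
  the observed covariates and :math:`\\mu_i` come from correlated normals
  with treated-group means shifted one latent standard deviation upward,
  and :math:`\\varepsilon_{it}` is an optionally AR(1)-correlated shock.
  Treatment starts in the final period (``T0 = T - 1``).

* :func:`generate_hospital_fixture` emulates hospital-quarter proportion
  panels (binomial fractions with admission counts as frequency weights)
  so the full pipeline can be exercised on case-study-shaped data.

Scenario presets A-F (and C1-C3) parameterize the canonical study grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import PanelDataset

__all__ = [
    "ScenarioConfig",
    "LambdaPath",
    "DgpDraw",
    "make_lambda",
    "simulate_errors",
    "generate_panel",
    "scenario_presets",
    "generate_hospital_fixture",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("A", "B", "C", "C1", "C2", "C3", "D", "E", "F")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """Full DGP parameterization.

    Parameters with units: ``sigma_eps`` is the AR(1) innovation SD of the
    idiosyncratic shock (outcome units); ``delta`` the trend coefficient in
    the confounder loading :math:`\\lambda_t`; ``amplitude``/``wavelength``
    the seasonal sine component (wavelength in periods, 4 = annual cycle on
    quarterly data); ``rho`` the AR(1) serial correlation; ``beta`` the
    covariate effects; ``tau`` the true ATT; ``mu_shift_sd`` the
    treated-group mean shift in latent-SD units; ``sigma_latent`` the
    common SD of the latent components (X1 anchor, X2 anchor, mu);
    ``latent_corr`` the correlation between the two covariate anchors;
    ``mu_x_corr`` the correlation of the confounder mu with each anchor
    (default 0: the observed covariates do not proxy mu); ``x_noise_sd``
    the SD of the per-period covariate innovation around its unit anchor.
    """

    T: int
    n_units: int = 150
    n_treated: int = 75
    sigma_eps: float = 10.0
    rho: float = 0.0
    delta: float = 0.0
    amplitude: float = 0.0
    wavelength: float = 4.0
    beta: tuple = (1.0, 1.0)
    tau: float = 10.0
    mu_shift_sd: float = 1.0
    sigma_latent: float = 4.0
    latent_corr: float = 0.3
    mu_x_corr: float = 0.0
    x_noise_sd: float = 1.0
    lambda_form: str = "linear"  # linear | quadratic | step
    sine_literal: bool = False   # t-free sine variant A*sin(2*pi/w)
    seed: int | None = None

    def __post_init__(self):
        if self.T < 2:
            raise ConfigError("T must be >= 2")
        if not 0 < self.n_treated < self.n_units:
            raise ConfigError("need 0 < n_treated < n_units")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be >= 0")
        if not abs(self.rho) < 1:
            raise ConfigError(f"|rho| must be < 1 (nonstationary AR(1)); got {self.rho}")
        if self.amplitude != 0 and self.wavelength <= 0:
            raise ConfigError("wavelength must be > 0 when amplitude != 0")
        if self.lambda_form not in ("linear", "quadratic", "step"):
            raise ConfigError(f"unknown lambda_form {self.lambda_form!r}")
        c, cm = self.latent_corr, self.mu_x_corr
        R = np.array([[1.0, c, cm], [c, 1.0, cm], [cm, cm, 1.0]])
        if np.linalg.eigvalsh(R).min() < -1e-12:
            raise ConfigError(
                "latent correlation matrix is not positive semidefinite "
                f"(latent_corr={c}, mu_x_corr={cm})"
            )

    @property
    def T0(self) -> int:
        return self.T - 1

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class LambdaPath:
    """Time path of the unobserved-confounder loading, lam[t-1] = lambda_t."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ConfigError("lambda path must be a finite 1-d vector")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)

    def is_constant(self) -> bool:
        return bool(np.all(self.values == self.values[0]))


@dataclass(frozen=True)
class DgpDraw:
    """Latent realizations retained for oracle tests: the confounder mu_i,
    the covariate anchors, the per-period covariates and shocks, and the
    lambda path that produced the outcomes."""

    mu: np.ndarray          # (n,)
    anchors: np.ndarray     # (n, 2) time-invariant covariate anchors
    X: np.ndarray           # (n, T, 2)
    eps: np.ndarray         # (n, T)
    lam: LambdaPath


def make_lambda(config: ScenarioConfig) -> LambdaPath:
    """Confounder-loading path lambda_t for t = 1..T.

    The default (``linear``) form is

        lambda_t = 1 + delta * (1 - (t - T)/50) + A * sin(2*pi*t / w),

    a constant plus a time trend plus a seasonal sine.  With
    ``sine_literal=True`` the sine argument drops ``t`` (the degenerate
    constant-offset variant, ``A*sin(2*pi/w)``).  The ``quadratic`` form
    squares the trend deviation, ``1 + delta*(1 + ((T - t)/50)**2) + sine``;
    the ``step`` form is a pre/post level change: ``1 + delta`` for
    ``t <= T0`` and ``1`` for ``t > T0`` (no sine).
    """
    t = np.arange(1, config.T + 1, dtype=float)
    if config.amplitude != 0 and config.wavelength <= 0:
        raise ConfigError("wavelength must be > 0 when amplitude != 0")
    if config.sine_literal:
        sine = config.amplitude * np.sin(2 * np.pi / config.wavelength) * np.ones_like(t)
    else:
        sine = config.amplitude * np.sin(2 * np.pi * t / config.wavelength)
    if config.lambda_form == "linear":
        vals = 1.0 + config.delta * (1.0 - (t - config.T) / 50.0) + sine
    elif config.lambda_form == "quadratic":
        vals = 1.0 + config.delta * (1.0 + ((config.T - t) / 50.0) ** 2) + sine
    else:  # step
        vals = np.where(t <= config.T0, 1.0 + config.delta, 1.0)
    return LambdaPath(vals)


def simulate_errors(
    n: int, T: int, sigma: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) idiosyncratic shocks, eps_it = rho*eps_{i,t-1} + N(0, sigma).

    Initialized at the stationary distribution N(0, sigma^2/(1-rho^2)) and
    independent across units.  Returns an (n, T) matrix.
    """
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if not abs(rho) < 1:
        raise ConfigError(f"|rho| must be < 1 (nonstationary AR(1)); got {rho}")
    eps = np.empty((n, T))
    if sigma == 0:
        eps.fill(0.0)
        return eps
    eps[:, 0] = rng.normal(0.0, sigma / np.sqrt(1.0 - rho**2), size=n)
    innov = rng.normal(0.0, sigma, size=(n, T - 1))
    for t in range(1, T):
        eps[:, t] = rho * eps[:, t - 1] + innov[:, t - 1]
    return eps


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_panel(
    config: ScenarioConfig, rng=None
) -> tuple[PanelDataset, DgpDraw]:
    """Draw one balanced panel from the Monte Carlo DGP.

    The first ``n_treated`` units form the treated group (assignment is
    deterministic; all randomness is in the draws).  Latents
    (X1 anchor, X2 anchor, mu) are jointly normal with common SD
    ``sigma_latent``, anchor-anchor correlation ``latent_corr`` and
    confounder-anchor correlation ``mu_x_corr``; treated means are
    shifted ``mu_shift_sd`` latent SDs upward per component.
    Covariates evolve as anchor + N(0, x_noise_sd) per period.  Treatment
    applies in the final period only (``T0 = T - 1``).
    """
    if rng is None:
        rng = config.seed
    rng = _as_rng(rng)
    n, T = config.n_units, config.T
    c, cm = config.latent_corr, config.mu_x_corr
    R = np.array([[1.0, c, cm], [c, 1.0, cm], [cm, cm, 1.0]])
    cov = (config.sigma_latent**2) * R
    L = np.linalg.cholesky(cov)
    latents = rng.standard_normal((n, 3)) @ L.T
    shift = config.mu_shift_sd * config.sigma_latent
    treated = np.zeros(n, dtype=bool)
    treated[: config.n_treated] = True
    latents[treated] += shift

    anchors = latents[:, :2]
    mu = latents[:, 2]
    X = anchors[:, None, :] + rng.normal(0.0, config.x_noise_sd, size=(n, T, 2))
    eps = simulate_errors(n, T, config.sigma_eps, config.rho, rng)
    lam = make_lambda(config)

    beta = np.asarray(config.beta, float)
    y = X @ beta + lam.values[None, :] * mu[:, None] + eps
    d = np.zeros((n, T))
    d[treated, config.T0:] = 1.0
    y = y + config.tau * d

    units = np.array([f"u{i + 1:03d}" for i in range(n)])
    panel = PanelDataset(
        units=units, y=y, treated=treated, T0=config.T0, X=X,
        covariate_names=("x1", "x2"),
    )
    return panel, DgpDraw(mu=mu, anchors=anchors, X=X, eps=eps, lam=lam)


def scenario_presets(name: str, T: int) -> ScenarioConfig:
    """Canonical scenario configurations.

    A: parallel trends holds (sigma_eps=10, constant lambda).
    B: parallel trends fails (delta=10, A=2, w=4).
    C/C1/C2/C3: B plus serial correlation rho = 0.7 / -0.7 / 0.4 / -0.4.
    D: B with high outcome variance (sigma_eps=50).
    E: B with a quadratic lambda trend.  F: pre/post step in lambda.
    Canonical T values are 3, 10 and 30 (final period post-treatment),
    but any T >= 2 is accepted.
    """
    name = name.upper()
    base = ScenarioConfig(T=T, sigma_eps=10.0, delta=0.0, amplitude=0.0, rho=0.0)
    b = base.replace(delta=10.0, amplitude=2.0, wavelength=4.0)
    table = {
        "A": base,
        "B": b,
        "C": b.replace(rho=0.7),
        "C1": b.replace(rho=-0.7),
        "C2": b.replace(rho=0.4),
        "C3": b.replace(rho=-0.4),
        "D": b.replace(sigma_eps=50.0),
        "E": b.replace(lambda_form="quadratic"),
        "F": b.replace(lambda_form="step"),
    }
    if name not in table:
        raise ConfigError(
            f"unknown scenario {name!r}; expected one of {', '.join(SCENARIO_NAMES)}"
        )
    return table[name]


def generate_hospital_fixture(
    n_treated: int,
    n_control: int,
    T: int,
    T0: int,
    rng=None,
    uplift: float = 0.0,
    base_rate: float = 0.6,
    mean_admissions: float = 120.0,
) -> PanelDataset:
    """Hospital-quarter proportion panel with admission-count weights.

    Outcomes are binomial fractions (e.g. proportion of admissions with
    surgery within 48 h) with unit-varying admission denominators used as
    frequency weights; covariates mimic age / male / admitted-from-home
    proportions.  ``uplift`` adds a post-period effect of that size to
    treated hospitals' underlying rate.
    """
    if min(n_treated, n_control, T, T0) <= 0 or T0 >= T:
        raise ConfigError("counts must be positive with T0 < T")
    rng = _as_rng(rng)
    n = n_treated + n_control
    treated = np.zeros(n, dtype=bool)
    treated[:n_treated] = True

    # unit-level admission scale and baseline rate (logit-normal heterogeneity)
    scale = rng.gamma(shape=6.0, scale=mean_admissions / 6.0, size=n)
    logit0 = np.log(base_rate / (1 - base_rate)) + rng.normal(0, 0.4, size=n)
    season = 0.1 * np.sin(2 * np.pi * np.arange(1, T + 1) / 4.0)
    logit = logit0[:, None] + season[None, :]
    p = 1.0 / (1.0 + np.exp(-logit))
    d = np.zeros((n, T))
    d[treated, T0:] = 1.0
    p = np.clip(p + uplift * d, 1e-6, 1 - 1e-6)

    admissions = rng.poisson(scale[:, None], size=(n, T)) + 1  # >= 1
    y = rng.binomial(admissions, p) / admissions

    age65 = np.clip(rng.normal(0.55, 0.05, size=n)[:, None]
                    + rng.normal(0, 0.02, size=(n, T)), 0, 1)
    male = np.clip(rng.normal(0.45, 0.04, size=n)[:, None]
                   + rng.normal(0, 0.02, size=(n, T)), 0, 1)
    home = np.clip(rng.normal(0.8, 0.05, size=n)[:, None]
                   + rng.normal(0, 0.02, size=(n, T)), 0, 1)
    X = np.stack([age65, male, home], axis=2)

    units = np.array([f"h{i + 1:03d}" for i in range(n)])
    return PanelDataset(
        units=units, y=y, treated=treated, T0=T0, X=X,
        weights=admissions.astype(float),
        covariate_names=("prop_age65", "prop_male", "prop_from_home"),
    )
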