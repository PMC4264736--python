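"""XCI ratio estimation from allelic ratios.

Phased route: the allelic ratios of each parental phase group are fitted to a
beta distribution by maximum likelihood (method-of-moments start), which
absorbs the over-dispersion of RNA-seq count data relative to a single
binomial; the XCI ratio is the pair of fitted means on the percentage scale,
e.g. a maternal mean of 0.65 and paternal mean of 0.35 reads as 65:35.  The
two percentages are estimated independently and need not sum to exactly 100.

Unphased route: the pooled ratios are modeled as a two-component
location-shift semiparametric mixture

    g(x) = lambda * f(x - mu1) + (1 - lambda) * f(x - mu2)

with a single unknown symmetric component density f, fitted by a stochastic
EM in the style of Bordes, Chauveau & Vandekerkhove: each sweep draws a
component label per point from the current posterior, updates the locations
and mixing weight from the labeled points, and re-estimates f by a
symmetrized kernel density on the centered residuals.  Parameter chains are
averaged after burn-in; several random starts are run and the start with the
best pseudo-likelihood is kept.  The two component means are the XCI ratio,
blind to parental origin.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats
from scipy.ndimage import gaussian_filter1d

from .datamodel import AllelicObservation, Phase

logger = logging.getLogger(__name__)


class SkewClass(str, Enum):
    COMPLETE = "complete"
    EXTREME = "extreme"
    MODERATE = "moderate"
    RANDOM = "random"


@dataclass
class BetaFit:
    alpha: float
    beta_param: float
    n: int
    loglik: float
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_param)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta_param
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))


@dataclass
class SPMixtureFit:
    component_means: tuple[float, float]  # sorted descending
    mixing_prop: float
    n_iterations: int
    converged: bool
    seed: int
    pseudo_loglik: float = float("nan")


@dataclass
class XCIEstimate:
    maternal_pct: Optional[float]
    paternal_pct: Optional[float]
    maternal_sd: Optional[float]
    paternal_sd: Optional[float]
    n_maternal: int
    n_paternal: int
    method: str  # "beta_phased" or "sp_unphased"
    skew_class: SkewClass
    seed: Optional[int] = None

    @property
    def major_pct(self) -> float:
        vals = [v for v in (self.maternal_pct, self.paternal_pct) if v is not None]
        return max(vals)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "maternal_pct": self.maternal_pct,
            "paternal_pct": self.paternal_pct,
            "maternal_sd": self.maternal_sd,
            "paternal_sd": self.paternal_sd,
            "n_maternal": self.n_maternal,
            "n_paternal": self.n_paternal,
            "skew_class": self.skew_class.value,
            "seed": self.seed,
        }


def clamp_boundary(ratios: Sequence[float], depths: Sequence[int]) -> np.ndarray:
    """Depth-aware shrinkage of boundary ratios into the open interval.

    A ratio of exactly 0 or 1 has no beta likelihood; each observation of
    depth d is clamped to [1/(2d), 1 - 1/(2d)], a half-read continuity
    correction that vanishes as depth grows.
    """
    r = np.asarray(ratios, dtype=float)
    d = np.asarray(depths, dtype=float)
    if np.any(d <= 0):
        raise ValueError("depths must be positive for boundary clamping")
    eps = 1.0 / (2.0 * d)
    return np.clip(r, eps, 1.0 - eps)


def _beta_nll_and_grad(params: np.ndarray, slog_x: float, slog_1mx: float, n: int):
    a, b = np.exp(params)
    psi_ab = special.digamma(a + b)
    nll = n * (special.betaln(a, b)) - (a - 1) * slog_x - (b - 1) * slog_1mx
    da = (n * (special.digamma(a) - psi_ab) - slog_x) * a
    db = (n * (special.digamma(b) - psi_ab) - slog_1mx) * b
    return nll, np.array([da, db])


def fit_beta(ratios: Sequence[float]) -> BetaFit:
    """Maximum-likelihood beta fit, initialized at method-of-moments.

    Values must already lie strictly inside (0, 1) (see
    :func:`clamp_boundary`).  If all values are identical the likelihood is
    unbounded; a degenerate fit anchored at the common value is returned with
    a warning.
    """
    x = np.asarray(ratios, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 ratios to fit a beta, got {len(x)}")
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("ratios must lie strictly inside (0,1); clamp boundaries first")
    m, v = float(np.mean(x)), float(np.var(x))
    if v <= 1e-12:
        warnings.warn(
            "all ratios (near-)identical: beta MLE degenerate, "
            "returning a moments-anchored point fit",
            RuntimeWarning,
            stacklevel=2,
        )
        conc = 1e6
        return BetaFit(
            alpha=m * conc, beta_param=(1 - m) * conc, n=len(x),
            loglik=float("nan"), degenerate=True,
        )
    common = max(m * (1 - m) / v - 1.0, 1e-3)
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    slog_x = float(np.sum(np.log(x)))
    slog_1mx = float(np.sum(np.log1p(-x)))
    res = optimize.minimize(
        _beta_nll_and_grad,
        x0=np.log([a0, b0]),
        args=(slog_x, slog_1mx, len(x)),
        jac=True,
        method="L-BFGS-B",
    )
    a, b = np.exp(res.x)
    return BetaFit(alpha=float(a), beta_param=float(b), n=len(x), loglik=float(-res.fun))


def _fit_phase_group(obs: Sequence[AllelicObservation]) -> BetaFit:
    raw = np.array([o.ratio for o in obs], dtype=float)
    if np.ptp(raw) < 1e-12:
        # A truly constant group (e.g. every ratio exactly 1.0 under complete
        # skew) carries no dispersion information: report the common value.
        conc = 1e6
        m = float(raw[0])
        return BetaFit(
            alpha=max(m, 1e-12) * conc, beta_param=max(1 - m, 1e-12) * conc,
            n=len(raw), loglik=float("nan"), degenerate=True,
        )
    clamped = clamp_boundary(raw, [o.depth for o in obs])
    return fit_beta(clamped)


def xci_from_phased(
    maternal_obs: Sequence[AllelicObservation],
    paternal_obs: Sequence[AllelicObservation],
) -> XCIEstimate:
    """Chromosome-wide XCI estimate from phased observations.

    Each phase group is beta-fitted separately; reported percentages are 100x
    the fitted means.  One empty group yields a one-sided estimate with a
    warning.
    """
    if not maternal_obs and not paternal_obs:
        raise ValueError("both phase groups empty")
    m_fit = _fit_phase_group(maternal_obs) if len(maternal_obs) >= 3 else None
    p_fit = _fit_phase_group(paternal_obs) if len(paternal_obs) >= 3 else None
    if m_fit is None or p_fit is None:
        warnings.warn("one phase group too small: one-sided estimate", RuntimeWarning, stacklevel=2)
    m_pct = 100.0 * m_fit.mean if m_fit else None
    p_pct = 100.0 * p_fit.mean if p_fit else None
    major = max(v for v in (m_pct, p_pct) if v is not None)
    return XCIEstimate(
        maternal_pct=m_pct,
        paternal_pct=p_pct,
        maternal_sd=100.0 * m_fit.sd if m_fit else None,
        paternal_sd=100.0 * p_fit.sd if p_fit else None,
        n_maternal=len(maternal_obs),
        n_paternal=len(paternal_obs),
        method="beta_phased",
        skew_class=classify_skew(max(major, 100.0 - major)),
    )


def _symmetric_unimodal_kde(
    residuals: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Constrained kernel estimate of the shared component density f.

    Binned Gaussian KDE, symmetrized about 0, then made unimodal at 0 by
    symmetric decreasing rearrangement (mass-preserving on the uniform grid).
    Unimodality is the identifiability constraint: with a mixing weight near
    one half, an unconstrained f could absorb the whole two-mode mixture
    shape and collapse both locations onto the pooled mean.
    """
    sym = np.concatenate([residuals, -residuals])
    lo = grid[0]
    step = grid[1] - grid[0]
    idx = np.clip(((sym - lo) / step).round().astype(int), 0, len(grid) - 1)
    hist = np.bincount(idx, minlength=len(grid)).astype(float)
    dens = gaussian_filter1d(hist, sigma=max(bandwidth / step, 1e-6), mode="constant")
    mid = len(grid) // 2  # grid is symmetric with a point at exactly 0
    right = np.sort(dens[mid:])[::-1]
    dens = np.concatenate([right[1:][::-1], right])
    dens /= max(dens.sum() * step, 1e-300)
    return dens


def _silverman(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25]))) / 1.349
    scale = min(sd, iqr) if iqr > 0 else sd
    return max(0.9 * scale * n ** (-0.2), 5e-3)


def sp_mixture_fit(
    ratios: Sequence[float],
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 600,
    burn_in: int = 150,
    bandwidth: Optional[float] = None,
    grid_size: int = 1025,
    estimate_mixing: bool = False,
) -> SPMixtureFit:
    """Stochastic-EM fit of the two-component location-shift SP mixture.

    Each start splits the data at a random quantile to initialize the
    locations; each sweep draws labels from the current posterior, updates
    the locations from the labeled points, and re-estimates f (Silverman
    bandwidth on the current residuals unless fixed).  Post-burn-in location
    chains are averaged per start and the start estimates combined by
    component-wise median, which is robust against the occasional chain that
    wanders onto the collapsed (coincident-locations) ridge when the two
    components barely separate.

    The mixing weight defaults to 1/2 and is held fixed: in allele-specific
    expression each heterozygous SNP's alt allele lies on either haplotype
    with probability one half, and the location-shift model is only weakly
    identified in lambda when the components nearly coincide.
    ``estimate_mixing=True`` re-estimates lambda each sweep instead.
    Deterministic given ``seed``.
    """
    x = np.asarray(ratios, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 ratios for the SP mixture, got {n}")
    if n < 20:
        logger.warning("sp_mixture_fit: only %d ratios; estimates may be unstable", n)
    rng = np.random.default_rng(seed)
    half_width = max(1.2, float(np.ptp(x)) + 0.2)
    grid = np.linspace(-half_width, half_width, grid_size)
    start_mu: list[np.ndarray] = []
    start_lam: list[float] = []
    n_converged = 0
    for _ in range(n_starts):
        # hard split at a random quantile initializes the locations
        cut = float(np.quantile(x, rng.uniform(0.25, 0.75)))
        z = x > cut
        if z.all() or not z.any():
            z = x > np.median(x)
        if z.all() or not z.any():  # all values identical
            z = np.zeros(n, dtype=bool)
            z[: n // 2] = True
        mu = np.array([x[z].mean(), x[~z].mean()])
        lam = float(z.mean()) if estimate_mixing else 0.5
        chain_mu, chain_lam = [], []
        for _it in range(max_iter):
            residuals = np.where(z, x - mu[0], x - mu[1])
            h = bandwidth if bandwidth is not None else _silverman(residuals)
            dens = _symmetric_unimodal_kde(residuals, grid, h)
            f1 = np.interp(x - mu[0], grid, dens)
            f2 = np.interp(x - mu[1], grid, dens)
            w1, w2 = lam * f1, (1 - lam) * f2
            total = w1 + w2
            post = np.where(total > 0, w1 / np.where(total > 0, total, 1.0), 0.5)
            z = rng.random(n) < post  # stochastic E-step
            n1 = int(z.sum())
            if 0 < n1 < n:
                mu = np.array([x[z].mean(), x[~z].mean()])
                if estimate_mixing:
                    lam = n1 / n
            else:  # empty component this sweep: keep previous parameters
                z = np.abs(x - mu[0]) < np.abs(x - mu[1])
            if chain_mu:
                # align labels to the previous sweep (labels carry no meaning,
                # but averaging a chain requires a consistent assignment;
                # sorting every sweep would bias coincident components apart)
                prev = chain_mu[-1]
                if abs(mu[0] - prev[0]) + abs(mu[1] - prev[1]) > abs(
                    mu[0] - prev[1]
                ) + abs(mu[1] - prev[0]):
                    mu = mu[::-1]
                    lam = 1.0 - lam
                    z = ~z
            chain_mu.append(mu.copy())
            chain_lam.append(lam)
        post_burn = np.array(chain_mu[burn_in:])
        lam_burn = np.array(chain_lam[burn_in:])
        mu_raw = post_burn.mean(axis=0)
        order = np.argsort(mu_raw)[::-1]
        lam_mean = float(lam_burn.mean())
        start_mu.append(mu_raw[order])
        start_lam.append(lam_mean if order[0] == 0 else 1.0 - lam_mean)
        half = len(post_burn) // 2
        drift = np.abs(
            post_burn[:half].mean(axis=0) - post_burn[half:].mean(axis=0)
        ).max()
        n_converged += drift < 0.005
    mu_hat = np.median(np.array(start_mu), axis=0)
    lam_hat = float(np.median(start_lam))
    converged = n_converged > n_starts // 2
    # pseudo-likelihood at the consensus, f re-estimated from MAP residuals
    assign = np.abs(x - mu_hat[0]) <= np.abs(x - mu_hat[1])
    residuals = np.where(assign, x - mu_hat[0], x - mu_hat[1])
    h = bandwidth if bandwidth is not None else _silverman(residuals)
    dens = _symmetric_unimodal_kde(residuals, grid, h)
    mix = lam_hat * np.interp(x - mu_hat[0], grid, dens) + (1 - lam_hat) * np.interp(
        x - mu_hat[1], grid, dens
    )
    pll = float(np.sum(np.log(np.maximum(mix, 1e-300))))
    if not converged:
        logger.warning(
            "sp_mixture_fit: location chains still drifting after %d sweeps", max_iter
        )
    return SPMixtureFit(
        component_means=(float(mu_hat[0]), float(mu_hat[1])),
        mixing_prop=lam_hat,
        n_iterations=max_iter,
        converged=converged,
        seed=seed,
        pseudo_loglik=pll,
    )


def xci_from_unphased(ratios: Sequence[float], seed: int = 0, **sp_kwargs) -> XCIEstimate:
    """XCI estimate from unphased ratios via the SP mixture.

    The two reported percentages are 100x the component means; they are not
    labeled maternal/paternal because the model is blind to allele origin
    (the larger component is stored in ``maternal_pct`` purely by the
    descending-sort reporting convention).
    """
    fit = sp_mixture_fit(ratios, seed=seed, **sp_kwargs)
    c1, c2 = fit.component_means
    return XCIEstimate(
        maternal_pct=100.0 * c1,
        paternal_pct=100.0 * c2,
        maternal_sd=None,
        paternal_sd=None,
        n_maternal=0,
        n_paternal=0,
        method="sp_unphased",
        skew_class=classify_skew(max(100.0 * c1, 100.0 - 100.0 * c1)),
        seed=seed,
    )


def classify_skew(major_pct: float) -> SkewClass:
    """Skew category by nearest named panel ratio.

    Cutoffs are midpoints between the named grid points: >= 97.5 complete,
    [87.5, 97.5) extreme, [77.5, 87.5) moderate, below that random.
    """
    if not 0.0 <= major_pct <= 100.0:
        raise ValueError(f"percentage out of range: {major_pct}")
    p = max(major_pct, 100.0 - major_pct)
    if p >= 97.5:
        return SkewClass.COMPLETE
    if p >= 87.5:
        return SkewClass.EXTREME
    if p >= 77.5:
        return SkewClass.MODERATE
    return SkewClass.RANDOM


def evaluate_concordance(
    panel: dict[float, Sequence[AllelicObservation]],
    min_depths: Sequence[int] = (10, 20, 30, 40, 50),
):
    """Observed-vs-expected Pearson correlation across a ratio panel.

    For each depth threshold, each dataset's phased observations are filtered
    and beta-fitted per phase; the maternal series is correlated against the
    expected maternal percentages and likewise for paternal.  Returns a
    DataFrame with columns (min_depth, phase, r, n_datasets).
    """
    import pandas as pd

    if len(panel) < 3:
        raise ValueError("need at least 3 panel datasets for a correlation")
    rows = []
    for min_depth in min_depths:
        series = {Phase.MATERNAL: ([], []), Phase.PATERNAL: ([], [])}
        for expected, observations in sorted(panel.items()):
            kept = [o for o in observations if o.depth >= min_depth]
            mat = [o for o in kept if o.phase is Phase.MATERNAL]
            pat = [o for o in kept if o.phase is Phase.PATERNAL]
            if len(mat) < 3 or len(pat) < 3:
                continue
            est = xci_from_phased(mat, pat)
            series[Phase.MATERNAL][0].append(100.0 * expected)
            series[Phase.MATERNAL][1].append(est.maternal_pct)
            series[Phase.PATERNAL][0].append(100.0 * (1.0 - expected))
            series[Phase.PATERNAL][1].append(est.paternal_pct)
        for phase, (exp_vals, obs_vals) in series.items():
            if len(exp_vals) < 3:
                continue
            r = float(stats.pearsonr(exp_vals, obs_vals).statistic)
            rows.append(
                {"min_depth": min_depth, "phase": phase.value, "r": r,
                 "n_datasets": len(exp_vals)}
            )
    return pd.DataFrame(rows)
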