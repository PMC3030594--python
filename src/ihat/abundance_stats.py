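"""Downstream statistics: database resampling, effective-sequence-count
normalization, quasipoisson regression and nutrient-record summarization.

Metagenomic samples differ both in sequencing depth and in average
community genome size; a gene's raw homolog count is comparable across
samples only after both are removed. The effective sequence count (ESC)
rescales each sample's size so that single-copy marker-gene frequency is
exactly constant across samples — one marker-gene's worth of sequence
per genome sampled — which is the operative requirement behind
average-genome-size normalization.

Gene counts are then modelled as quasipoisson: a Poisson log-linear mean
in the environmental covariate with log(ESC) offset, and a dispersion
parameter estimated from Pearson residuals to absorb the overdispersion
typical of such data. Nested models are compared with an analysis-of-
deviance F-test, the appropriate test under quasi-likelihood.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleAbundance",
    "GLMFit",
    "NutrientEstimate",
    "subsample_db",
    "esc_normalize",
    "fit_quasipoisson",
    "deviance_f_test",
    "estimate_nutrient",
]


@dataclass(frozen=True)
class SampleAbundance:
    """Per-sample gene counts with size and environmental metadata."""

    sample_id: str
    n_sequences: int
    gene_counts: dict[str, int] = field(default_factory=dict)
    marker_count: int = 0
    esc: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GLMFit:
    """A fitted quasipoisson regression (log link)."""

    coefficients: np.ndarray
    dispersion: float
    deviance: float
    null_deviance: float
    df_residual: int
    fitted: np.ndarray
    n_obs: int
    n_params: int
    iterations: int
    std_errors: np.ndarray | None = None  # quasi-likelihood (phi-scaled)


@dataclass(frozen=True)
class NutrientEstimate:
    site_id: str
    n_records: int
    median_value: float | None
    accepted: bool


def subsample_db(fragments, n: int, seed: int):
    """Uniform subsample of ``n`` fragments without replacement, seeded.

    Output preserves the original order restricted to the sampled set.
    """
    fragments = list(fragments)
    if n > len(fragments):
        raise ValueError(f"cannot sample {n} from {len(fragments)} fragments")
    rng = np.random.default_rng([seed, 404])
    idx = rng.choice(len(fragments), size=n, replace=False)
    return [fragments[i] for i in sorted(idx)]


def esc_normalize(samples) -> list[SampleAbundance]:
    """Set each sample's effective sequence count.

    Marker density ``m_i = marker_count_i / N_i``; the reference density is
    the median over samples; ``ESC_i = N_i * m_i / m_ref``. Afterwards
    ``marker_count_i / ESC_i`` equals ``m_ref`` for every sample exactly.
    """
    samples = list(samples)
    for s in samples:
        if s.marker_count <= 0:
            raise ValueError(f"sample {s.sample_id!r} has marker_count 0")
    density = [s.marker_count / s.n_sequences for s in samples]
    m_ref = float(np.median(density))
    return [
        replace(s, esc=s.n_sequences * d / m_ref)
        for s, d in zip(samples, density)
    ]


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _irls(y, X, offset, tol=1e-10, max_iter=100):
    mu = np.clip(y + 0.5, 0.5, None)
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    trace = [dev]
    for it in range(1, max_iter + 1):
        W = mu
        z = eta - offset + (y - mu) / mu
        WX = X * W[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        eta = X @ beta + offset
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        trace.append(new_dev)
        if abs(new_dev - dev) / (abs(new_dev) + 0.1) < tol:
            return beta, mu, new_dev, it
        dev = new_dev
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations; deviance trace: "
        f"{[round(d, 6) for d in trace[-5:]]}"
    )


def fit_quasipoisson(y, x=None, offset=None) -> GLMFit:
    """Fit a quasipoisson GLM of counts on covariate(s) with log link.

    Parameters
    ----------
    y:
        Non-negative integer counts.
    x:
        Covariate vector (1-D) or matrix (n, k); an intercept column is
        added automatically. ``None`` fits the intercept-only model.
    offset:
        Optional offset on the log scale (e.g. ``log(ESC)``).

    The mean structure is fitted by iteratively reweighted least squares
    (identical coefficients to the Poisson fit); the dispersion
    ``phi = sum((y-mu)^2/mu) / (n-p)`` from Pearson residuals rescales
    inference only.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    if not np.any(y > 0):
        raise ValueError("all-zero response; model has no information")
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    if x is None:
        X = np.ones((n, 1))
    else:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        X = np.column_stack([np.ones(n), x])
    if X.shape[0] != n or offset.shape[0] != n:
        raise ValueError("y, x and offset lengths differ")

    beta, mu, dev, iters = _irls(y, X, offset)
    p = X.shape[1]
    phi = float(np.sum((y - mu) ** 2 / mu) / (n - p))
    cov = phi * np.linalg.inv(X.T @ (X * mu[:, None]))
    std_errors = np.sqrt(np.diag(cov))
    if p == 1:
        null_dev = dev
    else:
        _, _, null_dev, _ = _irls(y, np.ones((n, 1)), offset)
    return GLMFit(
        coefficients=beta,
        dispersion=phi,
        deviance=dev,
        null_deviance=null_dev,
        df_residual=n - p,
        fitted=mu,
        n_obs=n,
        n_params=p,
        iterations=iters,
        std_errors=std_errors,
    )


def deviance_f_test(fit: GLMFit, null_fit: GLMFit) -> tuple[float, float]:
    """Analysis-of-deviance F-test between nested quasipoisson fits.

    ``F = ((D_null - D_full) / dp) / phi`` with the dispersion taken from
    the larger model; the p-value comes from F(dp, df_residual_full).
    Identical models give (0, 1).
    """
    if fit.n_obs != null_fit.n_obs:
        raise ValueError("fits are on different data")
    if null_fit.n_params > fit.n_params:
        raise ValueError("null model is not nested in the full model")
    if null_fit.deviance < fit.deviance - 1e-8:
        raise ValueError("null deviance below full deviance; models not nested")
    dp = fit.n_params - null_fit.n_params
    if dp == 0:
        return 0.0, 1.0
    F = max(0.0, (null_fit.deviance - fit.deviance) / dp / fit.dispersion)
    p = float(sps.f.sf(F, dp, fit.df_residual))
    return float(F), p


def estimate_nutrient(
    records,
    outlier_limit: float = 15000.0,
    min_records: int = 3,
) -> list[NutrientEstimate]:
    """Summarize per-site nutrient measurements.

    Values above ``outlier_limit`` (default 15000 uM = 15 mM, the extreme-
    outlier bound for phosphate) are removed; a site is accepted only when
    at least ``min_records`` measurements remain. The summary is the
    median (mean of the two middle values for even counts) — the annual
    distributions are positively skewed, so the median is used rather than
    the mean. Order-invariant.
    """
    by_site: dict[str, list[float]] = {}
    for site, value in records:
        if value < 0:
            raise ValueError(f"negative measurement at site {site!r}")
        by_site.setdefault(site, []).append(float(value))
    out = []
    for site in sorted(by_site):
        vals = [v for v in by_site[site] if v <= outlier_limit]
        accepted = len(vals) >= min_records
        median = statistics.median(sorted(vals)) if vals else None
        out.append(
            NutrientEstimate(
                site_id=site,
                n_records=len(vals),
                median_value=median,
                accepted=accepted,
            )
        )
    return out
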