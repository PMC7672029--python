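"""Kinship-corrected mixed-model association scan.

The association model per marker is

    y = X alpha + K beta + e,

with y the accession x location trait means, X the marker dosage (fixed
effect alpha), a polygenic random effect with covariance sigma_g^2 K (the
genomic relationship matrix) and residual e ~ N(0, sigma_e^2 I). Variance
components are estimated by REML on the null (no-marker) model via a single
eigendecomposition of K: with K = U S U', the rotated data have diagonal
covariance sigma_g^2 (S + delta I), delta = sigma_e^2 / sigma_g^2, and the
REML criterion is profiled over log10(delta) on a grid and refined by
bounded 1-D optimisation. Per-marker effects are then tested by generalised
least squares with delta fixed from the null fit (the standard
population-parameters-previously-determined shortcut; an exact per-marker
REML mode is available). The Wald statistic (alpha_hat / SE)^2 is referred
to a chi-square with 1 df, and family-wise significance uses a Bonferroni
correction on the effective number of independent markers M_eff:
threshold = -log10(alpha / M_eff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisConfig
from .qc import GenotypeMatrix, KinshipMatrix

logger = logging.getLogger(__name__)

LOG10_DELTA_GRID = np.arange(-5.0, 5.0 + 1e-9, 0.1)

#: median of the chi-square(1) distribution, reference for lambda_GC
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class MixedModelFit:
    """REML fit of the null polygenic model y = mu + u + e, u ~ N(0, sg2 K)."""

    loglik: float
    sigma_g2: float
    sigma_e2: float
    delta: float
    beta: np.ndarray  # fixed effects (intercept for the null model)
    n: int
    eigvals: np.ndarray
    eigvecs: np.ndarray
    accessions: list[str]

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _reml_loglik_rotated(
    log10_delta: float, yt: np.ndarray, Xt: np.ndarray, s: np.ndarray, logdet_xtx: float
) -> float:
    """Profiled REML log-likelihood at delta, in the eigenbasis of K.

    yt = U'y, Xt = U'X, s the eigenvalues of K. sigma_g^2 is profiled out.
    The -log|X'X| constant is included so the value matches a dense
    evaluation of the standard REML criterion.
    """
    delta = 10.0 ** log10_delta
    w = s + delta
    n, p = Xt.shape
    Xw = Xt / w[:, None]
    xtwx = Xt.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r / w))
    sg2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sg2) + 1.0)
        + float(np.sum(np.log(w)))
        + logdet_xtwx
        - logdet_xtx
    )


def fit_null_model(
    y: pd.Series | np.ndarray,
    K: KinshipMatrix,
    fixed_delta: Optional[float] = None,
) -> MixedModelFit:
    """REML variance components of the intercept-only polygenic model.

    ``y`` may be a Series indexed by accession id (missing values dropped,
    K subset accordingly) or an array aligned with ``K.accessions``.
    ``fixed_delta`` skips the optimisation and evaluates at the given ratio
    (used for limit checks and diagnostics).
    """
    if isinstance(y, pd.Series):
        y = y.reindex(K.accessions)
        mask = y.notna().to_numpy()
        accessions = [a for a, m in zip(K.accessions, mask) if m]
        yv = y.to_numpy(dtype=float)[mask]
        Ksub = K.subset(accessions)
    else:
        yv = np.asarray(y, dtype=float)
        mask = ~np.isnan(yv)
        accessions = [a for a, m in zip(K.accessions, mask) if m]
        yv = yv[mask]
        Ksub = K.subset(accessions)
    n = len(yv)
    if n < 10:
        raise ValueError(f"need at least 10 complete observations, got {n}")
    if np.var(yv) == 0:
        raise ValueError("phenotype has zero variance")

    s, U = np.linalg.eigh(Ksub.values)
    if s.min() < -1e-8:
        raise ValueError("kinship matrix not PSD beyond jitter")
    s = np.clip(s, 0.0, None)
    X = np.ones((n, 1))
    yt = U.T @ yv
    Xt = U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def neg(ld: float) -> float:
        return -_reml_loglik_rotated(ld, yt, Xt, s, logdet_xtx)

    if fixed_delta is not None:
        best_ld = float(np.log10(fixed_delta))
        best_ll = -neg(best_ld)
    else:
        grid_ll = np.array([-neg(ld) for ld in LOG10_DELTA_GRID])
        i = int(np.argmax(grid_ll))
        lo = LOG10_DELTA_GRID[max(i - 1, 0)]
        hi = LOG10_DELTA_GRID[min(i + 1, len(LOG10_DELTA_GRID) - 1)]
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        best_ld, best_ll = float(res.x), float(-res.fun)
        if grid_ll[i] > best_ll:  # refinement must never lose to the grid
            best_ld, best_ll = float(LOG10_DELTA_GRID[i]), float(grid_ll[i])

    delta = 10.0 ** best_ld
    w = s + delta
    Xw = Xt / w[:, None]
    xtwx = Xt.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    r = yt - Xt @ beta
    sg2 = float(np.sum(r * r / w)) / (n - X.shape[1])
    return MixedModelFit(
        loglik=best_ll,
        sigma_g2=sg2,
        sigma_e2=sg2 * delta,
        delta=delta,
        beta=beta,
        n=n,
        eigvals=s,
        eigvecs=U,
        accessions=accessions,
    )


def bonferroni_threshold(m_eff: float, alpha: float = 0.05) -> float:
    """Genome-wide -log10(p) cut-off: -log10(alpha / M_eff)."""
    if m_eff < 1:
        raise ValueError("M_eff must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / m_eff))


def association_scan(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    K: Optional[KinshipMatrix],
    config: AnalysisConfig | None = None,
    m_eff: Optional[float] = None,
    trait: str = "",
    location_id: str = "",
    exact_per_marker: bool = False,
    fixed_delta: Optional[float] = None,
) -> pd.DataFrame:
    """Per-marker mixed-model Wald scan.

    With ``K`` given, the polygenic covariance is modelled and each marker
    is tested by GLS in the eigenbasis of K at the null-model delta
    (``exact_per_marker`` re-optimises delta for every marker instead).
    With ``K=None`` the scan degrades to plain OLS, the uncorrected model
    used for the structure-correction contrast in the QQ diagnostics.

    Returns one row per marker: marker_id, scaffold, position, effect, se,
    wald, neg_log10_p, significant. Markers constant after the rotation get
    NaN statistics, are flagged unusable and never significant.
    """
    config = config or AnalysisConfig()
    if isinstance(y, pd.Series):
        y = y.reindex(g.accessions).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    yv = y[mask]
    n = int(mask.sum())
    G = g.values[mask, :]
    if np.isnan(G).any():
        raise ValueError("association_scan requires a filtered (complete) matrix")

    if K is not None:
        accessions = [a for a, m in zip(g.accessions, mask) if m]
        null = fit_null_model(
            pd.Series(yv, index=accessions), K.subset(accessions),
            fixed_delta=fixed_delta,
        )
        s, U, delta = null.eigvals, null.eigvecs, null.delta
        sqw = np.sqrt(s + delta)
        yt = (U.T @ yv) / sqw
        ones_t = (U.T @ np.ones(n)) / sqw
        Gt = (U.T @ G) / sqw[:, None]
    else:
        delta = np.nan
        yt = yv
        ones_t = np.ones(n)
        Gt = G

    if exact_per_marker and K is not None:
        effect = np.empty(g.n_markers)
        se = np.empty(g.n_markers)
        for j in range(g.n_markers):
            effect[j], se[j] = _exact_marker_fit(yv, G[:, j], null)
    else:
        # vectorised 2-column GLS via normal equations
        Saa = float(ones_t @ ones_t)
        Say = float(ones_t @ yt)
        Syy = float(yt @ yt)
        Sax = ones_t @ Gt
        Sxy = yt @ Gt
        Sxx = np.einsum("ij,ij->j", Gt, Gt)
        det = Saa * Sxx - Sax**2
        # scale-free degeneracy check: det / (Saa * Sxx) = sin^2 of the angle
        # between the marker and the intercept in the whitened space
        usable = det > 1e-10 * Saa * Sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = (Saa * Sxy - Sax * Say) / det
            intercept = (Say - Sax * effect) / Saa
            rss = Syy - intercept * Say - effect * Sxy
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / (n - 2)
            se = np.sqrt(sigma2 * Saa / det)
        effect[~usable] = np.nan
        se[~usable] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (effect / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    neg_log10_p = -np.log10(np.maximum(pvals, np.finfo(float).tiny))
    # p-values below ~1e-308 are reported at the representable limit

    if m_eff is None:
        m_eff = float(g.n_markers)
    threshold = bonferroni_threshold(m_eff, config.alpha)
    significant = np.where(np.isnan(wald), False, neg_log10_p >= threshold)

    records = pd.DataFrame(
        {
            "marker_id": g.markers["marker_id"].to_numpy(),
            "scaffold": g.markers["scaffold"].to_numpy(),
            "position": g.markers["position"].to_numpy(),
            "trait": trait,
            "location_id": location_id,
            "effect": effect,
            "se": se,
            "wald": wald,
            "neg_log10_p": neg_log10_p,
            "significant": significant,
        }
    )
    n_bad = int(np.isnan(wald).sum())
    if n_bad:
        logger.info("association_scan: %d markers unusable (constant)", n_bad)
    return records


def _exact_marker_fit(
    yv: np.ndarray, x: np.ndarray, null: MixedModelFit
) -> tuple[float, float]:
    """Re-optimise delta with the marker in the fixed effects (exact mode)."""
    n = len(yv)
    X = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(X) < 2:
        return np.nan, np.nan
    s, U = null.eigvals, null.eigvecs
    yt, Xt = U.T @ yv, U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def neg(ld: float) -> float:
        return -_reml_loglik_rotated(ld, yt, Xt, s, logdet_xtx)

    grid_ll = np.array([-neg(ld) for ld in LOG10_DELTA_GRID])
    i = int(np.argmax(grid_ll))
    lo = LOG10_DELTA_GRID[max(i - 1, 0)]
    hi = LOG10_DELTA_GRID[min(i + 1, len(LOG10_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    delta = 10.0 ** float(res.x)
    w = s + delta
    Xw = Xt / w[:, None]
    xtwx = Xt.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    r = yt - Xt @ beta
    sg2 = float(np.sum(r * r / w)) / (n - 2)
    cov = sg2 * np.linalg.inv(xtwx)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


def qq_diagnostic(
    records: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Observed vs expected p-value distribution for a random marker sample.

    Draws ``qq_sample_size`` records (seeded; all records when fewer are
    available, logged), pairs sorted observed -log10(p) with uniform
    order-statistic expectations, and summarises calibration by the genomic
    inflation factor lambda_GC (median Wald over the chi-square(1) median)
    and a Kolmogorov-Smirnov statistic of the sampled p-values against
    Uniform(0, 1).
    """
    config = config or AnalysisConfig()
    usable = records.dropna(subset=["wald"])
    k = config.qq_sample_size
    if len(usable) < k:
        logger.info(
            "qq_diagnostic: only %d records available (< %d); using all",
            len(usable), k,
        )
        sample = usable
    else:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(len(usable), size=k, replace=False)
        sample = usable.iloc[np.sort(idx)]
    m = len(sample)
    obs = np.sort(sample["neg_log10_p"].to_numpy())[::-1]
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    table = pd.DataFrame({"expected_neg_log10_p": exp, "observed_neg_log10_p": obs})

    lambda_gc = float(np.median(sample["wald"]) / CHI2_1_MEDIAN)
    pvals = np.power(10.0, -sample["neg_log10_p"].to_numpy())
    ks = stats.kstest(pvals, "uniform")
    summary = {
        "n_sampled": m,
        "lambda_gc": lambda_gc,
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
    return table, summary
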