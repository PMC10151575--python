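"""Posterior summaries of genetic parameters.

Heritability on the latent (liability) scale, conversion to the observed 0/1
scale for a given trait incidence (Dempster-Lerner), genetic-correlation
posteriors from bivariate chains, and highest-posterior-density intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOGIT_RESIDUAL_VARIANCE = math.pi**2 / 3.0
PROBIT_RESIDUAL_VARIANCE = 1.0

__all__ = [
    "HeritabilityEstimate",
    "GeneticCorrelationPosterior",
    "heritability_from_chain",
    "underlying_to_observed",
    "genetic_correlation",
    "hpd_interval",
    "residual_variance_for_link",
    "write_parameter_table",
]


def residual_variance_for_link(link: str) -> float:
    """Latent residual variance fixed by the link: 1 (probit) or pi^2/3 (logit)."""
    link = link.upper()
    if link == "PROBIT":
        return PROBIT_RESIDUAL_VARIANCE
    if link == "LOGIT":
        return LOGIT_RESIDUAL_VARIANCE
    raise ValueError(f"unknown link {link!r}")


@dataclass
class HeritabilityEstimate:
    scale: str  # UNDERLYING_LOGIT / UNDERLYING_PROBIT / OBSERVED
    mean: float
    sd: float
    hpd95: tuple[float, float]
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("heritability mean outside [0, 1]")


@dataclass
class GeneticCorrelationPosterior:
    parity_pair: tuple[int, int]
    samples: np.ndarray
    mean: float
    hpd95: tuple[float, float]
    n_dropped_degenerate: int = 0


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted samples."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need at least 2 finite samples")
    m = int(math.ceil(mass * x.size))
    m = min(max(m, 1), x.size)
    widths = x[m - 1 :] - x[: x.size - m + 1]
    j = int(np.argmin(widths))
    return (float(x[j]), float(x[j + m - 1]))


def heritability_from_chain(chain, link: str = "PROBIT") -> HeritabilityEstimate:
    """Posterior of h2 = var_a / (var_a + var_e,link) from a fitted chain.

    ``chain`` is a :class:`sowpop.sampler.PosteriorChain` (or anything exposing
    ``var_genetic`` samples).  The posterior sd is reported where REML software
    would report a standard error.
    """
    var_a = np.asarray(chain.var_genetic, dtype=float)
    if var_a.ndim != 1 or var_a.size == 0:
        raise ValueError("chain holds no univariate genetic-variance samples")
    var_e = residual_variance_for_link(link)
    h2 = var_a / (var_a + var_e)
    return HeritabilityEstimate(
        scale=f"UNDERLYING_{link.upper()}",
        mean=float(h2.mean()),
        sd=float(h2.std(ddof=1)) if h2.size > 1 else 0.0,
        hpd95=hpd_interval(h2) if h2.size > 1 else (float(h2[0]), float(h2[0])),
        n_samples=int(h2.size),
    )


def underlying_to_observed(h2_underlying: float, incidence: float) -> float:
    """Dempster-Lerner conversion of liability-scale h2 to the observed 0/1 scale.

    h2_obs = h2_u * z^2 / (p (1 - p)) with p the incidence, t the upper-p
    standard-normal quantile and z the normal density at t.  The normal
    liability is used regardless of the link the latent model was fitted with.
    """
    if not 0.0 < incidence < 1.0:
        raise ValueError("incidence must be in (0, 1)")
    if not 0.0 <= h2_underlying <= 1.0:
        raise ValueError("heritability must be in [0, 1]")
    t = stats.norm.ppf(1.0 - incidence)
    z = stats.norm.pdf(t)
    h2_obs = h2_underlying * z * z / (incidence * (1.0 - incidence))
    return float(min(max(h2_obs, 0.0), 1.0))


def genetic_correlation(chain, parity_pair: tuple[int, int] = (0, 0)) -> GeneticCorrelationPosterior:
    """Genetic-correlation posterior from a bivariate chain.

    Each saved sample provides a 2x2 genome-wide genetic covariance matrix; the
    correlation sample is the covariance divided by the product of the two
    genetic standard deviations.  Samples with either variance below 1e-12 are
    dropped and counted.
    """
    cov = np.asarray(chain.cov_genetic, dtype=float)
    if cov.ndim != 3 or cov.shape[1:] != (2, 2):
        raise ValueError("chain holds no 2x2 genetic covariance samples")
    v1, v2, c12 = cov[:, 0, 0], cov[:, 1, 1], cov[:, 0, 1]
    ok = (v1 > 1e-12) & (v2 > 1e-12)
    n_dropped = int((~ok).sum())
    if not ok.any():
        raise ValueError("all genetic covariance samples are degenerate")
    r = c12[ok] / np.sqrt(v1[ok] * v2[ok])
    r = np.clip(r, -1.0, 1.0)
    if r.size > 1:
        hpd = hpd_interval(r)
    else:
        hpd = (float(r[0]), float(r[0]))
    return GeneticCorrelationPosterior(
        parity_pair=parity_pair,
        samples=r,
        mean=float(r.mean()),
        hpd95=hpd,
        n_dropped_degenerate=n_dropped,
    )


def write_parameter_table(
    rows: Sequence[dict], path: str | Path | None = None
) -> pd.DataFrame:
    """Emit a genetic-parameter TSV: one row per estimate (h2 or r_g)."""
    df = pd.DataFrame(
        rows,
        columns=["analysis", "parity_pair", "estimate", "sd", "hpd_lower", "hpd_upper", "scale"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
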