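"""MCMC engines for binary-trait genetic analysis.

Three scikit-learn style estimators built around single-site Gibbs samplers:

* :class:`BayesMarkerThresholdModel` — univariate probit (threshold) marker
  model with Bayes-B, Bayes-C, Bayes-Cpi or Bayes-C0 priors, fitted by latent
  liability augmentation.  The latent residual variance is fixed at one, as it
  is not identifiable in threshold models.
* :class:`BivariateMarkerModel` — bivariate linear Bayes-C0 marker model
  (equivalent to GBLUP) with inverse-Wishart updates for the 2x2 marker-effect
  covariance G and residual covariance R; used for between-parity genetic
  correlations with binary phenotypes treated as 0/1 on the linear scale.
* :class:`BinaryAnimalModel` — threshold animal model with a pedigree or
  genomic relationship matrix, sampled in the eigenbasis of the relationship
  matrix.  The logit link is approximated by probit augmentation with the
  latent residual variance fixed at pi^2/3.

Conventions: genotype doses are centred by twice the allele frequency; ``pi``
is the prior probability that a marker has a *zero* effect (so Bayes-C0 is
``pi = 0``); the genome-wide genetic variance saved with each sample is the
realized variance of the marker-based genetic values across the analysed
individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from ._kernels import update_markers_bivariate, update_markers_univariate
from .genotypes import GenotypeMatrix, RelationshipMatrix
from .records import TraitDataset
from .varcomp import residual_variance_for_link

__all__ = [
    "ChainConfig",
    "MarkerModelSpec",
    "AnimalModelSpec",
    "PosteriorChain",
    "BayesMarkerThresholdModel",
    "BivariateMarkerModel",
    "BinaryAnimalModel",
    "fit_threshold_marker_model",
    "estimate_pi",
    "fit_bivariate_linear",
    "fit_binary_animal_model",
]


# ---------------------------------------------------------------------------
# Configuration types


@dataclass
class ChainConfig:
    """MCMC chain settings; defaults are the GWAS preset (50,000 / 5,000 / 100)."""

    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 100
    seed: int = 0
    pi: float | str = "estimate"

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def gwas_default(cls, seed: int = 0) -> "ChainConfig":
        return cls(50_000, 5_000, 100, seed)

    @classmethod
    def bivariate_default(cls, seed: int = 0) -> "ChainConfig":
        return cls(120_000, 20_000, 100, seed)

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class MarkerModelSpec:
    link: str = "PROBIT"  # LINEAR or PROBIT
    prior: str = "bayes_b"  # bayes_b / bayes_c / bayes_c0
    n_traits: int = 1
    include_parity: bool = False


@dataclass
class AnimalModelSpec:
    relationship: RelationshipMatrix
    link: str = "LOGIT"
    include_parity: bool = False


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples from one MCMC run."""

    effects: np.ndarray | None = None  # S x p (beta*delta) or S x p x 2
    include: np.ndarray | None = None  # S x p, 0/1
    var_genetic: np.ndarray | None = None  # S; samples used for h2
    var_genetic_realized: np.ndarray | None = None  # S; var of genetic values
    cov_genetic: np.ndarray | None = None  # S x 2 x 2 (bivariate)
    cov_residual: np.ndarray | None = None  # S x 2 x 2 (bivariate)
    var_marker: np.ndarray | None = None  # S (common marker-effect variance)
    pi: np.ndarray | None = None  # S (exclusion probability, when estimated)
    fixed: np.ndarray | None = None  # S x n_fixed
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_saved(self) -> int:
        for arr in (self.var_genetic, self.cov_genetic, self.effects):
            if arr is not None:
                return arr.shape[0]
        return 0

    @property
    def pip(self) -> np.ndarray:
        if self.include is None:
            raise ValueError("chain has no inclusion indicators")
        return self.include.mean(axis=0)

    def scalar_frame(self) -> pd.DataFrame:
        """Scalar sample series as a tidy DataFrame (one row per saved sample)."""
        data: dict[str, np.ndarray] = {}
        if self.var_genetic is not None:
            data["var_genetic"] = self.var_genetic
        if self.var_genetic_realized is not None:
            data["var_genetic_realized"] = self.var_genetic_realized
        if self.var_marker is not None:
            data["var_marker"] = self.var_marker
        if self.pi is not None:
            data["pi"] = self.pi
        if self.cov_genetic is not None:
            data["var_g1"] = self.cov_genetic[:, 0, 0]
            data["var_g2"] = self.cov_genetic[:, 1, 1]
            data["cov_g12"] = self.cov_genetic[:, 0, 1]
        if self.cov_residual is not None:
            data["var_e1"] = self.cov_residual[:, 0, 0]
            data["var_e2"] = self.cov_residual[:, 1, 1]
            data["cov_e12"] = self.cov_residual[:, 0, 1]
        return pd.DataFrame(data)

    def save(self, prefix: str | Path) -> None:
        """Persist scalar samples as TSV plus a compact binary cache (.npz)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.scalar_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        arrays = {
            k: v
            for k, v in self.__dict__.items()
            if isinstance(v, np.ndarray)
        }
        np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
        Path(prefix.with_suffix(".meta.json")).write_text(json.dumps(self.meta, default=str))

    @classmethod
    def load(cls, prefix: str | Path) -> "PosteriorChain":
        prefix = Path(prefix)
        arrays = dict(np.load(prefix.with_suffix(".npz")))
        meta = json.loads(Path(prefix.with_suffix(".meta.json")).read_text())
        return cls(**arrays, meta=meta)


# ---------------------------------------------------------------------------
# Fixed-effect machinery (flat priors on grouped categorical effects)


class _FactorSet:
    """Categorical fixed effects updated group-wise with flat priors.

    The first factor absorbs the intercept; later factors are re-anchored to a
    zero reference level after each update (the shift is moved into the first
    factor) so the confounded location cannot drift.
    """

    def __init__(self, factors: Sequence[Sequence]):
        self.index: list[np.ndarray] = []
        self.levels: list[list] = []
        self.b: list[np.ndarray] = []
        for labels in factors:
            if isinstance(labels, pd.Categorical):
                counts = labels.value_counts()
                empty = [str(lv) for lv in labels.categories if counts.get(lv, 0) == 0]
                if empty:
                    raise ValueError(f"singular fixed-effect design: empty level(s) {empty}")
                labels = list(labels)
            codes, levels = pd.factorize(np.asarray(labels, dtype=object))
            self.index.append(codes.astype(np.int64))
            self.levels.append(list(levels))
            self.b.append(np.zeros(len(levels)))
        self.counts = [
            np.bincount(idx, minlength=len(lv)).astype(float)
            for idx, lv in zip(self.index, self.levels)
        ]

    @property
    def n_effects(self) -> int:
        return sum(len(b) for b in self.b)

    def eta(self, n: int) -> np.ndarray:
        out = np.zeros(n)
        for idx, b in zip(self.index, self.b):
            out += b[idx]
        return out

    def flat(self) -> np.ndarray:
        return np.concatenate(self.b) if self.b else np.zeros(0)

    def update(self, e: np.ndarray, sigma2_e: float, rng: np.random.Generator) -> None:
        """Gibbs update of every factor; ``e`` is the full residual, in place."""
        for f, (idx, b) in enumerate(zip(self.index, self.b)):
            e += b[idx]
            sums = np.bincount(idx, weights=e, minlength=b.size)
            b_new = sums / self.counts[f] + rng.standard_normal(b.size) * np.sqrt(
                sigma2_e / self.counts[f]
            )
            if f > 0:
                shift = b_new[0]
                b_new = b_new - shift
                self.b[0] += shift
            e -= b_new[idx]
            self.b[f] = b_new


def _sample_liability(
    eta: np.ndarray, y: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal liability draws: l > 0 where y = 1, l < 0 where y = 0.

    Sampled via the tail probability (inverse-CDF on the small side) so draws
    stay accurate deep in either tail; the final clip only guards against
    floating-point underflow at |eta| beyond ~37 residual sd.
    """
    u = rng.uniform(size=eta.size)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    z = np.empty_like(eta)
    up = y == 1
    # P(l > 0) = ndtr(eta/sd); draw v uniform on (0, tail mass), invert there
    v_up = np.maximum(u[up] * ndtr(eta[up] / sd), 1e-300)
    z[up] = -ndtri(v_up)
    v_dn = np.maximum(u[~up] * ndtr(-eta[~up] / sd), 1e-300)
    z[~up] = ndtri(v_dn)
    l = eta + sd * z
    return np.where(up, np.maximum(l, 1e-10), np.minimum(l, -1e-10))


def _prepare_doses(X) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    """Centred Fortran-ordered dose matrix, allele freqs and marker ids."""
    marker_ids = None
    if isinstance(X, GenotypeMatrix):
        marker_ids = list(X.map["marker"])
        X = X.impute_missing().dose_matrix()
    M = np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    freq = M.mean(axis=0) / 2.0
    Mc = np.asfortranarray(M - 2.0 * freq)
    return Mc, freq, marker_ids


def _validate_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("phenotype must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("no liability threshold identifiable: phenotype is constant")
    return y.astype(np.int64)


def _marker_prior_scale(
    freq: np.ndarray, prior_h2: float, sigma2_e: float, incl_prob: float, nu: float
) -> tuple[float, float]:
    """Prior scale for marker-effect variance from a target heritability."""
    two_pq = 2.0 * freq * (1.0 - freq)
    mean2pq = float(two_pq[two_pq > 0].mean()) if (two_pq > 0).any() else 0.5
    p_eff = max((two_pq > 0).sum() * max(incl_prob, 1e-3), 1.0)
    v_g = prior_h2 / (1.0 - prior_h2) * sigma2_e
    target = v_g / (mean2pq * p_eff)
    scale = target * (nu - 2.0) / nu  # prior mean nu*S/(nu-2) = target
    return target, scale


# ---------------------------------------------------------------------------
# Univariate threshold marker model


class BayesMarkerThresholdModel(BaseEstimator):
    """Probit threshold model with Bayesian mixture priors on marker effects.

    Parameters
    ----------
    prior : {'bayes_b', 'bayes_c', 'bayes_c0'}
        Bayes-B uses marker-specific effect variances, Bayes-C a common
        variance, Bayes-C0 includes every marker (common variance, ``pi = 0``).
    pi : float or 'estimate'
        Prior probability that a marker effect is exactly zero.  ``'estimate'``
        gives pi a uniform prior and samples it (Bayes-Cpi); ignored for
        Bayes-C0.
    n_iter, burn_in, thin, seed
        Chain settings; samples are saved post burn-in every ``thin``
        iterations and runs are exactly reproducible for a given seed.
    prior_h2 : float
        Prior guess of liability-scale heritability used to set the
        scaled-inverse-chi-square prior scale for marker-effect variances.
    nu : float
        Prior degrees of freedom of the variance priors.

    Attributes
    ----------
    chain_ : PosteriorChain
    h2_samples_, h2_mean_ : posterior of var_g / (var_g + 1)
    pip_ : per-marker posterior inclusion probabilities
    effects_mean_ : posterior mean marker effects (beta * delta)
    pi_mean_ : posterior mean exclusion probability (when estimated)
    """

    def __init__(
        self,
        prior: str = "bayes_b",
        pi: float | str = 0.98,
        n_iter: int = 50_000,
        burn_in: int = 5_000,
        thin: int = 100,
        seed: int = 0,
        prior_h2: float = 0.3,
        nu: float = 4.0,
    ):
        self.prior = prior
        self.pi = pi
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_h2 = prior_h2
        self.nu = nu

    def fit(self, X, y, hyq=None, parity=None):
        if self.prior not in ("bayes_b", "bayes_c", "bayes_c0"):
            raise ValueError(f"unknown prior {self.prior!r}")
        cfg = ChainConfig(self.n_iter, self.burn_in, self.thin, self.seed, self.pi)
        y = _validate_binary(y)
        M, freq, marker_ids = _prepare_doses(X)
        n, p = M.shape
        if y.size != n:
            raise ValueError("phenotype length does not match genotype rows")
        factors = _FactorSet(
            [f for f in (hyq, parity) if f is not None] or [np.zeros(n, dtype=int)]
        )

        rng = np.random.default_rng(self.seed)
        sigma2_e = 1.0  # probit: residual variance not identifiable, fixed to 1
        sd_e = 1.0
        bayes_b = self.prior == "bayes_b"
        estimate_pi = (self.pi == "estimate") and self.prior != "bayes_c0"
        if self.prior == "bayes_c0":
            incl_prob = 1.0
        elif estimate_pi:
            incl_prob = 0.5
        else:
            incl_prob = 1.0 - float(self.pi)
        target, scale = _marker_prior_scale(
            freq, self.prior_h2, sigma2_e, incl_prob if not estimate_pi else 0.05, self.nu
        )

        xtx = np.einsum("ij,ij->j", M, M)
        beta = np.zeros(p)
        delta = np.zeros(p, dtype=np.int64)
        sig2b = np.full(p, target)
        sigma2_b_common = target
        l = np.where(y == 1, 0.7, -0.7).astype(float)
        e = l - factors.eta(n)  # marker effects start at zero

        S = cfg.n_saved
        effects = np.zeros((S, p))
        include = np.zeros((S, p), dtype=np.uint8)
        var_g = np.zeros(S)
        var_m = np.zeros(S)
        pi_s = np.zeros(S)
        fixed = np.zeros((S, factors.n_effects))

        s = 0
        for it in range(1, cfg.n_iter + 1):
            eta = l - e
            l_new = _sample_liability(eta, y, sd_e, rng)
            e += l_new - l
            l = l_new
            factors.update(e, sigma2_e, rng)
            if not bayes_b:
                sig2b[:] = sigma2_b_common
            kseed = int(rng.integers(0, 2**31 - 1))
            k_incl, ssq = update_markers_univariate(
                M, e, beta, delta, xtx, sig2b, sigma2_e, incl_prob,
                bayes_b, self.nu, scale, kseed,
            )
            if not bayes_b:
                sigma2_b_common = (self.nu * scale + ssq) / rng.chisquare(self.nu + k_incl)
            if estimate_pi:
                pi_excl = rng.beta(p - k_incl + 1.0, k_incl + 1.0)
                incl_prob = 1.0 - pi_excl
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                g = M @ beta
                effects[s] = beta
                include[s] = delta
                var_g[s] = g.var()
                var_m[s] = sigma2_b_common if not bayes_b else float(np.mean(sig2b))
                pi_s[s] = 1.0 - incl_prob
                fixed[s] = factors.flat()
                s += 1

        self.chain_ = PosteriorChain(
            effects=effects,
            include=include,
            var_genetic=var_g,
            var_genetic_realized=var_g,
            var_marker=var_m,
            pi=pi_s if estimate_pi else None,
            fixed=fixed,
            meta={
                "model": "threshold_marker",
                "prior": self.prior,
                "link": "PROBIT",
                "config": cfg.__dict__.copy(),
                "marker_ids": marker_ids,
                "n": n,
                "p": p,
            },
        )
        self.h2_samples_ = var_g / (var_g + sigma2_e)
        self.h2_mean_ = float(self.h2_samples_.mean())
        self.pip_ = include.mean(axis=0)
        self.effects_mean_ = effects.mean(axis=0)
        self.freq_ = freq
        if estimate_pi:
            self.pi_mean_ = float(pi_s.mean())
        return self

    def predict(self, X):
        """Posterior-mean genetic value on the liability scale."""
        M, _, _ = _prepare_doses(X)
        return M @ self.effects_mean_


# ---------------------------------------------------------------------------
# Bivariate linear Bayes-C0 model


class BivariateMarkerModel(BaseEstimator):
    """Bivariate linear Bayes-C0 marker model for between-parity correlations.

    Binary phenotypes enter as 0/1 on the linear scale.  Marker effect pairs
    get a MVN(0, G) prior with a 2x2 inverse-Wishart update for G; residual
    pairs are MVN(0, R), also inverse-Wishart.  Sows observed on only one of
    the two traits are handled by sampling the missing residual from its
    conditional given R (``missing='augment'``); ``missing='complete'``
    restricts to sows observed on both traits.

    Each saved sample stores the genome-wide genetic covariance matrix,
    computed as the 2x2 covariance across individuals of the marker-based
    genetic values.
    """

    def __init__(
        self,
        n_iter: int = 120_000,
        burn_in: int = 20_000,
        thin: int = 100,
        seed: int = 0,
        prior_h2: float = 0.3,
        nu: float = 4.0,
        missing: str = "augment",
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_h2 = prior_h2
        self.nu = nu
        self.missing = missing

    def fit(self, X, Y, hyq=None):
        cfg = ChainConfig(self.n_iter, self.burn_in, self.thin, self.seed, 0.0)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be n x 2 (NaN marks a missing trait)")
        M, freq, marker_ids = _prepare_doses(X)
        n, p = M.shape
        if Y.shape[0] != n:
            raise ValueError("Y rows do not match genotype rows")
        obs = ~np.isnan(Y)
        if not (obs.any(axis=1)).all():
            raise ValueError("rows with both traits missing are not allowed")
        both = obs.all(axis=1)
        if self.missing == "complete":
            if both.sum() < 2:
                raise ValueError("fewer than 2 sows observed on both traits")
            keep = np.where(both)[0]
            M = np.asfortranarray(M[keep])
            Y, obs = Y[keep], obs[keep]
            if hyq is not None:
                hyq = tuple(np.asarray(h, dtype=object)[keep] for h in hyq)
            n = keep.size
            both = obs.all(axis=1)
        elif self.missing != "augment":
            raise ValueError(f"unknown missing mode {self.missing!r}")

        if hyq is None:
            hyq = (np.zeros(n, dtype=int), np.zeros(n, dtype=int))
        fsets = [_FactorSet([hyq[t]]) for t in range(2)]

        rng = np.random.default_rng(self.seed)
        var_y = np.array([np.nanvar(Y[:, t]) for t in range(2)])
        var_y = np.maximum(var_y, 1e-6)
        target = np.zeros(2)
        for t in range(2):
            target[t], _ = _marker_prior_scale(freq, self.prior_h2, var_y[t], 1.0, self.nu)
        S_G = np.diag(target) * (self.nu - 3.0)  # IW mean S/(nu-p-1) = target
        S_R = np.diag(var_y * (1.0 - self.prior_h2)) * (self.nu - 3.0)
        G = np.diag(target)
        R = np.diag(var_y * (1.0 - self.prior_h2))

        yw = Y.copy()
        col_means = np.array([np.nanmean(Y[:, t]) for t in range(2)])
        for t in range(2):
            yw[~obs[:, t], t] = col_means[t]
        B = np.zeros((p, 2))
        E = yw - np.column_stack([fsets[t].eta(n) for t in range(2)])
        xtx = np.einsum("ij,ij->j", M, M)

        S = cfg.n_saved
        effects = np.zeros((S, p, 2))
        cov_g = np.zeros((S, 2, 2))
        cov_r = np.zeros((S, 2, 2))
        cov_g_param = np.zeros((S, 2, 2))

        s = 0
        for it in range(1, cfg.n_iter + 1):
            # residual augmentation for single-trait sows
            for t in range(2):
                o = 1 - t
                miss = ~obs[:, t] & obs[:, o]
                if miss.any():
                    c = R[t, o] / R[o, o]
                    v = R[t, t] - c * R[t, o]
                    E[miss, t] = c * E[miss, o] + rng.standard_normal(miss.sum()) * np.sqrt(
                        max(v, 1e-12)
                    )
            # fixed effects per trait, conditional on the other trait's residual
            for t in range(2):
                o = 1 - t
                c = R[t, o] / R[o, o]
                v = max(R[t, t] - c * R[t, o], 1e-12)
                d = E[:, t] - c * E[:, o]
                fsets[t].update(d, v, rng)
                E[:, t] = d + c * E[:, o]
            Ginv = np.linalg.inv(G)
            Rinv = np.linalg.inv(R)
            kseed = int(rng.integers(0, 2**31 - 1))
            s11, s12, s22 = update_markers_bivariate(M, E, B, xtx, Ginv, Rinv, kseed)
            BtB = np.array([[s11, s12], [s12, s22]])
            G = stats.invwishart.rvs(df=self.nu + p, scale=S_G + BtB, random_state=rng)
            EtE = E.T @ E
            R = stats.invwishart.rvs(df=self.nu + n, scale=S_R + EtE, random_state=rng)
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                gv = M @ B
                effects[s] = B
                cov_g[s] = np.cov(gv.T, ddof=0)
                cov_r[s] = R
                cov_g_param[s] = G
                s += 1

        self.chain_ = PosteriorChain(
            effects=effects,
            cov_genetic=cov_g,
            cov_residual=cov_r,
            meta={
                "model": "bivariate_bayes_c0",
                "config": cfg.__dict__.copy(),
                "marker_ids": marker_ids,
                "n": n,
                "p": p,
                "cov_marker_prior_mean": target.tolist(),
            },
        )
        rg = cov_g[:, 0, 1] / np.sqrt(np.maximum(cov_g[:, 0, 0] * cov_g[:, 1, 1], 1e-24))
        self.rg_samples_ = np.clip(rg, -1.0, 1.0)
        self.rg_mean_ = float(self.rg_samples_.mean())
        self.effects_mean_ = effects.mean(axis=0)
        return self

    def predict(self, X):
        M, _, _ = _prepare_doses(X)
        return M @ self.effects_mean_


# ---------------------------------------------------------------------------
# Threshold animal model


class BinaryAnimalModel(BaseEstimator):
    """Threshold animal model with a relationship matrix (pedigree A or genomic G).

    Sampled in the eigenbasis of the stabilized relationship matrix, which
    makes the breeding-value update an exact independent block draw.  The
    latent residual variance is fixed by the link: 1 for probit, pi^2/3 for
    logit (probit augmentation on the logit scale).  Heritability samples are
    sigma2_a / (sigma2_a + sigma2_e,link).
    """

    def __init__(
        self,
        link: str = "LOGIT",
        n_iter: int = 50_000,
        burn_in: int = 5_000,
        thin: int = 100,
        seed: int = 0,
        prior_h2: float = 0.3,
        nu: float = 4.0,
        blend: float = 0.01,
    ):
        self.link = link
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_h2 = prior_h2
        self.nu = nu
        self.blend = blend

    def fit(self, X, y, hyq=None, parity=None, ids: Sequence[str] | None = None):
        """Fit with X a relationship matrix (RelationshipMatrix or n x n array)."""
        cfg = ChainConfig(self.n_iter, self.burn_in, self.thin, self.seed, 0.0)
        y = _validate_binary(y)
        n = y.size
        if isinstance(X, RelationshipMatrix):
            if ids is not None:
                missing = [s for s in ids if s not in set(X.ids)]
                if missing:
                    raise ValueError(f"ids missing from relationship matrix: {missing[:5]}")
                X = X.subset(ids)
            K = X.stabilized(self.blend)
        else:
            K = np.asarray(X, dtype=float)
            K = (1.0 - self.blend) * K + self.blend * np.eye(K.shape[0])
        if K.shape != (n, n):
            raise ValueError("relationship matrix does not match phenotype length")
        if hyq is not None:
            labels = np.asarray(hyq, dtype=object)
            uniq, counts = np.unique(labels, return_counts=True)
            # all-constant phenotype within every contemporary group is degenerate
            df = pd.DataFrame({"g": labels, "y": y})
            if (df.groupby("g")["y"].nunique() == 1).all() and len(uniq) > 1:
                raise ValueError(
                    "phenotype constant within every contemporary group; "
                    "no residual contrast to estimate from"
                )
        factors = _FactorSet(
            [f for f in (hyq, parity) if f is not None] or [np.zeros(n, dtype=int)]
        )

        sigma2_e = residual_variance_for_link(self.link)
        sd_e = float(np.sqrt(sigma2_e))
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 1e-8, None)

        rng = np.random.default_rng(self.seed)
        sigma2_a = self.prior_h2 / (1.0 - self.prior_h2) * sigma2_e
        S_a = sigma2_a * (self.nu - 2.0) / self.nu

        a = np.zeros(n)
        l = np.where(y == 1, 0.7, -0.7) * sd_e
        e = l - factors.eta(n) - a

        S = cfg.n_saved
        var_a_s = np.zeros(S)
        var_a_real = np.zeros(S)
        fixed = np.zeros((S, factors.n_effects))
        bv = np.zeros((S, n))

        s = 0
        for it in range(1, cfg.n_iter + 1):
            eta = l - e
            l_new = _sample_liability(eta, y, sd_e, rng)
            e += l_new - l
            l = l_new
            factors.update(e, sigma2_e, rng)
            # breeding values: independent draws in the eigenbasis
            r = e + a  # l - Xb
            w = U.T @ r
            v = 1.0 / (1.0 / sigma2_e + 1.0 / (d * sigma2_a))
            c = v * w / sigma2_e + rng.standard_normal(n) * np.sqrt(v)
            a_new = U @ c
            e += a - a_new
            a = a_new
            ssq = float(np.sum(c * c / d))
            sigma2_a = (self.nu * S_a + ssq) / rng.chisquare(self.nu + n)
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                var_a_s[s] = sigma2_a
                var_a_real[s] = a.var()
                fixed[s] = factors.flat()
                bv[s] = a
                s += 1

        self.chain_ = PosteriorChain(
            var_genetic=var_a_s,
            var_genetic_realized=var_a_real,
            fixed=fixed,
            meta={
                "model": "binary_animal",
                "link": self.link.upper(),
                "config": cfg.__dict__.copy(),
                "n": n,
                "sigma2_e": sigma2_e,
            },
        )
        self.h2_samples_ = var_a_s / (var_a_s + sigma2_e)
        self.h2_mean_ = float(self.h2_samples_.mean())
        self.h2_samples_realized_ = var_a_real / (var_a_real + sigma2_e)
        self.breeding_values_ = bv.mean(axis=0)
        return self

    def predict(self, X=None):
        """Posterior-mean breeding values of the fitted individuals."""
        return self.breeding_values_


# ---------------------------------------------------------------------------
# Module-level wrappers over the estimators


def _dataset_fixed_effects(dataset: TraitDataset, include_parity: bool):
    hyq = ["|".join(map(str, h)) for h in dataset.hyq]
    parity = None
    if include_parity and dataset.parity_label is not None:
        parity = [str(p) for p in dataset.parity_label]
    return hyq, parity


def fit_threshold_marker_model(
    dataset: TraitDataset,
    genotypes: GenotypeMatrix,
    spec: MarkerModelSpec | None = None,
    chain: ChainConfig | None = None,
) -> PosteriorChain:
    """Fit the probit marker-effects model to a coded trait dataset."""
    spec = spec or MarkerModelSpec()
    chain = chain or ChainConfig.gwas_default()
    sub = genotypes.subset(dataset.sow_ids)
    hyq, parity = _dataset_fixed_effects(dataset, spec.include_parity)
    model = BayesMarkerThresholdModel(
        prior=spec.prior, pi=chain.pi, n_iter=chain.n_iter,
        burn_in=chain.burn_in, thin=chain.thin, seed=chain.seed,
    ).fit(sub, np.asarray(dataset.phenotype), hyq=hyq, parity=parity)
    return model.chain_


def estimate_pi(
    dataset: TraitDataset,
    genotypes: GenotypeMatrix,
    chain: ChainConfig | None = None,
    include_parity: bool = False,
) -> tuple[float, PosteriorChain]:
    """Bayes-Cpi run returning the posterior mean exclusion probability pi."""
    chain = chain or ChainConfig.gwas_default()
    sub = genotypes.subset(dataset.sow_ids)
    hyq, parity = _dataset_fixed_effects(dataset, include_parity)
    model = BayesMarkerThresholdModel(
        prior="bayes_c", pi="estimate", n_iter=chain.n_iter,
        burn_in=chain.burn_in, thin=chain.thin, seed=chain.seed,
    ).fit(sub, np.asarray(dataset.phenotype), hyq=hyq, parity=parity)
    return model.pi_mean_, model.chain_


def fit_bivariate_linear(
    dataset_k: TraitDataset,
    dataset_l: TraitDataset,
    genotypes: GenotypeMatrix,
    chain: ChainConfig | None = None,
    missing: str = "augment",
) -> PosteriorChain:
    """Bivariate Bayes-C0 fit of two by-parity trait datasets."""
    chain = chain or ChainConfig.bivariate_default()
    ids = sorted(set(dataset_k.sow_ids) | set(dataset_l.sow_ids))
    sub = genotypes.subset(ids)
    n = len(ids)
    Y = np.full((n, 2), np.nan)
    hyq = [np.array(["none"] * n, dtype=object), np.array(["none"] * n, dtype=object)]
    for t, ds in enumerate((dataset_k, dataset_l)):
        pos = {s: i for i, s in enumerate(ids)}
        for s_id, y, h in zip(ds.sow_ids, ds.phenotype, ds.hyq):
            i = pos[s_id]
            Y[i, t] = y
            hyq[t][i] = "|".join(map(str, h))
    model = BivariateMarkerModel(
        n_iter=chain.n_iter, burn_in=chain.burn_in, thin=chain.thin,
        seed=chain.seed, missing=missing,
    ).fit(sub, Y, hyq=tuple(hyq))
    return model.chain_


def fit_binary_animal_model(
    dataset: TraitDataset,
    spec: AnimalModelSpec,
    chain: ChainConfig | None = None,
) -> PosteriorChain:
    """Threshold animal model fit on a coded trait dataset."""
    chain = chain or ChainConfig.gwas_default()
    hyq, parity = _dataset_fixed_effects(dataset, spec.include_parity)
    model = BinaryAnimalModel(
        link=spec.link, n_iter=chain.n_iter, burn_in=chain.burn_in,
        thin=chain.thin, seed=chain.seed,
    ).fit(
        spec.relationship, np.asarray(dataset.phenotype),
        hyq=hyq, parity=parity, ids=dataset.sow_ids,
    )
    return model.chain_
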