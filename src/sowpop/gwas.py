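"""Window-based GWAS summaries from marker-effect posterior chains.

For every saved MCMC sample the genetic value of each individual is split over
non-overlapping 1 Mb windows; the variance of the window genetic values across
individuals, taken as a proportion of the genome-wide genetic variance in the
same sample, gives a posterior distribution of each window's share of genetic
variance.  Summaries:

* ``pct_var_mean`` — posterior mean of the per-sample proportion, x100;
* ``WPPA`` — fraction of samples in which the window's proportion exceeds a
  threshold ``rho`` (default: 1 / total number of genome windows);
* per-SNP posterior inclusion probabilities (PIP).

Windows explaining more than 1% of the genetic variance are called
significant; by-parity confirmation aggregates windows +/- 2 Mb around an
across-parity anchor window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, WindowMap
from .sampler import PosteriorChain

__all__ = [
    "WindowResult",
    "WindowPosterior",
    "RegionSummary",
    "window_variance_posterior",
    "wppa",
    "call_significant",
    "regional_aggregate",
    "manhattan_table",
    "pip_table",
]


@dataclass
class WindowResult:
    window: tuple[str, int]  # (chromosome, Mb index)
    n_snps: int
    pct_var_mean: float
    wppa: float
    top_snp: str
    top_snp_pip: float


@dataclass
class WindowPosterior:
    """Per-window posterior proportion samples plus summary rows."""

    results: list[WindowResult]
    prop_samples: np.ndarray  # S x n_windows, per-sample variance proportions
    windows: WindowMap
    snp_pips: np.ndarray | None = None
    marker_ids: list[str] | None = None

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.window[0] for r in self.results],
                "mb_window": [r.window[1] for r in self.results],
                "n_snps": [r.n_snps for r in self.results],
                "pct_var": [r.pct_var_mean for r in self.results],
                "wppa": [r.wppa for r in self.results],
                "top_snp": [r.top_snp for r in self.results],
                "top_pip": [r.top_snp_pip for r in self.results],
            }
        )


@dataclass
class RegionSummary:
    anchor: tuple[str, int]
    flank_mb: int
    pct_var_total: float


def window_variance_posterior(
    chain: PosteriorChain,
    genotypes: GenotypeMatrix,
    windows: WindowMap,
    rho: float | None = None,
) -> WindowPosterior:
    """Posterior % of genetic variance and WPPA for every marker-bearing window.

    For each saved sample, window genetic values are the dose-weighted sums of
    that sample's (included) marker effects; the window's variance across the
    analysed individuals is divided by the genome-wide genetic variance of the
    same sample (ratio first, then averaged over samples).
    """
    if chain.effects is None or chain.effects.ndim != 2:
        raise ValueError("chain holds no univariate marker-effect samples")
    effects = chain.effects
    S, p = effects.shape
    if genotypes.n_markers != p:
        raise ValueError(
            f"marker-set mismatch: chain has {p} markers, genotypes {genotypes.n_markers}"
        )
    M = genotypes.impute_missing().dose_matrix()
    M = M - M.mean(axis=0)  # centring does not change variances
    W = len(windows.windows)
    prop = np.zeros((S, W))
    g_all = effects @ M.T  # S x n genome-wide genetic values
    var_genome = g_all.var(axis=1)
    ok = var_genome > 1e-30
    for w, key in enumerate(windows.windows):
        idx = windows.marker_indices[key]
        g_w = effects[:, idx] @ M[:, idx].T
        var_w = g_w.var(axis=1)
        prop[ok, w] = var_w[ok] / var_genome[ok]

    if rho is None:
        rho = 1.0 / windows.n_genome_windows
    if rho <= 0:
        raise ValueError("rho must be positive")
    wppa_vals = (prop > rho).mean(axis=0)
    pct = prop.mean(axis=0) * 100.0

    pips = chain.include.mean(axis=0) if chain.include is not None else None
    marker_ids = chain.meta.get("marker_ids") or list(genotypes.map["marker"])
    results = []
    for w, key in enumerate(windows.windows):
        idx = windows.marker_indices[key]
        if pips is not None:
            top_local = idx[int(np.argmax(pips[idx]))]
            top_pip = float(pips[top_local])
        else:
            top_local = idx[int(np.argmax(np.abs(effects[:, idx]).mean(axis=0)))]
            top_pip = float("nan")
        results.append(
            WindowResult(
                window=key,
                n_snps=int(idx.size),
                pct_var_mean=float(pct[w]),
                wppa=float(wppa_vals[w]),
                top_snp=str(marker_ids[top_local]),
                top_snp_pip=top_pip,
            )
        )
    return WindowPosterior(results, prop, windows, snp_pips=pips, marker_ids=marker_ids)


def wppa(posterior: WindowPosterior, rho: float | None = None) -> dict[tuple[str, int], float]:
    """Window posterior probability of association at threshold ``rho``.

    WPPA is the fraction of saved samples in which the window explains more
    than ``rho`` of the genome-wide genetic variance; ``rho`` defaults to
    1 / (total genome windows).
    """
    if rho is None:
        rho = 1.0 / posterior.windows.n_genome_windows
    if rho <= 0:
        raise ValueError("rho must be positive")
    vals = (posterior.prop_samples > rho).mean(axis=0)
    return {key: float(v) for key, v in zip(posterior.windows.windows, vals)}


def call_significant(
    results: Sequence[WindowResult] | WindowPosterior, min_pct: float = 1.0
) -> list[WindowResult]:
    """Windows explaining strictly more than ``min_pct`` % of genetic variance.

    Sorted by share descending; ties broken by genome position.
    """
    rows = list(results)
    hits = [r for r in rows if r.pct_var_mean > min_pct]
    return sorted(hits, key=lambda r: (-r.pct_var_mean, str(r.window[0]), r.window[1]))


def regional_aggregate(
    results: Sequence[WindowResult] | WindowPosterior,
    anchor: tuple[str, int],
    flank_mb: int = 2,
) -> RegionSummary:
    """Sum of window variance shares in ``[anchor - flank, anchor + flank]`` Mb.

    Flanking windows beyond chromosome ends or without markers contribute 0.
    """
    rows = list(results)
    chrom, mb = str(anchor[0]), int(anchor[1])
    known = {str(r.window[0]) for r in rows}
    if chrom not in known:
        raise ValueError(f"anchor chromosome {chrom!r} not present in results")
    total = sum(
        r.pct_var_mean
        for r in rows
        if str(r.window[0]) == chrom and abs(r.window[1] - mb) <= flank_mb
    )
    return RegionSummary(anchor=(chrom, mb), flank_mb=flank_mb, pct_var_total=float(total))


def pip_table(
    posterior: WindowPosterior, genotypes: GenotypeMatrix, path: str | Path | None = None
) -> pd.DataFrame:
    """Per-SNP posterior inclusion probabilities with map coordinates."""
    if posterior.snp_pips is None:
        raise ValueError("posterior holds no inclusion probabilities")
    df = pd.DataFrame(
        {
            "marker": posterior.marker_ids,
            "chrom": genotypes.map["chrom"].astype(str),
            "bp": genotypes.map["bp"],
            "pip": posterior.snp_pips,
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def manhattan_table(
    results: Sequence[WindowResult] | WindowPosterior, path: str | Path | None = None
) -> pd.DataFrame:
    """Per-window rows in genome order (chromosome, then Mb), for plotting."""
    rows = list(results)
    df = pd.DataFrame(
        {
            "chrom": [str(r.window[0]) for r in rows],
            "mb_window": [r.window[1] for r in rows],
            "n_snps": [r.n_snps for r in rows],
            "pct_var": [r.pct_var_mean for r in rows],
            "wppa": [r.wppa for r in rows],
            "top_snp": [r.top_snp for r in rows],
            "top_pip": [r.top_snp_pip for r in rows],
        }
    )
    def _chrom_key(c: pd.Series) -> pd.Series:
        num = pd.to_numeric(c, errors="coerce")
        return num.fillna(np.inf)

    df = (
        df.assign(_ck=_chrom_key(df["chrom"]))
        .sort_values(["_ck", "chrom", "mb_window"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
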