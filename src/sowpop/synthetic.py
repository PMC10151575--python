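"""Synthetic sow populations with known genetic architecture.

Generates SNP genotypes, pedigrees and multi-parity life-history records with
the statistical structure the downstream analyses assume: a sparse set of QTL
acting on a latent liability, parity-specific heritabilities declining with
parity, genetic correlations between parities decaying geometrically with
parity distance, herd x year x quarter contemporary-group effects, culling for
pelvic organ prolapse (POP) when the liability exceeds a parity-specific
threshold, and independent culling for other reasons calibrated so that POP
makes up roughly 10% of removals.

Every generator records its ground truth so tests can compare recovered
parameters against what was simulated.
"""

from __future__ import annotations

import datetime as _dt
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, Pedigree
from .records import RemovalReason, SowRecord

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_pop_records",
    "truth_report",
    "gene_drop_genotypes",
    "simulate_binary_trait",
    "simulate_correlated_traits",
    "simulate_gwas_scenario",
]

PARITIES = (1, 2, 3, 4, 5, 6)
MARKER_SPACING_BP = 25_000


@dataclass
class SimulationScenario:
    """Parameters of one synthetic study population.

    Defaults mirror the structure of the source population at desk scale:
    liability-scale heritabilities declining from 0.41 (parity 2) to 0.15
    (parity 6), adjacent-parity genetic correlations of 0.7, POP incidence
    rising from ~0.35% (parity 1) to ~3% of sows present, a sparse QTL
    architecture (~2% of markers), and a small fraction of sows with missing
    sire from pooled-semen inseminations.
    """

    n_sows: int = 5_000
    n_markers: int = 2_000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    n_qtl: int | None = None  # default: 2% of markers
    h2_by_parity: dict[int, float] = field(
        default_factory=lambda: {1: 0.41, 2: 0.41, 3: 0.35, 4: 0.28, 5: 0.22, 6: 0.15}
    )
    rg_adjacent: float = 0.7
    incidence_by_parity: dict[int, float] = field(
        default_factory=lambda: {1: 0.0035, 2: 0.004, 3: 0.010, 4: 0.018, 5: 0.025, 6: 0.030}
    )
    other_cull_multiplier: float = 9.0  # other-reason culling ~9x POP => POP ~10% of culls
    hyq_sd: float = 0.3
    n_herds: int = 2
    start_year: int = 2015
    n_years: int = 5
    missing_sire_frac: float = 0.02
    confounded_culling: bool = False  # other-reason culling correlated with liability
    died_frac_of_other: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_qtl is None:
            self.n_qtl = max(1, round(0.02 * self.n_markers))
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        for d in (self.h2_by_parity, self.incidence_by_parity):
            for k, v in d.items():
                if not 0.0 <= v < 1.0:
                    raise ValueError(f"probability out of range for parity {k}: {v}")


@dataclass
class GroundTruth:
    """What was simulated, for test assertions."""

    qtl_indices: np.ndarray
    qtl_markers: list[str]
    beta_by_parity: dict[int, np.ndarray]  # per-QTL allele substitution effects
    realized_h2: dict[int, float]  # var(g) / (var(g) + 1) on the liability scale
    realized_rg: pd.DataFrame  # parities x parities correlation of genetic values
    thresholds: dict[int, float]
    hyq_effects: dict[tuple[str, int, int], float]
    liabilities: pd.DataFrame  # sow_id x parity latent liabilities
    pop_parity: dict[str, int]  # sow -> parity of POP removal
    qtl_variance_share: dict[int, np.ndarray]  # parity -> per-QTL share of var(l)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genotypes


def _markov_haplotypes(
    n_hap: int, freqs: np.ndarray, chrom_starts: np.ndarray, rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov haplotypes with adjacent-allele correlation ~rho.

    Transition probabilities are chosen so that corr(x_k, x_{k+1}) = rho when
    no clipping occurs; the chain restarts at each chromosome boundary.
    """
    p = freqs.size
    H = np.zeros((n_hap, p), dtype=np.int8)
    starts = set(chrom_starts.tolist())
    for k in range(p):
        f = freqs[k]
        if k in starts:
            H[:, k] = rng.random(n_hap) < f
            continue
        f0 = freqs[k - 1]
        s = math.sqrt(f * (1.0 - f))
        p11 = f + rho * s * math.sqrt((1.0 - f0) / f0)
        p01 = f - rho * s * math.sqrt(f0 / (1.0 - f0))
        p11 = min(max(p11, 0.0), 1.0)
        p01 = min(max(p01, 0.0), 1.0)
        prob = np.where(H[:, k - 1] == 1, p11, p01)
        H[:, k] = rng.random(n_hap) < prob
    return H


def _uniform_map(
    n_markers: int, n_chromosomes: int, spacing_bp: int = MARKER_SPACING_BP
) -> pd.DataFrame:
    per = [n_markers // n_chromosomes] * n_chromosomes
    for i in range(n_markers % n_chromosomes):
        per[i] += 1
    rows = []
    for c, k in enumerate(per, start=1):
        for j in range(k):
            rows.append((f"snp{c}_{j}", str(c), j * spacing_bp))
    return pd.DataFrame(rows, columns=["marker", "chrom", "bp"])


def simulate_genotypes(scenario: SimulationScenario) -> GenotypeMatrix:
    """Unrelated genotypes: doses are sums of two Markov-chain haplotypes."""
    rng = np.random.default_rng(scenario.seed)
    marker_map = _uniform_map(scenario.n_markers, scenario.n_chromosomes)
    freqs = rng.uniform(*scenario.maf_range, size=scenario.n_markers)
    chrom_starts = np.flatnonzero(
        np.r_[True, marker_map["chrom"].to_numpy()[1:] != marker_map["chrom"].to_numpy()[:-1]]
    )
    H = _markov_haplotypes(
        2 * scenario.n_sows, freqs, chrom_starts, scenario.ld_rho, rng
    )
    doses = (H[0::2] + H[1::2]).astype(np.int8)
    ids = [f"sow{i:06d}" for i in range(scenario.n_sows)]
    return GenotypeMatrix(ids, doses, marker_map)


def gene_drop_genotypes(
    pedigree: Pedigree,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_chromosomes: int = 1,
) -> GenotypeMatrix:
    """Drop unlinked biallelic loci through a pedigree (founders in HWE)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_markers)
    order = pedigree.order
    parents = {ind: (s, d) for ind, s, d in pedigree.triplets}
    hap: dict[str, np.ndarray] = {}  # 2 x p haplotypes per individual
    for ind in order:
        sire, dam = parents.get(ind, (None, None))
        h = np.zeros((2, n_markers), dtype=np.int8)
        for slot, par in enumerate((sire, dam)):
            if par is None or par not in hap:
                h[slot] = rng.random(n_markers) < freqs
            else:
                pick = rng.integers(0, 2, size=n_markers)
                h[slot] = hap[par][pick, np.arange(n_markers)]
        hap[ind] = h
    doses = np.stack([hap[ind].sum(axis=0) for ind in order]).astype(np.int8)
    marker_map = _uniform_map(n_markers, n_chromosomes)
    return GenotypeMatrix(list(order), doses, marker_map)


# ---------------------------------------------------------------------------
# Records


def _parity_effects(
    Mq: np.ndarray, parities: Sequence[int], rg: float, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """AR(1) QTL effects across parity with *exact* adjacent correlation.

    The innovation for each parity is Gram-Schmidt orthogonalized against the
    previous effect vector in the metric induced by the (centred) QTL dose
    matrix, so the realized correlation of adjacent-parity genetic values is
    exactly ``rg`` regardless of how few QTL there are; correlations at longer
    parity distances decay approximately as ``rg ** |k-l|``.
    """
    n_qtl = Mq.shape[1]

    def ip(a: np.ndarray, b: np.ndarray) -> float:
        return float((Mq @ a) @ (Mq @ b))

    u = rng.standard_normal(n_qtl)
    out = {}
    for j, parity in enumerate(parities):
        if j > 0 and rg < 1.0:
            w = rng.standard_normal(n_qtl)
            denom = ip(u, u)
            if denom > 0:
                w = w - (ip(w, u) / denom) * u
                norm_w = ip(w, w)
                if norm_w > 0:
                    w = w * math.sqrt(denom / norm_w)
            u = rg * u + math.sqrt(1.0 - rg * rg) * w
        out[parity] = u.copy()
    return out


def simulate_pop_records(
    genotypes: GenotypeMatrix, scenario: SimulationScenario
) -> tuple[list[SowRecord], GroundTruth]:
    """Multi-parity sow records with liability-threshold POP culling.

    Per parity, the liability is ``l = g + hyq + e`` with ``e ~ N(0, 1)`` and
    the genetic value ``g`` scaled so that var(g) / (var(g) + 1) equals the
    target heritability.  A sow develops POP in the first parity where her
    liability exceeds the parity-specific threshold set from the target
    incidence among sows present; other-reason culling strikes independently
    at ``other_cull_multiplier`` times the POP incidence.  Removed sows
    generate no later records.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    n = genotypes.n_individuals
    ids = list(genotypes.ids)
    M = genotypes.impute_missing().dose_matrix()
    freq = M.mean(axis=0) / 2.0
    Mc = M - 2.0 * freq

    qtl = np.sort(rng.choice(genotypes.n_markers, scenario.n_qtl, replace=False))
    Mq = Mc[:, qtl]
    raw = _parity_effects(Mq, PARITIES, scenario.rg_adjacent, rng)
    f_q = freq[qtl]

    beta_by_parity: dict[int, np.ndarray] = {}
    g_by_parity: dict[int, np.ndarray] = {}
    realized_h2: dict[int, float] = {}
    qtl_share: dict[int, np.ndarray] = {}
    for parity in PARITIES:
        h2 = scenario.h2_by_parity.get(parity, 0.0)
        g_raw = Mq @ raw[parity]
        sd_raw = g_raw.std()
        if h2 <= 0.0 or sd_raw == 0.0:
            c = 0.0
        else:
            c = math.sqrt(h2 / (1.0 - h2)) / sd_raw
        beta = c * raw[parity]
        g = Mq @ beta
        beta_by_parity[parity] = beta
        g_by_parity[parity] = g
        realized_h2[parity] = float(g.var() / (g.var() + 1.0))
        # per-QTL share of total liability variance under HWE/LE bookkeeping
        var_qtl = 2.0 * f_q * (1.0 - f_q) * beta**2
        var_l = var_qtl.sum() + scenario.hyq_sd**2 + 1.0
        qtl_share[parity] = var_qtl / var_l

    # sow-level structure: herd, parent ids, entry date
    herd = rng.integers(0, scenario.n_herds, size=n)
    n_sires, n_dams = max(2, n // 40), max(2, n // 8)
    sire = np.array([f"sire{j:05d}" for j in rng.integers(0, n_sires, size=n)], dtype=object)
    dam = np.array([f"dam{j:05d}" for j in rng.integers(0, n_dams, size=n)], dtype=object)
    sire[rng.random(n) < scenario.missing_sire_frac] = None
    entry = np.array(
        [
            _dt.date(scenario.start_year + int(y), int(m), int(dd))
            for y, m, dd in zip(
                rng.integers(0, scenario.n_years, size=n),
                rng.integers(1, 13, size=n),
                rng.integers(1, 29, size=n),
            )
        ]
    )

    hyq_effects: dict[tuple[str, int, int], float] = {}

    def hyq_effect(farm: str, date: _dt.date) -> float:
        key = (farm, date.year, (date.month + 2) // 3)
        if key not in hyq_effects:
            # stable per-label stream (crc32, not hash(): runs must reproduce)
            label_seed = zlib.crc32(repr((scenario.seed, key)).encode()) % (2**31)
            sub = np.random.default_rng(label_seed)
            hyq_effects[key] = float(sub.normal(0.0, scenario.hyq_sd))
        return hyq_effects[key]

    present = np.ones(n, dtype=bool)
    removal_parity = np.zeros(n, dtype=int)
    removal_reason = np.array([RemovalReason.NONE] * n, dtype=object)
    liab = np.full((n, len(PARITIES)), np.nan)
    thresholds: dict[int, float] = {}
    pop_parity: dict[str, int] = {}
    warnings: list[str] = []
    insem_dates: dict[tuple[int, int], _dt.date] = {}

    for pj, parity in enumerate(PARITIES):
        inc = scenario.incidence_by_parity.get(parity, 0.0)
        g = g_by_parity[parity]
        idx = np.flatnonzero(present)
        if idx.size == 0:
            break
        if inc * idx.size < 10:
            warnings.append(
                f"parity {parity}: expected cases {inc * idx.size:.1f} < 10 at this scenario size"
            )
        h_eff = np.zeros(idx.size)
        for pos, i in enumerate(idx):
            date = entry[i] + _dt.timedelta(days=int((parity - 1) * 160 + (i * 7) % 21))
            insem_dates[(i, parity)] = date
            h_eff[pos] = hyq_effect(f"farm{herd[i]}", date)
        eps = rng.standard_normal(idx.size)
        l = g[idx] + h_eff + eps
        liab[idx, pj] = l
        # threshold calibrated on the sows actually at risk: survivors of
        # earlier parities are selected for low liability, so a marginal
        # normal-theory quantile would under-realize the target incidence
        t = float(np.quantile(l, 1.0 - inc)) if 0.0 < inc < 1.0 else np.inf
        thresholds[parity] = t
        pop = l > t
        other = rng.random(idx.size) < scenario.other_cull_multiplier * inc
        if scenario.confounded_culling:
            other = rng.random(idx.size) < (
                scenario.other_cull_multiplier * inc * np.exp(0.5 * (l - l.mean()))
            )
        for pos, i in enumerate(idx):
            if pop[pos]:
                present[i] = False
                removal_parity[i] = parity
                removal_reason[i] = RemovalReason.POP
                pop_parity[ids[i]] = parity
            elif other[pos]:
                present[i] = False
                removal_parity[i] = parity
                removal_reason[i] = RemovalReason.OTHER

    # realized genetic correlations between parities
    gmat = np.column_stack([g_by_parity[p] for p in PARITIES])
    with np.errstate(invalid="ignore"):
        rg = np.corrcoef(gmat.T)
    realized_rg = pd.DataFrame(rg, index=list(PARITIES), columns=list(PARITIES))

    records: list[SowRecord] = []
    for i, sid in enumerate(ids):
        last = removal_parity[i] if removal_parity[i] > 0 else len(PARITIES)
        for parity in PARITIES:
            if parity > last:
                break
            insem = insem_dates.get((i, parity))
            if insem is None:
                continue
            removed_here = removal_parity[i] == parity
            farrow: _dt.date | None = insem + _dt.timedelta(days=113 + (i + parity) % 4)
            removal_date = None
            reason = RemovalReason.NONE
            died = False
            if removed_here:
                reason = removal_reason[i]
                if (i + parity) % 5 < 2:  # ~40% of removed sows culled before farrowing
                    farrow = None
                    removal_date = insem + _dt.timedelta(days=80 + (i % 30))
                else:
                    removal_date = farrow + _dt.timedelta(days=5 + (i % 25))
                if reason is RemovalReason.OTHER:
                    died = (i % 100) < int(100 * scenario.died_frac_of_other)
            records.append(
                SowRecord(
                    sow_id=sid,
                    farm_id=f"farm{herd[i]}",
                    parity=parity,
                    insemination_date=insem,
                    farrowing_date=farrow,
                    removal_date=removal_date,
                    removal_parity=parity if removed_here else None,
                    removal_reason=reason,
                    total_born=int(12 + (i % 7) - (parity % 3)) if farrow else None,
                    sire_id=sire[i],
                    dam_id=dam[i],
                    died_flag=died,
                )
            )

    truth = GroundTruth(
        qtl_indices=qtl,
        qtl_markers=[str(genotypes.map["marker"].iloc[j]) for j in qtl],
        beta_by_parity=beta_by_parity,
        realized_h2=realized_h2,
        realized_rg=realized_rg,
        thresholds=thresholds,
        hyq_effects=hyq_effects,
        liabilities=pd.DataFrame(liab, index=ids, columns=list(PARITIES)),
        pop_parity=pop_parity,
        qtl_variance_share=qtl_share,
        warnings=warnings,
    )
    return records, truth


def truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Realized per-parity summary of the simulated architecture."""
    rows = []
    for parity in PARITIES:
        liab = truth.liabilities[parity]
        at_risk = liab.notna().sum()
        cases = sum(1 for p in truth.pop_parity.values() if p == parity)
        rows.append(
            {
                "parity": parity,
                "realized_h2": truth.realized_h2.get(parity, np.nan),
                "n_at_risk": int(at_risk),
                "n_pop_cases": cases,
                "pop_incidence": cases / at_risk if at_risk else np.nan,
                "threshold": truth.thresholds.get(parity, np.nan),
                "qtl_var_share_total": float(truth.qtl_variance_share[parity].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Focused single-analysis generators used in recovery tests


def simulate_binary_trait(
    n: int = 3_000,
    p: int = 1_000,
    n_qtl: int = 20,
    h2: float = 0.40,
    incidence: float = 0.5,
    n_hyq: int = 10,
    hyq_sd: float = 0.3,
    ld_rho: float = 0.0,
    seed: int = 0,
    n_chromosomes: int = 5,
):
    """Single binary trait on a probit liability with known heritability.

    Returns ``(genotypes, y, hyq_labels, truth)`` where truth holds the QTL
    indices, effects and the realized liability-scale heritability.
    """
    scen = SimulationScenario(
        n_sows=n, n_markers=p, n_chromosomes=n_chromosomes, ld_rho=ld_rho, seed=seed
    )
    geno = simulate_genotypes(scen)
    rng = np.random.default_rng(seed + 17)
    M = geno.dose_matrix()
    Mc = M - M.mean(axis=0)
    qtl = np.sort(rng.choice(p, n_qtl, replace=False))
    u = rng.standard_normal(n_qtl)
    g_raw = Mc[:, qtl] @ u
    beta = u * (math.sqrt(h2 / (1.0 - h2)) / g_raw.std()) if h2 > 0 else u * 0.0
    g = Mc[:, qtl] @ beta
    hyq = rng.integers(0, n_hyq, size=n)
    h_eff = rng.normal(0.0, hyq_sd, size=n_hyq)
    l = g + h_eff[hyq] + rng.standard_normal(n)
    t = float(np.quantile(l, 1.0 - incidence)) if 0 < incidence < 1 else 0.0
    y = (l > t).astype(int)
    truth = {
        "qtl": qtl,
        "beta": beta,
        "h2_realized": float(g.var() / (g.var() + 1.0)),
        "threshold": t,
        "liability": l,
    }
    return geno, y, [f"hyq{j}" for j in hyq], truth


def simulate_correlated_traits(
    n: int = 2_000,
    p: int = 1_000,
    n_qtl: int = 30,
    h2: float = 0.35,
    rg: float = 0.7,
    overlap: float = 0.5,
    binary: bool = True,
    incidence: float = 0.5,
    seed: int = 0,
):
    """Two traits with genetic correlation ``rg`` on partially overlapping sows.

    Trait effects share an AR(1)-style decomposition (shared + specific) so the
    genetic correlation of the two marker-effect vectors is ``rg``.  A fraction
    ``overlap`` of sows carries both phenotypes; the rest are split between the
    traits.  Returns ``(genotypes, Y, hyq_pair, truth)`` with NaN marking the
    missing trait.
    """
    n_total = int(round(n * (2.0 - overlap)))
    scen = SimulationScenario(n_sows=n_total, n_markers=p, ld_rho=0.0, seed=seed)
    geno = simulate_genotypes(scen)
    rng = np.random.default_rng(seed + 29)
    M = geno.dose_matrix()
    Mc = M - M.mean(axis=0)
    qtl = np.sort(rng.choice(p, n_qtl, replace=False))
    u1 = rng.standard_normal(n_qtl)
    # innovation orthogonalized in the genetic-value metric: realized genetic
    # correlation equals rg exactly even with few QTL
    Mq = Mc[:, qtl]

    def ip(a, b):
        return float((Mq @ a) @ (Mq @ b))

    w = rng.standard_normal(n_qtl)
    w = w - (ip(w, u1) / ip(u1, u1)) * u1
    if ip(w, w) > 0:
        w = w * math.sqrt(ip(u1, u1) / ip(w, w))
    u2 = rg * u1 + math.sqrt(max(1.0 - rg * rg, 0.0)) * w
    Y = np.full((n_total, 2), np.nan)
    g_list = []
    for t, u in enumerate((u1, u2)):
        g_raw = Mc[:, qtl] @ u
        beta = u * (math.sqrt(h2 / (1.0 - h2)) / g_raw.std()) if h2 > 0 else u * 0.0
        g = Mc[:, qtl] @ beta
        g_list.append(g)
        l = g + rng.standard_normal(n_total)
        if binary:
            thr = float(np.quantile(l, 1.0 - incidence))
            Y[:, t] = (l > thr).astype(float)
        else:
            Y[:, t] = l
    # overlap pattern: first block both, then trait-1 only, then trait-2 only
    n_both = int(round(n * overlap))
    n_only = n - n_both
    Y[n_both : n_both + n_only, 1] = np.nan
    Y[n_both + n_only :, 0] = np.nan
    hyq = (np.zeros(n_total, dtype=int), np.zeros(n_total, dtype=int))
    truth = {
        "qtl": qtl,
        "rg_effects": float(np.corrcoef(u1, u2)[0, 1]),
        "rg_genetic": float(np.corrcoef(g_list[0], g_list[1])[0, 1]),
        "h2": h2,
    }
    return geno, Y, hyq, truth


def simulate_gwas_scenario(
    n: int = 3_000,
    p: int = 1_000,
    target_window_pct: float = 2.0,
    n_background_qtl: int = 50,
    h2: float = 0.40,
    incidence: float = 0.5,
    focal_chrom_index: int = 0,
    seed: int = 0,
    n_chromosomes: int = 5,
    spacing_bp: int = 100_000,
    ld_rho: float = 0.5,
):
    """Binary trait whose architecture plants ~``target_window_pct``% of the
    genetic variance in one 1 Mb window, the rest spread over background QTL.

    The map uses a 100 kb marker spacing so the scenario spans on the order of
    a hundred 1 Mb genome windows (the marker density of a genome-wide panel),
    which is the geometry the window-based false-positive behaviour depends
    on.  Adjacent markers carry moderate LD (``ld_rho``), as on a real
    livestock panel, so neighbouring markers partially tag the focal QTL and
    their fitted variance accrues to the same window.  The focal QTL sits
    mid-window with flanking markers on both sides.  Returns
    ``(genotypes, y, hyq, truth)``; truth names the focal window and its
    realized share of the genetic variance.
    """
    scen = SimulationScenario(
        n_sows=n, n_markers=p, n_chromosomes=n_chromosomes, ld_rho=ld_rho, seed=seed
    )
    geno = simulate_genotypes(scen)
    sparse_map = _uniform_map(p, n_chromosomes, spacing_bp)
    geno = GenotypeMatrix(geno.ids, geno.counts, sparse_map)
    rng = np.random.default_rng(seed + 43)
    M = geno.dose_matrix()
    Mc = M - M.mean(axis=0)
    chroms = geno.map["chrom"].astype(str).to_numpy()
    chrom_label = str(sorted(set(chroms), key=lambda c: int(c))[focal_chrom_index])
    bp = geno.map["bp"].to_numpy()
    in_focal = (chroms == chrom_label) & (bp // 1_000_000 == 0)
    focal_members = np.flatnonzero(in_focal)
    focal_idx = int(focal_members[len(focal_members) // 2])
    candidates = np.flatnonzero(~in_focal)
    back = np.sort(rng.choice(candidates, n_background_qtl, replace=False))

    u_back = rng.standard_normal(n_background_qtl)
    g_back = Mc[:, back] @ u_back
    share = target_window_pct / 100.0
    vg_total = h2 / (1.0 - h2) if h2 > 0 else 0.0
    # scale background to (1 - share) and the focal SNP to share of vg_total
    beta_back = u_back * math.sqrt(vg_total * (1.0 - share)) / g_back.std()
    x_f = Mc[:, focal_idx]
    beta_focal = math.sqrt(vg_total * share) / x_f.std()
    g = Mc[:, back] @ beta_back + x_f * beta_focal
    l = g + rng.standard_normal(n)
    thr = float(np.quantile(l, 1.0 - incidence))
    y = (l > thr).astype(int)
    v_f = (x_f * beta_focal).var()
    truth = {
        "focal_window": (chrom_label, 0),
        "focal_marker": str(geno.map["marker"].iloc[focal_idx]),
        "focal_share_pct": float(100.0 * v_f / g.var()) if g.var() > 0 else 0.0,
        "background_qtl": back,
        "h2_realized": float(g.var() / (g.var() + 1.0)),
    }
    return geno, y, [f"hyq{j}" for j in rng.integers(0, 8, size=n)], truth
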