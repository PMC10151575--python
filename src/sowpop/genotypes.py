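"""Genotype and pedigree handling.

Allele-count (dose) matrices with a physical marker map, genomic (VanRaden
method 1) and pedigree (tabular method) relationship matrices, and assignment
of markers to non-overlapping 1 Mb windows for window-based GWAS summaries.

Coordinates are 0-based half-open internally; PLINK ``.bim`` positions
(1-based) are converted on read.  Window ``k`` on a chromosome covers base-pair
positions ``[k*1e6, (k+1)*1e6)`` and is labelled by the integer ``k`` (the "Mb
window" of the results tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "RelationshipMatrix",
    "WindowMap",
    "genomic_relationship",
    "pedigree_relationship",
    "assign_windows",
    "read_plink",
    "write_plink",
    "read_dose_csv",
    "write_dose_csv",
]

MISSING = -1  # sentinel dose before mean imputation
WINDOW_BP = 1_000_000


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele doses (0/1/2) plus a marker map.

    ``counts`` holds the dose of the counted allele; missing genotypes are the
    sentinel ``-1`` until :meth:`impute_missing` is called.  ``map`` is a
    DataFrame with columns ``marker``, ``chrom``, ``bp`` (0-based).
    """

    ids: list[str]
    counts: np.ndarray
    map: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, p = self.counts.shape
        if len(self.ids) != n:
            raise ValueError("ids length does not match genotype rows")
        if len(self.map) != p:
            raise ValueError("marker map length does not match genotype columns")
        for col in ("marker", "chrom", "bp"):
            if col not in self.map.columns:
                raise ValueError(f"marker map missing column {col!r}")
        if (np.asarray(self.map["bp"]) < 0).any():
            raise ValueError("negative marker position")
        for chrom, sub in self.map.groupby("chrom", sort=False):
            bp = np.asarray(sub["bp"])
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"marker positions not strictly increasing on chromosome {chrom}")
        if np.issubdtype(self.counts.dtype, np.integer):
            valid = np.isin(self.counts, (0, 1, 2, MISSING))
            if not valid.all():
                raise ValueError("genotype doses must be 0/1/2 or the missing sentinel -1")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.counts == MISSING).any())

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per marker, ignoring missing doses."""
        c = np.asarray(self.counts, dtype=float)
        c[c == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(c, axis=0) / 2.0

    def impute_missing(self) -> "GenotypeMatrix":
        """Replace missing doses by the per-marker mean dose (2 * frequency)."""
        if not self.has_missing:
            return self
        c = np.asarray(self.counts, dtype=float).copy()
        c[c == MISSING] = np.nan
        means = np.nanmean(c, axis=0)
        idx = np.where(np.isnan(c))
        c[idx] = means[idx[1]]
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out.ids, out.counts, out.map = list(self.ids), c, self.map
        return out

    def dose_matrix(self) -> np.ndarray:
        """Float dose matrix; raises if missing doses are still present."""
        if self.has_missing:
            raise ValueError("missing doses present; call impute_missing() first")
        return np.asarray(self.counts, dtype=float)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not genotyped: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), self.counts[rows], self.map)


@dataclass
class Pedigree:
    """Triplets (individual, sire, dam); ``None`` marks an unknown parent."""

    triplets: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        self.order = self._toposort()

    def _toposort(self) -> list[str]:
        parents = {ind: (s, d) for ind, s, d in self.triplets}
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str, chain: list[str]) -> None:
            st = state.get(node, 0)
            if st == 2:
                return
            if st == 1:
                raise ValueError(f"pedigree cycle: {' -> '.join(chain + [node])}")
            state[node] = 1
            for par in parents.get(node, (None, None)):
                if par is not None:
                    visit(par, chain + [node])
            state[node] = 2
            order.append(node)

        for ind in parents:
            visit(ind, [])
        return order


@dataclass
class RelationshipMatrix:
    ids: list[str]
    values: np.ndarray
    kind: str  # "PEDIGREE_A" or "GENOMIC_G"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids missing from relationship matrix: {missing[:5]}")
        rows = np.array([index[s] for s in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(rows, rows)], self.kind)

    def stabilized(self, blend: float = 0.01) -> np.ndarray:
        """(1-blend)*K + blend*I, guaranteeing positive definiteness."""
        n = len(self.ids)
        return (1.0 - blend) * self.values + blend * np.eye(n)

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, kind: str = "GENOMIC_G") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(s) for s in df.index], df.to_numpy(dtype=float), kind)


@dataclass
class WindowMap:
    """Partition of the marker map into non-overlapping 1 Mb windows."""

    windows: list[tuple[str, int]]  # (chromosome, Mb index), non-empty only
    marker_indices: dict[tuple[str, int], np.ndarray]
    n_genome_windows: int  # total Mb windows spanned by the map, incl. empty

    def __len__(self) -> int:
        return len(self.windows)

    def window_of(self, chrom: str, bp: int) -> tuple[str, int]:
        return (chrom, bp // WINDOW_BP)


# ---------------------------------------------------------------------------
# Relationship matrices


def genomic_relationship(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = W W' / (2 * sum_k p_k (1 - p_k)) with W the dose matrix column-centred
    by twice the observed allele frequency.  Monomorphic markers carry no
    information and are dropped.
    """
    g = genotypes.impute_missing()
    m = g.dose_matrix()
    freq = m.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.any():
        raise ValueError("no informative markers: all markers are monomorphic")
    m = m[:, poly]
    p = freq[poly]
    w = m - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    values = (w @ w.T) / denom
    return RelationshipMatrix(list(g.ids), values, kind="GENOMIC_G")


def pedigree_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix via the recursive tabular method."""
    order = pedigree.order
    idx = {ind: i for i, ind in enumerate(order)}
    parents = {ind: (s, d) for ind, s, d in pedigree.triplets}
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        sire, dam = parents.get(ind, (None, None))
        si = idx.get(sire) if sire is not None else None
        di = idx.get(dam) if dam is not None else None
        f_par = a[si, di] if si is not None and di is not None else 0.0
        a[i, i] = 1.0 + 0.5 * f_par
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * a[j, si]
            if di is not None:
                val += 0.5 * a[j, di]
            a[i, j] = a[j, i] = val
    return RelationshipMatrix(order, a, kind="PEDIGREE_A")


# ---------------------------------------------------------------------------
# Windows


def assign_windows(marker_map: pd.DataFrame) -> WindowMap:
    """Assign each marker to its non-overlapping 1 Mb window.

    Only windows containing markers are listed, but ``n_genome_windows`` counts
    every window spanned by the map (per chromosome: up to and including the
    last marker's window), which is the denominator used for the default WPPA
    threshold.
    """
    bp = np.asarray(marker_map["bp"])
    if (bp < 0).any():
        raise ValueError("negative marker position")
    win_id = bp // WINDOW_BP
    chroms = np.asarray(marker_map["chrom"]).astype(str)
    windows: list[tuple[str, int]] = []
    marker_indices: dict[tuple[str, int], np.ndarray] = {}
    n_total = 0
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        ids = np.where(mask)[0]
        w = win_id[mask]
        n_total += int(w.max()) + 1
        for k in np.unique(w):
            key = (str(chrom), int(k))
            windows.append(key)
            marker_indices[key] = ids[w == k]
    return WindowMap(windows, marker_indices, n_total)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam and CSV I/O

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit PLINK codes -> dose of the A1 (counted) allele
_BED_DECODE = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple (SNP-major bed)."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "marker", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "marker": str, "bp": int},
    )
    ids = fam["iid"].tolist()
    n, p = len(ids), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {raw[:3]!r}; not a SNP-major bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * p:
        raise ValueError(f"{prefix}.bed: unexpected size for {n} samples x {p} markers")
    body = body.reshape(p, bytes_per_snp)
    # unpack 2-bit fields, individual index advances within a byte LSB-first
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(p, bytes_per_snp * 4)[:, :n]
    lut = np.empty(4, dtype=np.int8)
    for code, dose in _BED_DECODE.items():
        lut[code] = dose
    counts = lut[codes].T  # n x p
    marker_map = pd.DataFrame(
        {"marker": bim["marker"], "chrom": bim["chrom"].astype(str), "bp": bim["bp"] - 1}
    )
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        if not np.all(np.diff(np.asarray(sub["bp"])) > 0):
            raise ValueError(f"bim positions not strictly increasing on chromosome {chrom}")
    return GenotypeMatrix(ids, counts, marker_map)


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK .bed/.bim/.fam triple (SNP-major, 1-based bim positions)."""
    prefix = Path(prefix)
    n, p = genotypes.counts.shape
    fam = pd.DataFrame(
        {"fid": genotypes.ids, "iid": genotypes.ids, "sire": 0, "dam": 0, "sex": 2, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": genotypes.map["chrom"],
            "marker": genotypes.map["marker"],
            "cm": 0,
            "bp": np.asarray(genotypes.map["bp"]) + 1,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    enc = np.empty(4, dtype=np.uint8)
    for dose, code in _BED_ENCODE.items():
        enc[dose] = code  # MISSING == -1 wraps to index 3
    codes = enc[np.asarray(genotypes.counts, dtype=np.int64)]  # n x p
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4] | (padded[:, 1::4] << 2) | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_dose_csv(dose_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """CSV dose matrix (rows = individuals, header = marker ids) + CSV map."""
    doses = pd.read_csv(dose_path, index_col=0)
    marker_map = pd.read_csv(map_path, dtype={"marker": str, "chrom": str, "bp": int})
    if list(doses.columns) != list(marker_map["marker"]):
        raise ValueError("dose matrix columns do not match marker map order")
    return GenotypeMatrix(
        [str(s) for s in doses.index], doses.to_numpy(dtype=np.int64), marker_map
    )


def write_dose_csv(genotypes: GenotypeMatrix, dose_path: str | Path, map_path: str | Path) -> None:
    pd.DataFrame(
        genotypes.counts, index=genotypes.ids, columns=genotypes.map["marker"]
    ).to_csv(dose_path, index_label="id")
    genotypes.map.to_csv(map_path, index=False)
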