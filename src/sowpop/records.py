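"""Sow life-history records: parsing, quality control and binary trait coding.

The analyses code culling for pelvic organ prolapse (POP) as a binary trait in
two ways:

* **across-parity** — one record per culled/dead sow (parities 2-6), phenotype 1
  if the removal reason was POP and 0 if the sow was removed for any other
  reason;
* **by-parity** — for each parity 2-6, one record per sow at risk in that
  parity, phenotype 1 if the sow was removed in that parity for POP and 0 if she
  was not removed or was culled for another reason.

Contemporary groups are herd x year x quarter (HYQ) of the relevant
insemination date.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RemovalReason",
    "SowRecord",
    "TraitDataset",
    "QCReport",
    "read_records_csv",
    "write_records_csv",
    "qc_filter",
    "code_across_parity",
    "code_by_parity",
    "build_hyq",
    "monthly_pop_summary",
]

ANALYSIS_PARITIES = range(2, 7)  # parities 2..6 retained for analysis


class RemovalReason(str, Enum):
    POP = "POP"
    OTHER = "OTHER"
    NONE = "NONE"


@dataclass(frozen=True)
class SowRecord:
    """One sow x parity life-history row."""

    sow_id: str
    farm_id: str
    parity: int
    insemination_date: _dt.date
    farrowing_date: _dt.date | None = None
    removal_date: _dt.date | None = None
    removal_parity: int | None = None
    removal_reason: RemovalReason = RemovalReason.NONE
    total_born: int | None = None
    sire_id: str | None = None
    dam_id: str | None = None
    died_flag: bool = False

    def __post_init__(self) -> None:
        if self.parity < 1:
            raise ValueError(f"sow {self.sow_id}: parity must be >= 1")
        if (
            self.farrowing_date is not None
            and self.farrowing_date < self.insemination_date
        ):
            raise ValueError(
                f"sow {self.sow_id} parity {self.parity}: farrowing before insemination"
            )
        if (self.removal_reason is RemovalReason.NONE) != (self.removal_date is None):
            raise ValueError(
                f"sow {self.sow_id}: removal_reason must be NONE iff removal_date absent"
            )


@dataclass
class TraitDataset:
    """Binary phenotype vector plus fixed-effect labels for one analysis."""

    sow_ids: list[str]
    phenotype: list[int]
    hyq: list[tuple[str, int, int]]
    parity_label: list[int] | None
    analysis_tag: str

    def __post_init__(self) -> None:
        n = len(self.sow_ids)
        if len(self.phenotype) != n or len(self.hyq) != n:
            raise ValueError("phenotype/hyq length mismatch with sow_ids")
        if any(p not in (0, 1) for p in self.phenotype):
            raise ValueError("phenotype entries must be 0/1")
        if len(set(self.sow_ids)) != n:
            raise ValueError("duplicate sow ids within one TraitDataset")

    def __len__(self) -> int:
        return len(self.sow_ids)

    @property
    def n_cases(self) -> int:
        return int(sum(self.phenotype))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sow_id": self.sow_ids,
                "phenotype": self.phenotype,
                "hyq": ["|".join(map(str, h)) for h in self.hyq],
            }
        )
        if self.parity_label is not None:
            df["parity"] = self.parity_label
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class QCReport:
    """Counts of sows removed by each quality-control rule."""

    n_sows_in: int = 0
    n_sows_out: int = 0
    removed_missing_mortality_date: int = 0
    removed_overdue: int = 0
    removed_pedigree_inconsistent: int = 0
    n_missing_sire_retained: int = 0
    n_records_in: int = 0
    n_records_out: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# CSV I/O


_CSV_COLUMNS = [
    "sow_id",
    "farm",
    "parity",
    "insem_date",
    "farrow_date",
    "removal_date",
    "removal_parity",
    "removal_reason",
    "total_born",
    "sire",
    "dam",
    "died",
]


def _parse_date(value: object, sow_id: str, column: str) -> _dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"sow {sow_id}: cannot parse {column}={value!r} as ISO date") from exc


def read_records_csv(path: str | Path) -> list[SowRecord]:
    """Read sow x parity records from CSV (ISO-8601 dates, empty string = absent)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    records: list[SowRecord] = []
    for row in df.itertuples(index=False):
        sid = str(row.sow_id)
        records.append(
            SowRecord(
                sow_id=sid,
                farm_id=str(row.farm),
                parity=int(row.parity),
                insemination_date=_parse_date(row.insem_date, sid, "insem_date"),
                farrowing_date=_parse_date(row.farrow_date, sid, "farrow_date"),
                removal_date=_parse_date(row.removal_date, sid, "removal_date"),
                removal_parity=int(row.removal_parity) if row.removal_parity != "" else None,
                removal_reason=RemovalReason(row.removal_reason or "NONE"),
                total_born=int(row.total_born) if row.total_born != "" else None,
                sire_id=str(row.sire) if row.sire != "" else None,
                dam_id=str(row.dam) if row.dam != "" else None,
                died_flag=str(row.died).strip() in ("1", "true", "True"),
            )
        )
    _check_unique(records)
    return records


def write_records_csv(records: Sequence[SowRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sow_id": r.sow_id,
                "farm": r.farm_id,
                "parity": r.parity,
                "insem_date": r.insemination_date.isoformat(),
                "farrow_date": r.farrowing_date.isoformat() if r.farrowing_date else "",
                "removal_date": r.removal_date.isoformat() if r.removal_date else "",
                "removal_parity": r.removal_parity if r.removal_parity is not None else "",
                "removal_reason": r.removal_reason.value,
                "total_born": r.total_born if r.total_born is not None else "",
                "sire": r.sire_id or "",
                "dam": r.dam_id or "",
                "died": int(r.died_flag),
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _check_unique(records: Iterable[SowRecord]) -> None:
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.sow_id, r.parity)
        if key in seen:
            raise ValueError(f"duplicate record for sow {r.sow_id} parity {r.parity}")
        seen.add(key)


# ---------------------------------------------------------------------------
# Quality control

MAX_GESTATION_DAYS = 116  # sows farrowing > 116 d after insemination are overdue


def qc_filter(
    records: Sequence[SowRecord],
    *,
    check_missing_mortality_date: bool = True,
    check_overdue: bool = True,
    check_pedigree: bool = True,
    birth_dates: Mapping[str, _dt.date] | None = None,
) -> tuple[list[SowRecord], QCReport]:
    """Remove sows failing quality control; whole sows are dropped, not rows.

    Rules (individually switchable):

    1. died but no removal date recorded (missing mortality date);
    2. any parity with insemination-to-farrowing interval > 116 days (overdue);
    3. inconsistent pedigree: a sow listed as her own sire/dam, or — when
       ``birth_dates`` are supplied — a parent born on/after the sow's birth.

    Sows with merely *missing* sire (pooled semen) are retained and counted.
    """
    _check_unique(records)
    report = QCReport(n_records_in=len(records))
    by_sow: dict[str, list[SowRecord]] = {}
    for r in records:
        by_sow.setdefault(r.sow_id, []).append(r)
    report.n_sows_in = len(by_sow)

    bad: set[str] = set()
    for sow_id, rows in by_sow.items():
        if check_missing_mortality_date and any(
            r.died_flag and r.removal_date is None for r in rows
        ):
            bad.add(sow_id)
            report.removed_missing_mortality_date += 1
            continue
        if check_overdue and any(
            r.farrowing_date is not None
            and (r.farrowing_date - r.insemination_date).days > MAX_GESTATION_DAYS
            for r in rows
        ):
            bad.add(sow_id)
            report.removed_overdue += 1
            continue
        if check_pedigree and _pedigree_inconsistent(rows, birth_dates):
            bad.add(sow_id)
            report.removed_pedigree_inconsistent += 1

    kept = [r for r in records if r.sow_id not in bad]
    kept_sows = {r.sow_id for r in kept}
    report.n_sows_out = len(kept_sows)
    report.n_records_out = len(kept)
    report.n_missing_sire_retained = sum(
        1
        for sow_id, rows in by_sow.items()
        if sow_id in kept_sows and all(r.sire_id is None for r in rows)
    )
    return kept, report


def _pedigree_inconsistent(
    rows: Sequence[SowRecord], birth_dates: Mapping[str, _dt.date] | None
) -> bool:
    for r in rows:
        if r.sire_id == r.sow_id or r.dam_id == r.sow_id:
            return True
        if birth_dates is not None and r.sow_id in birth_dates:
            own = birth_dates[r.sow_id]
            for parent in (r.sire_id, r.dam_id):
                if parent is not None and parent in birth_dates and birth_dates[parent] >= own:
                    return True
    return False


# ---------------------------------------------------------------------------
# HYQ contemporary groups


def build_hyq(
    records: Sequence[SowRecord], date_field: str = "insemination_date"
) -> list[tuple[str, int, int]]:
    """Herd x year x quarter label per record, quarter = ceil(month/3)."""
    labels = []
    for r in records:
        d = getattr(r, date_field)
        if d is None:
            raise ValueError(f"sow {r.sow_id} parity {r.parity}: {date_field} absent")
        labels.append(_hyq_of(r.farm_id, d))
    return labels


def _hyq_of(farm_id: str, date: _dt.date) -> tuple[str, int, int]:
    return (farm_id, date.year, (date.month + 2) // 3)


# ---------------------------------------------------------------------------
# Trait coding


def code_across_parity(records: Sequence[SowRecord]) -> TraitDataset:
    """Across-parity trait: culled/dead sows only, POP vs any other reason.

    One row per sow removed in parities 2-6; phenotype 1 iff the removal reason
    was POP.  HYQ comes from the insemination date of the removal parity; the
    removal parity itself is kept as a fixed-effect label.
    """
    by_sow: dict[str, list[SowRecord]] = {}
    for r in records:
        by_sow.setdefault(r.sow_id, []).append(r)

    sow_ids, phenotype, hyq, parity_label = [], [], [], []
    for sow_id, rows in sorted(by_sow.items()):
        removal = [r for r in rows if r.removal_reason is not RemovalReason.NONE]
        if not removal:
            continue
        rem = removal[0]
        rp = rem.removal_parity
        if rp is None or rp not in ANALYSIS_PARITIES:
            continue
        at_parity = [r for r in rows if r.parity == rp]
        if not at_parity:
            raise ValueError(
                f"sow {sow_id}: removed in parity {rp} but has no record for that parity"
            )
        sow_ids.append(sow_id)
        phenotype.append(1 if rem.removal_reason is RemovalReason.POP else 0)
        hyq.append(_hyq_of(at_parity[0].farm_id, at_parity[0].insemination_date))
        parity_label.append(rp)
    return TraitDataset(sow_ids, phenotype, hyq, parity_label, analysis_tag="ACROSS")


def code_by_parity(records: Sequence[SowRecord], parity: int) -> TraitDataset:
    """By-parity trait for one parity in 2..6.

    One row per sow at risk (having a record) in that parity; phenotype 1 iff
    the sow was removed in that parity for POP, 0 if she was not removed during
    that parity or was culled for another reason.  Sows removed in a later
    parity (including parities beyond 6) contribute phenotype-0 records.
    """
    if parity not in ANALYSIS_PARITIES:
        raise ValueError(f"parity must be in 2..6, got {parity}")
    by_sow: dict[str, list[SowRecord]] = {}
    for r in records:
        by_sow.setdefault(r.sow_id, []).append(r)

    sow_ids, phenotype, hyq = [], [], []
    for sow_id, rows in sorted(by_sow.items()):
        at_parity = [r for r in rows if r.parity == parity]
        if not at_parity:
            continue
        rec = at_parity[0]
        removal = [r for r in rows if r.removal_reason is not RemovalReason.NONE]
        y = 0
        if removal:
            rem = removal[0]
            if rem.removal_parity == parity and rem.removal_reason is RemovalReason.POP:
                y = 1
        sow_ids.append(sow_id)
        phenotype.append(y)
        hyq.append(_hyq_of(rec.farm_id, rec.insemination_date))
    return TraitDataset(sow_ids, phenotype, hyq, None, analysis_tag=f"PARITY_{parity}")


def monthly_pop_summary(records: Sequence[SowRecord]) -> pd.DataFrame:
    """Descriptive table: % of removals that were for POP, by removal month."""
    rows = [
        (r.removal_date.year, r.removal_date.month, r.removal_reason is RemovalReason.POP)
        for r in records
        if r.removal_reason is not RemovalReason.NONE and r.removal_date is not None
    ]
    df = pd.DataFrame(rows, columns=["year", "month", "is_pop"])
    if df.empty:
        return pd.DataFrame(columns=["year", "month", "n_removals", "pct_pop"])
    out = (
        df.groupby(["year", "month"])
        .agg(n_removals=("is_pop", "size"), pct_pop=("is_pop", lambda s: 100.0 * s.mean()))
        .reset_index()
    )
    return out
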