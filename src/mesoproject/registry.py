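"""Cancer-registry incidence and population tables.

The whole package runs off two tabular inputs of the kind a national cancer
registry publishes: incident case counts by sex, age group and calendar
period, and person-years of population at risk on the same axes.  This
module defines validated wrappers around :class:`pandas.DataFrame` for both,
plus explicit re-binning (annual data is canonical; 5-year grouping is
always an explicit operation) and crude-rate arithmetic.

Conventions
-----------
* Age intervals are closed-open ``[lower, upper)``; the top group may be
  open-ended (``"80+"``).
* A period label ``"2014-2018"`` means calendar years 2014 through 2018
  inclusive; an annual record is a period with ``start == end``.
* Crude rates default to per 100,000 person-years.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "Period",
    "BinSpec",
    "IncidenceTable",
    "PopulationTable",
    "read_incidence_table",
    "read_population_table",
    "aggregate_to_bins",
    "crude_rate",
]

_SEX_ALIASES = {
    "m": "male", "male": "male", "men": "male", "man": "male",
    "f": "female", "female": "female", "women": "female", "woman": "female",
}


def normalize_sex(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unrecognised sex label {value!r}")
    return _SEX_ALIASES[key]


@dataclass(frozen=True, order=True)
class AgeGroup:
    """Closed-open age interval ``[lower, upper)``; ``upper=None`` is open-ended."""

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError(f"age upper bound must exceed lower bound: {self}")

    @property
    def label(self) -> str:
        if self.upper is None:
            return f"{self.lower}+"
        return f"{self.lower}-{self.upper - 1}"

    @property
    def representative_age(self) -> float:
        """Scalar age used where a group must map to one age (exposure windows).

        Interval midpoint for closed groups (60-69 -> 65); open-ended groups
        use ``lower + 5`` (80+ -> 85).
        """
        if self.upper is None:
            return float(self.lower + 5)
        return (self.lower + self.upper) / 2.0

    @classmethod
    def parse(cls, text: str) -> "AgeGroup":
        s = str(text).strip().replace("–", "-")
        m = re.fullmatch(r"(\d+)\s*\+", s)
        if m:
            return cls(int(m.group(1)), None)
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", s)
        if m:
            return cls(int(m.group(1)), int(m.group(2)) + 1)
        m = re.fullmatch(r"\d+", s)
        if m:
            return cls(int(s), int(s) + 1)
        raise ValueError(f"cannot parse age group {text!r}")

    def contains(self, other: "AgeGroup") -> bool:
        if other.lower < self.lower:
            return False
        if self.upper is None:
            return True
        if other.upper is None:
            return False
        return other.upper <= self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True, order=True)
class Period:
    """Inclusive run of calendar years; ``Period(2014, 2018)`` is 2014-2018."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"period end before start: {self}")

    @property
    def label(self) -> str:
        if self.start == self.end:
            return str(self.start)
        return f"{self.start}-{self.end}"

    @property
    def n_years(self) -> int:
        return self.end - self.start + 1

    @property
    def is_annual(self) -> bool:
        return self.start == self.end

    @classmethod
    def parse(cls, text: str) -> "Period":
        s = str(text).strip().replace("–", "-")
        if re.fullmatch(r"\d+", s):
            return cls(int(s), int(s))
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", s)
        if m:
            return cls(int(m.group(1)), int(m.group(2)))
        raise ValueError(f"cannot parse period {text!r}")

    def contains(self, other: "Period") -> bool:
        return self.start <= other.start and other.end <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class BinSpec:
    """Target binning: strictly ascending break lists on both axes.

    ``age_breaks = [0, 40, 50]`` with ``open_ended_top`` gives groups
    0-39, 40-49, 50+; without it the last break closes the top group.
    ``period_breaks = [1994, 1999, 2004]`` gives periods 1994-1998 and
    1999-2003 (the final break is exclusive).
    """

    age_breaks: tuple[int, ...]
    period_breaks: tuple[int, ...]
    open_ended_top: bool = True

    def __init__(self, age_breaks: Sequence[int], period_breaks: Sequence[int],
                 open_ended_top: bool = True) -> None:
        object.__setattr__(self, "age_breaks", tuple(int(b) for b in age_breaks))
        object.__setattr__(self, "period_breaks", tuple(int(b) for b in period_breaks))
        object.__setattr__(self, "open_ended_top", bool(open_ended_top))
        for name in ("age_breaks", "period_breaks"):
            breaks = getattr(self, name)
            if len(breaks) < 2:
                raise ValueError(f"{name} needs at least two breaks")
            if any(b >= c for b, c in zip(breaks, breaks[1:])):
                raise ValueError(f"{name} must be strictly ascending: {breaks}")

    def age_bins(self) -> list[AgeGroup]:
        b = self.age_breaks
        groups = [AgeGroup(lo, hi) for lo, hi in zip(b[:-1], b[1:])]
        if self.open_ended_top:
            groups.append(AgeGroup(b[-1], None))
        return groups

    def period_bins(self) -> list[Period]:
        b = self.period_breaks
        return [Period(lo, hi - 1) for lo, hi in zip(b[:-1], b[1:])]


def _find_bin(item, bins, contains):
    for b in bins:
        if contains(b, item):
            return b
    return None


class _Table:
    """Shared validation/IO for incidence and population tables."""

    value_col: str = ""
    _integral: bool = False

    def __init__(self, data: pd.DataFrame):
        required = {"sex", "age_group", "period", self.value_col}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        df = data.loc[:, ["sex", "age_group", "period", self.value_col]].copy()
        df["sex"] = df["sex"].map(normalize_sex)
        df["age_group"] = df["age_group"].map(
            lambda a: a if isinstance(a, AgeGroup) else AgeGroup.parse(a))
        df["period"] = df["period"].map(
            lambda p: p if isinstance(p, Period) else Period.parse(p))
        vals = df[self.value_col].to_numpy()
        for i, v in enumerate(vals):
            if self._integral:
                if not float(v).is_integer() or v < 0:
                    raise ValueError(
                        f"row {i}: {self.value_col} must be a non-negative "
                        f"integer, got {v!r}")
            elif not (float(v) > 0):
                raise ValueError(
                    f"row {i}: {self.value_col} must be > 0, got {v!r}")
        df[self.value_col] = vals.astype(int) if self._integral else vals.astype(float)
        dup = df.duplicated(subset=["sex", "age_group", "period"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate key (sex={row['sex']}, age_group={row['age_group'].label}, "
                f"period={row['period'].label})")
        self._check_age_overlap(df)
        def _sort_key(col: pd.Series) -> pd.Series:
            if col.name == "age_group":
                return col.map(lambda g: g.lower)
            if col.name == "period":
                return col.map(lambda p: (p.start, p.end))
            return col
        df = df.sort_values(by=["sex", "age_group", "period"], key=_sort_key,
                            kind="mergesort").reset_index(drop=True)
        self.data = df

    @staticmethod
    def _check_age_overlap(df: pd.DataFrame) -> None:
        groups = sorted(set(df["age_group"]), key=lambda g: g.lower)
        for g, h in zip(groups, groups[1:]):
            upper = g.upper if g.upper is not None else np.inf
            if h.lower < upper:
                raise ValueError(f"overlapping age groups {g.label} and {h.label}")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sexes(self) -> list[str]:
        return sorted(self.data["sex"].unique())

    @property
    def age_groups(self) -> list[AgeGroup]:
        return sorted(set(self.data["age_group"]), key=lambda g: g.lower)

    @property
    def periods(self) -> list[Period]:
        return sorted(set(self.data["period"]))

    def total(self, sex: str | None = None, period: Period | None = None) -> float:
        df = self.data
        if sex is not None:
            df = df[df["sex"] == normalize_sex(sex)]
        if period is not None:
            df = df[df["period"] == period]
        return df[self.value_col].sum()

    def value(self, sex: str, age_group: AgeGroup, period: Period):
        df = self.data
        hit = df[(df["sex"] == normalize_sex(sex))
                 & (df["age_group"] == age_group) & (df["period"] == period)]
        if hit.empty:
            raise KeyError(f"no cell ({sex}, {age_group.label}, {period.label})")
        return hit[self.value_col].iloc[0]

    # -- binning -----------------------------------------------------------

    def aggregate(self, spec: BinSpec):
        age_bins = spec.age_bins()
        period_bins = spec.period_bins()
        rows = []
        for _, rec in self.data.iterrows():
            ab = _find_bin(rec["age_group"], age_bins, AgeGroup.contains)
            pb = _find_bin(rec["period"], period_bins, Period.contains)
            if ab is None:
                raise ValueError(
                    f"age group {rec['age_group'].label} falls outside every bin")
            if pb is None:
                raise ValueError(
                    f"period {rec['period'].label} falls outside every bin")
            rows.append((rec["sex"], ab, pb, rec[self.value_col]))
        out = (pd.DataFrame(rows, columns=["sex", "age_group", "period", self.value_col])
               .groupby(["sex", "age_group", "period"], sort=False, as_index=False)
               [self.value_col].sum())
        return type(self)(out)

    # -- IO ----------------------------------------------------------------

    @classmethod
    def read_csv(cls, path) -> "_Table":
        df = pd.read_csv(path, dtype=str)
        cols = set(df.columns)
        if {"sex", "age_group", cls.value_col} - cols:
            raise ValueError(
                f"{path}: expected columns sex, age_group, "
                f"year|period_start+period_end, {cls.value_col}; got {sorted(cols)}")
        if "year" in cols:
            period = df["year"].map(lambda y: Period(int(y), int(y)))
        elif {"period_start", "period_end"} <= cols:
            period = [Period(int(s), int(e))
                      for s, e in zip(df["period_start"], df["period_end"])]
        else:
            raise ValueError(f"{path}: need a year or period_start/period_end column")
        vals = pd.to_numeric(df[cls.value_col])
        return cls(pd.DataFrame({"sex": df["sex"], "age_group": df["age_group"],
                                 "period": period, cls.value_col: vals}))

    def to_csv(self, path) -> None:
        Path(path).write_text(self.to_csv_text())

    def to_csv_text(self) -> str:
        annual = all(p.is_annual for p in self.data["period"])
        lines = []
        if annual:
            lines.append(f"sex,age_group,year,{self.value_col}")
            for _, r in self.data.iterrows():
                lines.append(f"{r['sex']},{r['age_group'].label},"
                             f"{r['period'].start},{self._fmt(r[self.value_col])}")
        else:
            lines.append(f"sex,age_group,period_start,period_end,{self.value_col}")
            for _, r in self.data.iterrows():
                lines.append(f"{r['sex']},{r['age_group'].label},{r['period'].start},"
                             f"{r['period'].end},{self._fmt(r[self.value_col])}")
        return "\n".join(lines) + "\n"

    def _fmt(self, v) -> str:
        if self._integral:
            return str(int(v))
        f = float(v)
        return str(int(f)) if f.is_integer() else repr(f)


class IncidenceTable(_Table):
    """Incident case counts by sex × age group × period."""

    value_col = "cases"
    _integral = True

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IncidenceTable":
        return cls(pd.DataFrame(records, columns=["sex", "age_group", "period", "cases"]))


class PopulationTable(_Table):
    """Person-years at risk by sex × age group × period."""

    value_col = "person_years"
    _integral = False

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "PopulationTable":
        return cls(pd.DataFrame(records,
                                columns=["sex", "age_group", "period", "person_years"]))


def read_incidence_table(path) -> IncidenceTable:
    """Read and validate an incidence CSV (annual or binned dialect)."""
    return IncidenceTable.read_csv(path)


def read_population_table(path) -> PopulationTable:
    """Read and validate a population CSV (annual or binned dialect)."""
    return PopulationTable.read_csv(path)


def aggregate_to_bins(table: _Table, spec: BinSpec) -> _Table:
    """Re-bin a table onto ``spec``, conserving totals; out-of-bin rows error."""
    return table.aggregate(spec)


def crude_rate(cases: float, person_years: float, scale: float = 1e5) -> float:
    """Crude incidence rate, ``cases / person_years * scale``.

    The default scale of 100,000 person-years is the registry reporting
    convention for rare cancers.
    """
    if not person_years > 0:
        raise ValueError(f"person_years must be > 0, got {person_years}")
    if cases < 0:
        raise ValueError(f"cases must be >= 0, got {cases}")
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return cases / person_years * scale
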