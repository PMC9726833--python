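"""Specimen and species bristle/ecology records.

A specimen record carries per-region bristle presence (upper rictal, lorial,
lower rictal, narial, interramal), up to three longest rictal-bristle
lengths per side of the head (mm), a shape category, sex and family.  The
"rictal bristle" character is the union of the upper rictal and lorial
regions.  Specimens aggregate to species-level traits (presence by any-
specimen OR, mean of specimen mean lengths, modal non-absent shape), and the
module runs the sex-pooling tests (Mann-Whitney on length, chi-square on
shape) that justify analysing males and females together.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources as _resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecimenRecord",
    "SpeciesTraits",
    "TestResult",
    "load_vocab",
    "derive_rictal_presence",
    "specimen_mean_length",
    "species_aggregate",
    "aggregate_table",
    "combine_guilds",
    "mann_whitney",
    "chi_square",
    "read_specimen_csv",
    "write_species_csv",
    "species_frame",
]

REGIONS = ("upper_rictal", "lorial", "lower_rictal", "narial", "interramal")
SHAPES = ("Absent", "Base", "Branched", "Unbranched")
#: tie-break precedence for the species-level shape (most derived first)
SHAPE_PRECEDENCE = ("Unbranched", "Branched", "Base")
SEXES = ("male", "female", "unknown")


def load_vocab() -> dict:
    """Ecological trait vocabularies and declared reference levels."""
    with _resources.files("bristlephylo.resources").joinpath(
            "ecology_vocab.json").open() as fh:
        return json.load(fh)


def derive_rictal_presence(upper: bool, lorial: bool) -> bool:
    """Rictal bristles are present if either the upper rictal or the lorial
    region bears bristles (the two form one continuum above the gape)."""
    return bool(upper) or bool(lorial)


def specimen_mean_length(left: Sequence[float], right: Sequence[float]) -> float:
    """Mean of the (up to three per side) longest rictal-bristle lengths.

    Bristle-less specimens contribute 0.  A missing side simply drops out of
    the mean.
    """
    vals = [float(v) for v in list(left) + list(right)]
    if any(v < 0 for v in vals):
        raise ValueError("bristle lengths must be non-negative")
    if not vals:
        return 0.0
    return float(np.mean(vals))


@dataclass
class SpecimenRecord:
    species: str
    sex: str = "unknown"
    upper_rictal: bool = False
    lorial: bool = False
    lower_rictal: bool = False
    narial: bool = False
    interramal: bool = False
    lengths_left: tuple = ()
    lengths_right: tuple = ()
    shape: str = "Absent"
    family: str = ""

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if len(self.lengths_left) > 3 or len(self.lengths_right) > 3:
            raise ValueError("at most three lengths per side")
        if any(v < 0 for v in (*self.lengths_left, *self.lengths_right)):
            raise ValueError("bristle lengths must be non-negative")
        if self.rictal_presence and self.shape == "Absent":
            raise ValueError("rictal bristles present but shape is 'Absent'")
        if not self.rictal_presence and self.shape != "Absent":
            raise ValueError("rictal bristles absent but shape is not 'Absent'")

    @property
    def rictal_presence(self) -> bool:
        return derive_rictal_presence(self.upper_rictal, self.lorial)

    @property
    def mean_length(self) -> float:
        if not self.rictal_presence:
            return 0.0
        return specimen_mean_length(self.lengths_left, self.lengths_right)


@dataclass
class SpeciesTraits:
    species: str
    rictal: bool
    lower_rictal: bool
    narial: bool
    interramal: bool
    mean_length: float
    shape: str
    family: str = ""
    activity_period: str | None = None
    habitat_type: str | None = None
    diet: str | None = None
    foraging_method: str | None = None
    foraging_height: str | None = None

    def __post_init__(self):
        if (self.mean_length == 0.0) != (not self.rictal):
            raise ValueError("mean length must be 0 exactly when rictal absent")


def species_aggregate(records: Iterable[SpecimenRecord]) -> SpeciesTraits:
    """Aggregate a species' specimens to species-level traits.

    Presence per region is the OR over specimens; length is the mean of the
    specimen means (bristle-less specimens contribute 0); shape is the modal
    non-Absent category with ties broken Unbranched > Branched > Base.
    """
    records = list(records)
    if not records:
        raise ValueError("no specimen records supplied")
    sp = {r.species for r in records}
    if len(sp) != 1:
        raise ValueError(f"records span multiple species: {sorted(sp)}")
    rictal = any(r.rictal_presence for r in records)
    mean_len = float(np.mean([r.mean_length for r in records])) if rictal else 0.0
    if rictal:
        shapes = Counter(r.shape for r in records if r.shape != "Absent")
        top = max(shapes.values())
        shape = next(s for s in SHAPE_PRECEDENCE if shapes.get(s, 0) == top)
    else:
        shape = "Absent"
    return SpeciesTraits(
        species=records[0].species,
        rictal=rictal,
        lower_rictal=any(r.lower_rictal for r in records),
        narial=any(r.narial for r in records),
        interramal=any(r.interramal for r in records),
        mean_length=mean_len,
        shape=shape,
        family=records[0].family,
    )


def aggregate_table(records: Iterable[SpecimenRecord]) -> list:
    """Aggregate a mixed-species list of specimens to one SpeciesTraits each."""
    by_sp: dict[str, list] = {}
    for r in records:
        by_sp.setdefault(r.species, []).append(r)
    return [species_aggregate(v) for _, v in sorted(by_sp.items())]


def combine_guilds(primary: str, secondary: str | None = None, *,
                   vocabulary: Sequence[str] | None = None,
                   extra: Sequence[str] = ()) -> str:
    """Combine at most two guilds into one category label ("A" or "A-B").

    Used both for diet (two dietary guilds) and foraging method (two
    methods); the primary guild comes first.
    """
    if extra:
        raise ValueError("at most two guilds may be combined")
    if vocabulary is not None:
        for g in (primary, secondary):
            if g is not None and g not in vocabulary:
                raise ValueError(f"{g!r} not in declared vocabulary")
    if secondary is None:
        return primary
    return f"{primary}–{secondary}"


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    n: int
    p_value: float
    df: int | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        if self.statistic < 0:
            raise ValueError("test statistic must be non-negative")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney test in the rank-sum-minus-offset (W) convention.

    W = (mid-rank sum of x) - n_x(n_x+1)/2; two-sided p from the normal
    approximation with tie-corrected variance and continuity correction.
    When every value in both samples is identical the variance degenerates
    and p = 1 is returned with a flag.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        w = x.size * y.size / 2.0
        return TestResult("MannWhitneyW", float(w), int(pooled.size), 1.0,
                          degenerate=True)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return TestResult("MannWhitneyW", float(res.statistic),
                      int(pooled.size), float(res.pvalue))


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if tab.sum() <= 0:
        raise ValueError("empty table")
    zero_rows = np.where(tab.sum(axis=1) == 0)[0]
    zero_cols = np.where(tab.sum(axis=0) == 0)[0]
    if zero_rows.size or zero_cols.size:
        raise ValueError(
            f"degenerate margin: zero rows {zero_rows.tolist()}, "
            f"zero columns {zero_cols.tolist()}")
    r, c = tab.shape
    df = (r - 1) * (c - 1)
    if df == 0:
        raise ValueError("degenerate margin: table has no degrees of freedom")
    stat, p, df_, _ = stats.chi2_contingency(tab, correction=False)
    return TestResult("ChiSquare", float(stat), int(tab.sum()), float(p),
                      df=int(df_))


# ----------------------------------------------------------------------
# CSV interface
#
# Specimen CSV columns: species, sex, family, upper_rictal, lorial,
# lower_rictal, narial, interramal (0/1), length_l1..l3, length_r1..r3
# (blank = not measured), shape, and optionally the five ecological columns.

_LENGTH_COLS_L = ("length_l1", "length_l2", "length_l3")
_LENGTH_COLS_R = ("length_r1", "length_r2", "length_r3")


def read_specimen_csv(path) -> list:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        left = tuple(float(row[c]) for c in _LENGTH_COLS_L
                     if c in df.columns and pd.notna(row[c]))
        right = tuple(float(row[c]) for c in _LENGTH_COLS_R
                      if c in df.columns and pd.notna(row[c]))
        records.append(SpecimenRecord(
            species=str(row["species"]),
            sex=str(row.get("sex", "unknown")),
            upper_rictal=bool(row["upper_rictal"]),
            lorial=bool(row["lorial"]),
            lower_rictal=bool(row["lower_rictal"]),
            narial=bool(row["narial"]),
            interramal=bool(row["interramal"]),
            lengths_left=left,
            lengths_right=right,
            shape=str(row["shape"]),
            family=str(row.get("family", "")),
        ))
    return records


def species_frame(species: Iterable[SpeciesTraits]) -> pd.DataFrame:
    rows = []
    for s in species:
        rows.append({
            "species": s.species, "family": s.family,
            "rictal": int(s.rictal), "lower_rictal": int(s.lower_rictal),
            "narial": int(s.narial), "interramal": int(s.interramal),
            "mean_length": s.mean_length, "shape": s.shape,
            "activity_period": s.activity_period,
            "habitat_type": s.habitat_type, "diet": s.diet,
            "foraging_method": s.foraging_method,
            "foraging_height": s.foraging_height,
        })
    return pd.DataFrame(rows)


def write_species_csv(species: Iterable[SpeciesTraits], path) -> None:
    species_frame(species).to_csv(path, index=False)
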