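"""Synthetic very-preterm cohort generator.

Real MRS/DTI feature tables of very preterm infants are not publicly
deposited, so the rest of the pipeline is exercised on synthetic cohorts that
reproduce the statistical structure the analysis assumes: class-conditional
normal characteristics (per-class mean/SD defaults packaged with the module),
a rare delayed outcome, optional planted low-localisation characteristics,
and missing-metabolite-peak dropout.

A cohort is a subjects x characteristics table: one row per infant, a binary
delay label (1 = Bayley-III scale score < 85), a severe-brain-injury flag,
and up to 42 numeric characteristics — the 5 metabolite ratios NAA/Cho,
NAA/Cr, Cho/Cr, NAA/mI and mI/Cr plus MD and FA, each in the 6
supraventricular white-matter regions FWMR, FWML, CWMR, CWML, PWMR, PWML.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("NAA/Cho", "NAA/Cr", "Cho/Cr", "NAA/mI", "mI/Cr", "MD", "FA")
RATIO_MEASURES = MEASURES[:5]
REGIONS = ("FWMR", "FWML", "CWMR", "CWML", "PWMR", "PWML")

#: column-token form of each measure name ("/" is not CSV-header friendly)
_MEASURE_TOKEN = {m: m.replace("/", "_") for m in MEASURES}
_TOKEN_MEASURE = {v: k for k, v in _MEASURE_TOKEN.items()}

META_COLUMNS = ("subject_id", "label", "severe_injury")


@dataclass(frozen=True, order=True)
class CharacteristicDescriptor:
    """One measured characteristic: a (measure, region) pair.

    MD carries units 10^-3 mm^2/s; FA and all metabolite ratios are unitless.
    """

    measure: str
    region: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(
                f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        if self.region not in REGIONS:
            raise ValueError(
                f"unknown region {self.region!r}; expected one of {REGIONS}")

    @property
    def column(self) -> str:
        """CSV column name, e.g. ``NAA_Cho.CWMR`` or ``FA.FWMR``."""
        return f"{_MEASURE_TOKEN[self.measure]}.{self.region}"

    @classmethod
    def from_column(cls, name: str) -> "CharacteristicDescriptor":
        token, _, region = name.partition(".")
        if token not in _TOKEN_MEASURE:
            raise ValueError(f"column {name!r}: unknown measure {token!r}")
        if region not in REGIONS:
            raise ValueError(f"column {name!r}: unknown region {region!r}")
        return cls(_TOKEN_MEASURE[token], region)

    def __str__(self) -> str:  # "NAA/Cho (CWMR)" — the field's usual notation
        return f"{self.measure} ({self.region})"


def all_characteristics() -> list[CharacteristicDescriptor]:
    """The full 42-characteristic panel in canonical (region, measure) order."""
    return [CharacteristicDescriptor(m, r) for r in REGIONS for m in MEASURES]


@dataclass(frozen=True)
class ClassDistribution:
    """Per-characteristic (mean, sd) for the delayed and non-delayed classes.

    ``rho`` adds equicorrelation between characteristics measured in the same
    region (left/right pairs and within-region metabolite ratios are plainly
    correlated in real data; the published summaries do not quantify this, so
    it is a free knob, default 0 = class-conditional independence).
    """

    delayed: Mapping[CharacteristicDescriptor, tuple[float, float]]
    normal: Mapping[CharacteristicDescriptor, tuple[float, float]]
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        for name, table in (("delayed", self.delayed), ("normal", self.normal)):
            for char, (_, sd) in table.items():
                if not sd > 0:
                    raise ValueError(f"{name} sd for {char} must be > 0")

    @property
    def characteristics(self) -> list[CharacteristicDescriptor]:
        return sorted(self.delayed.keys())

    @classmethod
    def packaged_defaults(cls, outcome: str, rho: float = 0.0) -> "ClassDistribution":
        """Defaults transcribed from published per-class summary tables.

        ``outcome`` is ``"motor"`` or ``"cognitive"``. Transcription
        corrections are listed in ``data/distribution_provenance.md``.
        """
        if outcome not in ("motor", "cognitive"):
            raise ValueError("outcome must be 'motor' or 'cognitive'")
        ref = importlib.resources.files("neoprog") / "data" / "class_distributions.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
        df = df[df["outcome"] == outcome]
        delayed, normal = {}, {}
        for row in df.itertuples(index=False):
            char = CharacteristicDescriptor(row.measure, row.region)
            delayed[char] = (float(row.delayed_mean), float(row.delayed_sd))
            normal[char] = (float(row.normal_mean), float(row.normal_sd))
        return cls(delayed=delayed, normal=normal, rho=rho)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort."""

    n_subjects: int
    prevalence: float
    planted_localised: tuple = ()  # of (CharacteristicDescriptor, octile 1..8)
    dropout_rate: float = 0.0
    severe_injury_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_subjects * self.prevalence < 1.0:
            raise ValueError(
                "expected delayed count n_subjects * prevalence is below 1; "
                "no delayed subjects to localise")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 <= self.severe_injury_rate < 1.0:
            raise ValueError("severe_injury_rate must be in [0, 1)")
        for char, octile in self.planted_localised:
            if not isinstance(char, CharacteristicDescriptor):
                raise TypeError("planted_localised entries are "
                                "(CharacteristicDescriptor, octile) pairs")
            if not 1 <= int(octile) <= 8:
                raise ValueError(f"octile_index must be in 1..8, got {octile}")


class CohortTable:
    """A subjects x characteristics table with delay labels.

    Thin wrapper over a pandas DataFrame with columns ``subject_id``,
    ``label`` (0/1, 1 = delayed), ``severe_injury`` (0/1) and one float
    column per characteristic named ``MEASURE.REGION``; NaN marks a missing
    value (a metabolite peak that could not be quantified).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns {missing}")
        chars = []
        for col in df.columns:
            if col in META_COLUMNS:
                continue
            chars.append(CharacteristicDescriptor.from_column(col))  # validates
        if len({c.column for c in chars}) != len(chars):
            raise ValueError("duplicate characteristic columns")
        bad = set(df["label"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1 only; found {sorted(bad)}")
        bad = set(df["severe_injury"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"severe_injury must be 0/1 only; found {sorted(bad)}")
        self.df = df.reset_index(drop=True)
        self.characteristics = chars

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def n_delayed(self) -> int:
        return int(self.labels.sum())

    def values(self, char: CharacteristicDescriptor) -> np.ndarray:
        return self.df[char.column].to_numpy(dtype=float)

    def subject_values(self, i: int) -> dict[CharacteristicDescriptor, float]:
        row = self.df.iloc[i]
        return {c: float(row[c.column]) for c in self.characteristics}

    def restrict(self, mask: Sequence[bool]) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def equals(self, other: "CohortTable") -> bool:
        return self.df.equals(other.df)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_class_block(rng: np.random.Generator, dist: ClassDistribution,
                      which: str, chars: list[CharacteristicDescriptor],
                      n: int) -> np.ndarray:
    """Draw n subjects' worth of values, (n, len(chars)).

    Ratios are plain normals; FA is truncated to [0, 1] and MD to (0, inf)
    to respect their physical ranges (truncation is negligible at the
    packaged parameters). With rho > 0 characteristics sharing a region are
    equicorrelated via a per-(subject, region) shared factor.
    """
    params = getattr(dist, which)
    out = np.empty((n, len(chars)))
    if dist.rho > 0.0:
        region_factor = {r: rng.standard_normal(n) for r in REGIONS}
    for j, char in enumerate(chars):
        mean, sd = params[char]
        if dist.rho > 0.0:
            shared = region_factor[char.region]
            z = (np.sqrt(dist.rho) * shared
                 + np.sqrt(1.0 - dist.rho) * rng.standard_normal(n))
            col = mean + sd * z
            if char.measure == "FA":
                col = np.clip(col, 1e-9, 1.0)
            elif char.measure == "MD":
                col = np.maximum(col, 1e-9)
        else:
            if char.measure == "FA":
                col = _truncated_normal(rng, mean, sd, n, 0.0, 1.0)
            elif char.measure == "MD":
                col = _truncated_normal(rng, mean, sd, n, 0.0, np.inf)
            else:
                col = rng.normal(mean, sd, size=n)
        out[:, j] = col
    return out


def generate_cohort(spec: CohortSpec, dist: ClassDistribution | None = None,
                    outcome: str = "motor") -> CohortTable:
    """Simulate one cohort.

    Labels are Bernoulli(prevalence); characteristic values come from the
    label's class distribution. Each planted (characteristic, octile) pair
    then redraws the delayed subjects' values uniformly inside the designated
    octile of that characteristic's pooled range, forcing its true
    localisation degree to the 0.125 floor. Dropout erases individual
    metabolite-ratio values (DTI maps are complete in practice, so MD/FA are
    exempt). Identical spec + seed gives an identical table.
    """
    if dist is None:
        dist = ClassDistribution.packaged_defaults(outcome)
    chars = sorted(dist.delayed.keys())
    missing_chars = [c for c, _ in spec.planted_localised if c not in dist.delayed]
    if missing_chars:
        raise ValueError(f"characteristic {missing_chars[0]} missing from "
                         "the class distribution")
    rng = np.random.default_rng(spec.seed)

    labels = (rng.random(spec.n_subjects) < spec.prevalence).astype(int)
    n = spec.n_subjects
    values = np.empty((n, len(chars)))
    delayed_mask = labels == 1
    n_del = int(delayed_mask.sum())
    n_norm = n - n_del
    # draw both class blocks unconditionally so the stream layout is stable
    block_d = _draw_class_block(rng, dist, "delayed", chars, n_del)
    block_n = _draw_class_block(rng, dist, "normal", chars, n_norm)
    values[delayed_mask] = block_d
    values[~delayed_mask] = block_n

    col_of = {c: j for j, c in enumerate(chars)}
    for char, octile in spec.planted_localised:
        j = col_of[char]
        if n_del == 0 or n_norm < 2:
            continue  # nothing to localise / no range to anchor
        # anchor the octile grid on the non-delayed range so that replanting
        # the delayed values cannot move the pooled min/max
        lo = values[~delayed_mask, j].min()
        hi = values[~delayed_mask, j].max()
        width = (hi - lo) / 8.0
        left = lo + (int(octile) - 1) * width
        u = rng.uniform(0.01, 0.99, size=n_del)  # strict interior of the octile
        values[delayed_mask, j] = left + u * width

    if spec.dropout_rate > 0.0:
        ratio_cols = [j for j, c in enumerate(chars) if c.measure in RATIO_MEASURES]
        drop = rng.random((n, len(ratio_cols))) < spec.dropout_rate
        for k, j in enumerate(ratio_cols):
            values[drop[:, k], j] = np.nan

    severe = (rng.random(n) < spec.severe_injury_rate).astype(int)

    data = {
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "label": labels,
        "severe_injury": severe,
    }
    for j, char in enumerate(chars):
        data[char.column] = values[:, j]
    return CohortTable(pd.DataFrame(data))


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort to CSV; missing values become empty cells.

    Floats are written at full round-trip precision, so write/read is
    value-exact and a fixed (spec, seed) pair yields byte-identical files.
    """
    table.df.to_csv(path, index=False, na_rep="", float_format="%.17g")


def read_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in META_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    parsed: dict[str, object] = {"subject_id": raw["subject_id"]}
    for col in ("label", "severe_injury"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any() or not vals.isin([0, 1]).all():
            bad = raw[col][~vals.isin([0, 1])].iloc[0]
            raise ValueError(f"column {col!r} must contain only 0/1; found {bad!r}")
        parsed[col] = vals.astype(int)
    for col in raw.columns:
        if col in META_COLUMNS:
            continue
        CharacteristicDescriptor.from_column(col)  # raises naming the bad part
        cells = raw[col]
        vals = np.empty(len(cells))
        for i, cell in enumerate(cells):
            if cell == "":
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(cell)  # correctly-rounded, exact round-trip
            except ValueError:
                raise ValueError(f"non-numeric cell {cell!r} at row {i}, "
                                 f"column {col!r}") from None
        parsed[col] = vals
    return CohortTable(pd.DataFrame(parsed))
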