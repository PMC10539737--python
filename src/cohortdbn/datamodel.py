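"""Factor definitions and longitudinal cohort tables.

A cohort is stored long-format: one row per (subject, timepoint), one column
per categorical factor, missing cells allowed.  Two complete-case datasets
are derived from it:

* the *initial dataset* — subjects with a fully observed record at t = 0,
  used to learn the network of dependencies at first presentation;
* the *transition dataset* — one row per pair of consecutive, fully
  observed timepoints of a subject, with columns ``<factor>@t`` and
  ``<factor>@t1``, used to learn the transition network.  The transition
  model is assumed homogeneous, so every consecutive pair contributes a row
  regardless of where it falls in the subject's follow-up.

No imputation is performed anywhere: eligibility is strict complete-case
per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DOMAIN_GROUPS",
    "FactorSpec",
    "CohortTable",
    "InitialDataset",
    "TransitionDataset",
    "SchemaError",
    "EmptyDatasetError",
    "validate_cohort",
    "build_initial_dataset",
    "build_transition_dataset",
    "collapse_to_binary",
    "load_factor_specs",
    "save_factor_specs",
    "T_SUFFIX",
    "T1_SUFFIX",
]

DOMAIN_GROUPS = (
    "function",
    "suicidality",
    "substance",
    "physical",
    "syndrome",
    "demographic",
)

SUBJECT_COL = "subject_id"
TIME_COL = "timepoint"
T_SUFFIX = "@t"
T1_SUFFIX = "@t1"


class SchemaError(ValueError):
    """A value or column violates the declared factor schema."""


class EmptyDatasetError(ValueError):
    """A complete-case construction produced zero rows."""


@dataclass(frozen=True)
class FactorSpec:
    """A categorical factor with 2 or 3 ordered levels.

    ``truthy_levels`` defines the binary collapse used for effect
    estimation: e.g. a diagnosis factor with levels (none, subthreshold,
    full-threshold) collapses to True for sub- and full-threshold.
    """

    name: str
    levels: tuple[str, ...]
    domain_group: str = "syndrome"
    truthy_levels: tuple[str, ...] = ()
    binarize: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        levels = tuple(str(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(set(levels)) != len(levels):
            raise SchemaError(f"factor {self.name!r}: duplicate levels {levels}")
        if len(levels) not in (2, 3):
            raise SchemaError(
                f"factor {self.name!r}: needs 2 or 3 levels, got {len(levels)}"
            )
        if self.domain_group not in DOMAIN_GROUPS:
            raise SchemaError(
                f"factor {self.name!r}: unknown domain_group {self.domain_group!r}"
            )
        truthy = tuple(str(v) for v in self.truthy_levels) or (levels[-1],)
        object.__setattr__(self, "truthy_levels", truthy)
        if not set(truthy) <= set(levels) or not truthy or set(truthy) == set(levels):
            raise SchemaError(
                f"factor {self.name!r}: truthy_levels {truthy} must be a "
                f"non-empty strict subset of levels {levels}"
            )

    @property
    def cardinality(self) -> int:
        return len(self.levels)


def collapse_to_binary(value: str, spec: FactorSpec) -> bool:
    """Collapse a categorical value to the binary (truthy) encoding."""
    if value not in spec.levels:
        raise SchemaError(
            f"factor {spec.name!r}: value {value!r} not in levels {spec.levels}"
        )
    return value in spec.truthy_levels


def _specs_by_name(specs: Iterable[FactorSpec]) -> dict[str, FactorSpec]:
    out: dict[str, FactorSpec] = {}
    for s in specs:
        if s.name in out:
            raise SchemaError(f"duplicate factor spec {s.name!r}")
        out[s.name] = s
    return out


@dataclass
class CohortTable:
    """Long-format cohort observations.

    ``data`` has columns ``subject_id``, ``timepoint`` and one column per
    factor; ``NaN``/``None`` marks a missing cell.  Timepoints are
    non-negative integers indexing visits; calendar spacing is not modelled.
    """

    data: pd.DataFrame
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        missing_cols = [c for c in (SUBJECT_COL, TIME_COL) if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"cohort table missing columns {missing_cols}")
        self.factors = tuple(self.factors)
        for f in self.factors:
            if f not in self.data.columns:
                raise SchemaError(f"cohort table missing factor column {f!r}")
        df = self.data.copy()
        if len(df):
            tp = pd.to_numeric(df[TIME_COL], errors="raise")
            if (tp < 0).any() or (tp != tp.astype(int)).any():
                raise SchemaError("timepoints must be non-negative integers")
            df[TIME_COL] = tp.astype(int)
            df = df.sort_values([SUBJECT_COL, TIME_COL], kind="mergesort")
        self.data = df.reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return sorted(self.data[SUBJECT_COL].unique().tolist())

    def select_factors(self, names: Sequence[str]) -> "CohortTable":
        """Restrict to a factor subset (complete-case rules then apply to it)."""
        missing = [f for f in names if f not in self.factors]
        if missing:
            raise SchemaError(f"unknown factors {missing}")
        return CohortTable(
            self.data[[SUBJECT_COL, TIME_COL, *names]], tuple(names)
        )

    @classmethod
    def from_csv(cls, path: str | Path, specs: Sequence[FactorSpec]) -> "CohortTable":
        """Read a cohort CSV (empty cell = missing).

        Factors carrying a ``binarize`` block in their spec are derived from
        a numeric source column: ``{source_column, threshold, direction}``
        with ``direction`` ``greater`` (value > threshold -> truthy level)
        or ``less``.  E.g. social/occupational functioning scored on SOFAS is
        commonly dichotomised at > 70 ("good"), and age at > 18 years.
        """
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        for spec in specs:
            if spec.binarize:
                cfg = dict(spec.binarize)
                src = str(cfg["source_column"])
                thr = float(cfg["threshold"])
                direction = str(cfg.get("direction", "greater"))
                if src not in df.columns:
                    raise SchemaError(
                        f"binarize source column {src!r} for factor "
                        f"{spec.name!r} not in CSV"
                    )
                vals = pd.to_numeric(df[src], errors="coerce")
                if direction == "greater":
                    hit = vals > thr
                elif direction == "less":
                    hit = vals < thr
                else:
                    raise SchemaError(f"binarize direction {direction!r} unknown")
                truthy = spec.truthy_levels[0]
                falsy = next(l for l in spec.levels if l not in spec.truthy_levels)
                df[spec.name] = [
                    None if pd.isna(v) else (truthy if h else falsy)
                    for v, h in zip(vals, hit)
                ]
        factors = tuple(s.name for s in specs)
        keep = [SUBJECT_COL, TIME_COL, *factors]
        return cls(df[keep], factors)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class ValidationReport:
    n_subjects: int
    n_records: int
    missing_per_factor: dict[str, int]

    @property
    def n_missing(self) -> int:
        return sum(self.missing_per_factor.values())


def validate_cohort(
    table: CohortTable, specs: Sequence[FactorSpec]
) -> ValidationReport:
    """Validate a cohort against factor specs and report counts.

    Raises :class:`SchemaError` on unknown level labels or duplicated
    (subject, timepoint) records.
    """
    by_name = _specs_by_name(specs)
    unknown = [f for f in table.factors if f not in by_name]
    if unknown:
        raise SchemaError(f"factors without a spec: {unknown}")
    df = table.data
    dup = df.duplicated([SUBJECT_COL, TIME_COL])
    if dup.any():
        first = df.loc[dup, [SUBJECT_COL, TIME_COL]].iloc[0]
        raise SchemaError(
            f"duplicate record for subject {first[SUBJECT_COL]!r} "
            f"timepoint {first[TIME_COL]}"
        )
    missing: dict[str, int] = {}
    for f in table.factors:
        col = df[f]
        isna = col.isna()
        missing[f] = int(isna.sum())
        bad = col[~isna & ~col.isin(by_name[f].levels)]
        if len(bad):
            raise SchemaError(
                f"factor {f!r}: value {bad.iloc[0]!r} not in levels "
                f"{by_name[f].levels}"
            )
    return ValidationReport(
        n_subjects=int(df[SUBJECT_COL].nunique()),
        n_records=int(len(df)),
        missing_per_factor=missing,
    )


@dataclass
class InitialDataset:
    """Complete cases at t = 0, one row per eligible subject."""

    rows: pd.DataFrame
    factors: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class TransitionDataset:
    """Stacked complete consecutive-timepoint pairs.

    Columns are ``<factor>@t`` and ``<factor>@t1``; a subject contributes
    one row per pair of consecutive timepoints at which every factor is
    observed.
    """

    rows: pd.DataFrame
    factors: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def t_columns(self) -> list[str]:
        return [f + T_SUFFIX for f in self.factors]

    @property
    def t1_columns(self) -> list[str]:
        return [f + T1_SUFFIX for f in self.factors]


def build_initial_dataset(
    table: CohortTable, specs: Sequence[FactorSpec]
) -> InitialDataset:
    """Complete-case dataset at the initial timepoint.

    A subject is eligible iff its t = 0 record exists and has no missing
    factor; later timepoints are irrelevant here.
    """
    validate_cohort(table, specs)
    factors = list(table.factors)
    df = table.data
    at0 = df[df[TIME_COL] == 0]
    complete = at0[at0[factors].notna().all(axis=1)]
    if complete.empty:
        raise EmptyDatasetError(
            "no subject has a complete record at t=0; consider reducing the "
            "factor subset"
        )
    rows = (
        complete.sort_values(SUBJECT_COL, kind="mergesort")[[SUBJECT_COL, *factors]]
        .reset_index(drop=True)
    )
    return InitialDataset(rows=rows, factors=tuple(factors))


def build_transition_dataset(
    table: CohortTable, specs: Sequence[FactorSpec]
) -> TransitionDataset:
    """Complete-case dataset of consecutive timepoint pairs.

    One row per (subject, t) with complete records at both t and t + 1;
    indices must be consecutive integers, so a gap (missed visit) breaks
    the pair but later pairs of the same subject still contribute.
    """
    validate_cohort(table, specs)
    factors = list(table.factors)
    df = table.data[table.data[factors].notna().all(axis=1)]
    left = df.copy()
    left["_t1"] = left[TIME_COL] + 1
    merged = left.merge(
        df,
        left_on=[SUBJECT_COL, "_t1"],
        right_on=[SUBJECT_COL, TIME_COL],
        suffixes=("_from", "_to"),
    )
    if merged.empty:
        raise EmptyDatasetError(
            "no subject has complete records at two consecutive timepoints"
        )
    out = pd.DataFrame(
        {
            SUBJECT_COL: merged[SUBJECT_COL],
            TIME_COL: merged[TIME_COL + "_from"],
        }
    )
    for f in factors:
        out[f + T_SUFFIX] = merged[f + "_from"].to_numpy()
        out[f + T1_SUFFIX] = merged[f + "_to"].to_numpy()
    out = out.sort_values([SUBJECT_COL, TIME_COL], kind="mergesort").reset_index(
        drop=True
    )
    return TransitionDataset(rows=out, factors=tuple(factors))


def load_factor_specs(path: str | Path) -> list[FactorSpec]:
    """Load factor specs from YAML: ``{name: {levels, truthy_levels, domain_group, binarize?}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for name, cfg in raw.items():
        specs.append(
            FactorSpec(
                name=str(name),
                levels=tuple(cfg["levels"]),
                domain_group=cfg.get("domain_group", "syndrome"),
                truthy_levels=tuple(cfg.get("truthy_levels", ())),
                binarize=cfg.get("binarize"),
            )
        )
    return specs


def save_factor_specs(specs: Sequence[FactorSpec], path: str | Path) -> None:
    raw = {
        s.name: {
            "levels": list(s.levels),
            "truthy_levels": list(s.truthy_levels),
            "domain_group": s.domain_group,
            **({"binarize": dict(s.binarize)} if s.binarize else {}),
        }
        for s in specs
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
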