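"""Cohort tables: variable schema, CSV round-trip, stratification, summaries.

A cohort table is a subjects x variables matrix with an explicit missingness
mask (NaN), plus per-subject ``sex``, ``age`` and ``wave`` columns that are
never network variables.  The schema declares each variable's measurement
level, which downstream validation (but not the rank-based estimator)
depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "VariableSchema",
    "CohortTable",
    "default_schema",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_schema",
    "write_schema",
    "split_by_sex",
    "summarize_cohort",
]

MISSING_TOKENS = ("", "NA")

LEVELS = ("continuous", "ordinal", "binary")
ROLES = ("network_node", "stratifier", "auxiliary")

#: column names reserved for subject metadata in CSV files
ID_COL = "subject_id"
SEX_COL = "sex"
AGE_COL = "age"
WAVE_COL = "wave"
RESERVED_COLS = (ID_COL, SEX_COL, AGE_COL, WAVE_COL)

SEX_LABELS = ("female", "male")


@dataclass(frozen=True)
class VariableSchema:
    """Measurement-level declaration for one variable."""

    name: str
    level: str
    ordinal_range: tuple[int, int] | None = None
    role: str = "network_node"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise SchemaError(f"unknown level {self.level!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.level == "ordinal":
            if self.ordinal_range is None:
                raise SchemaError(f"ordinal variable {self.name!r} needs ordinal_range")
            lo, hi = self.ordinal_range
            if lo >= hi:
                raise SchemaError(f"bad ordinal_range for {self.name!r}: {self.ordinal_range}")
        elif self.ordinal_range is not None:
            raise SchemaError(f"{self.name!r}: ordinal_range only valid for ordinal level")


def default_schema() -> list[VariableSchema]:
    """Schema for the 11-node inflammation / depression / cognition network.

    Five inflammatory biomarkers, depression (0-15 sum score), a global
    cognition z-score, education (1-5), alcohol consumption (1-6), a
    continuous cardiovascular risk score, and APOE-e4 carrier status.
    """
    return [
        VariableSchema("IL6", "continuous"),
        VariableSchema("IL8", "continuous"),
        VariableSchema("IL10", "continuous"),
        VariableSchema("IL12", "continuous"),
        VariableSchema("CRP", "continuous"),
        VariableSchema("depression", "ordinal", (0, 15)),
        VariableSchema("cognition", "continuous"),
        VariableSchema("education", "ordinal", (1, 5)),
        VariableSchema("alcohol", "ordinal", (1, 6)),
        VariableSchema("cvd_risk", "continuous"),
        VariableSchema("apoe4", "binary"),
    ]


def network_nodes(schema: Sequence[VariableSchema]) -> list[str]:
    return [v.name for v in schema if v.role == "network_node"]


def _check_schema(schema: Sequence[VariableSchema]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    for v in schema:
        if v.name in RESERVED_COLS:
            raise SchemaError(f"variable name {v.name!r} clashes with a reserved column")


@dataclass
class CohortTable:
    """Subjects x variables matrix with sex/age/wave metadata.

    ``values`` holds floats with NaN marking missing cells; the missingness
    mask is therefore always consistent with the values by construction.
    """

    subjects: list[str]
    values: pd.DataFrame  # index = subjects, columns = schema order
    sex: pd.Series
    age: pd.Series
    wave: int
    schema: list[VariableSchema] = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        _check_schema(self.schema)
        names = [v.name for v in self.schema]
        if list(self.values.columns) != names:
            raise SchemaError(
                f"value columns {list(self.values.columns)} do not match schema {names}"
            )
        if self.sex.isna().any():
            bad = list(self.sex.index[self.sex.isna()])
            raise ValidationError(f"missing sex for subjects {bad}")
        bad_sex = sorted(set(self.sex.unique()) - set(SEX_LABELS))
        if bad_sex:
            raise ValidationError(f"unknown sex labels {bad_sex}; expected {SEX_LABELS}")
        self._validate_cells()

    def _validate_cells(self) -> None:
        for v in self.schema:
            col = self.values[v.name]
            obs = col.dropna()
            if v.level == "binary":
                bad = obs[~obs.isin([0.0, 1.0])]
                if len(bad):
                    raise ValidationError(
                        f"{v.name}: non-binary value {bad.iloc[0]} at row {bad.index[0]!r}"
                    )
            elif v.level == "ordinal":
                lo, hi = v.ordinal_range
                bad = obs[(obs < lo) | (obs > hi) | (obs != np.round(obs))]
                if len(bad):
                    raise ValidationError(
                        f"{v.name}: value {bad.iloc[0]} at row {bad.index[0]!r} "
                        f"outside ordinal range [{lo}, {hi}]"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    @property
    def node_names(self) -> list[str]:
        return network_nodes(self.schema)

    def node_values(self) -> pd.DataFrame:
        """Values restricted to network-node variables, in schema order."""
        return self.values[self.node_names]

    def subset(self, subject_ids: Iterable[str]) -> "CohortTable":
        ids = [s for s in self.subjects if s in set(subject_ids)]
        return CohortTable(
            subjects=ids,
            values=self.values.loc[ids].copy(),
            sex=self.sex.loc[ids].copy(),
            age=self.age.loc[ids].copy(),
            wave=self.wave,
            schema=list(self.schema),
        )


def _coerce_cell(raw: str, var: VariableSchema, row: int) -> float:
    if raw is None or str(raw).strip() in MISSING_TOKENS:
        return np.nan
    try:
        val = float(raw)
    except ValueError as exc:
        raise ValidationError(f"{var.name}: unparsable value {raw!r} at row {row}") from exc
    return val


def read_cohort_csv(path, schema: Sequence[VariableSchema] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    The file must have a header with ``subject_id, sex, age, wave`` plus one
    column per schema variable.  Empty strings and ``NA`` are missing.
    """
    schema = list(schema) if schema is not None else default_schema()
    _check_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(RESERVED_COLS) | {v.name for v in schema}
    unknown = [c for c in raw.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown columns {unknown}")
    absent = [c for c in expected if c not in raw.columns]
    if absent:
        raise SchemaError(f"missing columns {sorted(absent)}")

    subjects = raw[ID_COL].tolist()
    if len(set(subjects)) != len(subjects):
        raise ValidationError("duplicate subject ids")

    sex_raw = raw[SEX_COL].str.strip()
    for i, s in enumerate(sex_raw):
        if s in MISSING_TOKENS:
            raise ValidationError(f"missing sex at row {i}")

    data = {}
    for var in schema:
        col = [
            _coerce_cell(raw[var.name].iloc[i], var, i) for i in range(len(raw))
        ]
        data[var.name] = col
    values = pd.DataFrame(data, index=subjects, columns=[v.name for v in schema], dtype=float)

    waves = raw[WAVE_COL].astype(int).unique()
    if len(waves) != 1:
        raise ValidationError(f"table mixes waves {sorted(waves)}")

    return CohortTable(
        subjects=subjects,
        values=values,
        sex=pd.Series(sex_raw.values, index=subjects),
        age=pd.Series(raw[AGE_COL].astype(float).values, index=subjects),
        wave=int(waves[0]),
        schema=schema,
    )


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort table; missing cells become empty strings."""
    out = pd.DataFrame(index=table.subjects)
    out[ID_COL] = table.subjects
    out[SEX_COL] = table.sex.values
    out[AGE_COL] = table.age.values
    out[WAVE_COL] = table.wave
    for v in table.schema:
        out[v.name] = table.values[v.name].values
    out.to_csv(path, index=False, na_rep="")


def write_schema(schema: Sequence[VariableSchema], path) -> None:
    payload = [
        {
            "name": v.name,
            "level": v.level,
            "ordinal_range": list(v.ordinal_range) if v.ordinal_range else None,
            "role": v.role,
        }
        for v in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_schema(path) -> list[VariableSchema]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        VariableSchema(
            name=item["name"],
            level=item["level"],
            ordinal_range=tuple(item["ordinal_range"]) if item.get("ordinal_range") else None,
            role=item.get("role", "network_node"),
        )
        for item in payload
    ]


def split_by_sex(table: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition into (female, male) tables; each stratum needs >= 2 subjects."""
    out = []
    for label in SEX_LABELS:
        ids = [s for s in table.subjects if table.sex[s] == label]
        if len(ids) < 2:
            raise InsufficientDataError(
                f"{label} stratum has {len(ids)} subject(s); need at least 2"
            )
        out.append(table.subset(ids))
    return out[0], out[1]


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Per-variable, per-sex descriptives.

    Continuous variables get mean/SD; ordinal and binary variables get counts
    per observed level (as a dict in the ``level_counts`` column).
    """
    rows = []
    for label in SEX_LABELS:
        ids = [s for s in table.subjects if table.sex[s] == label]
        sub = table.values.loc[ids]
        for v in table.schema:
            col = sub[v.name]
            obs = col.dropna()
            row = {
                "variable": v.name,
                "sex": label,
                "n_observed": int(obs.size),
                "n_missing": int(col.isna().sum()),
                "mean": float(obs.mean()) if obs.size else np.nan,
                "sd": float(obs.std(ddof=1)) if obs.size > 1 else (0.0 if obs.size == 1 else np.nan),
                "level_counts": None,
            }
            if obs.size and obs.nunique() == 1:
                row["sd"] = 0.0
            if v.level in ("ordinal", "binary"):
                counts = obs.value_counts().sort_index()
                row["level_counts"] = {int(k): int(c) for k, c in counts.items()}
            rows.append(row)
    return pd.DataFrame(rows)
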