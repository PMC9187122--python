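"""Tabular cohort data model: variable metadata, cohort tables, readers/writers.

A cohort is a subjects x variables table of continuous values and categorical
codes with missing values allowed, plus a per-variable metadata sidecar that
records the variable type, a free-form domain grouping, and the control
(reference-population) statistics used for scaling: mean/SD for continuous
variables, frequency for binary indicators.

Values are CSV (first column = subject id, header row = variable names, empty
cell = missing).  Metadata is CSV or YAML with columns/keys
``name, var_type, domain_group, control_mean, control_sd, control_freq,
subset_only``.  Multi-level categorical control frequencies may be given as a
``level:freq;level:freq`` string (CSV) or a mapping (YAML).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phenoclust")

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
_VAR_TYPES = (CONTINUOUS, CATEGORICAL)


@dataclass
class VariableMeta:
    """Per-variable metadata, including control-population reference statistics."""

    name: str
    var_type: str
    domain_group: str = ""
    control_mean: float | None = None
    control_sd: float | None = None
    control_freq: float | Mapping[object, float] | None = None
    subset_only: bool = False

    def __post_init__(self) -> None:
        if self.var_type not in _VAR_TYPES:
            raise ValueError(
                f"variable {self.name!r}: var_type must be one of {_VAR_TYPES}, "
                f"got {self.var_type!r}"
            )
        if self.var_type == CONTINUOUS and self.control_sd is not None:
            if not self.control_sd > 0:
                raise ValueError(
                    f"variable {self.name!r}: control_sd must be > 0, got {self.control_sd}"
                )


@dataclass
class CohortTable:
    """Subjects x variables table plus aligned variable metadata.

    ``values`` is a DataFrame indexed by unique subject ids whose columns match
    ``meta`` one-to-one (same order).  Missing cells are NaN.
    """

    values: pd.DataFrame
    meta: list[VariableMeta]

    def __post_init__(self) -> None:
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in metadata")
        if list(self.values.columns) != names:
            missing = set(names) - set(self.values.columns)
            extra = set(self.values.columns) - set(names)
            raise ValueError(
                f"metadata does not match value columns (missing from values: {sorted(missing)}, "
                f"absent from metadata: {sorted(map(str, extra))})"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dups[:5]}")
        for m in self.meta:
            if m.var_type == CONTINUOUS:
                col = pd.to_numeric(self.values[m.name], errors="coerce")
                bad = col.isna() & self.values[m.name].notna()
                if bad.any():
                    raise ValueError(
                        f"non-numeric value in continuous column {m.name!r} "
                        f"(subject {self.values.index[bad.argmax()]!r})"
                    )
                self.values[m.name] = col.astype(float)

    # -- convenience accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def meta_by_name(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def select(self, names: Sequence[str]) -> "CohortTable":
        metas = [self.meta_by_name(n) for n in names]
        return CohortTable(self.values[list(names)].copy(), metas)

    def continuous_names(self, include_subset: bool = True) -> list[str]:
        return [
            m.name
            for m in self.meta
            if m.var_type == CONTINUOUS and (include_subset or not m.subset_only)
        ]

    def categorical_names(self) -> list[str]:
        return [m.name for m in self.meta if m.var_type == CATEGORICAL]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_control_freq(raw):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, Mapping):
        return {k: float(v) for k, v in raw.items()}
    if isinstance(raw, str) and ":" in raw:
        out = {}
        for part in raw.split(";"):
            k, v = part.split(":")
            out[k.strip()] = float(v)
        return out
    return float(raw)


def _format_control_freq(freq):
    if freq is None:
        return ""
    if isinstance(freq, Mapping):
        return ";".join(f"{k}:{v!r}" for k, v in freq.items())
    return repr(float(freq))


def read_meta(path: str | Path) -> list[VariableMeta]:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        entries = yaml.safe_load(path.read_text())
        if isinstance(entries, Mapping):
            entries = entries.get("variables", entries)
    else:
        df = pd.read_csv(path)
        entries = df.to_dict(orient="records")
    metas = []
    for e in entries:
        def _num(key):
            v = e.get(key)
            if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        metas.append(
            VariableMeta(
                name=str(e["name"]),
                var_type=str(e["var_type"]),
                domain_group=str(e.get("domain_group") or ""),
                control_mean=_num("control_mean"),
                control_sd=_num("control_sd"),
                control_freq=_parse_control_freq(e.get("control_freq")),
                subset_only=bool(e.get("subset_only", False))
                and str(e.get("subset_only")).lower() not in ("false", "0", "nan", ""),
            )
        )
    return metas


def write_meta(meta: Sequence[VariableMeta], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "name": m.name,
            "var_type": m.var_type,
            "domain_group": m.domain_group,
            "control_mean": "" if m.control_mean is None else repr(m.control_mean),
            "control_sd": "" if m.control_sd is None else repr(m.control_sd),
            "control_freq": _format_control_freq(m.control_freq),
            "subset_only": m.subset_only,
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path_values: str | Path, path_meta: str | Path) -> CohortTable:
    """Read a values CSV plus a metadata sidecar into a typed :class:`CohortTable`."""
    meta = read_meta(path_meta)
    values = pd.read_csv(path_values, index_col=0)
    values.columns = [str(c) for c in values.columns]
    names = [m.name for m in meta]
    unknown = [n for n in names if n not in values.columns]
    if unknown:
        raise ValueError(f"metadata lists variables absent from values: {unknown}")
    extra = [c for c in values.columns if c not in names]
    if extra:
        raise ValueError(f"value columns missing from metadata: {extra}")
    return CohortTable(values[names], meta)


def write_cohort(table: CohortTable, path_values: str | Path, path_meta: str | Path) -> None:
    table.values.to_csv(path_values)
    write_meta(table.meta, path_meta)


# ---------------------------------------------------------------------------
# categorical expansion
# ---------------------------------------------------------------------------

def expand_categorical(table: CohortTable) -> CohortTable:
    """One-hot expand categorical variables into binary indicator columns.

    A categorical variable with L observed levels becomes L indicator columns
    named ``var=level``, each carrying its own control frequency.  A variable
    that is already binary (levels within {0, 1}) becomes a single indicator —
    Tanimoto similarity counts common ones only, so a complementary "absent"
    indicator would double-count absence.  Missingness on the source variable
    propagates to all of its indicators.  Continuous columns pass through.
    """
    cols: dict[str, pd.Series] = {}
    metas: list[VariableMeta] = []
    for m in table.meta:
        col = table.values[m.name]
        if m.var_type == CONTINUOUS:
            cols[m.name] = col
            metas.append(m)
            continue
        observed = col.dropna()
        levels = sorted(observed.unique(), key=str)
        is_binary = set(levels) <= {0, 1, 0.0, 1.0, "0", "1"}
        if len(levels) < 2:
            logger.warning(
                "categorical variable %r has a single observed level %r; indicator kept",
                m.name, levels,
            )
        if is_binary:
            ind = col.astype(float)
            freq = m.control_freq
            if isinstance(freq, Mapping):
                freq = freq.get(1, freq.get(1.0, freq.get("1")))
            cols[m.name] = ind
            metas.append(
                VariableMeta(
                    name=m.name,
                    var_type=CATEGORICAL,
                    domain_group=m.domain_group,
                    control_freq=None if freq is None else float(freq),
                    subset_only=m.subset_only,
                )
            )
            continue
        for lev in levels:
            name = f"{m.name}={lev}"
            ind = (col == lev).astype(float)
            ind[col.isna()] = np.nan
            freq = None
            if isinstance(m.control_freq, Mapping):
                freq = m.control_freq.get(lev, m.control_freq.get(str(lev)))
            cols[name] = ind
            metas.append(
                VariableMeta(
                    name=name,
                    var_type=CATEGORICAL,
                    domain_group=m.domain_group,
                    control_freq=None if freq is None else float(freq),
                    subset_only=m.subset_only,
                )
            )
    values = pd.DataFrame(cols, index=table.values.index)
    return CohortTable(values, metas)


__all__ = [
    "CONTINUOUS",
    "CATEGORICAL",
    "VariableMeta",
    "CohortTable",
    "read_meta",
    "write_meta",
    "read_cohort",
    "write_cohort",
    "expand_categorical",
]
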