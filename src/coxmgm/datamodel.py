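"""Core data structures for mixed continuous/discrete/censored datasets.

A dataset holds three blocks over the same n samples:

* continuous variables (an n x p float matrix),
* discrete (categorical) variables with declared level sets, and
* censored time-to-event variables, each a ``(time, event)`` pair where
  ``event == 1`` means the event was observed and ``event == 0`` means the
  time is a right-censoring time (a lower bound on the true event time).

Variable roles are declared explicitly in a :class:`VariableSpec` sidecar
rather than inferred from column names, because silently treating an event
indicator as an ordinary binary covariate is the worst failure mode for
downstream survival modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "VariableSpec",
    "MixedDataset",
    "validate_dataset",
    "nonparanormal_transform",
    "encode_discrete",
    "read_dataset",
    "read_variable_specs",
    "CONTINUOUS",
    "DISCRETE",
    "CENSORED",
]

CONTINUOUS = "continuous"
DISCRETE = "discrete"
CENSORED = "censored"
_KINDS = (CONTINUOUS, DISCRETE, CENSORED)


@dataclass(frozen=True)
class VariableSpec:
    """Declared type of one model variable.

    For ``kind == "discrete"`` the ordered ``levels`` list fixes the level
    order used by all encodings.  For ``kind == "censored"`` the spec names
    the two source columns (``time_col``, ``event_col``) in the raw table.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    time_col: str | None = None
    event_col: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == DISCRETE and (self.levels is None or len(self.levels) < 2):
            raise ValueError(f"discrete variable {self.name!r} needs >= 2 declared levels")
        if self.kind == CENSORED:
            if not self.time_col or not self.event_col or self.time_col == self.event_col:
                raise ValueError(
                    f"censored variable {self.name!r} must reference two distinct "
                    "columns (time_col, event_col)"
                )


@dataclass
class MixedDataset:
    """Validated complete-case dataset split into typed blocks.

    Attributes
    ----------
    sample_ids : list of str
    continuous : (n, p) float array; columns ordered as ``continuous_names``
    discrete : (n, q) integer array of level codes into ``levels[j]``
    times, events : (n, r) float / int arrays, one column per censored variable
    """

    sample_ids: list[str]
    continuous: np.ndarray
    discrete: np.ndarray
    times: np.ndarray
    events: np.ndarray
    continuous_names: list[str]
    discrete_names: list[str]
    censored_names: list[str]
    levels: list[tuple[str, ...]]
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return self.continuous.shape[1]

    @property
    def q(self) -> int:
        return self.discrete.shape[1]

    @property
    def r(self) -> int:
        return self.times.shape[1]

    @property
    def names(self) -> list[str]:
        return self.continuous_names + self.discrete_names + self.censored_names

    def kind_of(self, name: str) -> str:
        if name in self.continuous_names:
            return CONTINUOUS
        if name in self.discrete_names:
            return DISCRETE
        if name in self.censored_names:
            return CENSORED
        raise KeyError(f"unknown variable {name!r}")

    def n_levels(self, name: str) -> int:
        return len(self.levels[self.discrete_names.index(name)])

    def column(self, name: str):
        """Return the raw column(s) for a variable.

        Continuous -> (n,) floats; discrete -> (n,) level codes;
        censored -> (times, events) pair.
        """
        kind = self.kind_of(name)
        if kind == CONTINUOUS:
            return self.continuous[:, self.continuous_names.index(name)]
        if kind == DISCRETE:
            return self.discrete[:, self.discrete_names.index(name)]
        m = self.censored_names.index(name)
        return self.times[:, m], self.events[:, m]

    def subset(self, rows: np.ndarray) -> "MixedDataset":
        """Row-subset view (copy) preserving declared types."""
        rows = np.asarray(rows)
        return MixedDataset(
            sample_ids=[self.sample_ids[i] for i in rows],
            continuous=self.continuous[rows].copy(),
            discrete=self.discrete[rows].copy(),
            times=self.times[rows].copy(),
            events=self.events[rows].copy(),
            continuous_names=list(self.continuous_names),
            discrete_names=list(self.discrete_names),
            censored_names=list(self.censored_names),
            levels=list(self.levels),
            n_dropped=0,
        )

    def specs(self) -> list[VariableSpec]:
        out: list[VariableSpec] = []
        for s in self.continuous_names:
            out.append(VariableSpec(s, CONTINUOUS))
        for j, name in enumerate(self.discrete_names):
            out.append(VariableSpec(name, DISCRETE, levels=self.levels[j]))
        for name in self.censored_names:
            out.append(
                VariableSpec(name, CENSORED, time_col=f"{name}_time", event_col=f"{name}_event")
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flatten back to a raw table (censored pairs as two columns)."""
        data: dict[str, object] = {}
        for s, name in enumerate(self.continuous_names):
            data[name] = self.continuous[:, s]
        for j, name in enumerate(self.discrete_names):
            lv = np.asarray(self.levels[j], dtype=object)
            data[name] = lv[self.discrete[:, j]]
        for m, name in enumerate(self.censored_names):
            data[f"{name}_time"] = self.times[:, m]
            data[f"{name}_event"] = self.events[:, m]
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))


def _required_columns(spec: VariableSpec) -> list[str]:
    if spec.kind == CENSORED:
        return [spec.time_col, spec.event_col]  # type: ignore[list-item]
    return [spec.name]


def validate_dataset(raw_table: pd.DataFrame, specs: Sequence[VariableSpec]) -> MixedDataset:
    """Validate a raw table against declared variable specs.

    Rows containing any missing value (NaN / empty / "NA") in a declared
    column are dropped; the count is recorded on ``n_dropped``.  Raises on
    unknown columns, out-of-level discrete values, negative times, and
    non-binary event indicators.
    """
    df = raw_table.copy()
    df = df.replace({"NA": np.nan, "": np.nan})

    used: list[str] = []
    for spec in specs:
        for col in _required_columns(spec):
            if col not in df.columns:
                raise ValueError(f"unknown column {col!r} required by variable {spec.name!r}")
            used.append(col)

    sub = df[used]
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    if len(df) == 0:
        raise ValueError("zero rows remain after dropping incomplete cases")

    cont_names, disc_names, cens_names = [], [], []
    cont_cols, disc_cols, time_cols, event_cols, level_sets = [], [], [], [], []
    for spec in specs:
        if spec.kind == CONTINUOUS:
            cont_names.append(spec.name)
            cont_cols.append(pd.to_numeric(df[spec.name]).to_numpy(dtype=float))
        elif spec.kind == DISCRETE:
            vals = df[spec.name].astype(str).to_numpy()
            lv = tuple(str(x) for x in spec.levels)  # type: ignore[union-attr]
            lookup = {x: i for i, x in enumerate(lv)}
            bad = sorted(set(vals) - set(lv))
            if bad:
                raise ValueError(
                    f"discrete variable {spec.name!r} has values outside declared levels: {bad}"
                )
            disc_names.append(spec.name)
            level_sets.append(lv)
            disc_cols.append(np.array([lookup[v] for v in vals], dtype=np.int64))
        else:
            t = pd.to_numeric(df[spec.time_col]).to_numpy(dtype=float)
            e = pd.to_numeric(df[spec.event_col]).to_numpy(dtype=float)
            if np.any(t < 0):
                raise ValueError(f"negative time in censored variable {spec.name!r}")
            if not np.all(np.isin(e, (0.0, 1.0))):
                raise ValueError(f"non-binary event indicator for censored variable {spec.name!r}")
            cens_names.append(spec.name)
            time_cols.append(t)
            event_cols.append(e.astype(np.int64))

    n = len(df)
    ids = [str(i) for i in df.index]
    return MixedDataset(
        sample_ids=ids,
        continuous=np.column_stack(cont_cols) if cont_cols else np.empty((n, 0)),
        discrete=np.column_stack(disc_cols) if disc_cols else np.empty((n, 0), dtype=np.int64),
        times=np.column_stack(time_cols) if time_cols else np.empty((n, 0)),
        events=np.column_stack(event_cols) if event_cols else np.empty((n, 0), dtype=np.int64),
        continuous_names=cont_names,
        discrete_names=disc_names,
        censored_names=cens_names,
        levels=level_sets,
        n_dropped=n_dropped,
    )


def nonparanormal_transform(column: np.ndarray) -> np.ndarray:
    """Rank-based Gaussianization of a continuous column.

    Empirical CDF values (average ranks divided by n) are Winsorized at the
    truncation level ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))`` and mapped
    through the standard normal quantile function.  The output depends on the
    input only through its ranks, so any strictly increasing transform of the
    input yields an identical result.
    """
    v = np.asarray(column, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d column")
    n = v.size
    if np.unique(v).size < 2:
        raise ValueError("constant column cannot be nonparanormal-transformed")
    ranks = stats.rankdata(v, method="average")
    u = ranks / n
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    u = np.clip(u, delta, 1.0 - delta)
    return stats.norm.ppf(u)


def encode_discrete(codes: np.ndarray, n_levels: int, reference: bool = False) -> np.ndarray:
    """Indicator encoding of a discrete column given as level codes.

    ``reference=False`` gives one column per level (used by group penalties);
    ``reference=True`` drops the first level (used where an intercept makes
    the full encoding unidentifiable).
    """
    codes = np.asarray(codes)
    if n_levels < 2:
        raise ValueError("discrete encoding needs >= 2 levels")
    observed = np.unique(codes)
    if observed.size < 2:
        raise ValueError("discrete column has a single observed level")
    if codes.min() < 0 or codes.max() >= n_levels:
        raise ValueError("level code out of range")
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out[:, 1:] if reference else out


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling (columnwise, ddof=0)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def read_variable_specs(path: str) -> list[VariableSpec]:
    """Read a YAML/JSON sidecar: a list of {name, kind, levels?, time_col?, event_col?}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for entry in raw:
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                levels=tuple(str(x) for x in entry["levels"]) if "levels" in entry else None,
                time_col=entry.get("time_col"),
                event_col=entry.get("event_col"),
            )
        )
    return specs


def write_variable_specs(specs: Sequence[VariableSpec], path: str) -> None:
    out = []
    for s in specs:
        d: dict[str, object] = {"name": s.name, "kind": s.kind}
        if s.kind == DISCRETE:
            d["levels"] = list(s.levels)  # type: ignore[arg-type]
        if s.kind == CENSORED:
            d["time_col"] = s.time_col
            d["event_col"] = s.event_col
        out.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def read_dataset(data_path: str, meta_path: str) -> MixedDataset:
    """Read a delimited table plus its sidecar and validate."""
    sep = "\t" if str(data_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(data_path, sep=sep)
    specs = read_variable_specs(meta_path)
    return validate_dataset(df, specs)
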