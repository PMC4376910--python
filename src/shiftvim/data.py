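"""Longitudinal data model and reduction to cross-sectional problems.

The study design is discrete-time: subjects are measured on a grid
``t_0 < t_1 < ... < t_{J-1}`` (plus an implicit final open-ended interval),
each measurement consisting of baseline covariates ``L0`` (time-invariant),
longitudinal covariates ``L_{jk}`` with per-variable missingness indicators
``C_{jk}`` (1 = observed), and an interval death indicator ``Y_j`` for death
in ``(t_j, t_{j+1}]``.  Death is absorbing: rows after the death interval are
degenerate and ignored.

Every importance analysis of a variable ``k`` measured at time ``j`` on death
in interval ``j' >= j`` runs on a *cross-section*: the subjects still alive at
the start of interval ``j'``, with exposure ``A = L_{jk}``, observedness
``C = C_{jk}``, adjustment set ``W = (L0, C_{j-1}, L_{j-1})`` (most recent
history only, by the Markov assumption) and outcome ``Y = Y_{j'}``.
Contemporaneous covariates ``L_{jk*}``, ``k* != k`` are not confounders of the
effect of ``L_{jk}`` and are excluded from ``W``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateVariableError",
    "EmptyCrossSectionError",
    "VarMeta",
    "LongitudinalData",
    "CrossSection",
    "rescale_unit_interval",
    "extract_cross_section",
    "read_long_csv",
    "write_long_csv",
    "read_var_meta",
    "write_var_meta",
    "write_cross_section",
]


class DegenerateVariableError(ValueError):
    """A variable has zero range (or is otherwise constant) and must be dropped."""


class EmptyCrossSectionError(ValueError):
    """No subjects are at risk for the requested outcome interval."""


@dataclass(frozen=True)
class VarMeta:
    """Classification of one variable: measurement kind and analysis role."""

    name: str
    kind: str  # "continuous" | "binary"
    role: str  # "baseline" | "treatment"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.role not in ("baseline", "treatment"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class LongitudinalData:
    """One longitudinal study in array form.

    Attributes
    ----------
    subject_id : (n,) array of identifiers.
    baseline : DataFrame (n x p0) of baseline covariates (already in [0,1]
        for continuous columns).
    times : (J,) increasing measurement times.
    covariates : (n, J, K) float array of longitudinal covariates, NaN where
        missing; continuous variables in [0,1], binary in {0,1}.
    miss_flags : (n, J, K) 0/1 array, 1 = observed.
    death : (n, J) 0/1 array, ``death[i, j] = 1`` iff subject i dies in
        interval ``(t_j, t_{j+1}]`` (ties at the upper boundary resolve into
        that interval).
    var_meta : list of ``VarMeta`` for the K longitudinal variables, in
        column order.
    """

    subject_id: np.ndarray
    baseline: pd.DataFrame
    times: np.ndarray
    covariates: np.ndarray
    miss_flags: np.ndarray
    death: np.ndarray
    var_meta: list[VarMeta] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.subject_id)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_vars(self) -> int:
        return self.covariates.shape[2]

    def validate(self) -> None:
        n, J, K = self.covariates.shape
        if self.miss_flags.shape != (n, J, K) or self.death.shape != (n, J):
            raise ValueError("array shapes are inconsistent")
        if len(self.times) != J:
            raise ValueError("times length does not match covariate time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        obs = self.miss_flags.astype(bool)
        if np.any(np.isnan(self.covariates[obs])):
            raise ValueError("observed entries (flag = 1) must be non-missing")
        if not np.all(np.isnan(self.covariates[~obs])):
            raise ValueError("entries with flag = 0 must be NaN")
        if np.any(self.death.sum(axis=1) > 1):
            raise ValueError("death must occur in at most one interval")
        if self.var_meta and len(self.var_meta) != K:
            raise ValueError("var_meta length does not match variable axis")
        for k, meta in enumerate(self.var_meta):
            vals = self.covariates[:, :, k][obs[:, :, k]]
            if vals.size == 0:
                continue
            if meta.kind == "binary":
                if not np.all(np.isin(vals, (0.0, 1.0))):
                    raise ValueError(f"binary variable {meta.name} outside {{0,1}}")
            else:
                if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
                    raise ValueError(
                        f"continuous variable {meta.name} outside [0,1]; rescale first"
                    )


@dataclass
class CrossSection:
    """One reduced estimation problem (W, C, A, Y) for a (k, j, j') triple."""

    W: pd.DataFrame
    C: np.ndarray
    A: np.ndarray  # NaN where C = 0
    Y: np.ndarray
    exposure_kind: str  # "continuous" | "binary"
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.Y)

    def validate(self) -> None:
        obs = self.C.astype(bool)
        if np.any(np.isnan(self.A[obs])):
            raise ValueError("A must be defined where C = 1")
        if obs.sum() < len(obs) and not np.all(np.isnan(self.A[~obs])):
            raise ValueError("A must be NaN where C = 0")
        if self.exposure_kind == "binary":
            if not np.all(np.isin(self.A[obs], (0.0, 1.0))):
                raise ValueError("binary exposure outside {0,1}")
        elif np.any((self.A[obs] <= 0) | (self.A[obs] >= 1)):
            raise ValueError("continuous exposure must lie in the open interval (0,1)")


def rescale_unit_interval(values: np.ndarray) -> np.ndarray:
    """Map observed values affinely onto [0,1]: (x - min) / (max - min).

    Missing (NaN) entries are ignored when computing the range and stay
    missing in the output.  Raises :class:`DegenerateVariableError` when the
    observed values are constant, in which case the caller should drop the
    variable.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise DegenerateVariableError("need at least two observed values")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise DegenerateVariableError("zero range: variable is constant")
    return (values - lo) / (hi - lo)


def _w_frame(
    data: LongitudinalData, at_risk: np.ndarray, j: int, full_history: bool
) -> pd.DataFrame:
    """Assemble the adjustment set W for exposure time j.

    Past-covariate missingness: values are zero-filled and the corresponding
    observedness flags are kept as covariates, so that informative missingness
    enters the adjustment set without an imputation model.
    """
    parts: list[pd.DataFrame] = [data.baseline.loc[at_risk].reset_index(drop=True)]
    hist = range(j) if full_history else ([j - 1] if j >= 1 else [])
    names = [m.name for m in data.var_meta] or [
        f"v{k}" for k in range(data.n_vars)
    ]
    for jj in hist:
        vals = np.nan_to_num(data.covariates[at_risk, jj, :], nan=0.0)
        flags = data.miss_flags[at_risk, jj, :]
        parts.append(
            pd.DataFrame(vals, columns=[f"{nm}_t{jj}" for nm in names])
        )
        parts.append(
            pd.DataFrame(flags, columns=[f"{nm}_obs_t{jj}" for nm in names])
        )
    return pd.concat(parts, axis=1)


def extract_cross_section(
    data: LongitudinalData,
    k: int,
    j: int,
    j_prime: int,
    full_history: bool = False,
) -> CrossSection:
    """Reduce the longitudinal problem to the (variable k, time j, interval j') cross-section.

    Rows are restricted to subjects alive at the start of interval ``j'``
    (no death event in intervals ``< j'``); ``W`` contains the baseline
    covariates plus, for ``j >= 1``, the immediately preceding time point's
    covariates (zero-filled where missing) and missingness flags.  With
    ``full_history=True`` all time points before ``j`` enter ``W`` instead.
    """
    if j_prime < j:
        raise ValueError("outcome interval j' must satisfy j' >= j")
    if j >= data.n_times or j_prime >= data.n_times:
        raise ValueError("time index out of range")
    if data.var_meta and data.var_meta[k].role != "treatment":
        raise ValueError(f"variable {data.var_meta[k].name} is not a treatment variable")

    dead_before = data.death[:, :j_prime].sum(axis=1) > 0
    at_risk = ~dead_before
    if not at_risk.any():
        raise EmptyCrossSectionError(f"no subjects at risk at interval {j_prime}")

    A = data.covariates[at_risk, j, k].astype(float)
    C = data.miss_flags[at_risk, j, k].astype(int)
    Y = data.death[at_risk, j_prime].astype(int)
    W = _w_frame(data, at_risk, j, full_history)
    kind = data.var_meta[k].kind if data.var_meta else "continuous"
    name = data.var_meta[k].name if data.var_meta else f"v{k}"
    cs = CrossSection(
        W=W,
        C=C,
        A=A,
        Y=Y,
        exposure_kind=kind,
        meta={"variable": name, "var_index": k, "exposure_time": j, "outcome_interval": j_prime},
    )
    return cs


# ---------------------------------------------------------------------------
# plain-text I/O


def write_var_meta(metas: list[VarMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in metas]).to_csv(
        path, sep="\t", index=False
    )


def read_var_meta(path: str | Path) -> list[VarMeta]:
    df = pd.read_csv(path, sep="\t")
    return [VarMeta(r["name"], r["kind"], r["role"]) for _, r in df.iterrows()]


def write_long_csv(data: LongitudinalData, path: str | Path) -> None:
    """Write long format: one row per subject x time point.

    Columns: ``subject_id, time``, baseline columns (repeated across rows),
    one column per longitudinal variable, ``<var>_observed`` flags, ``death``.
    """
    names = [m.name for m in data.var_meta] or [f"v{k}" for k in range(data.n_vars)]
    rows = []
    for jj, t in enumerate(data.times):
        df = pd.DataFrame({"subject_id": data.subject_id, "time": t})
        for col in data.baseline.columns:
            df[col] = np.asarray(data.baseline[col])
        for k, nm in enumerate(names):
            df[nm] = data.covariates[:, jj, k]
            df[f"{nm}_observed"] = data.miss_flags[:, jj, k]
        df["death"] = data.death[:, jj]
        rows.append(df)
    pd.concat(rows).sort_values(["subject_id", "time"]).to_csv(path, index=False)


def read_long_csv(path: str | Path, var_meta: list[VarMeta]) -> LongitudinalData:
    df = pd.read_csv(path)
    treat = [m for m in var_meta if m.role == "treatment"]
    base = [m for m in var_meta if m.role == "baseline"]
    times = np.sort(df["time"].unique())
    subjects = np.sort(df["subject_id"].unique())
    n, J, K = len(subjects), len(times), len(treat)
    cov = np.full((n, J, K), np.nan)
    flags = np.zeros((n, J, K), dtype=int)
    death = np.zeros((n, J), dtype=int)
    df = df.set_index(["subject_id", "time"]).sort_index()
    first = df.xs(times[0], level="time")
    baseline = first.loc[subjects, [m.name for m in base]].reset_index(drop=True)
    for jj, t in enumerate(times):
        sl = df.xs(t, level="time").loc[subjects]
        for k, m in enumerate(treat):
            cov[:, jj, k] = sl[m.name].to_numpy()
            flags[:, jj, k] = sl[f"{m.name}_observed"].to_numpy().astype(int)
        death[:, jj] = sl["death"].to_numpy().astype(int)
    cov[flags == 0] = np.nan
    data = LongitudinalData(
        subject_id=subjects,
        baseline=baseline,
        times=times,
        covariates=cov,
        miss_flags=flags,
        death=death,
        var_meta=treat,
    )
    data.validate()
    return data


def write_cross_section(cs: CrossSection, path: str | Path) -> None:
    """Audit dump of one extracted problem as TSV."""
    out = cs.W.copy()
    out.insert(0, "Y", cs.Y)
    out.insert(0, "A", cs.A)
    out.insert(0, "C", cs.C)
    out.to_csv(path, sep="\t", index=False)
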