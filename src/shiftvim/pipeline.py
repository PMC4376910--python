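"""End-to-end study orchestration and report generation.

:func:`run_study` walks every estimation cell of a longitudinal study — one
cell per (treatment variable k, exposure time j, outcome interval j' >= j) —
extracting the cross-section, fitting nuisances, and running the requested
estimators.  :func:`rank_vims` reproduces the reporting convention of the
analysis: per outcome interval, keep the variables whose TMLE is significant
at level alpha and rank them by the magnitude of the estimate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    CrossSection,
    DegenerateVariableError,
    EmptyCrossSectionError,
    LongitudinalData,
    extract_cross_section,
)
from .estimators import ee_estimator, gcomp_ipmw, tmle, unadjusted
from .superlearner import DEFAULT_LIBRARY
from .vim import ShiftSpec, fit_nuisances, positivity_check

log = logging.getLogger("shiftvim")

__all__ = ["StudyConfig", "run_study", "rank_vims", "write_ranked_report",
           "format_estimates"]

ALL_ESTIMATORS = ("TMLE", "EE", "GcompIPMW", "Unadjusted")


@dataclass
class StudyConfig:
    """Study-level settings (YAML-loadable)."""

    delta: float = 0.01
    alpha: float = 0.05
    estimators: tuple = ALL_ESTIMATORS
    sl_library: tuple = DEFAULT_LIBRARY
    sl_folds: int = 10
    density_grid: tuple | None = None
    density_folds: int = 5
    density_floor: float = 1e-3
    tmle_max_iter: int = 20
    n_grid: int = 200
    seed: int = 0
    top: int = 5
    rank_order: str = "desc"  # "desc" = most important first; "asc" mirrors tables
    full_history: bool = False
    bh_correction: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("estimators", "sl_library", "density_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in raw[key]
                )
        return cls(**raw)


def _cell_seed(base: int, k: int, j: int, j_prime: int) -> int:
    return (base * 1_000_003 + k * 10_007 + j * 101 + j_prime) % (2**31 - 1)


def _run_cell(cs: CrossSection, cfg: StudyConfig, seed: int) -> list:
    spec = ShiftSpec(cfg.delta, cs.exposure_kind)
    nuis = None
    if {"TMLE", "EE"} & set(cfg.estimators):
        nuis = fit_nuisances(
            cs, library=cfg.sl_library, V=cfg.sl_folds, seed=seed,
            density_grid=cfg.density_grid, density_V=cfg.density_folds,
            density_floor=cfg.density_floor,
        )
        report = positivity_check(nuis, cs, spec, floor=cfg.density_floor)
        log.info("cell %s: %s", cs.meta, report.summary())
    out = []
    for name in cfg.estimators:
        if name == "TMLE":
            out.append(tmle(cs, nuis, spec, max_iter=cfg.tmle_max_iter,
                            alpha=cfg.alpha, n_grid=cfg.n_grid))
        elif name == "EE":
            out.append(ee_estimator(cs, nuis, spec, alpha=cfg.alpha,
                                    n_grid=cfg.n_grid))
        elif name == "GcompIPMW":
            out.append(gcomp_ipmw(cs, spec, alpha=cfg.alpha))
        elif name == "Unadjusted":
            out.append(unadjusted(cs, spec, alpha=cfg.alpha))
        else:
            raise ValueError(f"unknown estimator {name!r}")
    return out


def run_study(data: LongitudinalData, cfg: StudyConfig) -> pd.DataFrame:
    """Estimate every (variable, exposure time, outcome interval) cell.

    Returns a long DataFrame with one row per (cell, estimator).  Cells that
    fail (empty at-risk set, degenerate exposure, fit errors) are logged and
    recorded with ``status`` = "failed"; the run continues.
    """
    data.validate()
    rows = []
    J, K = data.n_times, data.n_vars
    for j_prime in range(J):
        for j in range(j_prime + 1):
            for k in range(K):
                if data.var_meta and data.var_meta[k].role != "treatment":
                    continue
                meta = {
                    "variable": data.var_meta[k].name if data.var_meta else f"v{k}",
                    "var_time": j,
                    "interval": j_prime,
                }
                try:
                    cs = extract_cross_section(data, k, j, j_prime,
                                               full_history=cfg.full_history)
                    obs_a = cs.A[cs.C.astype(bool)]
                    if len(np.unique(obs_a)) < 2:
                        raise DegenerateVariableError("constant observed exposure")
                    if cs.Y.sum() == 0 or cs.Y.sum() == cs.n:
                        raise DegenerateVariableError("degenerate outcome in interval")
                    ests = _run_cell(cs, cfg, _cell_seed(cfg.seed, k, j, j_prime))
                except (EmptyCrossSectionError, DegenerateVariableError,
                        ValueError) as exc:
                    log.warning("cell %s skipped: %s", meta, exc)
                    rows.append({**meta, "estimator": None, "status": "failed",
                                 "reason": str(exc), "psi": np.nan, "se": np.nan,
                                 "p_value": np.nan, "ci_lo": np.nan,
                                 "ci_hi": np.nan})
                    continue
                for est in ests:
                    rows.append({
                        **meta, "estimator": est.estimator, "status": "ok",
                        "reason": "", "psi": est.psi, "se": est.se,
                        "p_value": est.p_value, "ci_lo": est.ci[0],
                        "ci_hi": est.ci[1],
                    })
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["interval", "var_time", "variable", "estimator"]
    ).reset_index(drop=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    ok = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def rank_vims(
    estimates: pd.DataFrame,
    alpha: float = 0.05,
    top: int = 5,
    order: str = "desc",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-interval ranked table of TMLE-significant variables.

    Keeps cells whose TMLE p-value is below ``alpha`` (optionally after
    Benjamini-Hochberg adjustment within interval), ranks them by |psi| of
    the TMLE (sign retained), truncates to ``top`` rows, and attaches the
    companion estimators' columns for the kept rows.
    """
    ok = estimates[estimates["status"] == "ok"]
    tm = ok[ok["estimator"] == "TMLE"].copy()
    blocks = []
    for interval, grp in tm.groupby("interval"):
        p = grp["p_value"].to_numpy()
        if bh_correction:
            p = _bh_adjust(p)
        keep = grp[p < alpha].copy()
        keep = keep.reindex(
            keep["psi"].abs().sort_values(ascending=(order == "asc")).index
        ).head(top)
        keep.insert(0, "rank", np.arange(1, len(keep) + 1))
        blocks.append(keep)
    ranked = pd.concat(blocks) if blocks else tm.iloc[0:0].copy()
    if ranked.empty:
        return ranked
    wide = ok.pivot_table(
        index=["interval", "variable", "var_time"],
        columns="estimator", values=["psi", "p_value"], aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    out = ranked[["interval", "rank", "variable", "var_time"]].merge(
        wide.reset_index(), on=["interval", "variable", "var_time"], how="left"
    )
    return out.sort_values(["interval", "rank"]).reset_index(drop=True)


def _fmt_pair(psi: float, p: float) -> str:
    if not np.isfinite(psi):
        return ""
    ptxt = "< 0.001" if p < 0.001 else f"{p:.3f}"  # reported floor at 0.001
    return f"{psi:.4f} ({ptxt})"


def format_estimates(ranked: pd.DataFrame) -> pd.DataFrame:
    """Human-readable ranked table: one psi (p) column per estimator."""
    cols = {"interval": ranked.get("interval"), "rank": ranked.get("rank"),
            "variable": ranked.get("variable"), "var_time": ranked.get("var_time")}
    out = pd.DataFrame(cols)
    for est in ALL_ESTIMATORS:
        if f"psi_{est}" in ranked:
            out[est] = [
                _fmt_pair(ps, pv)
                for ps, pv in zip(ranked[f"psi_{est}"], ranked[f"p_value_{est}"])
            ]
    return out


def write_ranked_report(ranked: pd.DataFrame, path: str | Path) -> None:
    format_estimates(ranked).to_csv(path, sep="\t", index=False)
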