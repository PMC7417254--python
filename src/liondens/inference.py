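"""Birth-month inference, conception backdating and seasonality.

Combines the three movement indicators — monthly core-range size,
daily travel, and maximal residency duration — into a per-month
denning score for each female, z-scored against that female's own
months. The top-scoring month above the call threshold is the putative
birth month; conception is backdated by the ~3-month lion gestation.
Called events are then tallied by wet/dry season and related to prey
birth pulses and season through binomial GLMs compared by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as ldstats
from .homerange import monthly_ranges
from .trajectory import (
    DEFAULT_TZ_OFFSET_H,
    Trajectory,
    daily_net_displacement,
    detect_clusters,
    duration_of_stay,
)

__all__ = [
    "BirthCandidate",
    "SeasonalTally",
    "DEFAULT_WEIGHTS",
    "DEFAULT_WET_MONTHS",
    "backdate_conception",
    "season_of",
    "monthly_indicators",
    "score_birth_months",
    "call_birth",
    "seasonal_association",
]

DEFAULT_WET_MONTHS = (10, 11, 12, 1, 2, 3)

# Relative weight of core contraction, residency and displacement in the
# denning score. Core range is by far the most informative single
# indicator, but residency and displacement carry independent signal
# that a single-indicator score would discard (see docs/methods.md).
DEFAULT_WEIGHTS = {"core": 0.6, "residency": 0.2, "displacement": 0.2}
DEFAULT_CALL_THRESHOLD = 2.0
# A denning residency lasts weeks; carcass attendance lasts days. A month
# only becomes a birth candidate if it overlaps an unbroken residency of
# at least this many days (the published pipeline identifies the
# potential birth month from fix clusters first, then verifies it).
DEFAULT_MIN_DEN_RESIDENCY_DAYS = 12.0
_Z_CAP = 8.0


@dataclass(frozen=True)
class BirthCandidate:
    """A scored putative birth month with its backdated conception."""

    female_id: str
    birth_month: pd.Period
    conception_month: pd.Period
    score: float
    indicators: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SeasonalTally:
    """Wet/dry season event counts for one region."""

    region: str
    n_conceptions_wet: int
    n_conceptions_dry: int
    n_births_wet: int
    n_births_dry: int

    @property
    def fraction_wet_conceptions(self) -> float:
        tot = self.n_conceptions_wet + self.n_conceptions_dry
        return self.n_conceptions_wet / tot if tot else float("nan")

    @property
    def fraction_wet_births(self) -> float:
        tot = self.n_births_wet + self.n_births_dry
        return self.n_births_wet / tot if tot else float("nan")


def backdate_conception(birth_month: pd.Period, gestation_months: int = 3) -> pd.Period:
    """Shift a birth month back by the gestation, with correct year
    rollover (pandas Period arithmetic)."""
    if gestation_months < 0:
        raise ValueError("gestation must be non-negative")
    return birth_month - gestation_months

def season_of(month: int | pd.Period,
              wet_months: Sequence[int] = DEFAULT_WET_MONTHS) -> str:
    """'wet' or 'dry' for a calendar month (int 1-12 or Period)."""
    m = month.month if isinstance(month, pd.Period) else int(month)
    if not 1 <= m <= 12:
        raise ValueError(f"invalid month {month}")
    return "wet" if m in set(wet_months) else "dry"


# ---------------------------------------------------------------------------
# per-month indicators
# ---------------------------------------------------------------------------

def monthly_indicators(
    traj: Trajectory,
    radius_m: float = 200.0,
    min_fixes: int = 3,
    tz_offset_h: int = DEFAULT_TZ_OFFSET_H,
) -> pd.DataFrame:
    """Per-calendar-month indicator table for one female.

    Columns: ``core50_km2``, ``total90_km2``, ``displacement_km_day``
    (mean daily travel), ``residency_days`` (longest residency cluster
    overlapping the month). Indexed by month Period; months without a
    usable range estimate carry NaN core/total.
    """
    ranges = monthly_ranges(traj, tz_offset_h=tz_offset_h)
    disp = daily_net_displacement(traj, tz_offset_h=tz_offset_h, how="sum")
    clusters = detect_clusters(traj, radius_m=radius_m, min_fixes=min_fixes)

    if len(disp):
        disp_month = disp.groupby(pd.PeriodIndex(disp.index, freq="M")).mean()
    else:
        disp_month = pd.Series(dtype=float)
    months = sorted(
        set(disp_month.index) | {r.month for r in ranges}
    )
    rows = []
    rng_by_month = {r.month: r for r in ranges}
    for m in months:
        start = m.to_timestamp().tz_localize("UTC") - pd.Timedelta(hours=tz_offset_h)
        end = (m + 1).to_timestamp().tz_localize("UTC") - pd.Timedelta(
            hours=tz_offset_h)
        res = duration_of_stay(clusters, start, end)
        r = rng_by_month.get(m)
        rows.append(
            {
                "month": m,
                "core50_km2": r.core50_km2 if r else np.nan,
                "total90_km2": r.total90_km2 if r else np.nan,
                "displacement_km_day": float(disp_month.get(m, np.nan)),
                "residency_days": 0.0 if res["count"] == 0 else res["max_days"],
            }
        )
    return pd.DataFrame(rows).set_index("month")


def _robust_z(x: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores (consistent with the normal), capped; falls
    back to mean/sd when the MAD vanishes."""
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    z = np.full_like(x, np.nan)
    if ok.sum() < 2:
        return z
    med = np.median(x[ok])
    mad = np.median(np.abs(x[ok] - med))
    scale = 1.4826 * mad
    if scale <= 0:
        sd = x[ok].std(ddof=1)
        if sd <= 0:
            z[ok] = 0.0
            return z
        scale = sd
    z[ok] = np.clip((x[ok] - med) / scale, -_Z_CAP, _Z_CAP)
    return z


def score_birth_months(
    metrics: pd.DataFrame,
    female_id: str = "",
    gestation_months: int = 3,
    weights: dict | None = None,
    min_den_residency_days: float = DEFAULT_MIN_DEN_RESIDENCY_DAYS,
) -> list[BirthCandidate]:
    """Rank a female's months as birth candidates.

    ``metrics`` is the output of :func:`monthly_indicators`. Each month
    scores ``w_core * z(-log core50) + w_res * z(residency) +
    w_disp * z(-displacement)``, z-scored against the female's own
    months (robust median/MAD). Months overlapping a denning-length
    residency (>= ``min_den_residency_days`` unbroken days) rank ahead
    of all others; within each tier months sort by descending score,
    ties toward the earlier month. Requires at least 3 months of
    metrics.
    """
    if len(metrics) < 3:
        raise ValueError("need >= 3 months of metrics for a baseline")
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    core = metrics["core50_km2"].to_numpy(dtype=float)
    disp = metrics["displacement_km_day"].to_numpy(dtype=float)
    res = metrics["residency_days"].to_numpy(dtype=float)

    z_core = _robust_z(-np.log(np.clip(core, 1e-4, None)))
    z_disp = _robust_z(-disp)
    z_res = _robust_z(res)
    score = (
        w["core"] * np.nan_to_num(z_core)
        + w["residency"] * np.nan_to_num(z_res)
        + w["displacement"] * np.nan_to_num(z_disp)
    )
    baseline_disp = float(np.nanmedian(disp)) if np.isfinite(disp).any() else np.nan
    baseline_core = float(np.nanmedian(core)) if np.isfinite(core).any() else np.nan

    denning = res >= min_den_residency_days
    order = sorted(range(len(metrics)),
                   key=lambda i: (not denning[i], -score[i], metrics.index[i]))
    out = []
    for i in order:
        month = metrics.index[i]
        d = disp[i]
        c = core[i]
        out.append(
            BirthCandidate(
                female_id=female_id,
                birth_month=month,
                conception_month=backdate_conception(month, gestation_months),
                score=float(score[i]),
                indicators={
                    "displacement_reduction_frac": (
                        1.0 - d / baseline_disp
                        if np.isfinite(d) and baseline_disp else np.nan
                    ),
                    "core_contraction_ratio": (
                        c / baseline_core
                        if np.isfinite(c) and baseline_core else np.nan
                    ),
                    "max_residency_days": float(res[i]),
                },
            )
        )
    return out


def call_birth(
    candidates: Sequence[BirthCandidate],
    threshold: float = DEFAULT_CALL_THRESHOLD,
    min_den_residency_days: float = DEFAULT_MIN_DEN_RESIDENCY_DAYS,
) -> BirthCandidate | None:
    """The top-ranked candidate, if it shows a denning-length residency
    and clears the score threshold; otherwise no call."""
    if not candidates:
        return None
    top = candidates[0]
    if top.indicators.get("max_residency_days", 0.0) < min_den_residency_days:
        return None
    return top if top.score > threshold else None


# ---------------------------------------------------------------------------
# seasonality and ecological association
# ---------------------------------------------------------------------------

def seasonal_association(
    events: pd.DataFrame,
    env: pd.DataFrame,
    wet_months: Sequence[int] = DEFAULT_WET_MONTHS,
) -> tuple[list[SeasonalTally], ldstats.ModelSelectionTable]:
    """Seasonal tallies and GLM model selection for birth/conception.

    ``events`` needs columns ``female_id``, ``region``, ``birth_month``
    and ``conception_month`` (Periods). Each (female, month, response)
    becomes a binary outcome over the environment span; candidate
    binomial GLMs (response ~ prey pulse + season, per region and
    response) form one candidate set compared by AICc, alongside
    per-region wet/dry tallies.
    """
    if events.empty:
        raise ValueError("no candidate events supplied")
    env = env.copy()
    env_period = pd.PeriodIndex(
        pd.to_datetime(env["year"].astype(str) + "-" + env["month"].astype(str).str.zfill(2)),
        freq="M",
    )
    env["period"] = env_period

    tallies = []
    fits = []
    for region in ("south", "north"):
        ev = events[events["region"] == region]
        env_r = env[env["region"] == region]
        if ev.empty or env_r.empty:
            continue
        c_wet = sum(season_of(m, wet_months) == "wet" for m in ev["conception_month"])
        b_wet = sum(season_of(m, wet_months) == "wet" for m in ev["birth_month"])
        tallies.append(
            SeasonalTally(
                region=region,
                n_conceptions_wet=c_wet,
                n_conceptions_dry=len(ev) - c_wet,
                n_births_wet=b_wet,
                n_births_dry=len(ev) - b_wet,
            )
        )
        lookup = env_r.set_index("period")
        for response in ("birth", "conception"):
            col = f"{response}_month"
            rows_y, rows_x = [], []
            for _, e in ev.iterrows():
                for p in lookup.index:
                    rows_y.append(1.0 if e[col] == p else 0.0)
                    rows_x.append(
                        [1.0,
                         1.0 if lookup.loc[p, "prey_pulse"] else 0.0,
                         1.0 if season_of(p, wet_months) == "wet" else 0.0]
                    )
            X = np.asarray(rows_x)
            y = np.asarray(rows_y)
            # drop covariate columns that add no rank (constant columns,
            # or prey pulse coinciding with season over short spans)
            keep = [0]
            for j in (1, 2):
                cand = X[:, keep + [j]]
                if np.linalg.matrix_rank(cand) == len(keep) + 1:
                    keep.append(j)
            fits.append(
                ldstats.fit_binary_glm(
                    y, X[:, keep], name=f"{region}_{response} ~ prey + season"
                )
            )
    table = ldstats.akaike_table(fits)
    return tallies, table
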