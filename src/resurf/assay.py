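"""Anti-drug-antibody (ADA) assay analytics.

Implements the ELISA analysis chain used to characterise antibody binding
to engineered protein panels: per-plate background subtraction, endpoint
titer calling against a healthy-control baseline (3-fold rule), working
dilution selection, wild-type- and His-tag normalisation, Grubbs outlier
screening, binding-vs-mutational-distance regression, hypersensitivity
score ANOVA, and kinetic relVmax extraction.

All tabular input is a pandas DataFrame with the well schema in
:data:`ELISA_COLUMNS` (one row per well read).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ELISA_COLUMNS",
    "AssayDataError",
    "TiterResult",
    "RegressionResult",
    "load_elisa_csv",
    "background_subtract",
    "endpoint_titer",
    "pick_working_dilution",
    "normalize_to_wt",
    "his_normalize",
    "grubbs_critical",
    "grubbs_outlier",
    "binding_distance_regression",
    "anova_hypersensitivity",
    "kinetic_relvmax",
]

ELISA_COLUMNS = [
    "plate_id", "sample_id", "antigen_id", "dilution", "replicate", "role", "od450",
]
ROLES = {"experimental", "secondary_only", "healthy_control"}


class AssayDataError(ValueError):
    """Raised for malformed or insufficient assay data."""


def load_elisa_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ELISA_COLUMNS if c not in df.columns]
    if missing:
        raise AssayDataError(f"{path}: missing columns {missing}")
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise AssayDataError(f"{path}: unknown roles {sorted(bad_roles)}")
    if (df["dilution"] <= 0).any():
        raise AssayDataError(f"{path}: dilutions must be positive")
    if not np.isfinite(df["od450"]).all():
        raise AssayDataError(f"{path}: non-finite od450 values")
    return df


def background_subtract(wells: pd.DataFrame, clamp_negative: bool = True) -> pd.DataFrame:
    """Subtract each plate's mean secondary-only signal from its wells.

    Per plate, the average OD of wells run with secondary antibody alone is
    subtracted from every experimental and healthy-control well on that
    plate.  Negative results clamp to 0 by default (OD is non-negative);
    set ``clamp_negative=False`` to keep them.
    """
    out = wells.copy()
    for plate_id, grp in wells.groupby("plate_id"):
        bg = grp.loc[grp["role"] == "secondary_only", "od450"]
        if bg.empty:
            raise AssayDataError(f"plate {plate_id!r} has no secondary_only wells")
        mask = (out["plate_id"] == plate_id) & (out["role"] != "secondary_only")
        out.loc[mask, "od450"] = out.loc[mask, "od450"] - bg.mean()
    if clamp_negative:
        out.loc[out["role"] != "secondary_only", "od450"] = out.loc[
            out["role"] != "secondary_only", "od450"
        ].clip(lower=0.0)
    return out


@dataclass
class TiterResult:
    sample_id: str
    antigen_id: str
    titer: float | None  # fold dilution, None = undetected
    fold_over_control: float | None  # ratio at the called titer

    @property
    def detected(self) -> bool:
        return self.titer is not None

    def __str__(self) -> str:
        t = "undetected" if self.titer is None else f"1:{int(self.titer):,}"
        return f"{self.sample_id} vs {self.antigen_id}: {t}"


def _dilution_means(df: pd.DataFrame) -> pd.Series:
    return df.groupby("dilution")["od450"].mean().sort_index()


def endpoint_titer(
    series: pd.DataFrame,
    control: pd.DataFrame,
    factor: float = 3.0,
    control_floor: float = 1e-3,
) -> TiterResult:
    """Endpoint titer: the highest dilution whose background-subtracted
    mean signal is at least ``factor`` times the healthy-control mean.

    Both inputs are well tables for one sample/antigen (technical
    replicates are averaged per dilution).  Control means below
    ``control_floor`` are floored so a zero-background control cannot
    produce an infinite ratio.  When the control grid differs from the
    sample grid, the control is interpolated on log-dilution.
    """
    if series.empty or control.empty:
        raise AssayDataError("empty dilution series")
    s = _dilution_means(series)
    c = _dilution_means(control)
    if not set(s.index).issubset(set(c.index)):
        logd = np.log(np.asarray(c.index, dtype=float))
        cvals = np.interp(np.log(s.index.to_numpy(dtype=float)), logd, c.to_numpy())
        c = pd.Series(cvals, index=s.index)
    else:
        c = c.reindex(s.index)
    denom = np.maximum(c.to_numpy(), control_floor)
    ratio = s.to_numpy() / denom
    # boundary is inclusive ("at least 3-fold"); tolerate FP representation
    ok = ratio >= factor * (1.0 - 1e-9)
    sample_id = str(series["sample_id"].iloc[0])
    antigen_id = str(series["antigen_id"].iloc[0])
    if not ok.any():
        return TiterResult(sample_id, antigen_id, None, None)
    i = int(np.max(np.nonzero(ok)[0]))
    return TiterResult(sample_id, antigen_id, float(s.index[i]), float(ratio[i]))


def pick_working_dilution(series: pd.DataFrame, fraction: float = 0.8) -> float:
    """Dilution whose mean signal is closest to ``fraction`` of the max
    mean signal; ties resolve to the more dilute point."""
    if series.empty:
        raise AssayDataError("empty dilution series")
    means = _dilution_means(series)
    if len(means) < 3:
        raise AssayDataError("need at least 3 dilutions")
    if (means <= 0).all():
        raise AssayDataError("flat zero series")
    target = fraction * means.max()
    dist = (means - target).abs()
    best = dist[np.isclose(dist, dist.min(), rtol=0.0, atol=1e-9)]
    return float(best.index.max())  # larger fold = more dilute


def normalize_to_wt(
    means: Mapping[str, float], wt_antigen_id: str
) -> dict[str, float]:
    """Percent-of-wild-type binding per antigen."""
    if wt_antigen_id not in means:
        raise AssayDataError(f"missing wild-type antigen {wt_antigen_id!r}")
    wt = means[wt_antigen_id]
    if wt <= 0:
        raise AssayDataError("wild-type mean signal must be positive")
    return {a: 100.0 * v / wt for a, v in means.items()}


def his_normalize(
    pct_of_wt: Mapping[str, float],
    his_od: Mapping[str, float],
    wt_antigen_id: str,
) -> dict[str, float]:
    """Correct percent-of-WT binding for plate-coating differences.

    The anti-His OD of each antigen relative to wild type acts as a
    coating factor; binding percent is divided by it, so an antigen that
    coated at half the wild-type density has its apparent binding doubled.
    """
    if any(v <= 0 for v in his_od.values()):
        raise AssayDataError("anti-His OD must be positive for all antigens")
    if wt_antigen_id not in his_od:
        raise AssayDataError(f"missing wild-type anti-His OD {wt_antigen_id!r}")
    wt = his_od[wt_antigen_id]
    return {a: pct / (his_od[a] / wt) for a, pct in pct_of_wt.items()}


# ---------------------------------------------------------------------------
# Outlier screening

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    if n < 3:
        raise AssayDataError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(
    values: Sequence[float],
    alpha: float = 0.05,
    iterate: bool = False,
) -> list[int]:
    """Indices of values flagged by the two-sided Grubbs test.

    The max studentised deviation G = max|x − mean|/sd is compared to the
    t-based critical value; with ``iterate`` the flagged value is removed
    and the test repeated until no flag or fewer than 3 values remain.
    Zero-variance input flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise AssayDataError("Grubbs test requires n >= 3")
    flagged: list[int] = []
    active = list(range(x.size))
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical(len(active), alpha):
            flagged.append(active[i])
            if not iterate:
                break
            active.pop(i)
        else:
            break
    return sorted(flagged)


# ---------------------------------------------------------------------------
# Regression & ANOVA

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


def binding_distance_regression(
    points: Sequence[tuple[float, float]]
) -> RegressionResult:
    """Ordinary least squares of percent binding on mutation count.

    Returns slope, intercept, R² and the two-sided p-value for a non-zero
    slope.  A significant negative slope indicates that binding by
    polyclonal antibodies falls with mutational distance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise AssayDataError("regression requires at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise AssayDataError("zero variance in mutation counts (singular)")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def anova_hypersensitivity(
    records: pd.DataFrame,
    reference_group: str,
    days: Sequence[int] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA of hypersensitivity scores, each group vs reference.

    ``records`` needs columns mouse_id, group, day, score (ordinal 0–4).
    For every requested day, each non-reference group is compared to the
    reference arm by one-way ANOVA (two groups, so F equals the squared
    equal-variance t statistic).  P-values are reported unadjusted;
    ``holm`` adds a Holm-corrected column across each day's comparisons.
    """
    req = {"group", "day", "score"}
    if not req.issubset(records.columns):
        raise AssayDataError(f"records must have columns {sorted(req)}")
    bad = set(records["score"]) - {0, 1, 2, 3, 4}
    if bad:
        raise AssayDataError(f"scores outside 0-4: {sorted(bad)}")
    if days is None:
        days = sorted(records["day"].unique())
    rows = []
    for day in days:
        sub = records[records["day"] == day]
        ref = sub.loc[sub["group"] == reference_group, "score"].to_numpy(float)
        if ref.size == 0:
            raise AssayDataError(f"reference group {reference_group!r} empty on day {day}")
        day_rows = []
        for group, grp in sub.groupby("group"):
            if group == reference_group:
                continue
            vals = grp["score"].to_numpy(float)
            if vals.size < 2 or ref.size < 2:
                raise AssayDataError(f"group {group!r} day {day}: need n >= 2")
            if np.ptp(vals) == 0 and np.ptp(ref) == 0 and vals.mean() == ref.mean():
                f, p = 0.0, 1.0
            else:
                f, p = stats.f_oneway(vals, ref)
            day_rows.append({
                "day": day, "group": group, "n": int(vals.size),
                "n_ref": int(ref.size), "F": float(f), "p_value": float(p),
            })
        if holm and day_rows:
            order = np.argsort([r["p_value"] for r in day_rows])
            m = len(day_rows)
            prev = 0.0
            for rank, idx in enumerate(order):
                adj = min(1.0, (m - rank) * day_rows[idx]["p_value"])
                prev = max(prev, adj)
                day_rows[idx]["p_holm"] = prev
        rows.extend(day_rows)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kinetics

def kinetic_relvmax(
    times: Sequence[float],
    values: Sequence[float],
    window: int = 5,
    reference_vmax: float | None = None,
) -> float:
    """Maximum slope of a progress curve via sliding-window linear fits.

    Fits a line to every contiguous window of ``window`` points and takes
    the largest slope — the early linear phase of a saturating kinetic
    read.  With ``reference_vmax`` the result is returned relative to the
    reference enzyme (relVmax).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise AssayDataError("times and values differ in length")
    if t.size < window:
        raise AssayDataError(f"need at least {window} points, got {t.size}")
    if window < 2:
        raise AssayDataError("window must be >= 2")
    best = -np.inf
    for i in range(t.size - window + 1):
        slope = np.polyfit(t[i : i + window], y[i : i + window], 1)[0]
        best = max(best, float(slope))
    if reference_vmax is not None:
        if reference_vmax <= 0:
            raise AssayDataError("reference_vmax must be positive")
        return best / reference_vmax
    return best
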