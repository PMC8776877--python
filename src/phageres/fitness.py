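"""Growth-curve fitness statistics.

Fitness of each resistant clone is proxied by the *cumulative OD600*: the
plain sum of optical-density readings over the 18 h growth curve sampled at
20-minute intervals (proportional to the area under the curve on a uniform
grid). Clones are compared to the pooled untreated group (control clones
plus wild type) with one-way ANOVA followed by Tukey HSD clone-vs-control
contrasts; a clone is flagged significantly reduced when its adjusted
p-value falls below alpha (default 0.001) *and* its mean cumulative OD is
below the control mean. Associations between the reduced-growth flag and
clone features (resistance breadth, large deletion, carrier state, cocktail
treatment) are tested per strain with two-sided Fisher exact tests, breadth
additionally with a linear-by-linear ordinal trend test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD600 time series on a uniform minute grid."""

    clone_id: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        if t.size != od.size or t.size < 2:
            raise ValueError("times and od must have equal length >= 2")
        steps = np.diff(t)
        if (steps <= 0).any() or not np.allclose(steps, steps[0]):
            raise ValueError(
                f"{self.clone_id} rep {self.replicate}: non-uniform time grid"
            )
        if (od < 0).any():
            raise ValueError("OD values must be >= 0")


@dataclass(frozen=True)
class FitnessResult:
    """Cumulative-OD summary and significance flag for one clone."""

    clone_id: str
    cumulative_od: tuple
    mean: float
    sd: float
    significantly_reduced: bool | None
    p_adjusted: float | None
    comparison_group: str = "pooled_controls"
    reason: str | None = None


def read_growth_csv(path) -> dict:
    """Read a long-format growth CSV (clone, replicate, time_min, od600).

    Returns a mapping clone_id -> list of :class:`GrowthCurve`.
    """
    df = pd.read_csv(path)
    required = {"clone", "replicate", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    curves: dict = {}
    for (clone, rep), grp in df.groupby(["clone", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        curves.setdefault(str(clone), []).append(
            GrowthCurve(
                clone_id=str(clone),
                replicate=int(rep),
                times=grp["time_min"].to_numpy(),
                od=grp["od600"].to_numpy(),
            )
        )
    return curves


def cumulative_od(curve: GrowthCurve) -> float:
    """Sum of OD600 readings over the time grid (the fitness proxy)."""
    return float(curve.od.sum())


def flag_reduced(
    clone_curves: dict,
    control_curves,
    alpha: float = 0.001,
    all_pairs: bool = False,
):
    """Flag clones with significantly reduced cumulative OD vs controls.

    Parameters
    ----------
    clone_curves : mapping clone_id -> list of GrowthCurve
    control_curves : list of GrowthCurve
        The pooled untreated reference group (control clones + wild type).
    alpha : float
        Significance level on the Tukey-adjusted p-value.
    all_pairs : bool
        When true, additionally return the full Tukey HSD p-value matrix
        over (control, clone_1, ..., clone_m) as a DataFrame.

    Returns a list of :class:`FitnessResult` (plus the matrix if requested).
    Clones with fewer than two replicates get an undefined flag with a
    reason instead of entering the ANOVA.
    """
    control_vals = np.array([cumulative_od(c) for c in control_curves])
    if control_vals.size < 2:
        raise ValueError("need >= 2 control replicates")

    eligible, results = [], {}
    for clone_id in sorted(clone_curves):
        vals = np.array([cumulative_od(c) for c in clone_curves[clone_id]])
        if vals.size < 2:
            results[clone_id] = FitnessResult(
                clone_id=clone_id,
                cumulative_od=tuple(vals),
                mean=float(vals.mean()) if vals.size else float("nan"),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                significantly_reduced=None,
                p_adjusted=None,
                reason="insufficient_replicates",
            )
        else:
            eligible.append((clone_id, vals))

    matrix = None
    if eligible:
        groups = [control_vals] + [v for _, v in eligible]
        hsd = stats.tukey_hsd(*groups)
        if all_pairs:
            names = ["control"] + [cid for cid, _ in eligible]
            matrix = pd.DataFrame(hsd.pvalue, index=names, columns=names)
        for i, (clone_id, vals) in enumerate(eligible, start=1):
            p_adj = float(hsd.pvalue[0, i])
            reduced = bool(p_adj < alpha and vals.mean() < control_vals.mean())
            results[clone_id] = FitnessResult(
                clone_id=clone_id,
                cumulative_od=tuple(float(v) for v in vals),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)),
                significantly_reduced=reduced,
                p_adjusted=p_adj,
            )

    out = [results[cid] for cid in sorted(results)]
    return (out, matrix) if all_pairs else out


def associate(results, features: pd.DataFrame) -> pd.DataFrame:
    """Test associations between reduced growth and clone features.

    Parameters
    ----------
    results : list of FitnessResult (or mapping clone_id -> bool)
        Reduced-growth flags; clones with undefined flags are dropped.
    features : DataFrame indexed by clone_id
        Column ``strain`` plus any of: boolean columns (e.g. ``deletion``,
        ``carrier``, ``polyvalent``) tested with two-sided Fisher exact
        tests on 2x2 tables, and the ordinal column ``resistance_breadth``
        tested with a linear-by-linear trend test.

    Returns one row per strain x feature with the contingency counts and
    p-value; degenerate tables (constant feature or flag) are reported with
    an NA p-value and a note rather than skipped silently.
    """
    if isinstance(results, dict):
        reduced = pd.Series(results, dtype="object")
    else:
        reduced = pd.Series(
            {r.clone_id: r.significantly_reduced for r in results}, dtype="object"
        )
    reduced = reduced.dropna().astype(bool)
    feats = features.loc[features.index.intersection(reduced.index)].copy()
    reduced = reduced.loc[feats.index]
    if "strain" not in feats.columns:
        feats["strain"] = "all"

    rows = []
    feature_cols = [c for c in feats.columns if c != "strain"]
    for strain, idx in feats.groupby("strain").groups.items():
        red = reduced.loc[idx]
        for col in feature_cols:
            vals = feats.loc[idx, col]
            if col == "resistance_breadth":
                rows.append(_trend_row(strain, col, red, vals))
            else:
                rows.append(_fisher_row(strain, col, red, vals.astype(bool)))
    return pd.DataFrame(rows)


def _fisher_row(strain, feature, reduced: pd.Series, values: pd.Series) -> dict:
    table = np.array(
        [
            [int(((~values) & (~reduced)).sum()), int(((~values) & reduced).sum())],
            [int((values & (~reduced)).sum()), int((values & reduced).sum())],
        ]
    )
    row = {
        "strain": strain,
        "feature": feature,
        "test": "fisher_exact",
        "table": table.tolist(),
        "p_value": pd.NA,
        "note": "",
    }
    if values.nunique() < 2:
        row["note"] = "feature constant"
    elif reduced.nunique() < 2:
        row["note"] = "flag constant"
    else:
        row["p_value"] = float(stats.fisher_exact(table)[1])
    return row


def _trend_row(strain, feature, reduced: pd.Series, values: pd.Series) -> dict:
    levels = np.sort(values.unique())
    table = np.array(
        [
            [int(((values == lv) & (~reduced)).sum()),
             int(((values == lv) & reduced).sum())]
            for lv in levels
        ]
    )
    row = {
        "strain": strain,
        "feature": feature,
        "test": "ordinal_trend",
        "table": table.tolist(),
        "p_value": pd.NA,
        "note": "",
    }
    if len(levels) < 2:
        row["note"] = "feature constant"
    elif reduced.nunique() < 2:
        row["note"] = "flag constant"
    else:
        res = sm.stats.Table(table).test_ordinal_association(
            row_scores=np.asarray(levels, dtype=float)
        )
        row["p_value"] = float(res.pvalue)
    return row
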