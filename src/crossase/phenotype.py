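"""Phenotype contrasts between reciprocal-cross F1 groups.

Traits (body mass, fat mass, lean mass, liver mass, liver
triglyceride/protein, blood glucose) are adjusted for litter size —
residuals from a one-covariate least-squares fit of trait on litter
size, re-centred on the grand mean — before a two-group linear-model
test of the direction-of-cross effect within each sex (and fostering)
stratum.  Blood glucose and liver triglycerides pass through
unadjusted by default, matching the study's treatment.  Group
summaries report mean ± SD, the F-test p-value (identical to a
two-sided t-test for two groups) and the matBFMI/patBFMI fold ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_UNADJUSTED",
    "litter_adjust",
    "group_contrast",
    "fold_ratio",
    "grubbs_outliers",
]

#: traits the study did not adjust for litter size
DEFAULT_UNADJUSTED = ("blood_glucose", "liver_tg_protein")

DIRECTION_COL = "direction"       # values "matBFMI" / "patBFMI"


def litter_adjust(
    table: pd.DataFrame,
    traits,
    litter_col: str = "litter_size",
    skip=DEFAULT_UNADJUSTED,
) -> pd.DataFrame:
    """Adjust traits for litter size across the full cohort.

    adjusted = grand mean + residual of OLS(trait ~ litter size).
    Constant litter size gives slope 0, i.e. the identity.  Traits in
    ``skip`` are returned unchanged.  Rows with a missing trait value
    keep NaN.
    """
    if table[litter_col].isna().any():
        raise ValueError("litter size must be present for all animals")
    out = table.copy()
    x = table[litter_col].to_numpy(float)
    for trait in traits:
        if trait in skip:
            continue
        y = table[trait].to_numpy(float)
        ok = ~np.isnan(y)
        xc = x[ok] - x[ok].mean()
        denom = (xc ** 2).sum()
        slope = 0.0 if denom == 0 else float((xc * (y[ok] - y[ok].mean())).sum() / denom)
        adj = np.full_like(y, np.nan)
        adj[ok] = y[ok].mean() + (y[ok] - (y[ok].mean() + slope * xc))
        out[trait] = adj
    return out


def group_contrast(
    table: pd.DataFrame,
    trait: str,
    strata=("sex",),
) -> pd.DataFrame:
    """Two-group linear-model contrast of matBFMI vs patBFMI per stratum.

    Within each stratum (default: per sex), the direction-of-cross
    effect is tested with a one-way ANOVA F-test on the (already
    adjusted) trait values — for two groups the same p as a two-sided
    pooled t-test.  Strata with fewer than two animals in either group
    get p = NaN, flagged underpowered.
    """
    rows = []
    strata = list(strata)
    grouped = table.groupby(strata) if strata else [((), table)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        mat = sub.loc[sub[DIRECTION_COL] == "matBFMI", trait].dropna().to_numpy(float)
        pat = sub.loc[sub[DIRECTION_COL] == "patBFMI", trait].dropna().to_numpy(float)
        if len(mat) < 2 or len(pat) < 2:
            p, f = float("nan"), float("nan")
        elif np.array_equal(np.sort(mat), np.sort(pat)):
            p, f = 1.0, 0.0
        else:
            f, p = stats.f_oneway(mat, pat)
        rows.append(
            {
                **dict(zip(strata, key)),
                "trait": trait,
                "mean_mat": mat.mean() if len(mat) else float("nan"),
                "sd_mat": mat.std(ddof=1) if len(mat) > 1 else float("nan"),
                "n_mat": len(mat),
                "mean_pat": pat.mean() if len(pat) else float("nan"),
                "sd_pat": pat.std(ddof=1) if len(pat) > 1 else float("nan"),
                "n_pat": len(pat),
                "f_stat": float(f),
                "p_value": float(p),
                "fold_ratio": fold_ratio(
                    mat.mean() if len(mat) else float("nan"),
                    pat.mean() if len(pat) else float("nan"),
                ),
                "underpowered": len(mat) < 2 or len(pat) < 2,
            }
        )
    return pd.DataFrame(rows)


def fold_ratio(mean_mat: float, mean_pat: float) -> float:
    """matBFMI / patBFMI ratio of (adjusted) group means; NaN when the
    denominator is zero or missing.  Reported to 2 decimals in outputs."""
    if not np.isfinite(mean_pat) or mean_pat == 0:
        return float("nan")
    return float(mean_mat) / float(mean_pat)


def grubbs_outliers(values, alpha: float = 0.05) -> np.ndarray:
    """Indices of outliers by iterated two-sided Grubbs' test.

    Off by default in the pipeline; one observation (the most extreme)
    is tested and removed per iteration until no rejection.
    """
    x = np.asarray(values, dtype=float)
    idx = np.arange(len(x))
    out = []
    while len(x) >= 3:
        mean, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - mean)
        i = int(dev.argmax())
        g = dev[i] / sd
        n = len(x)
        t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        if g <= g_crit:
            break
        out.append(int(idx[i]))
        x = np.delete(x, i)
        idx = np.delete(idx, i)
    return np.array(sorted(out), dtype=int)
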