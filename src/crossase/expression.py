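"""Expression normalisation, differential expression and gene-set ORA.

The expression arm follows the study's processing order: quantile
normalisation of raw gene counts across samples, RPKM with library size
taken from the layer being normalised, an ln(n+1) transform to damp
extreme values, and per-gene two-sided t-tests between the two
reciprocal F1 groups (no multiple-testing correction at n = 3 per
group).  The fold change reported alongside is the ratio of the group
means *on the log layer* (matBFMI / patBFMI) — the convention the
study's tables use.  Differentially expressed genes feed a generic
upper-tail hypergeometric overrepresentation test against user-supplied
gene sets with Benjamini–Hochberg correction across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import GROUP_MAT, GROUP_PAT

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize",
    "rpkm",
    "log_transform",
    "fold_change",
    "de_test",
    "de_filter",
    "ora_hypergeometric",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples counts with lengths and derived layers."""

    counts: pd.DataFrame
    lengths: pd.Series
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        bad = self.lengths.isna() | (self.lengths <= 0)
        if bad.any():
            warnings.warn(
                f"excluding {int(bad.sum())} gene(s) with missing or non-positive length"
            )
            self.counts = self.counts.loc[~bad]
            self.lengths = self.lengths.loc[~bad]
        self.layers: dict[str, pd.DataFrame] = {"raw": self.counts}

    def normalize(self) -> "ExpressionMatrix":
        """Populate quantile-normalised, RPKM and log layers in order."""
        qn = quantile_normalize(self.counts)
        self.layers["quantile"] = qn
        self.layers["rpkm"] = rpkm(qn, self.lengths)
        self.layers["log"] = log_transform(self.layers["rpkm"])
        return self


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution
    of cross-sample means of sorted values; rank ties receive the mean of
    their reference values."""
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalisation with a single sample is the identity")
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties within a column share the mean of their reference slots
        out[:, j] = (
            pd.Series(assigned).groupby(x[:, j]).transform("mean").to_numpy()
        )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rpkm(matrix: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    value = count * 1e9 / (library_size * gene_length), with the library
    size the column sum of the layer passed in.
    """
    lengths = lengths.reindex(matrix.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all genes need a positive length")
    lib = matrix.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return matrix.mul(1e9).div(lib, axis=1).div(lengths, axis=0)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ln(value + 1)."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative values")
    return np.log1p(matrix)


def fold_change(mean_log_mat: float, mean_log_pat: float) -> float:
    """Ratio of group means on the log layer, matBFMI over patBFMI.

    NaN when the denominator is zero (flagged undefined downstream).
    """
    if mean_log_pat == 0:
        return float("nan")
    return mean_log_mat / mean_log_pat


def de_test(
    log_matrix: pd.DataFrame,
    sample_groups: dict[str, str],
    rpkm_matrix: pd.DataFrame | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided t-test between the reciprocal F1 groups.

    Operates on the log layer; Welch (unequal variance) by default with
    a pooled-variance option.  P-values are *not* corrected for multiple
    testing.  Degenerate genes (zero variance in both groups) get p = 1
    at equal means and p = 0 flagged ``degenerate`` otherwise.  When an
    RPKM layer is supplied its group means are attached for filtering.
    """
    mat_cols = [s for s in log_matrix.columns if sample_groups.get(s) == GROUP_MAT]
    pat_cols = [s for s in log_matrix.columns if sample_groups.get(s) == GROUP_PAT]
    if len(mat_cols) < 2 or len(pat_cols) < 2:
        raise ValueError("need at least two samples per F1 group")
    a = log_matrix[mat_cols].to_numpy(float)
    b = log_matrix[pat_cols].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger scipy's precision-loss warning; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    mean_mat, mean_pat = a.mean(axis=1), b.mean(axis=1)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = mean_mat == mean_pat
    p = np.where(zero_var & equal_means, 1.0, p)
    degenerate = zero_var & ~equal_means
    p = np.where(degenerate, 0.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        fch = np.where(mean_pat != 0, mean_mat / mean_pat, np.nan)
    out = pd.DataFrame(
        {
            "gene": log_matrix.index,
            "mean_log_mat": mean_mat,
            "mean_log_pat": mean_pat,
            "fold_change": fch,
            "p_value": p,
            "degenerate": degenerate,
        }
    ).set_index("gene")
    if rpkm_matrix is not None:
        out["rpkm_mat"] = rpkm_matrix[mat_cols].mean(axis=1)
        out["rpkm_pat"] = rpkm_matrix[pat_cols].mean(axis=1)
    return out


def de_filter(
    records: pd.DataFrame,
    p_max: float = 0.05,
    min_rpkm: float = 0.5,
    min_fch_diff: float = 0.20,
) -> pd.DataFrame:
    """Apply the study's DE filter: p < ``p_max``, mean RPKM above
    ``min_rpkm`` in at least one F1 group, and an expression difference
    of at least ``min_fch_diff`` (20%) in either direction.

    The 20% rule is ratio-wise: max(Fch, 1/Fch) >= 1 + ``min_fch_diff``,
    so a down-regulated gene at Fch 0.83 (1/0.83 = 1.20) passes just as
    an up-regulated one at 1.20 does.
    """
    required = {"p_value", "fold_change", "rpkm_mat", "rpkm_pat"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    fch = records["fold_change"]
    with np.errstate(divide="ignore"):
        ratio = np.maximum(fch, 1.0 / fch)
    keep = (
        (records["p_value"] < p_max)
        & (records[["rpkm_mat", "rpkm_pat"]].max(axis=1) > min_rpkm)
        & (ratio >= 1.0 + min_fch_diff)
        & fch.notna()
    )
    out = records.copy()
    out["passes_filter"] = keep
    return out.loc[keep]


def ora_hypergeometric(
    de_genes, universe, gene_sets: dict[str, set]
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of ``de_genes`` in
    each gene set, BH-corrected across sets.

    p = P(X >= overlap) with population |universe|, successes
    |set ∩ universe| and draws |de_genes|.  Sets are intersected with
    the universe first; de_genes must be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(members & de)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(de)))
        rows.append(
            {"gene_set": name, "overlap": overlap, "set_size": len(members),
             "n_de": len(de), "n_universe": len(universe), "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out
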