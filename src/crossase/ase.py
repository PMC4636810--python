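"""Allele-specific expression (ASE) cascade for reciprocal F1 crosses.

Given per-sample stranded allele counts (DP4: ref-forward, ref-reverse,
alt-forward, alt-reverse) at SNP sites across two parental inbred
strains and two reciprocal F1 groups, this module

1. selects *informative* sites — parental strains homozygous for
   different alleles, so every F1 read is assignable to a parental
   haplotype — and re-anchors the alternative allele to the BFMI allele;
2. applies population-coverage, per-individual quality and within-group
   consistency filters;
3. scores each F1 individual with a direction-signed square-root
   goodness-of-fit statistic,

   .. math:: s = \\mathrm{sign}(\\hat p - 1/2)\\,\\sqrt{\\chi^2},
      \\qquad \\chi^2 = \\frac{(\\mathrm{ref} - d/2)^2 + (\\mathrm{alt} - d/2)^2}{d/2}

   (algebraically :math:`s = (\\mathrm{alt}-\\mathrm{ref})/\\sqrt d`),
   sums the signed scores within each F1 cross direction, and takes the
   matBFMI − patBFMI difference per SNP;
4. calibrates a 5% false-discovery threshold on |difference| by
   permuting the per-individual scores into pseudo-groups.

The square-root transform caps the leverage any single individual with
an extreme allelic deviation can exert on the group sum; signing about a
50:50 ratio makes consistent imbalance in opposite directions across the
two cross directions (the imprinting signature) add up rather than
cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .design import GROUP_MAT, GROUP_PAT, GROUP_PARENTAL_B6N, GROUP_PARENTAL_BFMI

__all__ = [
    "SnpCountData",
    "FilterTrace",
    "AseParams",
    "select_informative_sites",
    "population_coverage_filter",
    "individual_quality_filter",
    "allele_ratio",
    "group_consistency_filter",
    "signed_sqrt_chi2",
    "group_difference_score",
    "permutation_fdr",
    "classify_parental_expression",
    "run_ase",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SnpCountData:
    """Vectorised collection of SNP observations across samples.

    ``dp4`` has shape (n_snps, n_samples, 4) with the samtools DP4
    layout (ref-fwd, ref-rev, alt-fwd, alt-rev); ``qual`` is the
    Phred-scaled call quality per site and sample; ``missing`` flags
    absent calls.  Coordinates are 1-based (VCF convention).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    dp4: np.ndarray
    qual: np.ndarray
    missing: np.ndarray
    gene_id: np.ndarray | None = None
    snp_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, s = len(self.pos), len(self.samples)
        if self.dp4.shape != (n, s, 4):
            raise ValueError(f"dp4 shape {self.dp4.shape} != ({n}, {s}, 4)")
        if (self.dp4 < 0).any():
            raise ValueError("negative allele counts")
        if n and (np.asarray(self.pos) < 1).any():
            raise ValueError("positions are 1-based; got pos < 1")
        if self.snp_id is None:
            self.snp_id = np.array(
                [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def ref_depth(self) -> np.ndarray:
        return self.dp4[:, :, 0] + self.dp4[:, :, 1]

    def alt_depth(self) -> np.ndarray:
        return self.dp4[:, :, 2] + self.dp4[:, :, 3]

    def depth(self) -> np.ndarray:
        return self.dp4.sum(axis=2)

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"sample {exc} not present in count data") from exc

    def subset(self, keep: np.ndarray) -> "SnpCountData":
        return SnpCountData(
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
            samples=list(self.samples),
            dp4=self.dp4[keep],
            qual=self.qual[keep],
            missing=self.missing[keep],
            gene_id=None if self.gene_id is None else self.gene_id[keep],
            snp_id=self.snp_id[keep],
        )


@dataclass
class FilterTrace:
    """Per-stage site accounting of the filter cascade."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, reasons: dict | None = None) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: sites out ({n_out}) exceed sites in ({n_in})")
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out),
             "reasons": dict(reasons or {})}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s["stage"], "n_in": s["n_in"], "n_out": s["n_out"],
             "reasons": ";".join(f"{k}={v}" for k, v in s["reasons"].items())}
            for s in self.stages
        ]
        return pd.DataFrame(rows, columns=["stage", "n_in", "n_out", "reasons"])


@dataclass(frozen=True)
class AseParams:
    """Thresholds of the ASE cascade; defaults are the study's values."""

    min_pop_reads: int = 100
    min_phred: float = 50.0
    min_hq_reads: int = 5
    max_group_sd: float = 0.20
    alpha: float = 0.05
    n_perm: int = 0          # 0 -> exhaustive 3+3 partitions
    null_method: str = "partition"  # or "pool": shuffle group scores across SNPs
    seed: int = 0


# ---------------------------------------------------------------------------
# filter cascade


def _strain_sample_names(sample_map: pd.DataFrame, group: str) -> list[str]:
    names = sample_map.loc[sample_map["group"] == group, "sample"].tolist()
    if not names:
        raise ValueError(f"no samples declared for group {group!r} in the sample map")
    return names


def select_informative_sites(
    data: SnpCountData, sample_map: pd.DataFrame, trace: FilterTrace | None = None
) -> tuple[SnpCountData, FilterTrace]:
    """Keep sites where the parental strains are homozygous for different
    alleles, and re-anchor the alternative allele to the BFMI allele.

    All parental samples must be non-missing with nonzero depth.  After
    this step ``alt`` is the BFMI allele at every retained site, so F1
    alt/(ref+alt) ratios read directly as the BFMI-allele fraction.
    """
    trace = trace or FilterTrace()
    bfmi = data.sample_index(_strain_sample_names(sample_map, GROUP_PARENTAL_BFMI))
    b6n = data.sample_index(_strain_sample_names(sample_map, GROUP_PARENTAL_B6N))
    parental = np.concatenate([bfmi, b6n])

    ref_d, alt_d = data.ref_depth(), data.alt_depth()
    present = ~data.missing[:, parental] & (ref_d[:, parental] + alt_d[:, parental] > 0)
    all_present = present.all(axis=1)

    def _hom_state(idx: np.ndarray) -> np.ndarray:
        # +1 all-alt-homozygous, -1 all-ref-homozygous, 0 otherwise
        all_alt = (ref_d[:, idx] == 0).all(axis=1) & (alt_d[:, idx] > 0).all(axis=1)
        all_ref = (alt_d[:, idx] == 0).all(axis=1) & (ref_d[:, idx] > 0).all(axis=1)
        return np.where(all_alt, 1, np.where(all_ref, -1, 0))

    bfmi_state, b6n_state = _hom_state(bfmi), _hom_state(b6n)
    informative = all_present & (bfmi_state != 0) & (b6n_state != 0) & (bfmi_state != b6n_state)

    reasons = {
        "parental_missing": int((~all_present).sum()),
        "not_homozygous": int((all_present & ((bfmi_state == 0) | (b6n_state == 0))).sum()),
        "no_strain_difference": int(
            (all_present & (bfmi_state != 0) & (bfmi_state == b6n_state)).sum()
        ),
    }
    out = data.subset(informative)

    # re-anchor: where BFMI is ref-homozygous, swap ref<->alt so alt = BFMI allele
    flip = (bfmi_state == -1)[informative]
    if flip.any():
        out.dp4[flip] = out.dp4[flip][:, :, [2, 3, 0, 1]]
        out.ref[flip], out.alt[flip] = out.alt[flip].copy(), out.ref[flip].copy()
    trace.add("informative", data.n_snps, out.n_snps, reasons)
    return out, trace


def population_coverage_filter(
    data: SnpCountData, min_total: int = 100, trace: FilterTrace | None = None
) -> tuple[SnpCountData, FilterTrace]:
    """Keep sites with at least ``min_total`` reads summed over *all*
    samples (population coverage, boundary inclusive)."""
    trace = trace or FilterTrace()
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    total = data.depth().sum(axis=1)
    keep = total >= min_total
    out = data.subset(keep)
    trace.add("population_coverage", data.n_snps, out.n_snps,
              {"below_min_reads": int((~keep).sum())})
    return out, trace


def individual_quality_filter(
    data: SnpCountData,
    sample_map: pd.DataFrame,
    min_phred: float = 50.0,
    min_hq_reads: int = 5,
    trace: FilterTrace | None = None,
) -> tuple[SnpCountData, FilterTrace]:
    """Mask low-confidence per-sample observations and drop sites whose
    F1 groups are incomplete.

    A sample's call at a site is treated as missing when its Phred
    quality is below ``min_phred`` or its high-quality depth is below
    ``min_hq_reads`` (both strict, as stated: "< 50" and "less than 5").
    A site is then dropped when *any* F1 individual is masked: group
    score sums over unequal numbers of individuals are not comparable.
    """
    trace = trace or FilterTrace()
    masked = data.missing | (data.qual < min_phred) | (data.depth() < min_hq_reads)
    f1 = data.sample_index(
        _strain_sample_names(sample_map, GROUP_MAT)
        + _strain_sample_names(sample_map, GROUP_PAT)
    )
    keep = ~masked[:, f1].any(axis=1)
    out = data.subset(keep)
    out.missing = out.missing | masked[keep]
    trace.add("individual_quality", data.n_snps, out.n_snps,
              {"f1_sample_masked": int((~keep).sum())})
    return out, trace


def allele_ratio(dp4) -> float:
    """alt/(ref+alt) from one DP4 tuple; NaN at zero depth."""
    rf, rr, af, ar = dp4
    d = rf + rr + af + ar
    if d <= 0:
        return float("nan")
    return (af + ar) / d


def _ratio_matrix(data: SnpCountData) -> np.ndarray:
    d = data.depth().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = data.alt_depth() / d
    r[d == 0] = np.nan
    return r


def group_consistency_filter(
    data: SnpCountData,
    sample_map: pd.DataFrame,
    max_sd: float = 0.20,
    trace: FilterTrace | None = None,
) -> tuple[SnpCountData, FilterTrace]:
    """Drop sites whose alt/(ref+alt) ratios disagree within an F1 group.

    The sample (n−1) standard deviation of the ratios across the
    individuals of either F1 group exceeding ``max_sd`` (ratio scale;
    0.20 ≡ 20 percentage points) removes the site.  Sites with fewer
    than two unmasked individuals in a group are dropped as
    "insufficient_replicates".
    """
    trace = trace or FilterTrace()
    ratios = _ratio_matrix(data)
    ratios[data.missing] = np.nan
    keep = np.ones(data.n_snps, dtype=bool)
    reasons = {"high_group_sd": 0, "insufficient_replicates": 0}
    for group in (GROUP_MAT, GROUP_PAT):
        idx = data.sample_index(_strain_sample_names(sample_map, group))
        r = ratios[:, idx]
        n_ok = (~np.isnan(r)).sum(axis=1)
        too_few = keep & (n_ok < 2)
        reasons["insufficient_replicates"] += int(too_few.sum())
        keep &= ~too_few
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(r, axis=1, ddof=1)
        high = keep & (n_ok >= 2) & (sd > max_sd)
        reasons["high_group_sd"] += int(high.sum())
        keep &= ~high
    out = data.subset(keep)
    trace.add("group_consistency", data.n_snps, out.n_snps, reasons)
    return out, trace


# ---------------------------------------------------------------------------
# scoring


def signed_sqrt_chi2(dp4) -> float:
    """Direction-signed square-root goodness-of-fit score for one sample.

    χ² tests the observed (ref, alt) counts against the balanced d/2,
    d/2 expectation; the score carries the sign of (ratio − 0.5) and
    equals (alt − ref)/√d in closed form.  NaN at zero depth.
    """
    rf, rr, af, ar = dp4
    ref, alt = rf + rr, af + ar
    d = ref + alt
    if d <= 0:
        return float("nan")
    return (alt - ref) / math.sqrt(d)


def _score_matrix(data: SnpCountData) -> np.ndarray:
    ref, alt = data.ref_depth().astype(float), data.alt_depth().astype(float)
    d = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (alt - ref) / np.sqrt(d)
    s[d == 0] = np.nan
    return s


def group_difference_score(
    scores: pd.DataFrame, group_of: dict[str, str]
) -> pd.DataFrame:
    """Sum per-individual signed scores within each F1 cross direction
    and take the matBFMI − patBFMI difference per SNP.

    ``scores`` is a SNP × sample frame of signed √χ² values; columns are
    mapped to groups via ``group_of``.
    """
    unknown = {group_of[c] for c in scores.columns} - {GROUP_MAT, GROUP_PAT}
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    mat_cols = [c for c in scores.columns if group_of[c] == GROUP_MAT]
    pat_cols = [c for c in scores.columns if group_of[c] == GROUP_PAT]
    if not mat_cols or not pat_cols:
        raise ValueError("both F1 groups must be represented")
    out = pd.DataFrame(index=scores.index)
    out["group_sum_mat"] = scores[mat_cols].sum(axis=1)
    out["group_sum_pat"] = scores[pat_cols].sum(axis=1)
    out["diff_score"] = out["group_sum_mat"] - out["group_sum_pat"]
    return out


def _null_diffs_partition(
    scores: np.ndarray,
    mat_idx: list[int],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null difference scores from pseudo-group reassignments.

    Exhaustive over the informative partitions of the individuals into
    pseudo-groups of the original sizes when ``n_perm`` is 0 or at least
    as large; otherwise a seeded random sample of them.  The identity
    partition and its label swap are excluded: the difference score is
    antisymmetric under the group swap, so those two reproduce
    ±observed at every SNP and would bound the achievable FDR below by
    2/n_partitions regardless of signal.  Returns (n_snps, n_partitions).
    """
    n = scores.shape[1]
    observed = frozenset(mat_idx)
    complement = frozenset(range(n)) - observed
    parts = [
        p for p in combinations(range(n), len(mat_idx))
        if frozenset(p) not in (observed, complement)
    ]
    if n_perm and n_perm < len(parts):
        idx = rng.choice(len(parts), size=n_perm, replace=True)
        parts = [parts[i] for i in idx]
    total = scores.sum(axis=1, keepdims=True)
    cols = [2.0 * scores[:, list(p)].sum(axis=1, keepdims=True) - total for p in parts]
    return np.hstack(cols)


def _null_diffs_pool(
    diff: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null by shuffling observed group-difference scores across SNPs
    with random sign flips (the "permute group scores" reading)."""
    n_perm = n_perm or 1000
    out = np.empty((len(diff), n_perm))
    for j in range(n_perm):
        perm = rng.permutation(diff)
        out[:, j] = perm * rng.choice([-1.0, 1.0], size=len(diff))
    return out


def permutation_fdr(
    scores: pd.DataFrame,
    group_of: dict[str, str],
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: int = 0,
    null_method: str = "partition",
) -> tuple[float, pd.DataFrame]:
    """Empirical-FDR threshold on |matBFMI − patBFMI difference scores|.

    Null difference scores are generated per SNP by reassigning the
    per-individual signed scores to two pseudo-groups of the original
    sizes (all partitions when exhaustive, a seeded random sample
    otherwise) and pooled across SNPs.  The threshold t* is the smallest
    observed |difference| at which

        FDR(t) = mean-per-permutation #{|null| >= t} / #{|observed| >= t}

    drops to ``alpha`` or below; sites with |difference| >= t* are
    flagged (ties inclusive).  If no observed score achieves the bound
    the threshold is +inf and nothing is flagged.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rec = group_difference_score(scores, group_of)
    obs = np.abs(rec["diff_score"].to_numpy())
    rng = np.random.default_rng(seed)
    mat_idx = [j for j, c in enumerate(scores.columns) if group_of[c] == GROUP_MAT]
    if null_method == "partition":
        null = _null_diffs_partition(scores.to_numpy(float), mat_idx, n_perm, rng)
    elif null_method == "pool":
        null = _null_diffs_pool(rec["diff_score"].to_numpy(), n_perm, rng)
    else:
        raise ValueError(f"unknown null_method {null_method!r}")
    n_part = null.shape[1]
    null_abs = np.sort(np.abs(null).ravel())

    threshold = math.inf
    if len(obs):
        cand = np.sort(np.unique(obs))
        # observed count >= t and mean null count >= t, evaluated at each candidate
        n_obs_ge = len(obs) - np.searchsorted(np.sort(obs), cand, side="left")
        n_null_ge = (len(null_abs) - np.searchsorted(null_abs, cand, side="left")) / n_part
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = n_null_ge / n_obs_ge
        ok = np.nonzero(fdr <= alpha)[0]
        if len(ok):
            threshold = float(cand[ok[0]])
    rec = rec.copy()
    rec["passes_fdr"] = obs >= threshold if math.isfinite(threshold) else False
    rec["fdr_threshold"] = threshold
    return threshold, rec


def classify_parental_expression(
    records: pd.DataFrame,
    mono_high: float = 0.90,
    mono_low: float = 0.10,
) -> pd.DataFrame:
    """Summarise flagged SNPs per gene and label the imbalance pattern.

    ``records`` must carry columns ``gene``, ``passes_fdr``,
    ``ratio_mat`` and ``ratio_pat`` (mean BFMI-allele fraction per F1
    group).  A gene whose mean BFMI-allele fraction is at least
    ``mono_high`` in the patBFMI group (BFMI father) and at most
    ``mono_low`` in the matBFMI group expresses the paternal allele;
    the mirror pattern expresses the maternal allele; anything else
    flagged is a partial imbalance.  Genes without flagged SNPs are
    absent from the summary.
    """
    flagged = records.loc[records["passes_fdr"] & records["gene"].notna()]
    if not len(flagged):
        return pd.DataFrame(
            columns=["gene", "n_snps", "pct_alt_mat", "pct_alt_pat", "pct_diff", "label"]
        )
    rows = []
    for gene, sub in flagged.groupby("gene", sort=True):
        mat = float(sub["ratio_mat"].mean()) * 100.0
        pat = float(sub["ratio_pat"].mean()) * 100.0
        if pat >= mono_high * 100 and mat <= mono_low * 100:
            label = "paternal-allele-expressed"
        elif mat >= mono_high * 100 and pat <= mono_low * 100:
            label = "maternal-allele-expressed"
        else:
            label = "partial imbalance"
        rows.append(
            {"gene": gene, "n_snps": len(sub), "pct_alt_mat": mat,
             "pct_alt_pat": pat, "pct_diff": pat - mat, "label": label}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def run_ase(
    data: SnpCountData, sample_map: pd.DataFrame, params: AseParams = AseParams()
) -> tuple[pd.DataFrame, pd.DataFrame, FilterTrace]:
    """Run the full cascade; returns (per-SNP scores, per-gene summary, trace)."""
    trace = FilterTrace()
    data, _ = select_informative_sites(data, sample_map, trace)
    data, _ = population_coverage_filter(data, params.min_pop_reads, trace)
    data, _ = individual_quality_filter(
        data, sample_map, params.min_phred, params.min_hq_reads, trace
    )
    data, _ = group_consistency_filter(data, sample_map, params.max_group_sd, trace)

    f1_samples = (
        sample_map.loc[sample_map["group"].isin([GROUP_MAT, GROUP_PAT])]
        .set_index("sample")["group"]
        .to_dict()
    )
    cols = [s for s in data.samples if s in f1_samples]
    idx = data.sample_index(cols)
    result = pd.DataFrame(
        {
            "snp": data.snp_id,
            "chrom": data.chrom,
            "pos": data.pos,
            "ref": data.ref,
            "alt": data.alt,
            "gene": data.gene_id if data.gene_id is not None else [None] * data.n_snps,
        }
    )
    if data.n_snps == 0:
        empty = result.assign(
            group_sum_mat=[], group_sum_pat=[], diff_score=[],
            passes_fdr=[], fdr_threshold=[], ratio_mat=[], ratio_pat=[],
        )
        trace.add("ase_fdr", 0, 0)
        return empty, classify_parental_expression(empty), trace

    ratios = _ratio_matrix(data)[:, idx]
    sc = _score_matrix(data)[:, idx]
    score_df = pd.DataFrame(sc, columns=cols)
    for j, s in enumerate(cols):
        result[f"ratio_{s}"] = ratios[:, j]
        result[f"score_{s}"] = sc[:, j]
    thr, rec = permutation_fdr(
        score_df, f1_samples, alpha=params.alpha, n_perm=params.n_perm,
        seed=params.seed, null_method=params.null_method,
    )
    result = pd.concat([result, rec.set_index(result.index)], axis=1)
    mat_j = [j for j, s in enumerate(cols) if f1_samples[s] == GROUP_MAT]
    pat_j = [j for j, s in enumerate(cols) if f1_samples[s] == GROUP_PAT]
    result["ratio_mat"] = ratios[:, mat_j].mean(axis=1)
    result["ratio_pat"] = ratios[:, pat_j].mean(axis=1)
    trace.add("ase_fdr", data.n_snps, int(result["passes_fdr"].sum()))
    genes = classify_parental_expression(result)
    return result, genes, trace
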