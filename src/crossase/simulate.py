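"""Synthetic reciprocal-cross datasets with planted signal.

Generators emulate the statistical structure the downstream analyses
assume, so every stage is testable without the (unreleased) raw
sequencing data:

* allele counts at informative SNPs — negative-binomial total depth,
  beta-binomially overdispersed alt counts in the F1s, homozygous
  parental strains, counts split across strands;
* parent-of-origin imprinting — the expected BFMI-allele fraction in
  the two F1 groups flips with cross direction and sums to 1;
* a gene-count matrix with planted multiplicative group differences;
* promoter sequences with embedded motif consensus occurrences;
* animal phenotypes with a litter-size confounder.

Every generator is a pure function of its parameters and seed; ground
truth is returned as a :class:`~crossase.design.SimTruth` sidecar,
never embedded in the emitted data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ase import SnpCountData
from .design import (
    GROUP_MAT,
    GROUP_PAT,
    GROUP_PARENTAL_B6N,
    GROUP_PARENTAL_BFMI,
    CrossDesign,
    SimTruth,
)
from .tfbs import Pwm

__all__ = [
    "beta_binomial",
    "simulate_allele_counts",
    "plant_imprinting",
    "simulate_expression",
    "simulate_promoters",
    "simulate_phenotypes",
]


def beta_binomial(
    rng: np.random.Generator, n, mu, rho: float, size=None
) -> np.ndarray:
    """Beta-binomial draws with mean n·mu and intra-class correlation rho.

    Variance is n·mu·(1−mu)·(1 + (n−1)·rho); rho = 0 degenerates to the
    plain binomial.  mu exactly 0 or 1 yields deterministic counts.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    n = np.asarray(n)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), n.shape if size is None else size)
    if rho == 0.0:
        return rng.binomial(n, mu, size=size)
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    p = np.empty_like(mu)
    interior = (mu > 0) & (mu < 1)
    p[~interior] = mu[~interior]
    if interior.any():
        p[interior] = rng.beta(a[interior], b[interior])
    return rng.binomial(n, p, size=size)


def _negbin_depth(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """Negative-binomial total depth with the given mean; ``dispersion``
    is the NB size parameter (larger = closer to Poisson)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_allele_counts(
    design: CrossDesign,
    n_snps: int,
    coverage_mean: float = 30.0,
    rho: float = 0.1,
    truth: SimTruth | None = None,
    coverage_min: int = 0,
    depth_dispersion: float = 10.0,
    base_quality: float = 99.0,
    snps_per_gene: int = 3,
    seed: int | None = None,
) -> tuple[SnpCountData, SimTruth]:
    """Simulate per-sample DP4 allele counts at informative SNP sites.

    All sites are informative by construction: the BFMI parentals are
    homozygous for the alternative allele, the B6N parentals for the
    reference.  F1 alt counts are beta-binomial with per-group mean
    ratio 0.5 except at sites planted in ``truth.ase_ratios``.  Counts
    are split between forward and reverse strand by a fair binomial.
    ``coverage_min`` floors the per-sample depth (shifted negative
    binomial), for designs that guarantee a minimum read depth.
    """
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    if coverage_min > coverage_mean:
        raise ValueError("coverage_min cannot exceed coverage_mean")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    truth = truth or SimTruth()
    truth.rho = rho
    rng = np.random.default_rng(design.seed if seed is None else seed)
    tab = design.sample_table()
    samples = tab["sample"].tolist()
    n_samples = len(samples)
    group = tab["group"].to_numpy()

    snp_ids = np.array([f"snp_{i:06d}" for i in range(n_snps)], dtype=object)
    chrom = np.array([f"chr{(i % 19) + 1}" for i in range(n_snps)], dtype=object)
    pos = np.array([1000 + 500 * (i // 19) for i in range(n_snps)], dtype=int) + (
        np.arange(n_snps) % 19
    )
    gene_id = np.array([f"gene_{i // snps_per_gene:05d}" for i in range(n_snps)], dtype=object)
    ref = np.array(["A"] * n_snps, dtype="<U1")
    alt = np.array(["G"] * n_snps, dtype="<U1")

    if coverage_min and coverage_mean > coverage_min:
        depth = coverage_min + _negbin_depth(
            rng, coverage_mean - coverage_min, depth_dispersion, (n_snps, n_samples)
        )
    elif coverage_min:
        depth = np.full((n_snps, n_samples), int(coverage_min))
    else:
        depth = _negbin_depth(rng, coverage_mean, depth_dispersion, (n_snps, n_samples))
    mu = np.full((n_snps, n_samples), 0.5)
    mu[:, group == GROUP_PARENTAL_BFMI] = 1.0
    mu[:, group == GROUP_PARENTAL_B6N] = 0.0
    planted = {s: r for s, r in truth.ase_ratios.items()}
    if planted:
        index = {s: i for i, s in enumerate(snp_ids)}
        for snp, ratios in planted.items():
            if snp not in index:
                raise KeyError(f"planted site {snp!r} is not among the simulated SNPs")
            i = index[snp]
            for g, r in ratios.items():
                mu[i, group == g] = r

    alt_count = beta_binomial(rng, depth, mu, rho)
    ref_count = depth - alt_count
    alt_fwd = rng.binomial(alt_count, 0.5)
    ref_fwd = rng.binomial(ref_count, 0.5)
    dp4 = np.stack(
        [ref_fwd, ref_count - ref_fwd, alt_fwd, alt_count - alt_fwd], axis=2
    ).astype(int)

    qual = np.full((n_snps, n_samples), float(base_quality))
    missing = depth == 0
    data = SnpCountData(
        chrom=chrom, pos=pos, ref=ref, alt=alt, samples=samples,
        dp4=dp4, qual=qual, missing=missing, gene_id=gene_id, snp_id=snp_ids,
    )
    return data, truth


def plant_imprinting(
    truth: SimTruth,
    snp_ids,
    expressed_parent: str = "paternal",
    expressed_fraction: float = 0.95,
    gene_of: dict[str, str] | None = None,
) -> SimTruth:
    """Plant parent-of-origin expression at the given SNP sites.

    For a paternally expressed locus the expressed allele comes from
    the father, so in the patBFMI cross (BFMI father) the BFMI(alt)
    allele fraction is ``expressed_fraction`` and in the matBFMI cross
    it is 1 − ``expressed_fraction``: the two group means always sum
    to 1.  Maternal expression mirrors this.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("snp_set must be non-empty")
    if expressed_parent not in ("paternal", "maternal"):
        raise ValueError("expressed_parent must be 'paternal' or 'maternal'")
    hi = float(expressed_fraction)
    if not 0.5 <= hi <= 1.0:
        raise ValueError("expressed_fraction must be in [0.5, 1]")
    for snp in snp_ids:
        if expressed_parent == "paternal":
            ratios = {GROUP_PAT: hi, GROUP_MAT: 1.0 - hi}
        else:
            ratios = {GROUP_PAT: 1.0 - hi, GROUP_MAT: hi}
        truth.ase_ratios[snp] = ratios
        if gene_of and snp in gene_of:
            truth.imprinted_genes[gene_of[snp]] = expressed_parent
    return truth


def simulate_expression(
    design: CrossDesign,
    n_genes: int,
    de_fraction: float = 0.05,
    fold_changes=(2.0,),
    truth: SimTruth | None = None,
    mean_log2_expression: float = 6.0,
    sd_log2_expression: float = 2.0,
    nb_dispersion: float = 20.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Simulate a gene × sample count matrix with planted DE genes.

    Counts are negative-binomial around log-normally distributed gene
    base means; a ``de_fraction`` of genes has its matBFMI group mean
    multiplied by a planted fold change (cycled from ``fold_changes``).
    Returns (counts, gene lengths in bp, truth).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if any(f <= 0 for f in np.atleast_1d(fold_changes)):
        raise ValueError("fold changes must be positive")
    truth = truth or SimTruth()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    tab = design.sample_table()
    samples = tab["sample"].tolist()
    group = tab["group"].to_numpy()
    genes = [f"gene_{i:05d}" for i in range(n_genes)]

    base = 2.0 ** rng.normal(mean_log2_expression, sd_log2_expression, size=n_genes)
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=genes, name="length")
    mean = np.tile(base[:, None], (1, len(samples)))
    n_de = int(round(de_fraction * n_genes))
    fcs = np.resize(np.atleast_1d(np.asarray(fold_changes, dtype=float)), n_de)
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    for i, fc in zip(de_idx, fcs):
        mean[i, group == GROUP_MAT] *= fc
        truth.de_genes[genes[i]] = float(fc)
    counts = rng.negative_binomial(
        nb_dispersion, nb_dispersion / (nb_dispersion + mean)
    )
    return (
        pd.DataFrame(counts, index=genes, columns=samples),
        lengths,
        truth,
    )


def simulate_promoters(
    n_genes: int,
    motif: Pwm,
    planted_set=(),
    region_len: int = 3000,
    composition=(0.25, 0.25, 0.25, 0.25),
    truth: SimTruth | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Random promoter sequences with motif consensus planted in a subset.

    Background bases are i.i.d. at ``composition``; each gene named in
    ``planted_set`` receives one embedded consensus occurrence at a
    recorded offset and strand.  Gene ids are ``gene_00000`` …; members
    of ``planted_set`` may be ids or integer indices.
    """
    if region_len < len(motif):
        raise ValueError("region shorter than the motif")
    truth = truth or SimTruth()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    planted = {g if isinstance(g, str) else genes[g] for g in planted_set}
    unknown = planted - set(genes)
    if unknown:
        raise KeyError(f"planted genes not simulated: {sorted(unknown)}")
    seqs = {}
    consensus = motif.consensus
    for g in genes:
        seq = rng.choice(bases, size=region_len, p=np.asarray(composition))
        if g in planted:
            off = int(rng.integers(0, region_len - len(motif) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = consensus if strand == "+" else consensus.translate(
                str.maketrans("ACGT", "TGCA"))[::-1]
            seq[off: off + len(motif)] = list(site)
            truth.motif_planted_genes.setdefault(g, []).append((off, strand))
        seqs[g] = "".join(seq)
    return seqs, truth


def simulate_phenotypes(
    design: CrossDesign,
    group_means: dict[str, dict[str, float]],
    litter_effect_slope: float = 0.3,
    noise_sd: float | dict[str, float] = 1.0,
    n_per_group: int = 12,
    litter_size_range: tuple[int, int] = (4, 11),
    fostering: str = "maternal",
    truth: SimTruth | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate animal phenotypes with a litter-size confounder.

    trait = group mean + slope · (litter size − mean litter size) +
    Gaussian noise.  ``group_means`` maps trait -> {"matBFMI": m,
    "patBFMI": m}; litter sizes are uniform over the observed breeding
    range (4–11 pups by default).
    """

    def _sd(trait: str) -> float:
        sd = noise_sd[trait] if isinstance(noise_sd, dict) else noise_sd
        if sd <= 0:
            raise ValueError("noise_sd must be positive")
        return float(sd)

    truth = truth or SimTruth()
    truth.litter_effect_slope = float(litter_effect_slope)
    truth.phenotype_group_means = {t: dict(g) for t, g in group_means.items()}
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lo, hi = litter_size_range
    rows = []
    for direction in ("matBFMI", "patBFMI"):
        for i in range(n_per_group):
            litter = int(rng.integers(lo, hi + 1))
            rows.append({"animal": f"{direction}_{i + 1}", "sex": "M",
                         "direction": direction, "fostering": fostering,
                         "litter_size": litter})
    table = pd.DataFrame(rows)
    centred = table["litter_size"] - table["litter_size"].mean()
    for trait, means in group_means.items():
        mu = table["direction"].map(means).to_numpy(float)
        table[trait] = (
            mu + litter_effect_slope * centred.to_numpy() +
            rng.normal(0.0, _sd(trait), size=len(table))
        )
    return table, truth
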