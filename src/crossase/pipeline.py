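"""Pipeline orchestration: config, stage execution, run manifests.

A run is described by a :class:`RunConfig` (loadable from YAML with
per-stage threshold overrides; every default equals the study's stated
value).  All randomness derives from one root seed via
``numpy.random.SeedSequence.spawn``-style offsets so stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .ase import AseParams, run_ase
from .design import GROUP_MAT, GROUP_PAT, CrossDesign, SimTruth
from .expression import ExpressionMatrix, de_filter, de_test, ora_hypergeometric
from .phenotype import DEFAULT_UNADJUSTED, group_contrast, litter_adjust
from .simulate import (
    plant_imprinting,
    simulate_allele_counts,
    simulate_expression,
    simulate_phenotypes,
    simulate_promoters,
)
from .tfbs import (
    ANDROGEN_ELEMENT_CONSENSUS,
    GeneRegion,
    build_pwm,
    count_hits,
    permutation_enrichment,
)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All stage thresholds; defaults are the published values."""

    out_dir: str = "crossase_out"
    seed: int = 0
    stages: tuple = ("simulate", "ase")
    # simulate
    n_snps: int = 2000
    coverage_mean: float = 30.0
    rho: float = 0.1
    n_f1_per_group: int = 3
    n_imprinted: int = 20
    imprint_fraction_expressed: float = 0.95
    # ase
    min_pop_reads: int = 100
    min_phred: float = 50.0
    min_hq_reads: int = 5
    max_group_sd: float = 0.20
    alpha: float = 0.05
    n_perm: int = 0
    null_method: str = "partition"
    # de / ora
    p_max: float = 0.05
    min_rpkm: float = 0.5
    min_fch_diff: float = 0.20
    # tfbs
    upstream: int = 2000
    downstream: int = 1000
    rel_threshold: float = 0.90
    tfbs_n_perm: int = 1000
    # pheno
    adjust_litter: bool = True
    traits: str | None = None      # comma-separated subset; default: all
    # inputs for analysis-only runs
    vcf: str | None = None
    sample_map: str | None = None
    counts: str | None = None
    gmt: str | None = None
    regions_fasta: str | None = None
    gene_set: str | None = None
    phenotypes: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    version: str = __version__
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    stage_summary: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``simulate`` writes the synthetic dataset into the output directory;
    analysis stages read either those files or the inputs named in the
    config.  Outputs: per-SNP score TSV, per-gene ASE summary, filter
    trace, DE/ORA tables, enrichment TSV, phenotype summary, plus a
    JSON manifest with config hash, input checksums and timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    cfg_path = out / "config.yaml"
    config.to_yaml(cfg_path)
    manifest.config_hash = _sha256(cfg_path)

    order = [s for s in ("simulate", "ase", "de", "ora", "tfbs", "pheno")
             if s in config.stages]
    design = CrossDesign(n_f1_per_group=config.n_f1_per_group, seed=config.seed)
    truth = SimTruth()

    for stage in order:
        t0 = time.perf_counter()
        if stage == "simulate":
            _stage_simulate(config, design, truth, out, manifest)
        elif stage == "ase":
            _stage_ase(config, out, manifest)
        elif stage == "de":
            _stage_de(config, out, manifest)
        elif stage == "ora":
            _stage_ora(config, out, manifest)
        elif stage == "tfbs":
            _stage_tfbs(config, out, manifest)
        elif stage == "pheno":
            _stage_pheno(config, out, manifest)
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)

    manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(config, design, truth, out, manifest) -> None:
    rng_seed = config.stage_seed("simulate")
    n_imp = min(config.n_imprinted, config.n_snps)
    if n_imp:
        ids = [f"snp_{i:06d}" for i in range(0, n_imp)]
        plant_imprinting(
            truth, ids, expressed_parent="paternal",
            expressed_fraction=config.imprint_fraction_expressed,
        )
    data, truth = simulate_allele_counts(
        design, config.n_snps, coverage_mean=config.coverage_mean,
        rho=config.rho, truth=truth, seed=rng_seed,
    )
    io.write_vcf(out / "simulated.vcf", data)
    design.sample_table().to_csv(out / "sample_map.tsv", sep="\t", index=False)
    counts, lengths, truth = simulate_expression(
        design, n_genes=500, truth=truth, seed=rng_seed + 1
    )
    io.write_counts(out / "counts.tsv", counts, lengths)
    pwm = build_pwm(ANDROGEN_ELEMENT_CONSENSUS["IR3"], name="IR3")
    seqs, truth = simulate_promoters(
        60, pwm, planted_set=range(15), truth=truth, seed=rng_seed + 2
    )
    io.write_fasta(out / "promoters.fa", seqs)
    pheno, truth = simulate_phenotypes(
        design,
        group_means={"fat_mass": {"matBFMI": 7.06, "patBFMI": 3.86}},
        truth=truth, seed=rng_seed + 3,
    )
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    truth.write_tsv(out / "truth.tsv")
    manifest.stage_summary["simulate"] = {
        "n_snps": config.n_snps, "n_planted_ase": len(truth.ase_ratios)
    }


def _stage_ase(config, out, manifest) -> None:
    vcf = config.vcf or out / "simulated.vcf"
    smap = config.sample_map or out / "sample_map.tsv"
    manifest.input_checksums["vcf"] = _sha256(vcf)
    data = io.read_vcf(vcf)
    sample_map = io.read_sample_map(smap)
    params = AseParams(
        min_pop_reads=config.min_pop_reads, min_phred=config.min_phred,
        min_hq_reads=config.min_hq_reads, max_group_sd=config.max_group_sd,
        alpha=config.alpha, n_perm=config.n_perm,
        null_method=config.null_method, seed=config.stage_seed("ase"),
    )
    scores, genes, trace = run_ase(data, sample_map, params)
    scores.to_csv(out / "ase_scores.tsv", sep="\t", index=False)
    genes.to_csv(out / "ase_genes.tsv", sep="\t", index=False)
    trace.to_frame().to_csv(out / "ase_filter_trace.tsv", sep="\t", index=False)
    manifest.stage_summary["ase"] = {
        "n_scored": int(len(scores)),
        "n_flagged": int(scores["passes_fdr"].sum()) if len(scores) else 0,
        "trace": [
            {k: s[k] for k in ("stage", "n_in", "n_out")} for s in trace.stages
        ],
    }


def _stage_de(config, out, manifest) -> None:
    counts_path = config.counts or out / "counts.tsv"
    smap = config.sample_map or out / "sample_map.tsv"
    counts, lengths = io.read_counts(counts_path)
    sample_map = io.read_sample_map(smap)
    groups = sample_map.set_index("sample")["group"].to_dict()
    em = ExpressionMatrix(counts, lengths, groups).normalize()
    records = de_test(em.layers["log"], groups, rpkm_matrix=em.layers["rpkm"])
    filtered = de_filter(records, config.p_max, config.min_rpkm, config.min_fch_diff)
    records.to_csv(out / "de_all.tsv", sep="\t")
    filtered.to_csv(out / "de_filtered.tsv", sep="\t")
    manifest.stage_summary["de"] = {
        "n_genes": int(len(records)), "n_de": int(len(filtered))
    }


def _stage_ora(config, out, manifest) -> None:
    if not config.gmt:
        raise ValueError("ora stage requires a GMT file (config key 'gmt')")
    filtered = pd.read_csv(out / "de_filtered.tsv", sep="\t")
    universe = pd.read_csv(out / "de_all.tsv", sep="\t")["gene"]
    res = ora_hypergeometric(filtered["gene"], universe, io.read_gmt(config.gmt))
    res.to_csv(out / "ora.tsv", sep="\t", index=False)
    manifest.stage_summary["ora"] = {"n_sets": int(len(res))}


def _stage_tfbs(config, out, manifest) -> None:
    fasta = config.regions_fasta or out / "promoters.fa"
    seqs = io.read_fasta(fasta)
    hits_frames = []
    enrich = []
    if config.gene_set:
        target = [l.strip() for l in open(config.gene_set) if l.strip()]
    else:  # default worked example: first quarter of the simulated genes
        target = sorted(seqs)[: max(1, len(seqs) // 4)]
    for name, consensus in ANDROGEN_ELEMENT_CONSENSUS.items():
        pwm = build_pwm(consensus, name=name)
        regions = [
            GeneRegion(g, tss=config.upstream + 1, strand="+", sequence=s)
            for g, s in seqs.items()
        ]
        hits = count_hits(pwm, regions, rel_threshold=config.rel_threshold)
        hits_frames.append(hits.rename(name))
        enrich.append(
            permutation_enrichment(
                hits, target, universe=list(seqs),
                n_perm=config.tfbs_n_perm, seed=config.stage_seed(f"tfbs:{name}"),
            )
        )
    pd.concat(hits_frames, axis=1).rename_axis("gene").to_csv(
        out / "tfbs_hits.tsv", sep="\t")
    pd.DataFrame(enrich).to_csv(out / "tfbs_enrichment.tsv", sep="\t", index=False)
    manifest.stage_summary["tfbs"] = {"n_motifs": len(enrich)}


def _stage_pheno(config, out, manifest) -> None:
    path = config.phenotypes or out / "phenotypes.tsv"
    table = pd.read_csv(path, sep="\t")
    traits = [c for c in table.columns
              if c not in ("animal", "sex", "direction", "fostering", "litter_size")]
    if config.traits:
        wanted = [t.strip() for t in config.traits.split(",")]
        missing = set(wanted) - set(traits)
        if missing:
            raise ValueError(f"traits not in phenotype table: {sorted(missing)}")
        traits = wanted
    if config.adjust_litter:
        adjusted = litter_adjust(table, traits, skip=DEFAULT_UNADJUSTED)
    else:
        adjusted = table
    summaries = pd.concat(
        [group_contrast(adjusted, t) for t in traits], ignore_index=True
    )
    summaries.to_csv(out / "phenotype_summary.tsv", sep="\t", index=False)
    manifest.stage_summary["pheno"] = {"n_traits": len(traits)}
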