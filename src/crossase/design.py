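"""Study design and simulation ground-truth containers.

The study layout modelled throughout the package is a reciprocal cross
between the obese Berlin Fat Mouse Inbred line (BFMI) and the lean
C57BL/6N (B6N) strain: liver RNA-seq of one male and one female of each
parental strain plus two groups of F1 males whose BFMI parent is the
mother (``F1_matBFMI``) or the father (``F1_patBFMI``).  Because the F1
autosomal genotypes are identical in both directions of the cross, any
expression difference between the groups implicates a parent-of-origin
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical group labels used across the package
GROUP_PARENTAL_BFMI = "parental_BFMI"
GROUP_PARENTAL_B6N = "parental_B6N"
GROUP_MAT = "F1_matBFMI"
GROUP_PAT = "F1_patBFMI"

F1_GROUPS = (GROUP_MAT, GROUP_PAT)
ALL_GROUPS = (GROUP_PARENTAL_BFMI, GROUP_PARENTAL_B6N, GROUP_MAT, GROUP_PAT)


@dataclass(frozen=True)
class CrossDesign:
    """Sample layout of a reciprocal BFMI x B6N cross experiment.

    Parameters
    ----------
    n_parental_per_strain:
        Animals per parental inbred strain (default 2: one male, one
        female, alternating sexes if more are requested).
    n_f1_per_group:
        F1 males per cross direction (default 3, as in the sequenced
        cohort of 10 liver samples).
    seed:
        Root seed recorded with the design; generators derive their
        stream from it unless given an explicit seed.
    """

    n_parental_per_strain: int = 2
    n_f1_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parental_per_strain < 1:
            raise ValueError("need at least one parental animal per strain")
        if self.n_f1_per_group < 2:
            raise ValueError("need at least two F1 animals per group")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_parental_per_strain + 2 * self.n_f1_per_group

    def sample_table(self) -> pd.DataFrame:
        """Per-sample metadata: sample id, group, strain role and sex."""
        rows = []
        sexes = ("M", "F")
        for strain, group in (("BFMI", GROUP_PARENTAL_BFMI), ("B6N", GROUP_PARENTAL_B6N)):
            for i in range(self.n_parental_per_strain):
                sex = sexes[i % 2]
                suffix = sex if self.n_parental_per_strain <= 2 else f"{sex}{i // 2 + 1}"
                rows.append((f"{strain}_{suffix}", group, strain, sex))
        for group, tag in ((GROUP_MAT, "matBFMI"), (GROUP_PAT, "patBFMI")):
            for i in range(self.n_f1_per_group):
                rows.append((f"{tag}_{i + 1}", group, "F1", "M"))
        return pd.DataFrame(rows, columns=["sample", "group", "strain", "sex"])

    @property
    def samples(self) -> list[str]:
        return self.sample_table()["sample"].tolist()

    def samples_in(self, group: str) -> list[str]:
        tab = self.sample_table()
        return tab.loc[tab["group"] == group, "sample"].tolist()


@dataclass
class SimTruth:
    """Sidecar ground truth emitted by the synthetic-data generators.

    Truth is keyed by feature id and never embedded in the emitted data
    files, so downstream code cannot accidentally consume it.

    Attributes
    ----------
    ase_ratios:
        snp id -> ``{"F1_matBFMI": r_mat, "F1_patBFMI": r_pat}``, the
        true mean BFMI(alt)-allele fraction per F1 group at sites with
        planted allelic imbalance.
    imprinted_genes:
        gene id -> expressed parental allele (``"paternal"`` or
        ``"maternal"``).
    de_genes:
        gene id -> true matBFMI/patBFMI fold change on the count scale.
    motif_planted_genes:
        gene id -> list of (offset, strand) of embedded consensus sites.
    rho:
        beta-binomial overdispersion of the allele-count generator.
    litter_effect_slope:
        trait units per pup used by the phenotype generator.
    phenotype_group_means:
        trait -> group -> true mean (before litter/noise effects).
    """

    ase_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    imprinted_genes: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    motif_planted_genes: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    rho: float = 0.0
    litter_effect_slope: float = 0.0
    phenotype_group_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"overdispersion rho must be in [0, 1), got {self.rho}")
        for snp, ratios in self.ase_ratios.items():
            for g, r in ratios.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"planted ratio for {snp}/{g} outside [0, 1]: {r}")

    def ase_frame(self) -> pd.DataFrame:
        rows = [
            {"snp": snp, "group": g, "true_alt_ratio": r}
            for snp, ratios in self.ase_ratios.items()
            for g, r in ratios.items()
        ]
        return pd.DataFrame(rows, columns=["snp", "group", "true_alt_ratio"])

    def write_tsv(self, path) -> None:
        """Write all truth tables into one long-format TSV keyed by feature."""
        frames = []
        ase = self.ase_frame()
        if len(ase):
            ase = ase.assign(kind="ase", feature=ase.pop("snp"))
            frames.append(ase.rename(columns={"true_alt_ratio": "value"})[
                ["kind", "feature", "group", "value"]])
        for gene, parent in self.imprinted_genes.items():
            frames.append(pd.DataFrame(
                [{"kind": "imprinted", "feature": gene, "group": "", "value": parent}]))
        for gene, fc in self.de_genes.items():
            frames.append(pd.DataFrame(
                [{"kind": "de", "feature": gene, "group": "", "value": fc}]))
        for gene, sites in self.motif_planted_genes.items():
            for off, strand in sites:
                frames.append(pd.DataFrame(
                    [{"kind": "motif", "feature": gene, "group": strand, "value": off}]))
        out = (pd.concat(frames, ignore_index=True)
               if frames else pd.DataFrame(columns=["kind", "feature", "group", "value"]))
        out.to_csv(path, sep="\t", index=False)
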