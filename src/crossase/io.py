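"""File-format adapters: VCF with per-sample DP4, TSV tables, GMT, FASTA, GTF.

Reading of standard formats goes through the field's usual libraries
(pysam for VCF, pyfaidx for FASTA, pyranges for GTF); writers emit
plain-text files in the simplest compliant dialect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ase import SnpCountData

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_sample_map",
    "write_counts",
    "read_counts",
    "read_lengths",
    "read_gmt",
    "write_fasta",
    "read_fasta",
    "read_gtf_tss",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP4,Number=4,Type=Integer,Description="High-quality ref-forward, ref-reverse, alt-forward, alt-reverse bases">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled call quality">
"""


def write_vcf(path, data: SnpCountData) -> None:
    """Write a VCF 4.2 with per-sample GT:DP4:GQ fields."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in dict.fromkeys(data.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(data.samples) + "\n")
        ref_d, alt_d = data.ref_depth(), data.alt_depth()
        for i in range(data.n_snps):
            gene = None if data.gene_id is None else data.gene_id[i]
            info = f"GENE={gene}" if gene else "."
            cols = [
                str(data.chrom[i]), str(data.pos[i]), str(data.snp_id[i]),
                str(data.ref[i]), str(data.alt[i]), ".", "PASS", info, "GT:DP4:GQ",
            ]
            for j in range(len(data.samples)):
                if data.missing[i, j]:
                    cols.append("./.:.,.,.,.:.")
                    continue
                r, a = ref_d[i, j], alt_d[i, j]
                gt = "0/0" if a == 0 else ("1/1" if r == 0 else "0/1")
                dp4 = ",".join(str(int(v)) for v in data.dp4[i, j])
                # GQ is Integer in VCF; floor keeps the <50 masking decision stable
                cols.append(f"{gt}:{dp4}:{int(np.floor(data.qual[i, j]))}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path) -> SnpCountData:
    """Read per-sample DP4 counts from a VCF via pysam.

    DP4 is taken from FORMAT when present, otherwise from a per-sample
    AD field (allele depths split evenly across strands).  Samples
    lacking both are flagged missing.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chrom, pos, ref, alt, snp_id, gene = [], [], [], [], [], []
    dp4_rows, qual_rows, miss_rows = [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(rec.alts[0])
        snp_id.append(rec.id or f"{rec.chrom}:{rec.pos}")
        gene.append(rec.info.get("GENE") if "GENE" in rec.info else None)
        row_dp4, row_q, row_m = [], [], []
        for s in samples:
            smp = rec.samples[s]
            vals = smp.get("DP4")
            if vals is None or any(v is None for v in vals):
                ad = smp.get("AD")
                if ad is not None and len(ad) >= 2 and all(v is not None for v in ad[:2]):
                    r, a = int(ad[0]), int(ad[1])
                    vals = (r - r // 2, r // 2, a - a // 2, a // 2)
            if vals is None or any(v is None for v in vals):
                row_dp4.append((0, 0, 0, 0))
                row_q.append(0.0)
                row_m.append(True)
            else:
                row_dp4.append(tuple(int(v) for v in vals))
                q = smp.get("GQ")
                row_q.append(float(q) if q is not None else 0.0)
                row_m.append(False)
        dp4_rows.append(row_dp4)
        qual_rows.append(row_q)
        miss_rows.append(row_m)
    n = len(pos)
    return SnpCountData(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=int),
        ref=np.array(ref, dtype="<U8"),
        alt=np.array(alt, dtype="<U8"),
        samples=samples,
        dp4=np.array(dp4_rows, dtype=int).reshape(n, len(samples), 4),
        qual=np.array(qual_rows, dtype=float).reshape(n, len(samples)),
        missing=np.array(miss_rows, dtype=bool).reshape(n, len(samples)),
        gene_id=np.array(gene, dtype=object),
        snp_id=np.array(snp_id, dtype=object),
    )


def read_sample_map(path) -> pd.DataFrame:
    """sample -> group/strain/sex table (TSV with header)."""
    tab = pd.read_csv(path, sep="\t")
    if "sample" not in tab.columns or "group" not in tab.columns:
        raise ValueError("sample map needs 'sample' and 'group' columns")
    return tab


def write_counts(path, counts: pd.DataFrame, lengths: pd.Series | None = None) -> None:
    out = counts.copy()
    out.insert(0, "gene", counts.index)
    if lengths is not None:
        out.insert(1, "length", lengths.reindex(counts.index).to_numpy())
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, pd.Series | None]:
    tab = pd.read_csv(path, sep="\t")
    tab = tab.set_index("gene")
    lengths = None
    if "length" in tab.columns:
        lengths = tab.pop("length")
    return tab, lengths


def read_lengths(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t")
    return tab.set_index(tab.columns[0])[tab.columns[1]]


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name]) for name in fa.keys()}


def read_gtf_tss(path, longest_transcript: bool = True) -> pd.DataFrame:
    """Per-gene TSS table (gene_id, chrom, tss, strand) from a GTF.

    The TSS is the annotated start of the longest transcript on the
    gene's strand (5' end: ``Start`` on +, ``End`` on −).
    """
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    tx = gr[gr["Feature"] == "transcript"].copy()
    if not len(tx):
        raise ValueError("GTF contains no transcript features")
    tx["length"] = tx["End"] - tx["Start"]
    if longest_transcript:
        tx = tx.sort_values("length", ascending=False).drop_duplicates("gene_id")
    # pyranges coordinates are 0-based half-open; TSS reported 1-based
    tss = np.where(tx["Strand"] == "+", tx["Start"] + 1, tx["End"])
    return pd.DataFrame(
        {"gene_id": tx["gene_id"].to_numpy(), "chrom": tx["Chromosome"].to_numpy(),
         "tss": tss.astype(int), "strand": tx["Strand"].to_numpy()}
    ).reset_index(drop=True)
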