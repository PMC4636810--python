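"""Promoter scanning for transcription-factor binding sites (TFBS).

Position weight matrices are built from aligned binding-site lists or
IUPAC consensus strings, converted to log-odds against a background
composition, and slid across TSS-anchored gene regions (2000 bp
upstream + 1000 bp downstream by default).  A window is a hit when its
log-odds score reaches a *relative* threshold — a fraction of the
min–max achievable score range, 0.90 by default — the conventional way
of trading sensitivity against specificity with a PWM.

Enrichment of a motif in a gene set (e.g. the up- or down-regulated
genes of a differential-expression contrast) is assessed against the
null of size-matched random gene sets drawn from the scanned universe:
the observed number of target genes carrying at least one hit is
compared with the same statistic over ``n_perm`` random subsets, with
the add-one empirical p-value (r+1)/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pwm",
    "GeneRegion",
    "build_pwm",
    "extract_regions",
    "scan",
    "permutation_enrichment",
    "ANDROGEN_ELEMENT_CONSENSUS",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Synthetic stand-in consensus sites for the four androgen-response
#: element arrangements scanned in the study: hexameric AGAACA-type
#: half-sites as inverted (ARE, IR3) or direct (ARE2, ADR3) repeats
#: with a 3-bp spacer.  These are IUPAC consensus approximations of the
#: published selective-ARE matrices, not the original matrices; supply
#: site lists via ``build_pwm`` to use measured ones.
ANDROGEN_ELEMENT_CONSENSUS = {
    "ARE": "GGWACANNNTGTTCT",
    "ARE2": "GGWACANNNGGWACA",
    "ADR3": "AGAACANNNAGAACA",
    "IR3": "AGAACANNNTGTTCT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position weight matrix with log-odds scoring semantics."""

    name: str
    probs: np.ndarray                     # (L, 4) per-position probabilities
    background: np.ndarray                # (4,)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("each position's probabilities must sum to 1")
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probs / self.background)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def score(self, seq: str) -> float:
        """Log-odds score of one window (len(seq) == len(self))."""
        if len(seq) != len(self):
            raise ValueError("window length must equal motif length")
        return float(sum(self.log_odds[j, _BASE_INDEX[b]] for j, b in enumerate(seq.upper())))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name, self.probs[::-1, ::-1].copy(), self.background[::-1].copy())


def build_pwm(
    sites,
    pseudocount: float = 0.1,
    background=(0.25, 0.25, 0.25, 0.25),
    name: str = "motif",
) -> Pwm:
    """Build a PWM from aligned site sequences (or one IUPAC consensus).

    Position probabilities are (count + pseudocount)/(n + 4·pseudocount);
    an IUPAC letter contributes fractional counts uniformly over its
    base set, so a consensus string alone yields a usable matrix.
    """
    if isinstance(sites, str):
        sites = [sites]
    if not sites:
        raise ValueError("need at least one site")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("all sites must have the same length")
    counts = np.zeros((length, 4))
    for site in sites:
        for j, letter in enumerate(site.upper()):
            bases = IUPAC.get(letter)
            if bases is None:
                raise ValueError(f"invalid base {letter!r}")
            for b in bases:
                counts[j, _BASE_INDEX[b]] += 1.0 / len(bases)
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return Pwm(name, probs, np.asarray(background, dtype=float))


@dataclass
class GeneRegion:
    """Strand-oriented TSS-anchored promoter region (5'→3' of the gene)."""

    gene_id: str
    tss: int                  # 1-based genomic coordinate
    strand: str
    sequence: str
    truncated: bool = False


def extract_regions(
    tss_table: pd.DataFrame,
    genome,
    upstream: int = 2000,
    downstream: int = 1000,
) -> list[GeneRegion]:
    """Extract TSS-anchored regions from a genome.

    ``tss_table`` needs columns gene_id, chrom, tss (1-based), strand.
    ``genome`` is any mapping chrom -> sequence string (a pyfaidx.Fasta
    works via str()).  Plus-strand gene at TSS t covers
    [t−upstream, t+downstream−1]; minus-strand genes take the mirrored
    interval reverse-complemented, so the returned sequence always reads
    5'→3' with the TSS ``upstream`` bases in.  Regions clipped at contig
    bounds are flagged truncated.
    """
    regions = []
    for row in tss_table.itertuples(index=False):
        chrom_seq = str(genome[row.chrom])
        t = int(row.tss)
        if row.strand == "+":
            start, end = t - upstream, t + downstream - 1
        else:
            start, end = t - downstream + 1, t + upstream
        clipped_start, clipped_end = max(start, 1), min(end, len(chrom_seq))
        seq = chrom_seq[clipped_start - 1: clipped_end].upper()
        if row.strand == "-":
            seq = reverse_complement(seq)
        regions.append(
            GeneRegion(
                gene_id=row.gene_id, tss=t, strand=row.strand, sequence=seq,
                truncated=(clipped_start != start or clipped_end != end),
            )
        )
    return regions


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def _scan_codes(lom: np.ndarray, codes: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and scores of windows reaching ``threshold``; windows
    containing N (code 4) are skipped."""
    L = lom.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    lom_n = np.hstack([lom, np.full((L, 1), -np.inf)])  # N kills the window
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lom_n[j, codes[j: j + n_win]]
    valid = np.ones(n_win, dtype=bool)
    is_n = codes == 4
    if is_n.any():
        # window invalid if any position is N
        cum = np.concatenate([[0], np.cumsum(is_n)])
        valid = (cum[L:] - cum[:-L]) == 0
    hit = valid & (scores >= threshold)
    return np.nonzero(hit)[0], scores[hit]


def scan(
    pwm: Pwm,
    region: GeneRegion | str,
    rel_threshold: float = 0.90,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan a region for PWM hits at a relative score threshold.

    A window at offset i (0-based from the region's 5' end) is a hit
    when its log-odds score is at least
    ``min + rel_threshold * (max − min)``.  With ``both_strands`` the
    reverse complement of the matrix is scanned too; minus-strand hits
    report the offset of the window's leftmost base on the given
    sequence.  Returns a frame with offset, strand, score, rel_score.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    seq = region.sequence if isinstance(region, GeneRegion) else region
    codes = _encode(seq.upper())
    span = pwm.max_score - pwm.min_score
    rows = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if both_strands else [])
    for strand, mat in strands:
        thr = mat.min_score + rel_threshold * (mat.max_score - mat.min_score)
        if not np.isfinite(thr):  # zero-probability entries: only exact max attainable
            thr = mat.max_score
        offsets, scores = _scan_codes(mat.log_odds, codes, thr)
        for off, sc in zip(offsets, scores):
            rel = (sc - mat.min_score) / span if np.isfinite(span) and span > 0 else 1.0
            rows.append({"offset": int(off), "strand": strand,
                         "score": float(sc), "rel_score": float(rel)})
    return pd.DataFrame(rows, columns=["offset", "strand", "score", "rel_score"])


def count_hits(
    pwm: Pwm,
    regions: list[GeneRegion],
    rel_threshold: float = 0.90,
    both_strands: bool = True,
) -> pd.Series:
    """Number of hits per gene over a region collection."""
    return pd.Series(
        {r.gene_id: len(scan(pwm, r, rel_threshold, both_strands)) for r in regions},
        dtype=int,
        name=pwm.name,
    )


def permutation_enrichment(
    hits_per_gene: pd.Series,
    target_set,
    universe=None,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "genes_with_hit",
) -> dict:
    """Permutation test of motif occurrence in a gene set.

    The observed statistic (default: number of target genes with ≥1
    hit; ``statistic="total_hits"`` sums hit counts) is compared with
    its null over ``n_perm`` uniform random subsets of the universe of
    the same size.  Empirical p is (1 + #null as-or-more-extreme in the
    observed direction)/(n_perm + 1); direction is "over" when the
    observed statistic is at or above the null mean, else "under".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = list(universe) if universe is not None else list(hits_per_gene.index)
    target = [g for g in target_set]
    if len(target) > len(universe):
        raise ValueError("target set larger than universe")
    if not set(target) <= set(universe):
        raise ValueError("target set must be a subset of the universe")
    counts = hits_per_gene.reindex(universe).fillna(0).to_numpy()
    pos = {g: i for i, g in enumerate(universe)}
    t_idx = np.array([pos[g] for g in target], dtype=int)

    def stat(idx: np.ndarray) -> float:
        c = counts[idx]
        return float((c > 0).sum()) if statistic == "genes_with_hit" else float(c.sum())

    if statistic not in ("genes_with_hit", "total_hits"):
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = stat(t_idx)
    rng = np.random.default_rng(seed)
    null = np.array(
        [stat(rng.choice(len(universe), size=len(target), replace=False))
         for _ in range(n_perm)]
    )
    direction = "over" if observed >= null.mean() else "under"
    extreme = (null >= observed) if direction == "over" else (null <= observed)
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return {
        "motif": hits_per_gene.name,
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=0)),
        "p_value": float(p),
        "direction": direction,
        "n_perm": n_perm,
        "n_target": len(target),
        "n_universe": len(universe),
    }
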