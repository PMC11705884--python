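"""Link candidate SNPs to genes through local linkage disequilibrium.

A candidate SNP tags a haplotype block rather than a single base, so genes
are collected over the interval spanned by all nearby sites whose dosage
correlation with the candidate reaches the threshold (|r| >= 0.9 by default;
the absolute value because the sign of r flips with the arbitrary
major/minor orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glcore
from .glcore import GLMatrix

__all__ = ["GeneModel", "LinkageReport", "read_gff3", "ld_link_genes"]

DEFAULT_R_THRESHOLD = 0.9
DEFAULT_SEARCH_WINDOW_BP = 500_000  # mirrors the LD-thinning window


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")


@dataclass
class LinkageReport:
    chrom: str
    pos: int
    linked_positions: list[int]  # includes the candidate itself
    span: tuple[int, int]
    genes: list[str]
    monomorphic: bool = False


def _attr_id(attrs: str) -> str:
    for part in attrs.strip().split(";"):
        part = part.strip()
        for key in ("ID=", "gene_id=", "Name="):
            if part.startswith(key):
                return part[len(key):].strip('"')
    return attrs.strip() or "unnamed"


def read_gff3(path) -> list[GeneModel]:
    """Parse gene-type records from a GFF3 file (comments tolerated, sorted output)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"GFF3 line {lineno}: {len(cols)} columns, expected 9")
            if cols[2] != "gene":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(f"GFF3 line {lineno}: non-integer coordinates") from None
            if end < start:
                raise ValueError(f"GFF3 line {lineno}: end < start")
            genes.append(
                GeneModel(
                    gene_id=_attr_id(cols[8]),
                    chrom=cols[0],
                    start=start,
                    end=end,
                    strand=cols[6],
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def ld_link_genes(
    candidates: pd.DataFrame,
    gl: GLMatrix,
    genes: list[GeneModel],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    search_window_bp: int = DEFAULT_SEARCH_WINDOW_BP,
) -> list[LinkageReport]:
    """Per candidate: linked sites (|r| >= threshold within the window), the
    spanned interval, and the genes overlapping that interval."""
    dos = glcore.dosages(gl)
    chroms = gl.sites["chrom"].to_numpy()
    poss = gl.sites["pos"].to_numpy()
    reports = []
    for _, cand in candidates.iterrows():
        ci = gl.site_index(cand["chrom"], int(cand["pos"]))
        cpos = int(poss[ci])
        cvec = dos.eg[ci]
        if np.std(cvec) == 0:
            reports.append(
                LinkageReport(
                    chrom=cand["chrom"],
                    pos=cpos,
                    linked_positions=[],
                    span=(cpos, cpos),
                    genes=[],
                    monomorphic=True,
                )
            )
            continue
        near = np.flatnonzero(
            (chroms == cand["chrom"]) & (np.abs(poss - cpos) <= search_window_bp)
        )
        linked = [cpos]
        for s in near:
            if s == ci or np.std(dos.eg[s]) == 0:
                continue
            r2 = glcore.ld_r2(cvec, dos.eg[s])
            if np.sqrt(r2) >= r_threshold:
                linked.append(int(poss[s]))
        linked = sorted(set(linked))
        span = (linked[0], linked[-1])
        hit = sorted(
            {
                g.gene_id
                for g in genes
                if g.chrom == cand["chrom"] and g.start <= span[1] and g.end >= span[0]
            }
        )
        reports.append(
            LinkageReport(
                chrom=cand["chrom"],
                pos=cpos,
                linked_positions=linked,
                span=span,
                genes=hit,
            )
        )
    return reports


def linkage_table(reports: list[LinkageReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate": [f"{r.chrom}:{r.pos}" for r in reports],
            "n_linked": [len(r.linked_positions) for r in reports],
            "span_start": [r.span[0] for r in reports],
            "span_end": [r.span[1] for r in reports],
            "genes": [",".join(r.genes) for r in reports],
            "monomorphic": [r.monomorphic for r in reports],
        }
    )
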