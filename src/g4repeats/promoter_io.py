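"""Strand-aware extraction of upstream-of-TSS promoter windows.

The window is the ``window`` nucleotides strictly upstream of each
gene's transcription start site (the TSS base itself is excluded):
for a + gene with 1-based TSS ``t`` that is ``[t-window, t-1]``; for a
- gene it is ``[t+1, t+window]`` reverse-complemented, so every
returned sequence reads 5'->3' on the gene's own strand.  Windows are
truncated (and flagged) at contig edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .pqs_scan import gc_content, reverse_complement

logger = logging.getLogger("g4repeats")


@dataclass
class PromoterRecord:
    """Upstream window of one gene (sequence 5'->3' on the gene strand)."""

    gene_id: str
    chrom: str
    tss: int  # 1-based position of the TSS base
    strand: str
    window: int
    seq: str
    gc: float
    truncated: bool = False


def _gene_coords(annotation: str | Path) -> list[tuple[str, str, int, int, str]]:
    """(gene_id, chrom, start, end, strand) per gene from GTF/GFF3.

    Prefers ``gene`` features; falls back to the 5'-most transcript per
    ``gene_id`` when the annotation carries only transcripts.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = list(db.features_of_type("gene"))
    if genes:
        out = []
        for f in genes:
            gid = (f.attributes.get("gene_id") or [f.id])[0]
            out.append((gid, f.seqid, f.start, f.end, f.strand))
        return out
    # transcript fallback: one window per gene at its 5'-most transcript start
    per_gene: dict[str, tuple[str, int, int, str]] = {}
    for f in db.all_features():
        if f.featuretype not in ("transcript", "mRNA"):
            continue
        gid = (f.attributes.get("gene_id") or [f.id])[0]
        cur = per_gene.get(gid)
        if cur is None:
            per_gene[gid] = (f.seqid, f.start, f.end, f.strand)
        else:
            chrom, s, e, strand = cur
            per_gene[gid] = (chrom, min(s, f.start), max(e, f.end), strand)
    return [(gid, *v) for gid, v in per_gene.items()]


def extract_upstream(
    annotation: str | Path, genome: str | Path, window: int = 100
) -> list[PromoterRecord]:
    """Extract the ``window`` nt strictly upstream of each gene's TSS.

    ``annotation`` is a GTF/GFF3 path, ``genome`` a FASTA path (indexed
    on first use).  Genes on missing contigs are skipped with a warning;
    windows hitting a contig edge are truncated and flagged.
    """
    from pyfaidx import Fasta

    if window < 0:
        raise ValueError("window must be >= 0")
    fa = Fasta(str(genome))
    records: list[PromoterRecord] = []
    for gene_id, chrom, start, end, strand in _gene_coords(annotation):
        if chrom not in fa:
            warnings.warn(f"gene {gene_id}: contig {chrom!r} absent from genome; skipped")
            continue
        contig_len = len(fa[chrom])
        truncated = False
        if strand not in ("+", "-"):
            warnings.warn(f"gene {gene_id}: strand {strand!r} unknown; skipped")
            continue
        if strand == "+":
            tss = start
            lo = max(0, tss - 1 - window)  # 0-based half-open [lo, hi)
            hi = tss - 1
            if lo == 0 and tss - 1 < window:
                truncated = True
            seq = str(fa[chrom][lo:hi]).upper() if hi > lo else ""
        else:
            tss = end
            lo = tss
            hi = min(contig_len, tss + window)
            if hi == contig_len and contig_len - tss < window:
                truncated = True
            raw = str(fa[chrom][lo:hi]).upper() if hi > lo else ""
            seq = reverse_complement(raw)
        if window == 0:
            truncated = True
        gc = gc_content(seq) if seq else float("nan")
        records.append(
            PromoterRecord(gene_id, chrom, tss, strand, window, seq, gc, truncated)
        )
    return records


def promoters_to_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id} {r.chrom}:{r.tss}({r.strand})\n{r.seq}\n")


def promoters_to_tsv(records: Iterable[PromoterRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "chrom": r.chrom,
                "tss": r.tss,
                "strand": r.strand,
                "window": r.window,
                "length": len(r.seq),
                "gc": round(r.gc, 4) if r.gc == r.gc else "NA",
                "truncated": r.truncated,
                "seq": r.seq,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
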