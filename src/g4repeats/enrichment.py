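"""Gene-set over-representation against a GC-matched background.

The foreground is the set of genes whose promoter window carries a
double or triple tandem G4; the background is built from genes whose
window shares the high GC content (> 60% by default) but carries no
such repeat, de-confounding base composition.  Each gene set is tested
with a one-sided (upper-tail) hypergeometric test over the universe
foreground+background, with Benjamini-Hochberg correction across
terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentInput:
    foreground: frozenset[str]
    background: frozenset[str]
    genesets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.foreground & self.background:
            raise ValueError("foreground and background overlap")

    @property
    def universe(self) -> frozenset[str]:
        return self.foreground | self.background


@dataclass
class EnrichmentResult:
    term: str
    k: int  # foreground genes in the set
    K: int  # universe genes in the set
    n: int  # foreground size
    N: int  # universe size
    p: float
    q: float


def select_background(reports, gc_min: float = 0.60) -> set[str]:
    """IDs with GC > ``gc_min`` and no double/triple repeat.

    ``reports`` may be ScanReports or any objects exposing ``seq_id``
    (or ``gene_id``), ``gc``, ``has_double`` and ``has_triple``.
    """
    out = set()
    for r in reports:
        rid = getattr(r, "seq_id", None) or getattr(r, "gene_id")
        if r.gc == r.gc and r.gc > gc_min and not r.has_double and not r.has_triple:
            out.add(rid)
    return out


def select_foreground(reports) -> set[str]:
    """IDs whose window carries a double or triple tandem G4."""
    return {
        getattr(r, "seq_id", None) or getattr(r, "gene_id")
        for r in reports
        if r.has_double or r.has_triple
    }


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT reader: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def hypergeom_enrich(inp: EnrichmentInput) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term, BH-corrected.

    Genes absent from the universe are dropped from each set before
    testing (not counted as misses).  Results are sorted by (q, p).
    """
    universe = inp.universe
    fg = inp.foreground
    N, n = len(universe), len(fg)
    if n == 0 or N == 0:
        raise ValueError("empty foreground or universe")
    results: list[EnrichmentResult] = []
    for term, genes in inp.genesets.items():
        members = genes & universe
        K = len(members)
        k = len(members & fg)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append(EnrichmentResult(term, k, K, n, N, p, q=1.0))
    if results:
        _, qs, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def results_to_tsv(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "q": r.q}
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
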