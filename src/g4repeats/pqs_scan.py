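"""Detection of single and tandem (multimeric) putative G-quadruplexes.

A G-quadruplex (G4) unit is built from four G-islands — runs of 3-4
consecutive guanines, optionally interrupted by a single 1-nt bulge —
joined by loops of bounded length.  A *G4 repeat* is a chain of two or
more adjacent G4 units on the same strand (8 islands for a double
repeat, 12 for a triple), with every inter-island gap, including the
linker between units, obeying the same loop bounds.

The scanner works in two phases:

1. ``find_g_islands`` enumerates the *island lattice*: every perfect
   sub-run of ``m..M`` guanines inside longer G-runs, plus every bulged
   span (two G-runs separated by exactly one non-G base) with ``m..M``
   guanines in total.
2. ``find_repeats`` chains ``n`` non-overlapping islands left to right
   with every loop length in ``[min_loop_len, max_loop_len]`` and at
   least ``p`` perfect islands, via dynamic programming over the
   lattice.  Existence flags are exact; the reported match list is by
   default a leftmost-then-longest greedy non-overlapping subset
   (``mode="all"`` enumerates every chain).

Coordinates are 0-based half-open on the forward strand throughout;
minus-strand islands/matches are found on the reverse complement and
mirrored back.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

logger = logging.getLogger("g4repeats")

# --------------------------------------------------------------------------
# sequence utilities
# --------------------------------------------------------------------------

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

KIND_BY_ISLANDS = {4: "single", 8: "double", 12: "triple"}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}.

    Raises ``ValueError`` naming the 0-based position of the first
    offending character.
    """
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _VALID_BASES:
            raise ValueError(
                f"invalid DNA character {ch!r} at position {i} (expected A/C/G/T/N)"
            )
    return up


def gc_content(seq: str) -> float:
    """Fraction of G or C among non-N bases.

    Empty input is an error; an all-N sequence has undefined GC and
    returns ``nan``.
    """
    if not seq:
        raise ValueError("gc_content: empty sequence")
    up = seq.upper()
    denom = len(up) - up.count("N")
    if denom == 0:
        return float("nan")
    return (up.count("G") + up.count("C")) / denom


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanParams:
    """Island/loop/bulge parameterization of the PQS pattern.

    Defaults correspond to the double-repeat search: islands of 3-4 Gs
    (``min_island_len``/``max_island_len``), loops of 1-5 nt
    (``min_loop_len``/``max_loop_len``), 8 islands total of which at
    least 5 perfect; bulged islands carry exactly one 1-nt gap.
    """

    min_island_len: int = 3
    max_island_len: int = 4
    max_loop_len: int = 5
    min_loop_len: int = 1
    total_islands: int = 8
    min_perfect_islands: int = 5
    max_gaps_per_island: int = 1
    gap_len: int = 1
    strands: Literal["forward", "reverse", "both"] = "both"

    def __post_init__(self) -> None:
        if not (1 <= self.min_island_len <= self.max_island_len):
            raise ValueError("require 1 <= min_island_len <= max_island_len")
        if self.min_loop_len < 0:
            raise ValueError("min_loop_len must be >= 0")
        if self.max_loop_len < self.min_loop_len:
            raise ValueError("max_loop_len must be >= min_loop_len")
        if self.total_islands < 1:
            raise ValueError("total_islands must be >= 1")
        if not (0 <= self.min_perfect_islands <= self.total_islands):
            raise ValueError("require 0 <= min_perfect_islands <= total_islands")
        if self.max_gaps_per_island != 1 or self.gap_len != 1:
            raise ValueError("bulged islands support exactly one gap of length 1")
        if self.strands not in ("forward", "reverse", "both"):
            raise ValueError("strands must be forward/reverse/both")

    # -- canonical parameter sets ------------------------------------------

    @classmethod
    def single(cls, **kw) -> "ScanParams":
        """One G4 unit: 4 islands, at most one bulged."""
        kw.setdefault("total_islands", 4)
        kw.setdefault("min_perfect_islands", 3)
        return cls(**kw)

    @classmethod
    def double(cls, **kw) -> "ScanParams":
        """Two adjacent G4 units: 8 islands, >=5 perfect."""
        kw.setdefault("total_islands", 8)
        kw.setdefault("min_perfect_islands", 5)
        return cls(**kw)

    @classmethod
    def triple(cls, **kw) -> "ScanParams":
        """Three adjacent G4 units: 12 islands, >=8 perfect."""
        kw.setdefault("total_islands", 12)
        kw.setdefault("min_perfect_islands", 8)
        return cls(**kw)

    @property
    def max_bulged(self) -> int:
        return self.total_islands - self.min_perfect_islands

    @property
    def kind(self) -> str:
        return KIND_BY_ISLANDS.get(self.total_islands, f"{self.total_islands}-island")

    def scan_strands(self) -> tuple[str, ...]:
        return {"forward": ("+",), "reverse": ("-",), "both": ("+", "-")}[self.strands]


# --------------------------------------------------------------------------
# islands
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GIsland:
    """A perfect or bulged G-island.

    ``start``/``end`` are 0-based half-open positions on the forward
    strand; ``n_g`` counts guanines on the scanned strand; ``gap_pos``
    is the forward-strand position of the single non-G base of a bulged
    island (``None`` for perfect islands).
    """

    start: int
    end: int
    n_g: int
    gap_pos: int | None = None
    strand: str = "+"

    @property
    def is_perfect(self) -> bool:
        return self.gap_pos is None

    def __len__(self) -> int:
        return self.end - self.start


def _g_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of G as (start, end) half-open intervals."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _find_islands_forward(seq: str, params: ScanParams) -> list[GIsland]:
    m, M = params.min_island_len, params.max_island_len
    runs = _g_runs(seq)
    islands: list[GIsland] = []
    # perfect islands: every sub-run of length m..M inside each maximal run
    for a, b in runs:
        for k in range(m, min(M, b - a) + 1):
            for s in range(a, b - k + 1):
                islands.append(GIsland(s, s + k, k))
    # bulged islands: adjacent runs separated by exactly one non-G, non-N base
    for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
        if a2 - b1 != 1 or seq[b1] == "N":
            continue
        for left in range(1, b1 - a1 + 1):
            for right in range(1, b2 - a2 + 1):
                ng = left + right
                if m <= ng <= M:
                    islands.append(
                        GIsland(b1 - left, a2 + right, ng, gap_pos=b1)
                    )
    islands.sort(key=lambda g: (g.start, g.end))
    return islands


def _mirror_island(g: GIsland, seq_len: int) -> GIsland:
    return GIsland(
        start=seq_len - g.end,
        end=seq_len - g.start,
        n_g=g.n_g,
        gap_pos=None if g.gap_pos is None else seq_len - 1 - g.gap_pos,
        strand="-",
    )


def find_g_islands(seq: str, params: ScanParams, strand: str = "+") -> list[GIsland]:
    """Enumerate all candidate G-islands on one strand.

    Returns the full island lattice (perfect sub-runs of ``m..M`` Gs and
    bulged spans with exactly one 1-nt internal gap) in forward-strand
    coordinates, sorted by position.  The reverse strand is scanned on
    the reverse complement and mirrored back.  ``N`` never counts as a
    guanine nor as a bulge gap.
    """
    seq = validate_dna(seq)
    if not seq:
        return []
    if strand == "+":
        return _find_islands_forward(seq, params)
    if strand == "-":
        rc = reverse_complement(seq)
        mirrored = [_mirror_island(g, len(seq)) for g in _find_islands_forward(rc, params)]
        mirrored.sort(key=lambda g: (g.start, g.end))
        return mirrored
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


# --------------------------------------------------------------------------
# repeats (island chaining)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class G4RepeatMatch:
    """A chain of ``n`` G-islands forming ``n/4`` tandem G4 units."""

    islands: tuple[GIsland, ...]
    strand: str
    kind: str
    n_perfect: int
    loops: tuple[int, ...]

    @property
    def start(self) -> int:
        return self.islands[0].start

    @property
    def end(self) -> int:
        return self.islands[-1].end

    @property
    def units(self) -> int:
        return len(self.islands) // 4

    def validate(self, params: ScanParams) -> None:
        """Audit every structural invariant against ``params``; raises on breach."""
        isl = self.islands
        if len(isl) != params.total_islands:
            raise AssertionError("wrong island count")
        bulged = sum(0 if g.is_perfect else 1 for g in isl)
        if self.n_perfect != len(isl) - bulged:
            raise AssertionError("n_perfect inconsistent with islands")
        if self.n_perfect < params.min_perfect_islands:
            raise AssertionError("too few perfect islands")
        for g in isl:
            if not (params.min_island_len <= g.n_g <= params.max_island_len):
                raise AssertionError("island guanine count out of range")
            span = g.n_g if g.is_perfect else g.n_g + 1
            if len(g) != span:
                raise AssertionError("island span inconsistent")
            if g.gap_pos is not None and not (g.start < g.gap_pos < g.end - 1):
                raise AssertionError("bulge gap on island edge")
        for a, b, loop in zip(isl, isl[1:], self.loops):
            if b.start - a.end != loop:
                raise AssertionError("recorded loop length wrong")
            if not (params.min_loop_len <= loop <= params.max_loop_len):
                raise AssertionError("loop length out of bounds")
            if b.start < a.end:
                raise AssertionError("islands overlap")


def _chain_tables(islands: Sequence[GIsland], params: ScanParams):
    """Suffix-chain DP.

    ``maxend[i][k][c]`` = largest end position of any chain of ``k+1``
    islands starting at island ``i`` and using at most ``c`` bulged
    islands, or -1 when no such chain exists.  Successors of ``i`` are
    islands ``j`` with loop ``j.start - i.end`` in bounds.
    """
    n = params.total_islands
    maxb = params.max_bulged
    N = len(islands)
    NEG = -1
    maxend = np.full((N, n, maxb + 1), NEG, dtype=np.int64)
    by_start: dict[int, list[int]] = defaultdict(list)
    for j, g in enumerate(islands):
        by_start[g.start].append(j)
    # islands sorted by start; process right-to-left so successors are done
    order = sorted(range(N), key=lambda i: islands[i].start, reverse=True)
    for i in order:
        g = islands[i]
        b0 = 0 if g.is_perfect else 1
        if b0 <= maxb:
            maxend[i, 0, b0:] = g.end
        lo = g.end + params.min_loop_len
        hi = g.end + params.max_loop_len
        for s in range(lo, hi + 1):
            for j in by_start.get(s, ()):
                # chain i -> j: budget at i must cover b0 plus chain at j
                sub = maxend[j, : n - 1, : maxb + 1 - b0]
                np.maximum(maxend[i, 1:, b0:], sub, out=maxend[i, 1:, b0:])
    return maxend, by_start


def _reconstruct(
    islands: Sequence[GIsland],
    maxend: np.ndarray,
    by_start: dict[int, list[int]],
    params: ScanParams,
    i: int,
) -> list[GIsland]:
    """Rebuild one maximal-end chain of ``total_islands`` islands from ``i``."""
    n = params.total_islands
    budget = params.max_bulged
    chain = [islands[i]]
    target = maxend[i, n - 1, budget]
    cur, k = i, n - 1
    while k > 0:
        g = islands[cur]
        b0 = 0 if g.is_perfect else 1
        budget -= b0
        lo, hi = g.end + params.min_loop_len, g.end + params.max_loop_len
        nxt = None
        for s in range(lo, hi + 1):
            for j in by_start.get(s, ()):
                if maxend[j, k - 1, budget] == target:
                    nxt = j
                    break
            if nxt is not None:
                break
        assert nxt is not None, "DP reconstruction failed"
        chain.append(islands[nxt])
        cur, k = nxt, k - 1
    return chain


def _make_match(chain: Sequence[GIsland], strand: str, params: ScanParams) -> G4RepeatMatch:
    loops = tuple(b.start - a.end for a, b in zip(chain, chain[1:]))
    n_perfect = sum(1 for g in chain if g.is_perfect)
    return G4RepeatMatch(
        islands=tuple(chain),
        strand=strand,
        kind=params.kind,
        n_perfect=n_perfect,
        loops=loops,
    )


def _mirror_match(match: G4RepeatMatch, seq_len: int, params: ScanParams) -> G4RepeatMatch:
    islands = tuple(_mirror_island(g, seq_len) for g in reversed(match.islands))
    return _make_match(islands, "-", params)


def _enumerate_all(
    islands: Sequence[GIsland],
    maxend: np.ndarray,
    by_start: dict[int, list[int]],
    params: ScanParams,
) -> Iterator[list[GIsland]]:
    """Exhaustive chain enumeration, pruned by DP feasibility."""
    n = params.total_islands

    def walk(i: int, budget: int, chain: list[GIsland]) -> Iterator[list[GIsland]]:
        if len(chain) == n:
            yield list(chain)
            return
        g = islands[i]
        k_left = n - len(chain)  # islands still to place after current
        lo, hi = g.end + params.min_loop_len, g.end + params.max_loop_len
        for s in range(lo, hi + 1):
            for j in by_start.get(s, ()):
                bj = 0 if islands[j].is_perfect else 1
                if bj > budget:
                    continue
                if maxend[j, k_left - 1, budget] < 0:
                    continue
                chain.append(islands[j])
                yield from walk(j, budget - bj, chain)
                chain.pop()

    for i in range(len(islands)):
        b0 = 0 if islands[i].is_perfect else 1
        if b0 <= params.max_bulged and maxend[i, n - 1, params.max_bulged] >= 0:
            yield from walk(i, params.max_bulged - b0, [islands[i]])


def _find_repeats_one_strand(
    seq: str, params: ScanParams, mode: str
) -> list[G4RepeatMatch]:
    islands = _find_islands_forward(seq, params)
    n = params.total_islands
    if len(islands) < n:
        return []
    maxend, by_start = _chain_tables(islands, params)
    feasible = maxend[:, n - 1, params.max_bulged]
    matches: list[G4RepeatMatch] = []
    if mode == "all":
        for chain in _enumerate_all(islands, maxend, by_start, params):
            matches.append(_make_match(chain, "+", params))
        return matches
    # greedy leftmost-then-longest non-overlapping representative set
    order = sorted(
        (i for i in range(len(islands)) if feasible[i] >= 0),
        key=lambda i: (islands[i].start, -int(feasible[i])),
    )
    cursor = 0
    for i in order:
        if islands[i].start < cursor or feasible[i] < 0:
            continue
        chain = _reconstruct(islands, maxend, by_start, params, i)
        match = _make_match(chain, "+", params)
        matches.append(match)
        cursor = match.end
    return matches


def find_repeats(
    seq: str, params: ScanParams, mode: Literal["greedy", "all"] = "greedy"
) -> list[G4RepeatMatch]:
    """Find tandem-G4 matches of ``params.total_islands`` islands.

    Existence is exact: the returned list is non-empty iff some
    admissible chain exists on a scanned strand.  ``mode="greedy"``
    (default) reports a leftmost-then-longest non-overlapping
    representative subset per strand; ``mode="all"`` enumerates every
    admissible chain (combinatorially large on G-rich input).

    A sequence shorter than the minimal match span simply yields no
    matches.
    """
    seq = validate_dna(seq)
    if mode not in ("greedy", "all"):
        raise ValueError("mode must be 'greedy' or 'all'")
    out: list[G4RepeatMatch] = []
    for strand in params.scan_strands():
        if strand == "+":
            out.extend(_find_repeats_one_strand(seq, params, mode))
        else:
            rc = reverse_complement(seq)
            for m in _find_repeats_one_strand(rc, params, mode):
                out.append(_mirror_match(m, len(seq), params))
    out.sort(key=lambda m: (m.start, m.end, m.strand))
    return out


def has_repeat(seq: str, params: ScanParams) -> bool:
    """Exact existence test for a chain satisfying ``params``."""
    seq = validate_dna(seq)
    n = params.total_islands
    for strand in params.scan_strands():
        s = seq if strand == "+" else reverse_complement(seq)
        islands = _find_islands_forward(s, params)
        if len(islands) < n:
            continue
        maxend, _ = _chain_tables(islands, params)
        if (maxend[:, n - 1, params.max_bulged] >= 0).any():
            return True
    return False


def count_tandem_units(seq: str, params: ScanParams) -> int:
    """Largest ``k`` such that ``4k`` islands chain under the loop bounds.

    Uses only the island and loop constraints (the perfect-island quota
    applies to fixed-size pattern searches, not to this open-ended
    count).  Returns 0 when no 4-island unit exists on any scanned
    strand.
    """
    seq = validate_dna(seq)
    best = 0
    for strand in params.scan_strands():
        s = seq if strand == "+" else reverse_complement(seq)
        islands = _find_islands_forward(s, params)
        if not islands:
            continue
        # longest-path DP over the island DAG
        by_start: dict[int, list[int]] = defaultdict(list)
        for j, g in enumerate(islands):
            by_start[g.start].append(j)
        longest = [1] * len(islands)
        for i in sorted(range(len(islands)), key=lambda i: islands[i].start, reverse=True):
            g = islands[i]
            for pos in range(g.end + params.min_loop_len, g.end + params.max_loop_len + 1):
                for j in by_start.get(pos, ()):
                    longest[i] = max(longest[i], 1 + longest[j])
        best = max(best, max(longest))
    return best // 4


# --------------------------------------------------------------------------
# classification and FASTA scanning
# --------------------------------------------------------------------------


@dataclass
class ScanReport:
    """Per-sequence classification summary.

    ``has_single/has_double/has_triple`` are cumulative (a triple repeat
    implies the double and single flags), so the hierarchy
    triple => double => single always holds; the raw per-pattern
    existence flags are kept in ``raw_flags``.
    """

    seq_id: str
    length: int
    gc: float
    has_single: bool
    has_double: bool
    has_triple: bool
    max_tandem_units: int
    strands: dict[str, str] = field(default_factory=dict)
    matches: list[G4RepeatMatch] = field(default_factory=list)
    raw_flags: dict[str, bool] = field(default_factory=dict)


def classify_sequence(
    seq: str,
    params_single: ScanParams | None = None,
    params_double: ScanParams | None = None,
    params_triple: ScanParams | None = None,
    seq_id: str = "seq",
    mode: Literal["greedy", "all"] = "greedy",
) -> ScanReport:
    """Classify one sequence for single/double/triple tandem G4s."""
    seq = validate_dna(seq)
    params_single = params_single or ScanParams.single()
    params_double = params_double or ScanParams.double()
    params_triple = params_triple or ScanParams.triple()

    matches: list[G4RepeatMatch] = []
    raw: dict[str, bool] = {}
    strands: dict[str, str] = {}
    for params in (params_single, params_double, params_triple):
        found = find_repeats(seq, params, mode=mode) if seq else []
        raw[params.kind] = bool(found)
        if found:
            strands[params.kind] = "".join(sorted({m.strand for m in found}))
        matches.extend(found)

    has_triple = raw["triple"]
    has_double = raw["double"] or has_triple
    has_single = raw["single"] or has_double
    return ScanReport(
        seq_id=seq_id,
        length=len(seq),
        gc=gc_content(seq) if seq else float("nan"),
        has_single=has_single,
        has_double=has_double,
        has_triple=has_triple,
        max_tandem_units=count_tandem_units(seq, params_single) if seq else 0,
        strands=strands,
        matches=matches,
        raw_flags=raw,
    )


def scan_fasta(
    path: str | Path,
    params_single: ScanParams | None = None,
    params_double: ScanParams | None = None,
    params_triple: ScanParams | None = None,
    mode: Literal["greedy", "all"] = "greedy",
) -> Iterator[ScanReport]:
    """Stream one ``ScanReport`` per FASTA record."""
    from Bio import SeqIO

    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            yield classify_sequence(
                str(rec.seq),
                params_single,
                params_double,
                params_triple,
                seq_id=rec.id,
                mode=mode,
            )
        except ValueError as exc:
            raise ValueError(f"FASTA record {idx} ({rec.id!r}): {exc}") from exc


def write_summary_tsv(reports: Iterable[ScanReport], path: str | Path) -> None:
    """One row per record: id, length, GC, flags, max tandem units."""
    import pandas as pd

    rows = [
        {
            "id": r.seq_id,
            "length": r.length,
            "gc": round(r.gc, 4) if r.gc == r.gc else "NA",
            "has_single": r.has_single,
            "has_double": r.has_double,
            "has_triple": r.has_triple,
            "max_tandem_units": r.max_tandem_units,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(reports: Iterable[ScanReport], path: str | Path) -> None:
    """BED6 of reported matches: name = kind, score = perfect-island count."""
    with open(path, "w") as fh:
        for r in reports:
            for m in r.matches:
                fh.write(
                    f"{r.seq_id}\t{m.start}\t{m.end}\t{m.kind}\t{m.n_perfect}\t{m.strand}\n"
                )
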