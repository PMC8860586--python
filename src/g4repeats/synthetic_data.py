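"""Seeded generators for every input the pipeline consumes.

All randomness flows through ``numpy.random.default_rng(seed)``
(platform-stable PCG64), so identical seeds give identical outputs,
byte for byte.  Promoter sets emulate the GC-rich composition of human
promoter windows (target GC ~ 0.8) with tandem-G4 repeats planted at
controlled rates and verified against the scanner at generation time;
spontaneous repeats arising in the background are allowed and simply
recorded in the truth table, never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import pqs_scan
from .binding_models import AnisotropyModel, anisotropy_model, simulate_job_series
from .pqs_scan import ScanParams, has_repeat

# ---------------------------------------------------------------------------
# the twelve studied oligonucleotides
# ---------------------------------------------------------------------------

#: Printed 5'->3' sequences of the studied oligonucleotides (repeat
#: notation expanded).  KIT2KIT*, ILPR and hTERT come from the c-KIT,
#: insulin and telomerase core promoters; the TEL ladder carries 1-4
#: tandem telomeric G4 units; G-rich noG4 is a G-rich control unable to
#: fold into G4.
TABLE1_SEQUENCES: dict[str, str] = {
    "KIT2KIT*": "CGGGCGGGCGCGAGGGAGGGGAGGCGAGGAGGGGCGTGGCCGGC",
    "KIT2": "CGGGCGGGCGCGAGGGAGGGG",
    "KIT*": "GGCGAGGAGGGGCGTGGCCGGC",
    "G-rich noG4": "TGGCCCTGGTGGGCGGAGGCAAAGGGGGAGCCAGGGGCGGAGAAAGGGT",
    "TEL": "TTAGGG" * 4,
    "2TEL": "TTAGGG" * 8,
    "3TEL": "TTAGGG" * 12,
    "4TEL": "TTAGGG" * 16,
    "2TEL(6)": "TTAGGG" * 4 + "TTA" + "TTAGGG" * 4,
    "2TEL(9)": "TTAGGG" * 4 + "TTATTA" + "TTAGGG" * 4,
    "ILPR": "ACAGGGGTGTGGGG" * 4,
    "hTERT": "GGGGAGGGGCTGGGAGGGCCCGGAGGGGGCTGGGCCGGGGACCCGGGAGGGGTCGGGACGGGGCGGGG",
}


def table1_fixtures() -> dict[str, str]:
    """The twelve studied oligonucleotides, name -> sequence."""
    return dict(TABLE1_SEQUENCES)


def write_table1_fasta(path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in TABLE1_SEQUENCES.items():
            fh.write(f">{name.replace(' ', '_')}\n{seq}\n")


# ---------------------------------------------------------------------------
# promoter sets with planted repeats
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterSimSpec:
    """Specification of a synthetic promoter-window set."""

    n_sequences: int = 100
    window: int = 100
    gc_target: float = 0.80
    fraction_with_double: float = 0.0
    fraction_with_triple: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_with_triple <= self.fraction_with_double <= 1):
            raise ValueError("require 0 <= fraction_with_triple <= fraction_with_double <= 1")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.window < 1 or self.n_sequences < 0:
            raise ValueError("window must be >= 1 and n_sequences >= 0")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAT"), size=n, p=p))


def _plant_repeat(rng: np.random.Generator, units: int, max_len: int) -> str:
    """A tandem repeat of ``units`` G4 units: 4*units perfect islands.

    Islands of 3-4 Gs joined by 1-5 nt non-G loops.  The insert length
    is drawn between the pattern minimum and ``max_len`` and the slack
    is distributed at random over island (+1 G) and loop (+1..4 nt)
    extensions, so any window that can host the minimal repeat works.
    """
    n_islands = 4 * units
    base = n_islands * 3 + (n_islands - 1) * 1
    if base > max_len:
        raise ValueError(f"window too small to host a {units}-unit repeat")
    slack = int(rng.integers(0, max_len - base + 1))
    island_lens = np.full(n_islands, 3, dtype=int)
    loop_lens = np.ones(n_islands - 1, dtype=int)
    while slack > 0:
        grow = [("i", j) for j in range(n_islands) if island_lens[j] < 4]
        grow += [("l", j) for j in range(n_islands - 1) if loop_lens[j] < 5]
        if not grow:
            break
        kind, j = grow[int(rng.integers(len(grow)))]
        if kind == "i":
            island_lens[j] += 1
        else:
            loop_lens[j] += 1
        slack -= 1
    parts = []
    for i, il in enumerate(island_lens):
        parts.append("G" * int(il))
        if i < n_islands - 1:
            parts.append("".join(rng.choice(list("ACT"), size=int(loop_lens[i]))))
    return "".join(parts)


def gen_promoter_set(spec: PromoterSimSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate GC-rich windows with planted double/triple repeats.

    Returns ``(records, truth)`` where records are (id, sequence) pairs
    and truth is a DataFrame with the planted kind, the planted-insert
    coordinates and the realized GC per sequence.  Every planted repeat
    is re-detected by the scanner before the set is returned
    (generation-time recall = 1).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    n_triple = int(round(n * spec.fraction_with_triple))
    n_double = int(round(n * spec.fraction_with_double)) - n_triple
    kinds = ["triple"] * n_triple + ["double"] * (max(n_double, 0)) + ["none"] * (
        n - n_triple - max(n_double, 0)
    )
    rng.shuffle(kinds)

    p_double, p_triple = ScanParams.double(), ScanParams.triple()
    records: list[tuple[str, str]] = []
    rows = []
    for i, kind in enumerate(kinds):
        sid = f"sim{i:05d}"
        if kind == "none":
            seq = _random_bases(rng, spec.window, spec.gc_target)
            off, ins_len = -1, 0
        else:
            units = 3 if kind == "triple" else 2
            insert = _plant_repeat(rng, units, spec.window)
            off = int(rng.integers(0, spec.window - len(insert) + 1))
            flank_l = _random_bases(rng, off, spec.gc_target)
            flank_r = _random_bases(rng, spec.window - off - len(insert), spec.gc_target)
            seq = flank_l + insert + flank_r
            ins_len = len(insert)
            params = p_triple if kind == "triple" else p_double
            if not has_repeat(seq, params):  # pragma: no cover - by construction
                raise AssertionError(f"planted {kind} repeat not re-detected in {sid}")
        records.append((sid, seq))
        rows.append(
            {
                "id": sid,
                "planted": kind,
                "insert_start": off,
                "insert_len": ins_len,
                "gc": round(pqs_scan.gc_content(seq), 4),
            }
        )
    return records, pd.DataFrame(rows)


def write_promoter_set(
    spec: PromoterSimSpec, fasta_path: str | Path, truth_path: str | Path
) -> pd.DataFrame:
    records, truth = gen_promoter_set(spec)
    with open(fasta_path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")
    truth.to_csv(truth_path, sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# toy annotation + genome
# ---------------------------------------------------------------------------


def gen_toy_annotation(
    n_genes: int,
    contig_len: int,
    seed: int = 0,
    window: int = 100,
    outdir: str | Path | None = None,
) -> tuple[str, str, list[dict]]:
    """A toy single-contig genome with genes of known TSS on both strands.

    Returns ``(gtf_text, genome_seq, truth)``; truth rows carry the
    gene id, strand, 1-based TSS and the expected upstream window
    (5'->3' on the gene strand), computed directly from the genome by
    construction.  When ``outdir`` is given, ``toy.gtf`` and ``toy.fa``
    are written there.
    """
    rng = np.random.default_rng(seed)
    genome = _random_bases(rng, contig_len, 0.5)
    gene_len = 200
    spacing = window + 20
    pos = window + 10  # leave room for the first upstream window
    lines = []
    truth: list[dict] = []
    for i in range(n_genes):
        start = pos  # 0-based
        end = start + gene_len
        if end > contig_len:
            raise ValueError("contig too short for the requested gene count")
        strand = "+" if i % 2 == 0 else "-"
        gid = f"gene{i:04d}"
        # GTF is 1-based inclusive
        lines.append(
            f"chr1\ttoysim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f'gene_id "{gid}";'
        )
        if strand == "+":
            tss = start + 1
            win = genome[max(0, start - window) : start]
            truncated = start < window
        else:
            tss = end
            win = pqs_scan.reverse_complement(genome[end : min(contig_len, end + window)])
            truncated = contig_len - end < window
        truth.append(
            {"gene_id": gid, "strand": strand, "tss": tss, "window_seq": win,
             "truncated": truncated}
        )
        pos = end + spacing
    gtf = "\n".join(lines) + ("\n" if lines else "")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "toy.gtf").write_text(gtf)
        (outdir / "toy.fa").write_text(f">chr1\n{genome}\n")
    return gtf, genome, truth


# ---------------------------------------------------------------------------
# titration and Job series
# ---------------------------------------------------------------------------


def gen_titration(
    model: AnisotropyModel,
    n_points: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    conc_range_nM: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Synthetic anisotropy titration from the exact 1:1 model.

    Tetramer concentrations are log-spaced over ``conc_range_nM``
    (default 0.04x-40x K_D, spanning sub- to super-K_D); Gaussian noise
    of the stated sd is added to the anisotropy.
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    lo, hi = conc_range_nM or (0.04 * model.kd, 40.0 * model.kd)
    conc = np.logspace(np.log10(lo), np.log10(hi), n_points)
    a = np.asarray(anisotropy_model(model, conc), dtype=float)
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return pd.DataFrame({"conc_nM": conc, "anisotropy": a})


def gen_job_series(
    s: int,
    kd_nM: float = 25.0,
    total_uM: float = 10.0,
    step: float = 0.02,
) -> pd.DataFrame:
    """Equilibrium-solved Job series on a uniform DNA-fraction grid."""
    if s not in (1, 2, 3):
        raise ValueError("s must be 1, 2 or 3")
    fractions = np.round(np.arange(step, 1.0 - step / 2, step), 10)
    series = simulate_job_series(s, kd_nM=kd_nM, total_uM=total_uM, fractions=fractions)
    return pd.DataFrame({"fraction": series.fractions, "signal": series.signal})
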