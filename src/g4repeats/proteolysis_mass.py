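"""Peptide/fragment masses and limited-proteolysis band interpretation.

Fragment masses are sums of standard residue masses plus one water,
with optional fixed carbamidomethylation of cysteines (+57.02146 Da
monoisotopic).  ``assign_band`` proposes tryptic-compatible fragments
of a parent protein whose average mass matches an observed gel-band
mass; ``band_composition`` reproduces the intensity-ratio bookkeeping
used to read band composition off LC-MS peptide lists (reference
peptides above 3000 counts, band peptides above 100 counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pt_mass

# residue masses (mass of amino acid minus water), from the pyteomics tables
WATER_MONO = float(_pt_mass.calculate_mass(formula="H2O", average=False))
WATER_AVG = float(_pt_mass.calculate_mass(formula="H2O", average=True))
CARBAMIDOMETHYL_MONO = float(_pt_mass.calculate_mass(formula="C2H3NO", average=False))
CARBAMIDOMETHYL_AVG = float(_pt_mass.calculate_mass(formula="C2H3NO", average=True))

_AA = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_MONO: dict[str, float] = {
    aa: float(_pt_mass.calculate_mass(sequence=aa, average=False)) - WATER_MONO for aa in _AA
}
RESIDUE_AVG: dict[str, float] = {
    aa: float(_pt_mass.calculate_mass(sequence=aa, average=True)) - WATER_AVG for aa in _AA
}

_SUPPORTED_MODS = {"carbamidomethyl-C"}


def vimentin_sequence() -> str:
    """Bundled human vimentin (UniProt P08670) sequence.

    Shipped with the package so no network access is ever needed; the
    copy is validated by its printed anchors (466 residues, one Cys,
    monoisotopic mass with one carbamidomethyl-Cys = 53 676 Da).
    """
    text = (resources.files("g4repeats") / "data" / "P08670.fasta").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


@dataclass(frozen=True)
class ProteinFragment:
    """A contiguous fragment of a parent protein, 1-based inclusive coords."""

    parent_id: str
    start: int
    end: int
    mass_mono: float
    mass_avg: float
    numbering: str = "full"  # "full" (Met1 = residue 1) or "des-met1"
    n_term_tryptic: bool = True
    c_term_tryptic: bool = True


def _validate_protein(seq: str) -> str:
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in RESIDUE_MONO:
            raise ValueError(f"unknown residue {ch!r} at position {i + 1}")
    return up


def fragment_mass(
    parent_seq: str,
    start: int,
    end: int,
    mods: Sequence[str] = ("carbamidomethyl-C",),
    kind: Literal["mono", "average"] = "mono",
) -> float:
    """Mass (Da) of residues ``start..end`` (1-based inclusive) of a protein.

    The mass is the residue-mass sum plus one water, plus the fixed-
    modification deltas (carbamidomethylation applies to every Cys in
    the fragment).  ``end = start - 1`` denotes the empty fragment,
    whose mass is that of water.
    """
    seq = _validate_protein(parent_seq)
    if not (1 <= start <= len(seq) + 1) or end > len(seq) or end < start - 1:
        raise ValueError(f"fragment {start}..{end} outside 1..{len(seq)}")
    for mod in mods:
        if mod not in _SUPPORTED_MODS:
            raise ValueError(f"unsupported modification {mod!r}")
    frag = seq[start - 1 : end]
    if kind == "mono":
        table, water, cam = RESIDUE_MONO, WATER_MONO, CARBAMIDOMETHYL_MONO
    elif kind == "average":
        table, water, cam = RESIDUE_AVG, WATER_AVG, CARBAMIDOMETHYL_AVG
    else:
        raise ValueError("kind must be 'mono' or 'average'")
    total = water + sum(table[aa] for aa in frag)
    if "carbamidomethyl-C" in mods:
        total += cam * frag.count("C")
    return total


def tryptic_sites(seq: str) -> list[int]:
    """1-based positions of K/R residues (cleavage is C-terminal to them)."""
    return [i + 1 for i, aa in enumerate(seq) if aa in "KR"]


def assign_band(
    observed_kda: float,
    parent_seq: str,
    tolerance_kda: float = 0.3,
    parent_id: str = "protein",
    mods: Sequence[str] = ("carbamidomethyl-C",),
) -> list[ProteinFragment]:
    """Candidate tryptic fragments matching an observed band mass.

    Candidates are contiguous fragments whose internal termini follow
    the trypsin rule (start right after a K/R, end on a K/R) or
    coincide with the protein's ends; the N-terminus with and without
    the initiator Met is accepted, and each candidate records which
    numbering convention ("full" or "des-met1") it belongs to.  The
    *average* mass is compared to ``observed_kda`` within
    ``tolerance_kda``; candidates are sorted by |mass error|.
    """
    seq = _validate_protein(parent_seq)
    if tolerance_kda < 0:
        raise ValueError("tolerance must be >= 0")
    n = len(seq)
    # prefix sums for O(1) fragment masses
    avg = np.zeros(n + 1)
    mono = np.zeros(n + 1)
    cys = np.zeros(n + 1, dtype=int)
    for i, aa in enumerate(seq):
        avg[i + 1] = avg[i] + RESIDUE_AVG[aa]
        mono[i + 1] = mono[i] + RESIDUE_MONO[aa]
        cys[i + 1] = cys[i] + (aa == "C")
    cam = "carbamidomethyl-C" in mods

    sites = tryptic_sites(seq)
    starts = {1: "full"}
    if seq.startswith("M"):
        starts[2] = "des-met1"  # recombinant/processed N-terminus without Met1
    for s in sites:
        if s + 1 <= n:
            starts.setdefault(s + 1, "internal")
    ends = set(sites) | {n}

    out: list[ProteinFragment] = []
    for start, origin in starts.items():
        for end in ends:
            if end < start:
                continue
            m_avg = avg[end] - avg[start - 1] + WATER_AVG
            m_mono = mono[end] - mono[start - 1] + WATER_MONO
            if cam:
                ncys = int(cys[end] - cys[start - 1])
                m_avg += CARBAMIDOMETHYL_AVG * ncys
                m_mono += CARBAMIDOMETHYL_MONO * ncys
            if abs(m_avg / 1000.0 - observed_kda) <= tolerance_kda:
                numbering = "des-met1" if origin == "des-met1" else "full"
                rep_start = start - 1 if numbering == "des-met1" else start
                rep_end = end - 1 if numbering == "des-met1" else end
                out.append(
                    ProteinFragment(
                        parent_id=parent_id,
                        start=rep_start,
                        end=rep_end,
                        mass_mono=m_mono,
                        mass_avg=m_avg,
                        numbering=numbering,
                        n_term_tryptic=origin == "internal",
                        c_term_tryptic=end in set(sites),
                    )
                )
    out.sort(key=lambda f: abs(f.mass_avg / 1000.0 - observed_kda))
    return out


# --------------------------------------------------------------------------
# band composition from LC-MS peptide intensities
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptide:
    """One peptide observation from an LC-MS peptide list."""

    peptide_id: str
    intensity: float
    rt_min: float | None = None


@dataclass(frozen=True)
class BandCompositionEntry:
    peptide_id: str
    intensity_band: float
    intensity_ref: float
    percent_ratio: float


def band_composition(
    band_peptides: Iterable[Peptide | Mapping],
    reference_peptides: Iterable[Peptide | Mapping],
    ref_min: float = 3000.0,
    band_min: float = 100.0,
    rt_tol_min: float | None = None,
) -> list[BandCompositionEntry]:
    """Per-peptide percent ratio of band intensity over reference intensity.

    The reference list keeps only peptides above ``ref_min`` counts
    (the undigested-protein run), the band list only peptides above
    ``band_min`` counts; band peptides absent from the filtered
    reference are dropped with a warning.  When ``rt_tol_min`` is set
    and both observations carry retention times, peptides whose
    retention times disagree beyond the tolerance are also dropped.
    The ratio normalizes out per-peptide ionization efficiency.
    """

    def as_pep(p) -> Peptide:
        if isinstance(p, Peptide):
            return p
        return Peptide(p["peptide_id"], float(p["intensity"]), p.get("rt_min"))

    ref = {p.peptide_id: p for p in map(as_pep, reference_peptides) if p.intensity > ref_min}
    if not ref:
        raise ValueError(f"no reference peptides above {ref_min} counts")
    out: list[BandCompositionEntry] = []
    for p in map(as_pep, band_peptides):
        if p.intensity <= band_min:
            continue  # below the identification threshold
        r = ref.get(p.peptide_id)
        if r is None:
            warnings.warn(f"peptide {p.peptide_id!r} absent from reference list; dropped")
            continue
        if (
            rt_tol_min is not None
            and p.rt_min is not None
            and r.rt_min is not None
            and abs(p.rt_min - r.rt_min) > rt_tol_min
        ):
            warnings.warn(f"peptide {p.peptide_id!r}: retention-time mismatch; dropped")
            continue
        out.append(
            BandCompositionEntry(
                p.peptide_id, p.intensity, r.intensity, 100.0 * p.intensity / r.intensity
            )
        )
    return out


def composition_to_tsv(entries: Iterable[BandCompositionEntry], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "peptide_id": e.peptide_id,
                "intensity_band": e.intensity_band,
                "intensity_ref": e.intensity_ref,
                "percent_ratio": e.percent_ratio,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)
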