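# Methods

## Tandem-G4 pattern model

A putative G4 unit is modelled as four G-islands joined by loops; a tandem
repeat of `u` units is a single chain of `n = 4u` islands in which *every*
inter-island gap — including the linker between adjacent units — obeys the
same loop bounds. Pattern parameters (`ScanParams`):

| parameter | meaning | default | unit |
|---|---|---|---|
| `min_island_len` (m) | minimum guanines per island | 3 | nt |
| `max_island_len` (M) | maximum guanines per island | 4 | nt |
| `max_loop_len` (L) | maximum loop length | 5 | nt |
| `min_loop_len` | minimum loop length | 1 | nt |
| `total_islands` (n) | islands in the pattern | 8 (double), 12 (triple) | — |
| `min_perfect_islands` (p) | perfect-island quota | 5 (double), 8 (triple) | — |
| `gap_len` (l) | bulge gap length | fixed 1 | nt |
| `strands` (b) | strands scanned | both | — |

A *perfect* island is `m..M` consecutive guanines; a *bulged* island carries
exactly one non-G base strictly inside the span (never on an edge) and still
contributes `m..M` guanines. `N` and other ambiguity codes never count as a
guanine nor as the bulge base: they can only sit in loops, so the scanner
never invents guanines.

### Algorithm

Phase 1 builds the full **island lattice**: every sub-run of `m..M` Gs inside
each maximal G-run (a run longer than `M` may contribute any sub-run, with
the unused guanines lying in flanking loops — required, e.g., for a 5-G run
to split as loop-G + 4-G island), plus every bulged span formed by two
adjacent G-runs separated by one base. Phase 2 chains islands left to right
with a dynamic program over (island, chain length, bulged-islands used),
which makes the **existence** of a valid chain exact. The reported match
list is, by default, a leftmost-then-longest greedy non-overlapping
representative subset — exhaustive enumeration (`mode="all"`) is available
but grows combinatorially on G-rich windows, which is why it is not the
default for genome-scale input. The minus strand is scanned as a G-search on
the reverse complement and coordinates are mirrored back; this is exactly
equivalent to a C-pattern search on the forward strand and avoids duplicated
pattern code.

`count_tandem_units` reports the largest `k` such that `4k` islands chain
under the island/loop constraints. It deliberately ignores the
perfect-island quota, which is defined per fixed-size pattern, not for an
open-ended count; on telomeric ladders (all islands perfect) the two
definitions coincide.

### Classification hierarchy

Report flags are cumulative: a triple repeat sets `has_double` and
`has_single` too. The raw per-pattern flags are kept alongside, because the
double (p=5/8) and triple (p=8/12) quotas do not nest exactly — a chain of
12 islands with 4 bulged ones need not contain 8 consecutive islands with at
most 3 bulged. The single-unit pattern, which the double/triple definitions
do not pin down, uses n=4, p=3 (at most one bulged island per unit,
consistent with the per-unit allowance implied by 5-of-8 and 8-of-12).

### Minimum loop length and KIT2KIT*

The default minimum loop is 1 nt — physically a G4 loop spans at least one
nucleotide — and it is configurable down to 0. This choice is observable on
the printed KIT2KIT* 44-mer: with `min_loop_len=1` no 8-island chain exists
(confirmed by brute-force enumeration), while with `min_loop_len=0` the
double repeat is found. Both behaviours are pinned by tests; the package
does not force a match either way.

## Promoter windows

The TSS is the annotated gene's 5′ end (feature type `gene`; with
transcript-only annotations, the 5′-most transcript start per gene). The
window is *strictly* upstream — the TSS base is excluded — `[tss−w, tss−1]`
for + genes and `[tss+1, tss+w]` reverse-complemented for − genes (1-based
inclusive; internally 0-based half-open). Windows truncated at contig edges
are flagged rather than dropped. GC content is computed over non-N bases;
all-N windows get `NaN`.

## Enrichment

The original study fed its gene lists to an external annotation web service;
this package instead ships an auditable statistic: for each gene set, the
upper-tail hypergeometric probability of the observed foreground overlap
within the universe foreground ∪ background, BH-corrected across terms.
The background selector keeps genes with GC > 0.60 (strict) and neither a
double nor a triple repeat, so enrichment is read against composition-matched
controls. Genes absent from the universe are dropped from gene sets, not
counted as misses. Exactness is tested against draw-by-draw enumeration for
all universes of size ≤ 12, and calibration (≈ 5% of terms below p = 0.05
under a uniformly random foreground) is property-tested.

## Binding models

**Anisotropy titration.** The observed anisotropy follows the exact 1:1
quadratic solution (see README for the closed form); concentrations are in
nM, with the protein counted as tetramers. Fitting uses
`scipy.optimize.least_squares` with K_D ≥ 0 bounds and multi-start
initialization (K_D at 0.1×/1×/10× the median titration concentration;
A0/ΔA from the data extremes), keeping the lowest-cost solution. Standard
errors are asymptotic (Jacobian-based). A flat titration is reported as
`identifiable=False` rather than fitted to a meaningless K_D: with ΔA ≈ 0
the data place no constraint on K_D.

**Job plot.** The x-axis is the DNA-strand molar fraction of a fixed total
of DNA strands + protein *monomers* (default 10 µM): a 1-tetramer complex
then peaks at 0.2 = 1 DNA per 4 monomers, and a 2-tetramer complex at
1/9 ≈ 0.1, i.e. peak = 1/(1+4s) in the strong-binding limit. The s-tetramer
complex is modelled as a single-step overall equilibrium D + s·T ⇌ DT_s
with overall dissociation constant K_D^s (K_D per step, default 25 nM);
intermediate species are not identifiable from a Job curve and are not
modelled. Each grid point is solved with a bracketing root search
(`brentq`) on [0, min(D0, T0/s)] at relative tolerance 1e-12; a
conservation audit (mass-action residual < 1e-9 relative) runs in the test
suite. The peak is the grid argmax refined by the parabola through the top
three points, and the inferred stoichiometry is `round((1/x* − 1)/4)`
tetramers per DNA.

**Circular dichroism.** Observed ellipticity (mdeg) converts to molar
ellipticity (deg·cm²·dmol⁻¹) as θ/(10·l·c) with the DNA *residue*
concentration c (M) and path length l (cm).

## Proteolysis and masses

Fragment masses are residue-mass sums plus one water, monoisotopic or
average (pyteomics tables), with fixed carbamidomethylation of cysteines
(+57.02146 Da mono). Band assignment enumerates fragments with
tryptic-compatible termini (cleavage C-terminal to K/R; protein ends exempt)
and compares the *average* mass to the observed gel mass within a tolerance
(default 0.3 kDa, reflecting SDS-PAGE accuracy). Because recombinant or
processed proteins often lack the initiator methionine, the des-Met1
N-terminus is also accepted and every candidate records which numbering
convention ("full" or "des-met1") it belongs to. Band composition follows
the intensity-ratio bookkeeping of MS^E band reading: reference peptides
(undigested-protein run) above 3000 counts, band peptides above 100 counts,
percent ratio band/reference per peptide to normalize ionization efficiency,
with an optional retention-time concordance check.

The bundled human vimentin sequence (UniProt P08670) is validated by its
independent anchors — 466 residues, a single cysteine, monoisotopic mass
with one carbamidomethyl-Cys rounding to 53 676 Da — and the package never
touches the network at runtime.

## Synthetic data: what it emulates and what it does not

The promoter generator emulates the composition of GC-rich human promoter
windows: 100-nt windows, i.i.d. bases with P(G)=P(C)=gc_target/2 (default
gc_target = 0.80, matching the median GC of repeat-positive promoter
windows), with double/triple repeats planted at controlled rates at random
offsets. Planted repeats are drawn from the pattern itself (perfect 3–4-G
islands, 1–5-nt non-G loops, length-budgeted to the window) and re-detected
by the scanner before the set is returned, so planted recall is 1 by
construction *and* verified. Spontaneous repeats arising in the background
are allowed and recorded, never suppressed — precision against planted truth
is therefore measurable. The generator does **not** reproduce real promoter
grammar (TATA/Inr elements, CpG-island dinucleotide structure, strand
asymmetries), so passing tests demonstrate correctness of the scanner and
statistics on composition-matched sequence, not biological discovery on real
genomes.

Titration tables are generated from the exact isotherm on a log-spaced
concentration grid (default 0.04×–40× K_D, 20 points) with optional Gaussian
noise (the round-trip tests use sd = 0.002, a realistic anisotropy
measurement error); Job tables come from the same equilibrium solver the
analysis uses. All randomness flows through `numpy.random.default_rng(seed)`
(PCG64), so outputs are platform-stable and byte-reproducible.

## Problem sizes in the default suite

The test suite runs at desk scale by design: oracle-equivalence on 500
seeded sequences of ≤ 60 nt (mixed GC-rich random and mutated planted
repeats, so both positives and negatives are exercised for the double and
triple patterns), 100-replicate noisy-fit recovery, 100-sequence planted
promoter sets. The study's genomic run (38 404 GENCODE v34 promoter windows;
1 477 double- and 295 triple-positive genes; 14 053-gene background) depends
on a genome download and on reporting semantics of the original search tool
that are not fully specified (match maximality, minimum loop); it is an
optional approximate replication, not a packaged result, and the property
suite above is the correctness evidence instead.

## Known limitations

- The scanner predicts pattern compatibility, not folding: no
  thermodynamic stability score, topology, or tetrad-count prediction.
- Exhaustive match listing is exponential in G-run density; the default
  greedy representative set is a deliberate reporting choice, and only
  existence flags are guaranteed canonical.
- The enrichment stage tests user-supplied gene sets as flat sets: no GO
  DAG propagation.
- The Job model's single-step equilibrium cannot resolve binding
  intermediates; only the peak position is meaningful.
- One gene set per GMT line; duplicate term names keep the last entry.
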