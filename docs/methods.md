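# Methods

## The charge model

Every quantity in this package derives from a Henderson–Hasselbalch model
of protein ionization. For a protein with `n_g` instances of each
ionizable group `g` — the side chains D, E, C, Y (acidic) and H, K, R
(basic), plus one N-terminal amine and one C-terminal carboxyl — the net
charge at a given pH is

    Z(pH) = Σ_g sign_g · n_g · f_g(pH),
    f_g = 1 / (1 + 10^(pH − pKa_g))   for positive groups,
    f_g = 1 / (1 + 10^(pKa_g − pH))   for negative groups.

Z is strictly decreasing in pH whenever any group is present, so the
isoelectric point (pI) — the unique zero of Z — is found by bisection on
[0, 14]. The default tolerance is 1e-3 pH units (about 14 iterations);
results are displayed to 2 decimals, matching the resolution at which pI
distributions are usually plotted. Sequences with no ionizable side chain
still titrate through their termini, so pI is always defined (for the
default table it is then (8.6 + 3.6)/2 = 6.10). In side-chain-only mode
(termini excluded) a sequence with no ionizable side chains has constant
zero charge and pI is reported as NaN.

pI is meaningful only relative to a pKa table. Three tables ship:

| table | Nterm | Cterm | D | E | C | Y | H | K | R |
|---|---|---|---|---|---|---|---|---|---|
| `emboss` (default) | 8.6 | 3.6 | 3.9 | 4.1 | 8.5 | 10.1 | 6.5 | 10.8 | 12.5 |
| `bjellqvist` | 7.5 | 3.55 | 4.05 | 4.45 | 9.0 | 10.0 | 5.98 | 10.0 | 12.0 |
| `ipc_protein` | 9.094 | 2.869 | 3.872 | 4.412 | 7.555 | 10.85 | 5.637 | 9.052 | 11.84 |

The EMBOSS Pepstats constants are the default so that whole-proteome pI
surveys computed here are directly comparable with the large body of work
that used that tool. The `bjellqvist` table here is the flat variant:
residue-specific terminal pKa overrides (used e.g. by Biopython's
`IsoelectricPoint`) are not applied, which changes pI by up to a few
hundredths of a unit when the termini carry an overriding residue.

Ambiguity codes (X, B, Z, J, U, O) are retained in sequences but carry no
charge and are excluded from Mole% composition — numerator and
denominator alike — so MAG-derived artifacts cannot shift any statistic.
No corrections are attempted for modifications, disulfides, temperature
or ionic strength.

## Spectra and habitat aggregates

A proteome's pI spectrum is the relative-frequency histogram of its
per-protein pIs, binned at 0.25 pH units over [2, 14] (half-open bins,
last bin closed; the rare pI outside the range is clipped into the
terminal bin so frequencies always sum to one). The 0.25 width resolves
the canonical acid/neutral/basic peak structure of prokaryotic proteomes
(~4.5 / ~6.8 / ~9.8) and nests exactly inside the diagnostic aggregation
ranges: acid 3.25–6.25, neutral 6.75–7.25, basic 7.75–13.75. A bin
belongs to a range when its center falls inside it (inclusive); because
the printed ranges leave gaps, the three fractions sum to less than one.
Aggregates are invariant to refining the bin width by an integer factor.

Peak finding smooths the spectrum with a 3-bin moving average
(zero-padded edges), takes local maxima (plateaus are reported at the bin
holding the most unsmoothed mass, ties to the lowest pH), suppresses
maxima within 1.0 pH of a higher one, and drops wiggles below 10% of the
highest peak — finite samples always produce small local maxima in the
tails, and without a relative floor a "unimodal" proteome would never
report a single peak.

## Distance statistics

Bray–Curtis dissimilarity between pI profiles, Σ|p−q| / Σ(p+q), equals
half the L1 distance for relative frequencies and is defined as 0 for two
all-zero vectors. One-way PERMANOVA follows Anderson's formulation:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²_ij
    pseudo-F  = (SS_among/(a−1)) / (SS_within/(N−a)),  R² = SS_among/SS_total

with a permutation p-value computed by shuffling group labels over
objects with a seeded generator and the (1+b)/(1+m) estimator, which
never returns zero and has resolution 1/(m+1). Habitat and taxon are
tested as separate single factors (two one-way runs), not jointly. If
SS_within is zero, pseudo-F is reported as infinite and the p-value
computed normally. Profiles are used as relative frequencies with no
further normalization by default; an optional row-standardization exists
because published analyses sometimes normalize profile matrices without
stating how.

PCA is an SVD of the column-centered profile matrix; components are
ordered by explained variance and signed so the largest-magnitude loading
is positive. The habitat classifier is a nearest centroid in the
3-dimensional (acid, neutral, basic) aggregate space under Euclidean
distance — this matches the acid/neutral/basic framing used to eyeball
habitat from a pI plot; margins are distance(runner-up) −
distance(winner), and exact ties resolve to the lexicographically smaller
label.

## Localization

Imported SignalP/Phobius-style predictions (TSV: protein id, signal
peptide flag, TM segment count) are the fidelity route. When annotations
are absent, a deliberately simple hydropathy heuristic stands in; it is
not a re-implementation of those tools and every call it emits is marked
`heuristic`. The heuristic scans Kyte–Doolittle hydropathy in a
19-residue window; a TM segment is a run of ≥ 5 consecutive window
centers with mean ≥ 1.6 (a hydrophobic region of ≥ 23 residues, a TM
helix plus flanks); a signal peptide requires ≥ 1 K/R in the first 5
residues and an 8-residue hydrophobic stretch ending within the first 35.
Precedence: TM outside the signal-peptide region → transmembrane; else
signal peptide → secreted; else cytoplasmic/inner-membrane, so the three
categories always partition the proteome. Proteins with both a signal
peptide and downstream TM segments count as transmembrane (membrane
anchoring dominates the charge environment). Sequences shorter than the
window are cytoplasmic with a flag.

On synthetic proteomes the heuristic recovers ≥ 90% of planted TM and
secreted proteins, but roughly a fifth of plain cytoplasmic proteins are
miscalled (random sequences produce hydrophobic clusters at a
non-negligible rate under these fixed thresholds). Analyses that need
clean categories should use imported annotations or the generator's
ground truth; the heuristic exists to keep the pipeline self-contained.

## Pairwise genome comparison

All-vs-all hits use affine-gap Smith–Waterman with BLOSUM62 (gap open 11,
extend 1) behind a k-mer prefilter: a subject is aligned only if it
shares ≥ 2 exact 5-mers with the query, which bounds the quadratic cost
at desk scale without losing homologs (a 20%-diverged 250-mer still
shares ~90 intact 5-mers). Percent identity is counted over all alignment
columns, gaps included; coverage is the aligned span over the query
length; hits below 30% identity or 50% coverage are discarded. An e-value
proxy follows Karlin–Altschul, E = K·m·n·e^(−λS) with the standard gapped
BLOSUM62 constants (K = 0.041, λ = 0.267) and n = subject proteome
residue count; it exists only to apply the conserved-protein threshold
and is stated in every report.

AAI is the unweighted mean identity over reciprocal best hits (ties
broken by score then lexicographic subject id); each RBH pair contributes
the mean of its two directional identities, making AAI exactly symmetric.
POCP = 100·(C_a + C_b)/(n_a + n_b) with conserved = e-value < 1e-5,
identity > 40%, aligned > 50% of the query. For a two-genome comparison
the core/flexible partition is simply RBH membership; multi-genome
clustering adds nothing at n = 2. Nucleotide ANI and 16S identity are out
of scope (they need nucleotide data) and are accepted as pass-through
metadata in reports.

## The synthetic generator

The generator produces the statistical structure the analysis is built to
detect, with everything a pure function of one seed (no global random
state). Residues are i.i.d. draws from a shifted composition; the
baseline is an average prokaryotic residue-frequency table (a documented
modelling constant). Lengths are log-normal, median 250 and sigma 0.45,
floored at 30 (45 for secreted, 90 for TM proteins so planted features
fit). Habitat shifts move probability mass in Mole% onto the acidic pool
{D, E} and/or the basic pool {K, R, H}, taken from the neutral polar pool
{N, Q, S, T} proportionally to baseline frequencies — this alters charge
while leaving hydropathy (and hence the localization heuristic)
approximately unchanged, isolating the effect under study. The canonical
habitat conditions are +1.0 Mole% acid (marine), +1.0 Mole% basic
(freshwater), +0.5 acid (brackish) and +8 acid (halophile; salt-in
organisms such as Haloquadratum or Salinibacter carry D+E around 20
Mole%, and at this shift the simulated spectrum is reliably unimodal
acidic, as observed for such organisms).

The shift is graded by solvent exposure: secreted proteins receive the
bulk shift plus an optional `secreted_extra_delta` (extracellular
conditions differ most between habitats), cytoplasmic proteins the bulk
shift, and transmembrane proteins half of it (membrane-embedded residues
are exempt from the aqueous milieu). This plants the secreted >
cytoplasmic > transmembrane sharpness ordering as ground truth; the
analyses then have to recover it. A naive alternative — same composition
everywhere, with TM proteins diluted by their hydrophobic segments —
inverts the ordering, because proteins with fewer charged groups have
*more* pI-sensitive compositions, not less.

Planted features: secreted proteins get an N-terminal signal peptide
(M + 2 K/R + 10 hydrophobic + short polar c-region); TM proteins get 1–6
non-overlapping hydrophobic 21-mers from residue 40 on. Category counts
are deterministic (rounded fractions), so `frac_tm = 0.2, n = 500` plants
exactly 100 TM proteins.

Pairs: proteome A is generated under the acid (marine) shift; shared
proteins are copied to B and mutated per site with probability
`mutation_rate`, redrawing mutated sites from B's basic-shifted
(freshwater) composition — including inside planted features; unique
proteins are drawn fresh per side. Expected ortholog identity is
1 − r(1 − p_same) with p_same ≈ 0.06 (a redrawn site may coincide), i.e.
~81% at r = 0.2 before local-alignment trimming. Note that orthologous
coupling attenuates the *realized* composition difference between pair
members (B is 80% A-like at r = 0.2); the full Mole% contrast between
habitats is expressed between independently generated proteomes, as in
the cohort.

What the generator does not emulate: real length/composition covariance,
codon- or GC-driven composition bias, domain structure, taxonomic
signal beyond the habitat shift, and realistic substitution matrices for
divergence. Passing tests therefore demonstrate that the pipeline
recovers planted charge structure of realistic magnitude from sequences
alone — not that any particular real proteome will show it.

## Problem sizes and numerical choices

Simulated analyses run at desk scale, chosen so the statistics are
well-powered while the whole suite runs quickly: cohorts of 20 proteomes
per habitat at 300 proteins each (PERMANOVA with 999 permutations), null
calibration over 50 cohorts of 8 × 150 (199 permutations), type-I error
over 500 replicates of 16 Dirichlet profiles, and 20 genome pairs of 300
proteins (240 shared, 60 unique per side) for the direction and
category-ordering analyses. Per-category mean-pI differences are pooled
over pairs before taking magnitudes — per-protein pI variance is large
(SD ≈ 2 pH units), so per-pair magnitudes of small-sample differences
would be dominated by noise. Bisection tolerance, bin layout, tie-breaks
and the permutation estimator are as described above; all table output
uses 6 significant digits with '.' decimal separator for diff-ability.

## Known limitations

- The pI model ignores electrostatic interactions between groups,
  modified residues and folded-state pKa shifts; it is the standard
  sequence-only estimate, comparable across proteomes but not an
  experimental pI prediction for any single protein.
- The localization heuristic over-calls secreted/TM on random sequence
  (see above) and knows nothing of β-barrels, lipoprotein signals or
  archaeal signal peptides.
- The e-value proxy is not a BLAST e-value; POCP values are comparable
  within this package but not digit-for-digit with BLAST-based POCP.
- Two-genome core/flexible partition by RBH will split multi-copy
  families arbitrarily (best-scoring member wins).
- PERMANOVA is one-way only; no interaction between habitat and taxonomy
  is modelled, and no dispersion test (PERMDISP) is included, so a
  significant R² can reflect dispersion as well as location differences.
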