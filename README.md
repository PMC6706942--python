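# piscape

Proteome isoelectric-point landscapes for aquatic prokaryotes.

Marine and freshwater microbes — even close phylogenetic neighbours —
differ systematically in the charge of their predicted proteomes: marine
(and, extremely, halophilic) organisms accumulate acidic residues (D, E),
shifting their proteome pI distribution toward the acidic peak, while
freshwater organisms drift basic (K, R, H). `piscape` is a self-contained
pipeline for detecting and quantifying that signal from protein FASTA
files: per-protein isoelectric points under a Henderson–Hasselbalch
model, localization-stratified pI spectra, distance-based habitat
statistics, a habitat classifier, and pairwise genome comparisons (AAI,
POCP, core/flexible partition). A seeded synthetic-proteome generator
emulates the marine acid shift and freshwater basic shift so the entire
analysis runs with no downloads.

## The model in brief

Per-protein net charge at a given pH is the Henderson–Hasselbalch sum
over ionizable groups (side chains D, E, C, Y, H, K, R plus the two
termini):

    Z(pH) = Σ_g sign_g · n_g / (1 + 10^(± (pH − pKa_g)))

Z is strictly decreasing in pH, and the isoelectric point pI is its
unique zero, found by bisection (default tolerance 1e-3, EMBOSS
Pepstats pKa constants; Bjellqvist and IPC tables available). Proteome pI
spectra are 0.25-pH-wide histograms over [2, 14], aggregated into acid
(3.25–6.25), neutral (6.75–7.25) and basic (7.75–13.75) fractions.
Habitat vs. taxonomy effects are tested by one-way PERMANOVA (pseudo-F,
R², permutation p) on Bray–Curtis distances between spectra; genome pairs
are compared through reciprocal-best-hit AAI and POCP over affine-gap
Smith–Waterman alignments (BLOSUM62, open 11 / extend 1). See
`docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small marine/freshwater cohort and test whether habitat
explains the pI spectra:

```python
import numpy as np
import piscape as ps

specs = {"marine": ps.SyntheticSpec(n_proteins=300, acid_shift_delta=1.0),
         "freshwater": ps.SyntheticSpec(n_proteins=300, basic_shift_delta=1.0)}
proteomes, metas = ps.generate_cohort(10, specs, seed=11)

spectra = {pid: ps.bin_spectrum(ps.isoelectric_points([r.sequence for r in recs]))
           for pid, recs in proteomes.items()}
ids = sorted(spectra)
habitat = {m.proteome_id: m.habitat for m in metas}
dm = ps.distance_matrix(np.vstack([spectra[p].rel_freq for p in ids]), ids)
res = ps.permanova(dm, [habitat[p] for p in ids], n_permutations=999, seed=0)
print(f"pseudo-F={res.pseudo_F:.2f}  R2={res.r_squared:.3f}  p={res.p_value}")
```

```
pseudo-F=12.72  R2=0.414  p=0.002
```

A +1.0 Mole% acid shift against a +1.0 Mole% basic shift separates the
two habitats cleanly: habitat explains ~41% of the Bray–Curtis variance
among these 20 spectra and only one permutation in a thousand reaches the
observed pseudo-F. The acid fractions behind that separation:

```python
from piscape.spectrum import acid_neutral_basic
for hab in ("marine", "freshwater"):
    accs = [acid_neutral_basic(spectra[p]).acid_fraction
            for p in ids if habitat[p] == hab]
    print(hab, round(float(np.mean(accs)), 3))
```

```
marine 0.502
freshwater 0.326
```

The same operations are available from the shell:

```bash
piscape pi proteome.faa --pka-set emboss        # per-protein pI table
piscape profile proteome.faa --outdir out/      # spectra + summary JSON
piscape compare-pair marine.faa fresh.faa --outdir pair/
piscape run config.yaml                         # full cohort pipeline
```

The `analysis/` directory holds numbered driver scripts that reproduce
the study-style analyses end to end on synthetic data
(`01_simulate_cohort.py`, `02_cohort_statistics.py`,
`03_pair_comparisons.py`), writing their tables under `results/`.

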