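# dualmark

Analysis toolkit for **histone double-mark readout**: how a chromatin
reader domain (the UHRF1 Tandem-Tudor domain, TTD) recognizes histone H3
tails carrying *two* modifications at once — H3K4me1 together with
H3K9me2/3 — and what that combined recognition looks like genome-wide.

The package is aimed at chromatin biochemists and computational
epigenomicists who need, in one tested place:

1. **Equilibrium binding analysis** of fluorescence-anisotropy peptide
   titrations, including the ligand-depletion regime, replicate pooling
   and the preference/mutation-effect ratio tables used to compare
   reader-domain variants.
2. **A genome-wide co-occurrence pipeline** for coverage tracks:
   blacklist-aware binning, decile-conditioned correlation,
   mononucleosome-scale peak fragmentation with k-means clustering,
   shuffle-null interval enrichment and region-centered signal matrices.
3. **A differential-regulation stage** for rescue-experiment expression
   tables: probe-to-gene medians, fold-change thresholding, the
   reader-dependent gene set, and enhancer-mark association tests.
4. **A synthetic-genome generator** with planted ground truth, so every
   pipeline stage is exercised end to end without downloading anything.

## The models

**Binding.** A fluorescent peptide at fixed concentration `c_pep`
(100 nM by default) is titrated with protein. The anisotropy change is
fitted to the hyperbolic isotherm

    Δr(c) = BL + F · c / (c + K_D)

or, when binding is tight enough that complex formation depletes the
free protein (`K_D` below ~100 nM), to the exact two-component
mass-balance solution

    Δr(c) = BL + F · Θ,   Θ = A − √(A² − c / c_pep),
    A = (K_D + c_pep + c) / (2 c_pep)

where Θ is the fraction of peptide bound. In `auto` mode the simple
model is fitted first and the curve is refitted with the depletion model
when the fitted `K_D` falls below 100 nM. Replicate `K_D` values are
pooled as mean ± CI95 = 1.96·σ/√n (spreadsheet population-σ convention).
Variant panels report the double-mark preference `K_D(single)/K_D(double)`
and the mutation effect `K_D(WT)/K_D(mutant)`, display-rounded to two
significant figures.

**Genome.** The co-occurrence question — "does the reader track follow
H3K4me1 *specifically inside* broad H3K9me2 domains?" — is answered by
ranking 1-kb genome bins by H3K9me2 signal, splitting them into deciles,
and computing the Pearson correlation r(TTD, H3K4me1) within each
decile; by fragmenting peaks into 150-bp windows (kept at ≥50 % overlap)
and k-means clustering their per-track signals; and by scoring interval
overlaps against shuffled controls of equal number and length.

## Worked example

Fit simulated titrations for the wild-type reader and the E153D variant
(two replicates each, true K_D values 680/240 and 640/50 nM), pool, and
build the preference panel:

```python
import numpy as np
from dualmark import binding as bd

conc = np.array(bd.DEFAULT_CONC_SCHEME_NM)       # 0–10 uM titration grid
results = {}
for variant, (kd_s, kd_d) in {"WT": (680, 240), "E153D": (640, 50)}.items():
    for pep, kd in (("H3K9me3", kd_s), ("H3K4me1-K9me3", kd_d)):
        gen_model = "depletion" if kd < 100 else "simple"
        true = bd.BindingModelParams(KD=kd, BL=0.05, F=0.10)
        kds = [
            bd.fit_curve(
                bd.simulate_titration(true, 100.0, conc, 0.001, seed=rep,
                                      model=gen_model),
                model="auto",
            ).params.KD
            for rep in (1, 2)
        ]
        mean, ci = bd.pool_replicates(kds)
        print(f"{variant:6s} {pep:14s} KD = {mean:7.1f} +/- {ci:5.1f} nM  (n=2)")
        results[(variant, pep)] = mean
print(bd.build_preference_panel(results).to_string(index=False))
```

Output:

```
WT     H3K9me3        KD =   676.5 +/-  19.3 nM  (n=2)
WT     H3K4me1-K9me3  KD =   243.7 +/-   1.6 nM  (n=2)
E153D  H3K9me3        KD =   637.4 +/-  17.6 nM  (n=2)
E153D  H3K4me1-K9me3  KD =    52.3 +/-   0.9 nM  (n=2)

variant  KD_single_nM  KD_double_nM  ratio  rel_effect_single  rel_effect_double
     WT    676.489962    243.700837    2.8                NaN                NaN
  E153D    637.360041     52.331712   12.0                1.1                4.7
```

The `ratio` column is the fold preference for the doubly modified
peptide: ~2.8-fold for the wild-type domain and ~12-fold for E153D, the
variant whose acidic-pocket substitution sharpens H3K4me1 selectivity;
`rel_effect_double` ≈ 4.7 says E153D binds the double-mark peptide about
5-fold more tightly than wild type. The fits recover the generating
K_D values (680/240 and 640/50 nM, exact ratios 2.8, 12.8 and 4.8)
within a few percent at this noise level; the residual wobble in the
display-rounded ratios (12 vs 13) is the fitting noise, not bias.

The genome side runs the same way from the synthetic generator:

```bash
dualmark pipeline --seed 3 --out runs/demo
```

which simulates the 5-Mb toy genome, writes bedGraph/BED outputs, and
reports (in `summary.json`) the decile-conditioned correlation gap
(r ≈ 0.99 in the top H3K9me2 decile vs ≈ 0.48 in the bottom), the
fragment clustering (the highest-TTD cluster is the planted
K4me1∩K9me2 class), the Enhancer-state enrichment ratio (≈ 30× over
shuffled controls) and the exact recovery of the planted 115-gene
reader-dependent set.

Every CLI subcommand (`fit-titration`, `panel`, `simulate-genome`,
`corr`, `decile-corr`, `fragment-cluster`, `state-enrich`,
`peak-overlap`, `region-matrix`, `drg`, `mark-assoc`, `expr-bins`,
`pipeline`) is a thin wrapper over the library; see `dualmark --help`.

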