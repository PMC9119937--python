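# tiffms

3D MS1 feature matching for low-input, label-free proteomics: transferring
peptide identities by **retention time, accurate mass, and FAIMS
compensation voltage (CV)**.

## The problem

Single-cell and other mass-limited LC-MS proteomics runs contain far more
MS1 features than can be identified by MS/MS: with only nanograms of
peptide, most instrument time is better spent accumulating precursor ions
than fragmenting them.  Match-between-runs style approaches recover
identities by matching MS1 features against a spectral library built from
high-input runs, using two coordinates — accurate mass and aligned
retention time.  When the instrument carries a FAIMS ion-mobility filter
and cycles through several compensation voltages, each library peptide
additionally acquires a characteristic CV, and matching can insist that a
feature and a library peptide agree on all **three** coordinates.  The CV
constraint shrinks the confusable search space roughly by the number of
CVs and thereby lowers the false-transfer rate, at essentially no cost in
true transfers.

`tiffms` implements that method end to end for people who want a
transparent, scriptable engine rather than a monolithic search platform:

* **mzML demultiplexing** — split a multi-CV run into single-CV sub-runs
  (PSI cvParam MS:1001581) and assign the non-adjacent fraction numbers
  (1, 3, 5, 7) that stop matching from crossing CV boundaries;
* **MS1 feature detection** — XIC tracing plus a transparent greedy
  isotope-envelope assembler (charge from the 1.003355/z spacing);
* **3D-tag library** — (peptide, charge, CV) entries with exact
  monoisotopic masses and reference RTs, built from per-CV identification
  tables, with mixed-species (entrapment) support;
* **RT alignment** — robust LOWESS through unambiguous anchors inside a
  10-min coarse window, isotonized to a monotone warp;
* **identity transfer** — candidates within 6 ppm (on neutral mass) and
  0.4 min (on aligned RT), CV-exact in 3D mode, resolved on a normalized
  distance with an ambiguity guard and one-to-one entry use;
* **entrapment FDR** — false-match rate from accepted hits to a species
  known to be absent from the sample, raw and library-composition
  corrected, at peptide and protein level;
* **iBAQ quantification** — protein roll-up, theoretical tryptic peptide
  counts (7–30 aa, no missed cleavages), missingness/quantifiability
  filters, downshifted-normal imputation (width 0.3, downshift 1.8) and
  width normalization;
* **a ground-truth simulator** — per-peptide preferred CV correlated with
  mass/charge, monotone RT drift, ppm-scale mass error, log-normal
  intensities, dropout, entrapment species and a realistic population of
  library-less "unknown" features — so every stage is testable closed-loop
  without instrument data.

## Worked example

Simulate a study at the default conditions (5,000 target + 2,280
entrapment library peptides, 4 CVs at −45/−55/−65/−75 V, 2 ppm mass error,
0.1 min RT jitter, 30% dropout), align each CV sub-run and compare 2D vs
3D matching:

```python
from tiffms import (MatchParams, SimConfig, simulate_library, simulate_run,
                    select_anchors, fit_alignment, apply_alignment,
                    compare_modes, AlignmentModel)

config = SimConfig(seed=1)
library, truth = simulate_library(config)
features, links = simulate_run(truth, run_seed=1)

for cv in sorted({f.cv for f in features}):
    subset = [f for f in features if f.cv == cv]
    model = fit_alignment(select_anchors(subset, library))
    apply_alignment(model, subset)
    print(f"CV {cv:+.0f} V: {len(subset):5d} features, "
          f"{model.n_anchors} anchors, residual sd {model.residual_sd:.3f} min")

reports = compare_modes(features, library, AlignmentModel.identity(),
                        MatchParams(), config.entrap_species)
for mode in ("2d", "3d"):
    r = reports[mode]
    print(f"{mode.upper()}: {r.n_total_accepted} peptides accepted, "
          f"{r.n_entrap_accepted} entrapment -> FMR {100 * r.fmr:.2f}% "
          f"(protein FDR {100 * r.protein_fdr:.2f}%)")
```

Output:

```
CV -75 V:  5956 features, 844 anchors, residual sd 0.110 min
CV -65 V:  5936 features, 863 anchors, residual sd 0.112 min
CV -55 V:  5744 features, 857 anchors, residual sd 0.105 min
CV -45 V:  5849 features, 856 anchors, residual sd 0.104 min
2D: 3491 peptides accepted, 10 entrapment -> FMR 0.29% (protein FDR 0.99%)
3D: 3484 peptides accepted, 4 entrapment -> FMR 0.11% (protein FDR 0.40%)
```

Reading it: each CV sub-run aligns to the library on ~850 unambiguous
anchors with ~0.1 min residual scatter (the injected RT noise).  Both
modes accept ~3,500 peptides — the CV constraint costs almost no true
transfers — but entrapment hits, which are demonstrable false transfers,
drop from 10 to 4 when the CV coordinate is enforced: a ~60% reduction in
the false-match rate, amplified at the protein level.

The same workflow is available from the shell:

```sh
tiffms simulate --config study.yaml --out-dir sim/     # library + runs
tiffms split sim_run1.mzML --out-dir by_cv/ --fraction-map fractions.tsv
tiffms match --library lib.tsv --features f.tsv --mode 3d --ppm 6 --rt-window 0.4 --out m.tsv
tiffms fdr --matches m.tsv --library lib.tsv --entrap-species SHEWON
tiffms run --config study.yaml --out-dir out/          # full pipeline
```

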