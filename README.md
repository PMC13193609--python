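# condensate-kit

Quantitative analysis of stress-induced bacterial RNA–protein condensates.

Under nitrogen starvation, the RNA chaperone Hfq condenses into polar,
polyphosphate-dependent foci ("H-bodies") in *E. coli*.  Characterizing these
condensates and their functional consequences takes a chain of bespoke
quantitative procedures spanning single-molecule microscopy, in vivo and in
vitro image quantitation, transcriptome-wide decay kinetics, poly(A) tail
modelling and set-level statistics.  `condensate-kit` implements that chain
as one tested Python package, for microscopists and RNA biologists who need
the same analyses on their own data — and ships a synthetic-data generator so
every stage is verifiable by parameter recovery, with no external data.

## What it computes

| Module | Analysis |
| --- | --- |
| `trajectory_dynamics` | Per-track MSD fits (MSD = 4Dτ + 4σ²); stable-focus detection from localization composites; In/In-out/Out overlap classes; two/three-state fits of the squared-displacement CDF `P(r²,τ) = 1 − Σ αᵢ e^(−r²/((8/3)Dᵢτ))`; condensate/nucleoid/free state fractions |
| `focus_quant` | Robust focus threshold (median + 3.5·MAD within cells), local-maximum-seeded focus calls, focus/background intensity ratios, per-cell Spearman colocalization, FRAP one-phase-association fits (t½ = ln2/k) |
| `droplet_quant` | CLAHE → blur → Canny → closing droplet segmentation, five-way shape filtering, Otsu-thresholded phase-diagram calls |
| `rna_decay` | ERCC spike-in normalization, per-gene y = a·e^(−t/b) fits, BH-filtered stability classification, Wilcoxon genotype comparison |
| `polya_tails` | Terminal-A run counting, strand-aware −50/+250 bp 3′-window gene assignment, per-gene zero-inflated negative-binomial regression across a 2×2 design, Wald condition contrasts |
| `enrichment_stats` | Quintile binning, small-sample + Yates-corrected odds ratios, permutation overlap tests, one-sample proportion test |
| `synthetic_data` | Ground-truth generators for all of the above |

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example: diffusion-state decomposition

Simulate single-molecule trajectories with a planted ground truth (25%
condensate-bound, 30% nucleoid-bound, 45% free; D = 0.05/0.3/2.0 µm²/s;
20 ms frames), then run the full state-fraction pipeline:

```bash
condensate-kit simulate --stage trajectories --seed 1 --out demo/sim
condensate-kit smtrack --trajectories demo/sim/trajectories.csv \
    --pixel-size 0.05 --tau 0.02 --seed 0 --out demo/smtrack
```

which prints

```
{"F_free": 0.45003848550102965, "F_condensate": 0.24534675625120292, "F_nucleoid": 0.3046147582477674}
```

The pipeline detected the planted foci from the localization composite,
classified 766 + 2,358 of 12,733 displacements as In/In-out, fit the
three-state CDF model to the full pool (fitted α₃ = 0.450 → F_free) and to
the focus-overlapping subset (α₁+α₂ = 1.0 → condensate weight), and
recovered the displacement-weighted planted fractions — condensate 0.244,
nucleoid 0.304, free 0.452 for this seed — to within 0.01.  The full report
(fits, per-track classes, focus set) lands in `demo/smtrack/`.

The same pattern works for the other stages: `condensate-kit simulate
--stage decay|polya` followed by `condensate-kit decay|polya`, and
`condensate-kit foci|droplets|enrich` on image/TSV inputs (see `--help`).

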