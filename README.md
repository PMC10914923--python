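# sangeredit

Quantitative base-editing readout from Sanger chromatograms.

Targeted RNA-editing assays (TRIBE/HyperTRIBE-style) fuse an RNA-binding
protein to an editing enzyme — typically the hyperactive ADAR catalytic
domain — so that RNAs bound in vivo acquire A→I changes, read as A→G in
the cDNA. On an amplicon of interest the assay's readout is a Sanger
trace of an RT-PCR product: at each edited adenosine the chromatogram
shows a mixed A/G peak whose area ratio reports the fraction of edited
molecules. `sangeredit` turns such traces (or externally quantified
peak-area tables) into per-position editing fractions with
replicate-based significance calls, and bundles the two companion
quantifications used to validate the readout: a plasmid-mix calibration
of peak-ratio linearity and a CAPS (cleaved amplified polymorphic
sequence) restriction assay.

## The statistic

For every adenosine position *i* along the reference amplicon (or every
cytosine, for C→U editors), the relative editing of one replicate is

```
e_i = G_i / (A_i + G_i)
```

where `A_i` and `G_i` are the integrated areas of the A and G trace
peaks at the called base. Control replicates (e.g. a Luciferase
infiltration) define a per-position background mean `c_i` which is
subtracted from each sample replicate. A site is called **significant**
when both criteria hold across n ≥ 3 biological replicates:

1. `mean(e_i − c_i) > 3 · sd(e_i − c_i)` — the corrected editing is more
   than three standard deviations above zero (sample SD, n−1);
2. `mean(e_i) ≥ 2 · c_i` — the uncorrected editing is at least twice the
   control value at that position (with a zero-control rule: any
   positive editing passes when the control is exactly zero).

No multiple-testing correction is applied; the 3σ rule is the guard, and
per-run site counts are reported so an FDR can be added externally.

The CAPS assay converts editing at one position into a restriction site;
the cleaved fraction `cut / (cut + uncut)` of Bioanalyzer band
molarities is compared between constructs with an unpaired two-tailed
Welch t-test.

## Worked example

Generate a synthetic experiment (six adenosines, all edited at a true
fraction of 0.40, four sample and four control replicates) and call
significant sites:

```
$ sangeredit simulate --n-sites 6 --fraction 0.4 --seed 7 -o sim
$ sangeredit call -r sim/reference.fasta \
    -s sim/sample_rep1.ab1 -s sim/sample_rep2.ab1 \
    -s sim/sample_rep3.ab1 -s sim/sample_rep4.ab1 \
    -c sim/control_rep1.ab1 -c sim/control_rep2.ab1 \
    -c sim/control_rep3.ab1 -c sim/control_rep4.ab1 -o out
$ cat out/summary.json
{
  "max_corrected_mean": 0.39691042032773466,
  "max_position": 18,
  "n_evaluable": 6,
  "n_significant": 6,
  "n_sites": 6,
  ...
}
$ head -2 out/results.tsv
position  ref_base  raw_rep1  raw_rep2  raw_rep3  raw_rep4  control_mean  corrected_mean  corrected_sd  criterion1  criterion2  significant  n_sample  n_control
3         A         0.396774  0.402389  0.411391  0.399897  0.00688086    0.395732        0.00628705    true        true        true         4         4
```

All six truly edited sites are recovered: the corrected means sit within
one percent of the generating truth 0.40 (the ~0.007 control mean is the
channel-crosstalk background that the correction removes), and both
criteria pass at every site. `sangeredit plot out/results.tsv -o
profile.png` draws the editing-percent profile along the amplicon with
significant sites highlighted.

Other subcommands: `quantify` (AB1 → peak-area CSV), `characterize`
(Monte-Carlo power / type-I error of the criteria), `calibrate`
(mix-series OLS fit), `caps` (cleaved fractions and group test).

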