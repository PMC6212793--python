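# focistat

Quantitative analysis of a defined number of CRISPR/Cas9-induced DNA
double-strand breaks (DSBs) and their cell-cycle consequences, with a
fully synthetic, ground-truthed data generator for every input.

## The problem

Inducible Cas9 systems can introduce a countable number of DSBs: a guide
RNA matching *n* genomic sites can break 2 alleles per site in G1 cells and
4 in G2. The damage is read out as nuclear foci of markers such as γH2AX or
53BP1 in fixed cells, as focus retention in live imaging, and as cell-cycle
timing in FUCCI reporter cells. `focistat` implements the full analysis
chain for this kind of experiment:

- **Segmentation** — nuclei detected by thresholding the median-filtered
  DAPI channel (Otsu by default), touching nuclei split by a watershed on
  the smoothed distance transform.
- **Focus detection** — the marker channel is background-subtracted with a
  Difference-of-Gaussians filter; a focus is a connected pixel group whose
  filtered intensity exceeds the nuclear background (per-nucleus median) by
  *k*-fold (default 2) the median background SD of all nuclei, exceeds an
  absolute minimum, and covers strictly more than a minimum area (default
  16 px).
- **Tracking** — greedy nearest-neighbour linking of foci across frames
  (no gap closing); retention = frames × interval.
- **Break-number model** — per-allele cut fraction
  `F(t) = p_max (1 − exp(−(t − t_lag)/τ))` for `t > t_lag`
  (defaults `t_lag = 2 h`, `τ = 6/ln 2 h`, so half of all alleles are cut
  at 8 h), expected foci per nucleus
  `background + n_sites (f_G1·2 + f_G2·4) F(t)`, a Monte-Carlo
  simulator of concurrent (cut-but-unrepaired) foci, and an indel-spectrum
  classifier splitting repair products into NHEJ-type small indels
  (+1, +2, −1…−4) and resection-dependent deletions (≤ −5).
- **Cell-cycle statistics** — cumulative S-phase/mitotic entry curves,
  quantile-crossing delay, relative entry reduction, micronucleation fold
  change with Fisher's exact test, Welch *t* and one-way ANOVA with
  Bonferroni-corrected pairwise comparisons.
- **Synthetic data** — seeded generators for two-channel image fields with
  planted nuclei and foci, per-cell break-event timelines, focus
  time-lapses, FUCCI-style single-cell tracks (transient G2 delay, partial
  G1 arrest, micronucleation on division), and multinomial indel spectra.

## Worked example

```python
import numpy as np
from focistat import (
    CutKinetics, DetectionParams, FieldSpec, GuideTarget, PhaseMix,
    background_stats, detect_foci, dog_filter, expected_foci,
    generate_field, sample_focus_counts, segment_nuclei,
)

guide = GuideTarget("HS1", n_sites=1)          # one genomic target site
kinetics = CutKinetics()                       # half-maximal cutting at 8 h

# plant per-nucleus focus counts drawn from the break model (G1 cells,
# 2 alleles, cut probability 0.5 at 8 h, Poisson background of 3)
counts = sample_focus_counts(guide, kinetics, t=8.0, n_nuclei=8, seed=0,
                             fraction_g1=1.0)
dapi, marker, truth = generate_field(FieldSpec(foci_per_nucleus=counts), seed=1)

labels = segment_nuclei(dapi)
params = DetectionParams(abs_min=80.0)
filtered = dog_filter(marker, params)
stats, global_sd = background_stats(filtered, labels)
result = detect_foci(filtered, labels, stats, global_sd, params)

# segmentation assigns its own label order, so compare count multisets
print("nuclei:", labels.n_labels)
print("planted: ", sorted(truth.focus_count(i) for i in range(1, 9)))
print("detected:", sorted(result.counts.values()))
print("mean detected:", np.mean(list(result.counts.values())))
print("model expectation:",
      expected_foci(guide, PhaseMix(1.0, 0.0), 8.0, kinetics, background=3.0))
```

Output:

```
nuclei: 8
planted:  [3, 3, 3, 4, 5, 5, 7, 8]
detected: [3, 3, 3, 4, 5, 5, 7, 8]
mean detected: 4.75
model expectation: 4.0
```

Eight nuclei are segmented, every planted focus is recovered, and the mean
per-nucleus count scatters around the closed-form expectation of 4
foci/nucleus (1 site × 2 alleles × 0.5 cut fraction + 3 background foci;
the mean of this particular 8-nucleus draw is 4.75).

A demo of the whole pipeline (three guide conditions, per-stage TIFF/CSV
outputs, JSON summary) runs with `focistat run --seed 0 --out demo/`; see
`focistat --help` for the other subcommands (`simulate`, `segment`,
`detect`, `track`, `expect`, `curves`, `compare`, `classify-indels`).

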