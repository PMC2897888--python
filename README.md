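# chipgas

A ChIP-seq analysis toolkit for transcription-factor binding sites of the
STAT1 / GAS type, built for epigenomics analysts who work from mapped tag
coordinates rather than raw reads. It implements the classic SGA-format
workflow — strand-aware tag centering, fragment-size estimation by +/−
displacement correlation, fixed-threshold peak calling — together with a
variable-spacer hidden Markov model of the GAS motif, integer
position-weight-matrix scanning, occupancy and induction statistics, and
repeat/tandem/conservation annotation analyses. A synthetic data generator
plants known sites, repeats and conservation signal so the entire pipeline
runs and is testable at desk scale.

## The model in brief

**Tag centering.** ChIP-seq tags mark fragment 5′ ends, so + and − strand
tags flank a bound site at roughly one fragment length *L*. The histogram
of signed distances between + and − tags peaks at *L*; shifting + tags by
+*L*/2 and − tags by −*L*/2 stacks both on the fragment midpoint.

**Peak calling.** Every centered SGA line is a candidate. With window *w*,
vicinity *v*, threshold *T* and count cut-off *C*, position *p* is a peak
iff `s(p) = Σ_{|q−p| ≤ w/2} min(count(q), C) ≥ T` and `s(p) > s(q)` for
every other candidate within *v*/2 (ties to the leftmost).

**GAS motif.** The motif is two half-sites, TTC…GAA, around a spacer of 2,
3 or 4 bp. A hidden Markov model with three parallel spacer branches is
refined by Baum–Welch on peak-centered windows; when the spacer-3 branch
dominates, it collapses to an 11-position probability matrix `p_ib`,
converted to integer weights

    w_ib = int( (3 / ln 2) · ln(p_ib / q_b) ),   q_b = 1/4,

so +3 score units correspond to a doubling of a base frequency over
background. Sites score as the sum of per-position weights.

**Induction.** Binding change between stimulated and unstimulated
conditions at a locus or annotation class is the natural log ratio of
pseudocounted, library-normalized tag counts:

    ln( ((c_stim + 1) / N_stim) / ((c_unstim + 1) / N_unstim) ).

## Worked example

Simulate a two-condition experiment, recover the fragment length, call
peaks and rank repeat families by induction:

```python
from chipgas.synth import SimulationConfig, generate_truth, simulate_tags
from chipgas.tagproc import (center_tags, displacement_histogram,
                             estimate_fragment_length)
from chipgas.peakcall import call_peaks
from chipgas.annotate import repeat_induction_table

cfg = SimulationConfig(seed=1)
truth = generate_truth(cfg)
stim = simulate_tags(truth, "stimulated")
unstim = simulate_tags(truth, "unstimulated")

est = estimate_fragment_length(displacement_histogram(stim, 0, 500))
print(f"fragment length: {est.length} bp  (centering shift {est.centering})")

stim_c = center_tags(stim, est.centering)
unstim_c = center_tags(unstim, est.centering)
peaks = call_peaks(stim_c)   # window 200, vicinity 400, threshold 50
print(f"peaks called: {len(peaks)}  (planted sites: {len(truth.sites)})")

table = repeat_induction_table(stim_c, unstim_c, truth.repeat_intervals,
                               cfg.stim_library_total,
                               cfg.unstim_library_total, min_coverage_kb=1)
print(table[["class_label", "name", "ln_ratio", "tags_stim",
             "tags_unstim", "coverage_kb"]].to_string(index=False))
```

Output:

```
fragment length: 139 bp  (centering shift 70)
peaks called: 110  (planted sites: 240)
class_label     name  ln_ratio  tags_stim  tags_unstim  coverage_kb
        LTR SynMER41      4.85       8500           56         8.25
       SINE   SynAlu      0.76          4            1         7.50
        LTR    Class      4.85       8500           56         8.25
       SINE    Class      0.76          4            1         7.50
```

The displacement mode recovers the planted 140 bp fragment length to
within a base pair, giving the 70 bp centering shift. 110 peaks cover the
planted sites (tandem pairs 21 bp apart merge into single peaks; weak
sites fall below the threshold of 50 tags). The induced synthetic LTR
family tops the induction ranking by a wide margin, while the control SINE
family shows only pseudocount noise around zero.

The same pipeline is available from the shell:

```sh
chipgas simulate --seed 1 --outdir sim
chipgas center sim/tags_stimulated.sga stim_centered.sga --shift 70
chipgas peak stim_centered.sga peaks.sga
chipgas induction --stim 68619 --unstim 3978 \
        --nstim 15250744 --nunstim 13019977   # prints 2.69
```

## Layout

| module              | contents                                                        |
|---------------------|-----------------------------------------------------------------|
| `chipgas.sga`       | SGA/BED/interval/wiggle I/O, sort-order enforcement             |
| `chipgas.tagproc`   | centering, displacement histogram, fragment length, correlation |
| `chipgas.peakcall`  | window-sum peak caller, peak-set matching                       |
| `chipgas.motif`     | spacer-branch HMM, Baum–Welch, integer PWM, scanning, k-mers    |
| `chipgas.occupancy` | tag-count occupancy, induction log-ratio, consensus profiles    |
| `chipgas.annotate`  | repeat/tandem/compartment/TSS/conservation analyses             |
| `chipgas.synth`     | synthetic genomes, annotations, tracks and two-condition tags   |
| `chipgas.cli`       | `chipgas` command with one subcommand per stage                 |

See `docs/methods.md` for the modeling decisions and their rationale.
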