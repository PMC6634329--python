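# pupiltag

Decoding perceptual dominance in binocular rivalry from induced pupil-size
oscillations ("pupil frequency tagging"), with a synthetic-data generator
that emulates the dichoptic luminance-modulation experiment end to end.

## The problem

In binocular rivalry, two incompatible images — one shown to each eye —
alternate in visual awareness while the physical stimulation stays
constant. If each image's luminance is modulated sinusoidally at a common
frequency *f* (1.7 Hz) but with an inter-eye phase offset Δφ ∈ {90°, 180°},
the pupil light response entrains to the *perceived* stimulus: the phase of
the induced pupil oscillation, relative to the stimulus, carries the
identity of the currently dominant image. `pupiltag` implements the full
analysis chain that extracts this signature:

1. **Preprocessing** — reject samples whose change rate exceeds 5 SD of
   the block's change-rate distribution, remove 50 ms around each blink,
   fill gaps with gap-local cubic splines, z-standardize each block.
2. **Per-cycle F1 extraction** — chunk the trace into 588 ms presentation
   cycles (one modulation period, aligned so the left-eye sinusoid starts
   at −90°), label each cycle with the exclusively reported percept, and
   compute the complex Fourier component at the modulation frequency,

   `Z = (2/N) Σₙ xₙ [cos(2πn/N) + i·sin(2πn/N)]`,

   so Im(Z) is the sine-phase (reference-aligned) content and Re(Z) the
   cosine-phase content of the cycle.
3. **Decoding** — two-sided paired t-tests on Im(Z) between left-eye- and
   right-eye-reported cycles; single-cycle ROC/AUC classification; and an
   upper decodability bound from the optimal complex-plane rotation
   (scores Im(Z·e^(−iθ)), θ searched in 1° steps over [0°, 180°)).
4. **Behavioral statistics** — median exclusive-dominance durations, a
   2 (stimulus type) × 7 (condition) repeated-measures ANOVA with
   generalized η²_G, attention-instruction comparisons with the d_s effect
   size, and a noncentral-*t* sensitivity analysis.

The analytic backbone is the two-source mixture model: if the dominant
percept drives the pupil with weight *w* and the suppressed percept with
1 − *w*, the summed oscillation has amplitude `|w + (1 − w)·e^(iΔφ)|`
relative to a single source — 91% for *w* = 0.9 at Δφ = 90°, 80% at 180°,
and √0.5 ≈ 71% / 0 for equal weights.

Because real experiments are expensive, the package ships a first-class
synthetic-data generator (`pupiltag.synthetic`): gamma-distributed
dominance durations (median 2.7 s) with mixed-percept interludes, a
delayed, inverted, percept-weighted pupil response to the two luminance
signals, slow drift, white noise, and blink artifacts — everything the
pipeline has to cope with, plus the lag-free ground truth it can be
scored against.

## Worked example

```sh
python examples/04_decode_percept.py
```

simulates six subjects in three 120 s conditions, cleans every block,
extracts per-cycle Z and prints:

```
   condition  mean_auc_im  mean_auc_opt     im_t   im_p  auc_p
mod0_control       0.4714        0.5847   2.4310 0.0593 0.3419
mod180_naive       0.9929        0.9959 -80.8708 0.0000 0.0000
 mod90_naive       0.9693        0.9859 -30.1874 0.0000 0.0000
```

`mean_auc_im` is the group-mean area under the ROC when each 588 ms cycle
is classified from Im(Z) (0.5 = chance). The counterphase (180°) and
90°-shifted conditions decode the dominant percept almost perfectly at the
generator's default signal-to-noise ratio, and the paired t-test on Im(Z)
(`im_t`, `im_p`) is decisively significant; the in-phase control carries no
percept information, so its AUC stays at chance and its t-test is null —
the qualitative contrast the method lives on. The other examples
(`examples/01…05`) walk through the mixture model, the session generator,
the preprocessing report and the sensitivity analysis one capability at a
time.

The same pipeline is scriptable from a shell:

```sh
pupiltag simulate --seed 7 --out session/
pupiltag preprocess --in session/block2_mod180_naive_trace.tsv --out clean.tsv
pupiltag cycles --trace clean.tsv --events session/block2_mod180_naive_events.tsv \
         --condition mod180_naive --out cycles.tsv
pupiltag run-all --seed 1 --subjects 6 --out results/
```

## Layout

```
src/pupiltag/
  io.py            data containers + TSV/YAML formats
  synthetic.py     session generator with ground truth
  preprocessing.py artifact rejection, padding, interpolation, z-scoring
  cycles.py        cycle segmentation, labelling, F1 extraction
  decoding.py      mixture model, paired tests, ROC/AUC, optimal rotation
  behavior.py      dominance statistics, rm-ANOVA, sensitivity analysis
  pipeline.py      end-to-end drivers
  cli.py           thin command-line front end
docs/methods.md    model, assumptions, numerical choices, limitations
examples/          one narrative script per capability
```
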