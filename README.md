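# odorpop

Single-unit and population analyses of odour-evoked spiking, for
electrophysiologists working with sorted extracellular recordings from the
olfactory bulb and its cortical targets. The package reimplements, as a
tested and reusable pipeline, the standard analysis chain for experiments in
which a homologous odorant series (aldehydes of carbon chain length C3–C8)
is presented repeatedly to a head-fixed animal:

* **Response classification.** Per unit-odour pair, the trial-averaged
  firing rate is z-scored against the pre-stimulus baseline,
  `z_t = (FR_t − FR_baseline) / σ_baseline` in 100 ms bins with the baseline
  taken over −2.5 to −0.5 s. A pair is *odour-excited* if the mean z over
  the odour window (0 to +0.5 s) exceeds +1.96, *odour-inhibited* below
  −1.96. Peak amplitude, width at half prominence, and time to peak are
  extracted per response.
* **Discriminability.** Pairwise `d′ = |μ_A − μ_B| / σ_RMS` on odour-window
  spike counts, with `σ_RMS = √((sd_A² + sd_B²)/2)`.
* **Chemical-similarity coding.** Per-unit responses normalized to the
  strongest odour response, summarized as ranked-response curves and as
  curves over carbon-chain distance |Δc|, compared across genotypes with
  two-way (and mixed repeated-measures) ANOVAs and Šídák post-hocs.
* **Population geometry.** Euclidean distances between trial population
  vectors (per-unit spike counts, 0–0.5 s), within- vs cross-odour, tested
  with Welch (or Brown–Forsythe) ANOVA and Games–Howell post-hocs.
* **Decoding.** A subsampled leave-one-trial-out classifier: random unit
  subsamples in steps of 10, 500 iterations per step, joint PCA to 4
  dimensions, one full-covariance Gaussian per odour class (equal priors),
  with a kNN/ECOC control model; accuracy tested one-sided against the
  6-class chance level 1/6.
* **Synthetic sessions.** An inhomogeneous-Poisson generator that emulates
  the experimental design (6 odours × 19 trials, 500 ms stimulus, ≥ 2.5 s
  baseline) with genotype presets — control: chain-length-tuned amplitudes
  decaying as `exp(−|Δc|/λ)` and intact inhibition; mutant: flat tuning,
  weaker and temporally blurred responses, reduced inhibition — so every
  stage is testable without any recording on disk.

A raw-trace preprocessing stage (common average referencing, 300–5000 Hz
4th-order zero-phase Butterworth, threshold detection at 7.5 × the median of
the absolute signal) validates the event-detection formulas; spike sorting
is out of scope and synthetic sessions are born sorted.

## Worked example

```python
import odorpop as op
from odorpop import decoding, responses, similarity

session, truth = op.generate_session(op.control_preset(n_units=60, seed=7))

fr = responses.response_fractions(responses.session_zresponses(session))
print(fr["fraction_responsive_units"], fr["n_excited_pairs"], fr["n_inhibited_pairs"])
# 0.58 responsive units; 62 excited and 15 inhibited unit-odour pairs

rel = similarity.relative_responses(responses.response_strengths(session))
print(similarity.chain_distance_curve(rel))
#  chain_distance  mean   sem  count
#               1 0.796 0.013     98
#               2 0.718 0.019     76
#               3 0.664 0.027     60
#               4 0.643 0.032     44
#               5 0.570 0.051     22
print(similarity.chain_distance_effect(rel))
# F(4, 295) = 11.7, p = 8e-09  -> graded similarity coding

pop = decoding.build_pseudopopulation([session])
curve = decoding.decode_accuracy(pop, sizes=[10, 30, 60], iters=500, seed=7)
print(curve.to_frame())
#  size  accuracy  binom_p
#    10     0.540      0.0
#    30     0.746      0.0
#    60     0.910      0.0
```

The relative response strength falls monotonically with chain distance
(graded coding of chemical similarity), and decoding accuracy grows with
population size, far above the 0.1667 chance level — the signatures the
pipeline is designed to quantify. The mutant preset
(`op.mutant_preset(...)`) abolishes the chain-distance gradient and lowers
the decoding curve.

The same stages are available from a shell:

```bash
odorpop simulate --genotype control --n-units 60 --seed 7 --out bundle/
odorpop responses --bundle bundle/ --out resp/
odorpop decode --bundle bundle/ --sizes 10:10:60 --iters 500 --seed 7 --out dec/
odorpop report --control-bundle c1/ --mutant-bundle m1/ --out report/
```

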