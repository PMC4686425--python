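# kogbody

Quantitative analysis of Kog1-body formation experiments in budding yeast.

When glucose-starved yeast inactivate TORC1, the substrate-recruiting
subunit Kog1 (the yeast Raptor ortholog) leaves the vacuolar membrane and
condenses into a single perivacuolar body. Studies of this process lean on
a small set of quantitative analyses, and `kogbody` packages all of them as
a tested, reusable library:

* **Band-shift densitometry** (`kogbody.bandshift`) — TORC1 activity is read
  out from the SDS-PAGE mobility shift of its substrate Sch9: phosphorylated
  species migrate more slowly. Each lane profile *I* (index 0 = top of gel)
  is total-signal normalized against a *t* = 0 control and scored as
  Σᵢ wᵢ·Iᵢ, with weights falling linearly from 100 at the first pixel
  ("100% phosphorylated") to 0 at the last. An affine transform then pins
  the wild-type 2%-glucose lane to 1.0 and the 0%-glucose lane to 0.0, and
  rescales every other lane with the same constants.
* **Exponential kinetics** (`kogbody.kinetics`) — the fraction of cells with
  bodies over time is fit by nonlinear least squares to
  *A*(1 − e^(−t/τ)) + *c* (starvation/formation) or *A*·e^(−t/τ) + *c*
  (repletion/dissociation), or to a line when nothing changes; standard
  errors come from the fit covariance.
* **Prion-like motif quantitation** (`kogbody.prilm`) — Kog1 agglomeration
  depends on two glutamine/asparagine-rich prion-like motifs (PriLMs).
  The module counts Q+N content of stated intervals (the count/percentage
  pairs of ortholog comparison tables), scans sequences for Q/N-rich
  intervals by sliding-window composition, and applies in-silico Q/N→A
  disruption.
* **Foci counting** (`kogbody.foci`) — z-stacks are collapsed to maximum
  projections; punctate bodies are detected (Gaussian smoothing, robust
  median + k·MAD threshold, connected components), assigned to cells and
  summarized as the body-positive fraction with a Wilson 95% interval, plus
  two-channel co-localization fractions.
* **Exact contingency inference** (`kogbody.contingency`) — viability of
  phosphomimetic alleles is inferred from loop-in/loop-out clone counts with
  Fisher's exact test computed by exact integer hypergeometric enumeration.
* **Synthetic data** (`kogbody.simulate`) — generators for all four input
  kinds (gel lanes, time courses, sequences, cell image stacks) with known
  ground truth, so every analysis is testable end-to-end without raw data.

## Worked example

Fit the body-formation kinetics of a simulated glucose-starvation time
course (3 replicates, 200 cells inspected per timepoint):

```sh
$ python examples/kinetics_fit.py
t (min)  mean fraction  sd
      0          0.075  0.005
      5          0.253  0.031
     ...
     60          0.573  0.033

truth: A=0.49, tau=11.0 min, c=0.08
fit:   A=0.493+/-0.017, tau=11.7+/-1.0 min, c=0.077+/-0.015
```

The fit recovers the generating parameters within their standard errors: ~49%
of cells form a body during starvation with an apparent time constant of
~11 min on top of an 8% baseline. The other capabilities each have a
matching script under `examples/` (band-shift scoring, motif scanning and
disruption, foci counting, viability inference).

The same stages are available from a thin CLI for file-based, reproducible
runs (identical config + seed ⇒ byte-identical outputs):

```sh
kogbody simulate --kind timecourse --spec tc.yaml --seed 1 --out sim/
kogbody kinetics --data sim/timecourse.tsv --model formation --out fits.tsv
kogbody fisher --table 7,3,0,20 --alternative greater --bound 0.0001
kogbody run --config pipeline.yaml --out run/
```

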