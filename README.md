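# rloopkin

Analysis toolkit for CRISPR–Cas9 R-loop dynamics, built for the
quantitative readouts of combined ensemble + single-molecule studies of
guide-RNA engineering: how modifications to a gRNA (extra 5′ nucleotides,
appended RNA hairpins) change ribonucleoprotein loading, R-loop
formation/dissociation kinetics, R-loop size, and plasmid cleavage rates.

It is aimed at single-molecule biophysicists and enzymologists who have
(or want to simulate) four kinds of records:

| input | analysis |
| --- | --- |
| plasmid cleavage time courses (supercoiled → nicked → linear counts) | sequential first-order kinetic fits, per replicate, averaged |
| magnetic-tweezers bead traces (60 Hz extension vs magnet turns) | smoothing, phase segmentation, R-loop step detection, dwell times |
| dwell-time collections | survival curves, single/double-exponential fits, model selection, concentration dependence |
| rotation ("hat") curves ± enzyme | pairwise turn-shift estimation, turns → bp calibration, group comparisons |
| emission spectra under 530/630 nm excitation | (ratio)_A loading readout, dye-labelling efficiency |

A seeded synthetic-data module (`rloopkin.synth`) generates all of these
with ground-truth sidecars, so the whole pipeline is testable end to end.

## The models

**Cleavage kinetics.** SC →(k_a) OC →(k_b) LIN, solved in closed form
(Bateman); optionally preceded by R-loop formation,
U →(k_formation) R →(k_a) OC →(k_b) LIN, integrated adaptively with the
observed SC = U + R (R-loop-bound uncut plasmid co-migrates with SC).
Fits minimise squared residuals over all three species jointly and
support clamping any rate (e.g. k_a = 0.14 s⁻¹) while the others float.

**Dwell times.** The empirical survival function P(T > t) = 1 − rank/N is
fitted with S(t) = e^(−t/τ) or
S(t) = a·e^(−t/τ_slow) + (1−a)·e^(−t/τ_fast); AICc on the raw-dwell
likelihood arbitrates one vs two components. Formation rates follow
rate = k·Cⁿ on log–log axes.

**R-loop sizing.** A trapped R-loop shifts the negative flank of the
extension-vs-turns curve by the turns it absorbs. Every reference curve
is paired with every trapped curve (20 × 22 = 440 shift estimates);
bp = 20 × mean_turns / mean(full-length turns).

**(ratio)_A.** Acceptor peak under 530 nm excitation (sensitized, with
optional donor bleed-through correction) over the acceptor peak under
630 nm excitation — high for apo Cas9, low once a gRNA is loaded.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate one scintillation-counting cleavage time course (true rates
k_a = 0.1 s⁻¹, k_b = 0.01 s⁻¹, 2000 counts/lane) and fit it:

```sh
$ rloopkin simulate cleavage --seed 11 --out sim
wrote synthetic cleavage to sim
$ rloopkin fit-cleavage --model two_step sim/cleavage.csv
{
  "model": "two_step",
  "per_replicate": [
    {
      "replicate": "rep0",
      "params": {
        "k_a": 0.10071293580977986,
        "k_b": 0.009750706643444377
      },
      "rss": 0.002362140694853775,
      "converged": true
    }
  ],
  "averaged": {
    "k_a": { "mean": 0.10071293580977986, "sd": NaN },
    "k_b": { "mean": 0.009750706643444377, "sd": NaN }
  }
}
```

The fitted first- and second-strand cleavage rate constants (0.1007 and
0.00975 s⁻¹) recover the generator truth to within the Poisson counting
noise; `sd` is NaN because a single replicate has no spread (the result
carries an explicit single-replicate flag). The same pattern applies to
the other subcommands (`analyze-traces`, `fit-dwells`, `size-rloop`,
`ratio-a`), and `rloopkin run` chains a complete synthetic study —
simulate, analyze, fit, report — into one JSON report with a seed-bearing
manifest.

From Python:

```python
from rloopkin.synth import SynthConfig, gen_rotation_curves
from rloopkin.rloopsize import aggregate_shifts, turns_to_bp

config = SynthConfig(seed=1)
refs = gen_rotation_curves(config, 20, 0.0, prefix="ref")
trapped = gen_rotation_curves(config, 22, 1.9, prefix="rl", index_offset=100)
estimate = aggregate_shifts(refs, trapped)     # 440 pairwise shifts
estimate.mean_turns                            # ~1.9 turns
```

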