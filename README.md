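# lethalmap

Analysis machinery for balancer-chromosome screens of naturally occurring
recessive lethal mutations, written for population geneticists running (or
re-analysing) *Drosophila* second-chromosome screens: wild chromosomes are
captured over the CyO balancer, scored for homozygous lethality, localized by
deficiency complementation, grouped into allelic sets by pairwise crosses,
and resolved to candidate mutations from whole-genome variant tables.

The package covers the full chain of estimators such a screen needs:

- **Lethal-fraction estimation** under the screen's distinct-chromosome
  counting rules (male sublines may resample the same chromosome; female
  sublines are recombinants and are deduplicated at random), with binomial
  SE and 95% CI.
- **A zero-truncated Poisson null model** for the number of
  deficiency-mapped lethal mutations. With non-lethal proportion P0,
  λ = −ln P0 and a lethal chromosome carries λ/(1 − e^(−λ)) lethal mutations
  on average, so X1 lethal chromosomes scanned over a coverage fraction *c*
  should yield X1 · c · λ/(1 − e^(−λ)) mapped mutations; the CI of P0 is
  propagated through the same transform. Falling far short of this
  expectation indicates multigenic or gain-of-function lethality. A
  calibrated prediction interval for a single realized screen is also
  provided, plus the mutation-selection-balance yardstick q = √(μ/s).
- **Complementation interpretation**: lethality, deficiency and knock-out
  cross scoring (≥35 balanced offspring, 0 wildtype), conservative merging
  of overlapping deficiencies into distinct regions, allelism graphs with
  intransitive-triad detection, and allelic-set sample frequencies.
- **Genomic-landscape correlation** of per-deficiency mapping frequency
  (mapped / size / crosses) with coding density, recombination rate, or GC
  content.
- **Candidate-mutation filtering** (HIGH/MODERATE impact, inside the
  fine-mapped interval, absent from non-allelic lines), read-depth-ratio
  detection of heterozygous terminal deletions, and KING-robust kinship
  between balanced lines.
- **A forward simulator of the whole screen** (`lethalmap.synthetic_data`)
  whose defaults mirror the study conditions, used throughout the test suite
  and available for power and calibration studies.

See `docs/methods.md` for the model, its assumptions, and the design choices.

## Worked example

The screen's headline numbers from the library:

```python
from lethalmap import ChromosomeCount, lethal_fraction, nonlethal_proportion
from lethalmap import mapping_expectation

count = ChromosomeCount(n_lethal=262, n_total=555)
print(round(100 * lethal_fraction(count).p))        # 47  (% lethal chromosomes)
exp = mapping_expectation(nonlethal_proportion(count), x1=262, coverage_fraction=0.67)
print(exp.rounded())                                # (238, 230, 246)
```

or from the shell:

```console
$ lethalmap nullmodel --n 555 --lethal 262 --x1 262 --coverage 0.67
{
  "p0": 0.527927927927928,
  "lam": 0.6387955047293671,
  "ztp_mean": 1.353173683682438,
  "expected_mapped": 237.5361084336152,
  "ci": [229.57356676957318, 246.3328424689812],
  "rounded": [238, 230, 246]
}
```

Reading: 53% of the 555 distinct chromosomes are non-lethal, so lethal
mutations arrive at λ ≈ 0.64 per chromosome and each lethal chromosome
carries ≈1.35 of them; scanning 262 lethal chromosomes over 67% of the
chromosome should map ≈238 lethal mutations (95% CI 230–246) if all are
single-locus loss-of-function. An observed mapped count in this range is
consistent with single-locus lethality; a large shortfall is not.

A full synthetic screen, end to end:

```console
$ lethalmap simulate --seed 7 --outdir demo
wrote 566 sublines, 19810 crosses to demo
$ lethalmap freq --sublines demo/sublines.tsv --allelism demo/allelism.tsv --seed 7
{
  "n_lethal": 239.0,
  "n_total": 475.5,
  "n_excluded": 58,
  "lethal_fraction": 0.5026288117770767,
  "lethal_percent": 50,
  "ci": [0.45768759647424645, 0.5475700270799071],
  "p0": 0.49737118822292326
}
```

566 sublines from 410 simulated flies collapse to 475.5 distinct chromosomes
after the counting rules (58 sublines excluded as female or allelic
duplicates), half of them lethal — consistent with the generator's lethal
rate of 1 − e^(−0.639) ≈ 0.47 at this seed. Other subcommands (`map`,
`allelic`, `landscape`, `filter`, `depthratio`, `kinship`) drive the
remaining stages from the same fixture files.

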