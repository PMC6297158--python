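# Methods

## Correction model

Stable-isotope tracer experiments measure, per metabolite, one signal
per labeling state. Two processes scramble the true state amounts
before measurement:

1. **Natural isotope abundance.** Every atom not fixed by the tracer
   label draws its isotope from the element's natural abundance table.
   The total nominal mass shift of a fragment is the sum of independent
   per-atom shifts, so its distribution is the convolution of per-atom
   tables — a binomial for two-isotope elements (C, H, N), a multinomial
   collapsed by total shift for O, Si, S. This moves signal from lighter
   to heavier channels.
2. **Tracer impurity.** Each nominally labeled position carries the
   tracer isotope only with probability equal to the substrate's
   isotopic purity, i.e. a Binomial(t, purity) over the t labeled
   positions. This moves signal from heavier to lighter channels, and
   both directions must be modeled simultaneously when purity
   correction is enabled.

For a molecule with k labeling states these distributions form the
columns of a k×k matrix P; the measured vector is v_m = P·v_c. The
corrected vector solves min‖P·v_c − v_m‖₂ subject to v_c ≥ 0
(Lawson–Hanson NNLS via `scipy.optimize.nnls`, the global optimum of
this convex problem; when the unconstrained solution is feasible the
two coincide). Corrected values are also reported as fractions
(v_c normalized to 1) and as per-tracer mean enrichment
Σ_s t_i(s)·f(s) / n_i.

### Modes

* **ms1** — single tracer, nominal resolution; channels at shifts
  i·(tracer shift), i = 0…n. k = n+1.
* **msms** — the measured unit is a precursor/product transition
  (p, q); label can sit in the product ion (q of it) and in the neutral
  loss (p − q). The entry for species (t_prod, t_nl) at channel (p, q)
  is the product of the two fragments' independent shift distributions.
  k = (n+1)(m+1).
* **highres** — mass defects are resolved, so the only interference on
  a tracer element's observed label count comes from that element's own
  tracer isotope: Binomial(t, purity) over labeled positions convolved
  with Binomial(N_e − t, a_e) over the element's remaining atoms
  (labelable and plain alike), where a_e is the tracer isotope's
  natural abundance. Non-tracer elements, and non-tracer isotopes of
  tracer elements, are treated as spectrally resolved and contribute
  nothing to the measured channels. Per-element distributions combine
  as an outer product over tracer elements. k = Π(n_i+1).

### Channel binning and dropped mass

Measured MS1 bins sit at integer multiples of the tracer shift; for
tracers with shift > 1 (e.g. ¹⁸O) intermediate shifts produced by
natural abundance fall between bins. Such mass — and mass beyond the
heaviest bin, produced by heavy isotopes on derivatization atoms — is
treated as unmeasured and dropped, so column sums of P may be < 1.
Dropped mass per column above 1e-6 is surfaced as a run-log warning.
Row and column orderings are lexicographic ascending everywhere, which
makes outputs byte-reproducible.

## Parameters

| parameter | meaning | default |
|---|---|---|
| isotope abundances | per-element shift:abundance table | packaged IUPAC values (C 0.9893/0.0107; H 0.999885/0.000115; N 0.99636/0.00364; O 0.99757/0.00038/0.00205; Si 0.92223/0.04685/0.03092; S 0.9499/0.0075/0.0425/0.0001 at shift 4) |
| tracer shift | nominal shift of the tracer isotope | 1 for the packaged C and N tracers |
| tracer purity | probability a labeled position carries tracer, per element, unitless in (0, 1] | 1.0 unless set in the element file or per run |
| `purity_correction` | include impurity terms in P | on |
| `residual_warn` | relative-residual data-quality threshold | 0.05 |
| `strict_na` | withhold samples with missing cells instead of zero-filling | off |

The default element table ships with C and N designated as tracers
(shift 1) because ¹³C and ¹⁵N are the dominant tracers in metabolomics;
any element can be (re)designated in a user-supplied table, including
multi-shift tracers such as ¹⁸O.

## Missing values and degenerate inputs

Empty measurement cells count as missing: by default they enter the
solve as 0 with a logged warning; under `strict_na` the whole
molecule/sample result is withheld. Negative measured intensities are
clamped to 0 with a warning. An all-zero measured vector yields an
all-zero corrected vector, undefined fractions (empty output cells) and
a warning. A condition-number estimate above 1e12 attaches an
ill-conditioning warning to the result. The residual-warning threshold
0.05 is a package choice for flagging poor data quality; it is
configurable and has no effect on the numbers.

## Synthetic data and what it shows

The simulator applies the correction matrix forward, v_m = P·v_c, to
known truth — the same reverse application used to validate correction
tools against mixtures of known composition. Packaged scenarios:

* **Alanine isotopomer mixtures** (four mixtures of m+0…m+3 components;
  the two singly labeled isotopomers are pooled into m+1 since nominal
  MID data cannot distinguish positional isotopomers). The TMS
  derivative formula is parameterized by the number of TMS groups
  (default 2, i.e. LabC3C6H23NO2Si2).
* **Composition series**: hypothetical molecules with one labelable
  carbon and varying plain C/Si content, equal true m+0 and m+1 —
  isolates how molecular composition drives the uncorrected-ratio
  distortion (the 10-carbon molecule shows ratio ≈ 0.894 instead of 1).
* **Two-tracer scenario**: a ¹³C₄/¹⁵N₂ asparagine-like core (k = 15)
  with truth concentrated on highly labeled states flanked by
  low-abundance states one tracer atom lighter — the regime where
  impurity contributions from adjacent states dominate, and where
  skipping purity correction inflates those states most. The truth
  values are fixture constants of this package.
* **Random datasets**: seeded uniform truth on [0, 100) per state,
  optional relative Gaussian noise truncated at zero on the measured
  vectors. The noise model is a plain stand-in for peak-integration
  error; it reproduces none of the structured biases of real
  chromatography (saturation, coelution, baseline), so passing
  round-trip tests demonstrates algorithmic correctness of the
  correction, not robustness to real instrument artifacts.

## Numerical choices

Convolutions are exact double-precision sparse-dict operations; no
term pruning is applied by default (probabilities are kept exactly as
computed). The NNLS solve and all accumulation are double precision;
the correction path contains no randomness, so identical inputs give
bit-identical outputs. Output CSV numbers carry 10 significant digits.
Test oracles enumerate every per-atom isotope assignment exhaustively
(exponential cost), so oracle-checked molecules are kept to ≤ 12 atoms
with bounded assignment counts; engine and oracle agree to ~1e-15,
comfortably inside the 1e-12 assertion bound.

## Known limitations

* Nominal shifts only — no exact masses, mass defects, adducts or
  charge states > 1; no partially resolved intermediate between the
  nominal and high-resolution extremes.
* MS/MS assumes product-ion and neutral-loss isotope draws are
  independent given the label split.
* High-resolution mode assumes every non-tracer isotope is fully
  resolved from every measured channel.
* Purity is a single per-element value (uniform across positions).
* CSV is the only input dialect; spreadsheet input is out of scope.
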