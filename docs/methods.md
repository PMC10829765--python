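# Methods

## Model and procedure

The package operationalizes the prioritization stage of a horizon scan of
nanotechnology-enabled health products (NHPs). Its unit of analysis is the
*detected signal*: one record from a literature, patent or clinical-trial
scan, classified with a four-position signature and one or more design
solution codes (DSCs). Only signals marked `selected` enter the analysis;
discarded rows are retained for the per-(source, period) tallies.

**Novelty.** Following the design-creativity metric of Shah and
co-workers, the novelty of design solution *i* is

    S_i = (T − C_i) / T × 10,

with `C_i` its frequency and `T` the total number of selected signals.
`T` is deliberately the number of *signals*, not of distinct DSCs and not
the sum of DSC counts: a multifunctional signal increments each of its
DSCs' counts but contributes once to `T`. Only this convention reproduces
the reference scores (C = 95, T = 836 → 8.86; C = 61 → 9.27; C = 1 →
9.99). Scores are computed at full precision; display rounding is
half-up to 2 decimals with `.` as the decimal separator.

**Quartile selection.** DSCs are ordered by descending count, ties broken
by canonical DSC string ascending (determinism). Each DSC occupies the
half-open cumulative interval `(before, before + C]`. A DSC is a *trend*
iff its interval opens below `q1_fraction × T` (default 0.25) — the DSC
whose interval crosses Q1 is included. Mirror rule at the other end: a
DSC is a *tentative wild card* iff its interval closes above
`q3_fraction × T` (default 0.75). On the reference structure (T = 836,
top counts 95/61/61, tail ≤ 45) this yields exactly 3 trend DSCs covering
217 signals: the third DSC's interval (156, 217] straddles Q1 = 209. The
tentative wild-card *signal* set comprises selected signals carrying at
least one tentative-wild-card DSC and no trend DSC. If the two crossings
collapse onto the same DSC (tiny or single-entry spectra) the selection
is flagged degenerate, a warning is emitted, and the overlapping DSCs are
reported as trends only.

**Enrichment.** The raw score of a tentative wild card is the novelty of
its exact DSC *combination* — `C` counts selected signals with the same
DSC set — because a multifunctional product is the unit being prioritized
and a one-off combination among 836 signals scores 9.99 whatever its
component DSCs' frequencies. Four criteria multiply into a correction
factor: unspecific Y/Z codes (0, the signal is removed, else 1); DSC
count (1 → 1, 2 → 3⁄2, > 2 → 2); DSCs shared with trends (0 → 2, 1 → 2⁄3,
> 1 → 1⁄2); signature equal to some trend signal's signature (yes → 1,
no → 2). The product rule is a design choice: the printed factors are
ratios and the zero factor must annihilate the score, which only
multiplication honors. Zero-factor signals are excluded before ranking
rather than ranked at 0. The nonzero factor range over the 3 × 3 × 2 grid
is [1⁄2, 8]; the maximal product 8 requires a ≥ 3-DSC signal sharing
nothing with the trends. Final selection defaults to *max-cluster* (all
signals attaining the maximal corrected score — after enrichment the
distribution segregates), with *top-k* as an alternative.

**Regulatory matching.** Each regulatory document carries the signature
pattern of the NHP type it addresses; `n` is a per-position wildcard and
`0` the literal "undefined" code. Strict matching requires every
non-wildcard position of the document's pattern to intersect the query's
code set; composition codes match exactly, with the self-assembling `s`
flag significant (`3s` ≠ `3`). Lenient mode additionally lets code 0 on
either side match its position. For *flagging*, a stricter full-coverage
predicate is the default: a document counts as specific guidance only if
it admits every code of every (possibly multivalued) query position —
guidance covering one component function of a multifunctional product is
not specific guidance for the product. For single-valued queries full
coverage coincides with strict matching. Trend DSCs are queried by the
modal signature of the signals carrying them; wild cards by their own
signature. Document status (draft/current/final) is carried through but
never affects matching.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `q1_fraction` | 0.25 | Q1 mark on the cumulative signal-count axis |
| `q3_fraction` | 0.75 | Q3 mark (tentative wild-card threshold) |
| rounding | 2 dp, half-up | display only; arithmetic is full precision |
| `mode` | max-cluster | final wild-card selection rule |
| `lenient` | off | relax literal 0 in regulatory matching |
| `flag_full_coverage` | on | gap flag requires full positional coverage |

## The synthetic generator

`generate(GeneratorConfig(...))` emulates the classified-signal layer of
the scan — never bibliographic text, patent claims or trial metadata.
Defaults are the study conditions:

* per-(source, period) selected/discarded counts fixed to the nine scan
  strata (selected totals 102 literature + 524 patents + 210 trials =
  836; discarded rows get reasons from a small pool);
* planted trends `B.T.2.3` × 95, `E.T.2.1` × 61, `C.T.2.3` × 61, each
  signal's signature drawn from a per-trend pool whose mode matches the
  dominant classification reported for that trend (e.g. `2.3.2.1` for
  polymer nanocarriers, `2.3.3s.1` for lipid ones); the dental trend is
  biased 70% toward the clinical-trials stratum;
* five planted triple-DSC wild cards with unique combinations, no DSC
  shared with the trends, and exactly one multivalued signature position;
* a Zipf-like tail for the remaining single-DSC signals: rank-r frequency
  `45·r^−0.6` floored at 1, plus a 15% singleton layer and unspecific
  Y/Z codes at rate 0.05.

The tail exponent is calibrated so the Q3 crossing falls in the
moderate-frequency region (counts ≈ 5) and ≈ 25% of signals lie past it,
mirroring the reference tail share (26%) and the reference range of
tentative wild-card scores (≈ 9.89–9.99, i.e. frequencies up to ~9 near
the crossing). This placement also makes the planted-structure assertions
seed-robust: every count ≤ 2 DSC — in particular all components of the
planted wild cards — lies past Q3 regardless of how ties order within a
count group. A much steeper tail would push the crossing inside the
count-1 tie group, where the deterministic string tie-break, not
frequency, would decide which singletons count as wild cards.

Everything stochastic flows from one `numpy` `default_rng(seed)`: same
seed, byte-identical CSV; different seeds change only tail composition
and placement, never the planted structure. What passing tests show is
therefore that the *arithmetic and selection rules* behave as specified
on data with the assumed structure — not that real scan data has that
structure. In particular the real frequency spectrum beyond the top three
counts is not public, so all tail-shape claims are property-based; and
real signals exhibit cross-source duplication and classification noise
the generator does not model.

## Numerical choices and degenerate inputs

* Quartile thresholds compare exact integers against `fraction × T`
  (float); with the default quarters and integer counts no crossing can
  sit within rounding distance of the boundary, so no epsilon is needed.
* Frequency ties: canonical-string ascending, everywhere.
* Corrected-score ties in ranking: `signal_id` ascending.
* Correction factors are exact `fractions.Fraction`s; corrected scores
  become floats only at the final multiplication.
* Single-entry or all-tied spectra: the Q1 rule still selects the first
  tie-broken DSC; the joint selection flags degeneracy instead of
  reporting the same DSC as both trend and wild card.
* Empty selection (no `selected` signals) is an error for spectrum
  construction; empty enrichment input is an error for final selection.

## Known limitations

* One signal = one NHP; multi-DSC signals are never split, and
  cross-source deduplication is out of scope.
* The treating/prophylactic split of mode-1 design problems rides on the
  DSC effect qualifier (`T` treating, `P` prophylactic by default); only
  `T` is attested in the packaged vocabulary, so the split is exercised
  synthetically. Likewise the in-vitro-diagnostic split is a DSC-level
  override table with no packaged entries.
* The packaged regulatory table covers galenic-function NHPs only;
  DSC-level document tagging (documents addressing a design solution
  rather than a signature) is not modelled for lack of packaged ground
  truth — the dental trend is therefore flagged insufficient against the
  packaged table even though broader guidance exists elsewhere.
* The per-source scan tallies are taken from the scan-results table; the
  narrative selected-count for clinical trials (195) disagrees with that
  table's column sum (210), and only 210 is consistent with the grand
  total of 836, so the table governs.
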