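# Provenance notes for the packaged lassi study fixtures.
design:
  mixture_total_pct: 84.5        # dahi + microgreen juice + water; sugar 15% + CMC 0.5% excluded
  components: [juice, dahi, water]
  lower_bounds: {juice: 5.0, dahi: 60.0, water: 15.0}
  upper_bounds: {juice: 9.5, dahi: 64.5, water: 19.5}
  notes:
    - >
      Runs 12 and 15 are published rounded to 2 dp (61.88/5.75/16.88 and
      60.75/6.88/16.88, summing to 84.51); the fixture stores the evident
      unrounded design values 61.875/5.75/16.875 and 60.75/6.875/16.875 so
      every run sums exactly to the fixed mixture total.
optimum:
  amounts_pct: {juice: 9.189, dahi: 60.0, water: 15.311}
  desirability: 0.781            # published headline; goal set not published, not reproducible
  notes:
    - >
      The published observed ascorbic acid at the optimum (59.32 +/- 0.20)
      duplicates the DPPH row and conflicts with the day-0 narrative value
      62.85; the table value is stored as printed.
storage:
  temperatures_C: [5, 15, 25]
  days: [0, 3, 6, 9, 12, 15]
  replicates: 3
rates:
  notes:
    - >
      The published rate-constant table labels its middle temperature "10";
      the methods text specifies storage at 5, 15 and 25 C, so the fixture
      encodes it as 15 C.
    - >
      Yeast & mold first-order k at 25 C prints 0.6560, an order of magnitude
      above every other first-order entry (probable typo for 0.0656); stored
      as printed.
    - >
      Published t_half values for acidity and tba are ~1-2% below C0/(2k)
      recomputed from the printed C0 and k, likely computed from unrounded
      quantities; they are stored as printed.
fit_stats:
  notes:
    - >
      The whc adjusted R^2 is garbled in the source text and stored as
      missing. The color_appearance CV column (0.12) is inconsistent with
      the printed mean/SD pair and is stored as printed.
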