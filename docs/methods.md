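# Methods

## Scope and model

`iemscreen` models a two-tier tandem-MS newborn-screening programme for
inborn errors of metabolism (IEMs). A dried-blood-spot panel quantifies 41
primary markers (11 amino acids, free carnitine C0 and 29 acylcarnitine
species, μmol/L) from which 13 analyte ratios are derived, including the
composite ratios C0/(C16 + C18) and (C16 + C18:1)/C2. Screening compares
every marker against a fixed reference interval; a specimen is *primary
positive* per a configurable trigger policy, positives are recalled for a
repeat specimen (some are lost to follow-up), the recall panel is re-flagged
with the same cut-offs, and recall positives go to diagnostic confirmation.
Confirmation is treated as an oracle input (a diagnosis map, or the
simulator's truth labels): the confirmatory biochemistry and sequencing are
outside computational scope.

The packaged fixtures are the Liuzhou programme's published panel: the
cut-off table, the 16 disorder signatures with their per-tier observed case
ranges, the disease-spectrum counts for 111,986 newborns (30 confirmed) and
7,461 high-risk infants (19 confirmed), and the 49-patient genotype tables.

## Flagging and matching

* **Interval convention.** Cut-off intervals are closed by default: a value
  exactly on a bound is normal. The source material never states strictness;
  closed is the conservative screening convention (it never flags a specimen
  the printed bounds could call normal). An "open" policy is available per
  cut-off table.
* **Missing values** never flag. A panel missing more than 10% of its markers
  is logged as a QC failure but still processed.
* **Ratio extensions.** Phe/Tyr (0.2–2.0), Cit/Phe (0.14–0.72) and Met/Phe
  (0.25–1.2) appear only in per-disorder reference columns of the source, not
  in its main cut-off panel; they are packaged as tagged `table3-extension`
  entries because four disorder signatures require them. Where per-disorder
  reference columns disagree with the main panel (C6, C10, C12, C14, C18:1),
  the main panel governs flagging and the per-disorder values are retained as
  `reported_reference` metadata.
* **Trigger policies.** Whether the lab's primary-positive rule was
  single-marker or full-pattern is not stated, so both are first-class:
  `any_abnormal_marker` (default; one out-of-range marker suffices) and
  `any_pattern_match` (a full disorder signature must be satisfied).
* **Pattern matching.** `all_markers` mode requires every signature marker to
  deviate in its stated direction; `any_marker` requires one. Candidates are
  ranked by fraction of the signature satisfied, ties broken lexicographically.
  MMA and PA carry identical signatures (C3, C3/C2, C3/C0 high) and are
  biochemically indistinguishable at this tier — both are always reported and
  the final call belongs to confirmation. Directions are derived from the side
  on which the printed observed range leaves the reference interval, not from
  pathophysiology, and are validated against the fixture at load time.

## Summary statistics

Rates are exact rational arithmetic with half-up rounding at the displayed
digit (one decimal for rates, integer option for carrier shares). Incidence
is presented as "1/N" with N = round-half-up(screened/cases) and comma
grouping; half-up is the unique convention consistent with both printed tie
cases (1,243.5 → 1,244 and 3,730.5 → 3,731), and the golden-fixture sweep in
the test suite checks every printed spectrum row of both cohorts. PPV uses
recalled specimens as its denominator (confirmed / recalled), matching the
published definition "confirmed cases / positive recalls". The chi-square
statistic is the plain Pearson Σ(O−E)²/E with margin-derived expectations,
df = (r−1)(c−1), and no continuity correction by default (a Yates flag
exists for 2×2 tables); tests cross-check it against an independent
reference implementation.

## Cohort simulator

The screened cohort itself is not deposited, so population-level results are
reproduced structurally from a generator whose defaults *are* the published
study conditions:

| parameter | default | origin |
|---|---|---|
| `prevalence` | per-disorder cases / 111,986 | published newborn spectrum |
| `prevalence_high_risk` | cases / 7,461 | published high-risk spectrum |
| `target_primary_positive_rate` | 0.022 | published 2.2% |
| `alpha` (healthy panel FP prob.) | solved: (0.022 − P)/(1 − P), P = Σprevalence | calibration to the funnel |
| `loss_rate` | 1 − 2,275/2,464 ≈ 0.0767 | published recall loss |
| `fp_persistence`, `tp_persistence` | 1.0 | recalled positives persist in the published funnel; confirmation discriminates |
| `noise_cv` | 0.10 | typical MS/MS re-measurement repeatability; no value is published |
| `healthy_marker_alpha` | 0.05 | per-marker shape of the healthy marginals |

**Healthy marginals** are independent log-normals — the reference intervals
are the only population information available, and independence is the
minimal assumption. Location is the interval's log-midpoint; scale is solved
in closed form so the tail mass outside [L, U] equals `healthy_marker_alpha`,
split equally between tails. Markers printed with L = 0 have no lower tail:
the location is anchored two decades below U (an assumed dynamic range) and
the scale is solved one-sided. `healthy_marker_alpha = 0` degenerates to a
point mass at the midpoint (σ clamped to 0).

**Panel-level calibration.** Ratios share numerators and denominators, so
per-marker tail masses do not compose into a panel positive rate; notably the
Met/Phe extension interval sits almost on the healthy log-midpoint ratio, and
independent marginals alone would flag a large share of healthy panels.
The false-positive probability is therefore imposed at the panel level: with
probability 1 − α a healthy panel is rejection-sampled until *every* marker,
ratios included, is in range (capped attempts; the cap failing is reported as
a model/cut-off inconsistency); with probability α one uniformly chosen
primary marker is drawn from a tail (side split evenly where both exist).
This makes the expected primary positive rate exactly α + (1 − α)·Σprevalence.

**Affected panels** draw each signature marker uniformly over its printed
per-disorder (min, max) range — the only distributional fact published — at
the matching tier (preliminary vs re-examination ranges). Non-signature
markers come from the healthy model. Ratio signatures are honoured
deterministically: signature primaries are set first, then each signature
ratio in pattern order; if the drawn primaries already satisfy the printed
ratio range nothing changes, otherwise the ratio's denominator primary (the
sole/last denominator member) is back-solved to a freshly drawn target. Every
printed signature range lies wholly outside its reference interval, so
affected specimens are primary positive by construction.

**Recall.** Primary positives are lost with `loss_rate`; surviving specimens
get a repeat panel: multiplicative log-normal noise (mean 1, CV `noise_cv`)
on all markers, then (i) persistent affected specimens redraw their signature
from the re-examination ranges — using the published recall-tier data rather
than noise alone, which could otherwise cross a cut-off by chance and break
exact sensitivity; (ii) persistent healthy false positives redraw their
forced marker from the tail; (iii) non-persistent specimens redraw as fully
in-range healthy panels and screen negative at recall.

**Randomness.** One root seed; each specimen owns a spawn-keyed child stream
(separate sub-stream for its recall draws), so cohorts are byte-stable under
reordering and two runs with the same config are identical.

**What the generator does not emulate:** analyte covariance (unknowable from
the published material), gestational-age/birth-weight covariates, batch and
seasonal effects, referral bias in the high-risk cohort beyond its higher
prevalences, and specimen-quality failure modes. Passing tests therefore
demonstrate the pipeline's correctness and calibration under these stated
conditions, not distributional fidelity to the real population.

## Variant catalog

Variant identity is the normalized printed string keyed by gene — no
transcript or reference sequence accompanies the tables, so positional
normalization would be invention. The c.-notation parser covers the dialects
that occur: substitutions, del/dup/ins/delins (with or without stated bases),
intronic offsets (plus the legacy `IVS` token; spacing like "c.252 + 1G > A"
is normalized), free-text gross deletions ("2-7exon del", "1076bp del"), and
the printed hyphen-range dialect ("c.132-134del…", disambiguated from
intronic offsets by requiring an offset magnitude exceeding its own base).
Unparseable strings — including the verbatim "c.580A>" genotype printed
without an alternate base — are retained and counted by string identity;
parsing never gates counting. Homozygotes contribute two occurrences;
single-variant records (the OTC cases and one PCCB case) contribute one.

Novelty is double-booked: membership in the publication's canonical
unreported-variant list and the tables' "#" marks, which disagree for a few
variants. Text-vs-table conflicts (including the SLC22A5 narrative total of
26 allele occurrences vs the 28 derivable from the tables, whose own quoted
28.6% frequency equals 8/28) are listed in
`variant_catalog.KNOWN_DISCREPANCIES` and surfaced, never silently merged;
counts always follow the tables.

## Numerical and sizing choices

* All displayed rounding goes through exact `Fraction` arithmetic; no binary
  float ever decides a half case.
* Truncated log-normal sampling uses inverse-CDF (Φ⁻¹ of a uniform restricted
  to [Φ(a), Φ(b)]) with the uniform clamped away from 0/1 by 10⁻¹⁵.
* Simulation-based tests run at n = 300–10,000 specimens (the calibration
  check at n = 10,000, ~240 expected positives), sized so Monte-Carlo bands
  (3 SEs) are meaningful while the default suite stays fast; all stochastic
  tests are fixed-seed.

## Known limitations

* The healthy model is a modelling device fitted to interval endpoints, not a
  fitted population distribution; α-level calibration is exact but marker
  covariance is absent.
* The confirmed-case ranges are per-marker; joint structure within an
  affected specimen's signature (beyond back-solved ratios) is not modelled.
* `any_pattern_match` positivity is not calibrated to the published 2.2%
  (the published trigger rule is unknown; the default policy is calibrated).
* Single-case disorders have degenerate (point) observed ranges; their
  simulated specimens are correspondingly less variable than reality.
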