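# Methods

`camvote` re-implements the classification-processing chain used by large
citizen-science camera-trap surveys of the Snapshot Serengeti type: many
untrained volunteers each classify a capture event (a 1–3 photo burst from
one camera trigger), and the toolkit turns that pile of individual answers
into a single consensus record per event with explicit certainty metrics,
validates it against expert labels, and exports detection histories for
ecological models. A synthetic volunteer simulator stands in for the
multi-million-row survey download so the whole chain is testable at desk
scale.

## Retirement of image sets

While in circulation, each capture event accumulates classifications until
one of four stopping rules fires, checked after every answer in this order:

| rule | condition | default |
|---|---|---|
| Blank | first *k* answers all 'nothing here', consecutively | k = 5 |
| Blank_Consensus | *k* 'nothing here' answers in total | k = 10 |
| Consensus | *k* matching answers of the same species *set* | k = 10 |
| Complete | *k* non-blank answers, agreement not required | k = 25 |

"Matching" compares species sets: a lion-zebra answer advances only the
lion-zebra tally, never the lion-only one. Retirement is absorbing; answers
arriving afterwards (live deployments re-circulate images, so 11–57 answers
per animal image are typical) are tallied separately and still feed
consensus. Thresholds are configuration (`retire.*` keys) with the deployed
values as defaults. The evaluation order follows the listed order; only
constructed edge cases (e.g. a blank run of 5 when both blank thresholds
are 5) depend on it.

One subtlety: the published per-volunteer streams for the three reference
image sets bundled in `camvote.examples` are *samples* of the full streams
those images received. The Complete-retired antelope sample
(`ASG000xzxd`) contains 22 animal answers and 3 blanks, so replaying the
sample alone does not reach the 25-non-blank threshold; the tests assert
instead that its tally reaches no other rule, which is what makes Complete
the only retirement consistent with it.

## Normalization

Volunteers sometimes repeat a species within one answer to give two
behaviours ('1 zebra, standing' + '1 zebra, moving'). Before aggregation
these merge into one annotation per species: behaviour and young flags are
OR-ed, and counts combine by lower-bound arithmetic with saturation on the
ordinal scale — numeric bins sum exactly (1+1→2), sums landing in 11–50
give that bin, and anything past 50 (or any 51+ operand) saturates at 51+.
This is the unique order-preserving extension of the one exact worked case
(1+1=2) onto the bin scale; it is commutative and monotone, which the
property tests exercise. Merging never crosses ClassificationIDs: the raw
table keeps each volunteer's answer intact.

## Plurality consensus

For one capture event with at least one non-blank answer:

1. **Richness** S\* = median over non-blank classifications of the number
   of distinct species named. Half-integer medians round *down* (floored at
   1): expert comparisons show missed-second-species errors dominate over
   invented-species errors, so the conservative direction matches observed
   volunteer behaviour.
2. **Species**: the S\* species with most votes. Ties at the cut are broken
   by votes, then alphabetically, and always flagged so downstream analyses
   can drop them — the published three-way antelope tie (impala /
   Grant's gazelle / dik dik at 5 votes each in the sample) is flagged, not
   silently resolved.
3. **Count** per winning species: median of the reported bins on the
   12-level ordinal scale 1…10, 11–50, 51+; even-length medians take the
   lower middle bin so the result is always a real bin.
4. **Behaviours and young**: proportion of classifications *naming that
   species* which set the flag — the only conditioning consistent with a
   per-species output schema.
5. **Certainty**: Pielou's evenness of the vote distribution,
   J = −(Σᵢ pᵢ ln pᵢ)/ln S over the S distinct species voted, with pᵢ each
   species' share of all species votes; defined as 0 on unanimity. 0 means
   a confident crowd, 1 a maximal split; for multi-species images evenness
   is intrinsically high and not a useful accuracy gauge. Percent support
   = NumVotes/NumClassifications, whose denominator deliberately includes
   blank answers (a blank is information that the image is hard), while
   evenness and vote tallies exclude them.

All-blank events emit nothing: the consensus table covers animal-containing
events only. Events are aggregated whether or not they formally retired.

## Validation against expert labels

Each gold-covered event falls in exactly one category: correct (species
sets equal), impossible (experts declared the image unidentifiable — always
counted incorrect, since volunteers have no such option), missed_species
(consensus ⊂ gold), extra_species (consensus ⊃ gold), wrong_species
(otherwise). Per-species accuracy excludes impossible events. Count
agreement is computed over events where consensus captured all or a subset
of the true species, as exact-bin share and within-±1-bin share, where ±1
is ordinal adjacency (10 and 11–50 are adjacent); both a pooled and a
single-species-events-only version are reported because group images make
counts intrinsically harder. Evenness separation reports mean ± s.e. of
evenness for correct vs incorrect events.

## The simulator

`camvote.simulate` generates the study conditions, not an arbitrary
benchmark. Defaults: 73% of scenes blank (the share of real triggers that
were heat/vegetation misfires), species drawn from the observed relative
capture frequencies of the 48 options (wildebeest and zebra dominant, 5%
of animal scenes with two species), true group size decaying geometrically
across bins, scene difficulty ~ Beta(2, 5), volunteer pool of 100,
per-volunteer base accuracy 0.85, blank-when-unsure propensity 0.3 scaled
by difficulty, geometric count displacement (step 0.25) truncated at the
scale ends, 5% behaviour-flag flips, and 0.2% of gold rows marked
impossible. All randomness flows from one seed through NumPy SeedSequence
spawning; a fixed seed reproduces output byte-for-byte.

Two structural choices matter:

* **Errors concentrate on hard images and agree with each other.** A
  volunteer misidentifies with probability (1 − accuracy) ×
  difficulty²/E[difficulty²] (capped at 0.9), so the marginal error rate
  stays at the configured level while hard images absorb most mistakes;
  and a misidentification goes, with probability 0.7, to a *scene-level*
  look-alike species shared by all volunteers (the rest scatter along the
  volunteer's confusion row). This mirrors how real crowds err — an
  ambiguous gazelle looks like the *same* wrong gazelle to everyone. With
  independent errors only, a 20-volunteer plurality vote is essentially
  never wrong and the observed evenness gap between correct and incorrect
  answers cannot arise; with difficulty-coupled, correlated errors the
  simulated survey lands at 95–97% consensus accuracy with incorrect
  events showing markedly higher evenness — the qualitative pattern of
  real expert validations, under unchanged headline conditions.
* **Unsure volunteers answer blank.** The probability of a blank answer on
  an animal scene is blank_propensity × difficulty, reproducing the
  observed use of 'nothing here' as an "I don't know" substitute; this is
  why NumBlanks is a useful difficulty signal downstream.

What the simulator does **not** model: volunteer learning over time,
image pixel content, per-species difficulty differences beyond the
look-alike structure, temporally clustered herds, and camera failures.
Passing recovery tests therefore show that the aggregation machinery
behaves correctly under realistic error structure — not that any particular
real survey reaches a particular accuracy.

## Capture histories

Operation intervals (per SD card, inclusive dates) convert to a site ×
time-bin effort matrix by counting each active day once per site, so
overlapping cards never double-count and splitting an interval changes
nothing. Bins are half-open [start, end) multiples of whole calendar days
in camera-local time (UTC+3, no DST), putting midnight events in exactly
one bin. Days not covered by any card count as zero effort (gaps between
cards are treated as downtime). Detection histories mark presence or count
events per site/bin; detections on zero-effort cells are flagged, never
dropped. Relative abundance is events per 100 trap-days per site.
Certainty filtering (percent support / evenness / NumBlanks thresholds) is
an analyst choice, so it is an optional pre-filter, not a default.

## Numerical and interface choices

* Count bins are interned objects with a total order; all medians and
  distances are ordinal — nothing is interpolated between bins.
* Species labels are matched case-insensitively after trimming, with
  typographic apostrophes folded to ASCII and published spelling variants
  (G. gazelle, lion (female&cubs), rodent, …) aliased to the canonical
  48-entry vocabulary; `blank` and `impossible` are reserved tokens, the
  latter legal only in gold tables.
* Behaviour flags are written 0/1 and read as 0/1 or Y/N.
* Blank raw rows carrying stray count/behaviour values are ingested as
  blank with a warning rather than rejected.
* CSV columns mirror the public release schemas exactly; the consensus
  writer can append two non-schema diagnostics (Tie, PercentSupport) on
  request. CLI outputs carry provenance comment headers (`#`-prefixed)
  that every reader skips; `--no-provenance` disables them.

## Problem sizes used in the tests

The test suite runs the oracle checks at full enumeration (every count
multiset of size ≤ 7 over the 12 bins; 1,000 random evenness tallies) and
the recovery study at 2,000 scenes × {1, 5, 10, 20} volunteers × 3 seeds,
with a shared 300-scene survey for pipeline and round-trip checks — sizes
chosen so the whole suite completes in seconds while keeping binomial
interval checks comfortably powered.

## Known limitations

* The published headline validation figures of the original survey derive
  from its full raw-classification download, which this package does not
  ship; the validation module recomputes all of those quantities from any
  consensus+gold pair supplied to it.
* Contiguous grouping: the raw reader groups rows sharing
  (CaptureEventID, ClassificationID) only when adjacent, as in the released
  files; an interleaved file would split a classification.
* The tie-break (votes, then alphabetical) is a deterministic convention;
  the original deployment's rule is not documented, which is precisely why
  ties are flagged.
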