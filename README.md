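# camvote

Aggregation toolkit for crowd-sourced camera-trap classifications.

Large camera-trap surveys in the Snapshot Serengeti mould ask thousands of
untrained volunteers to classify each capture event (a 1–3 photo burst from
one camera trigger): which of 48 species/species-group options are present,
how many individuals (on the ordinal scale 1…10, 11–50, 51+), what they are
doing, and whether young are present — or 'nothing here' for the roughly
three-quarters of triggers that are misfires. `camvote` is for the
ecologists and citizen-science researchers who must turn that pile of
noisy individual answers into analysis-ready data. It implements:

* **Retirement** — the streaming stopping rules that take an image set out
  of circulation: *Blank* (first 5 answers blank), *Blank_Consensus*
  (10 blanks total), *Consensus* (10 matching species-set answers),
  *Complete* (25 non-blank answers), checked in that order.
* **Plurality consensus** — species richness S\* as the median number of
  species named per classification (half-integers round down); the S\*
  top-voted species win; per-species counts are ordinal-bin medians and
  behaviours become vote proportions. Certainty comes as Pielou's
  evenness of the vote distribution, J = −(Σᵢ pᵢ ln pᵢ)/ln S (0 on
  unanimity, 1 on a maximal split), and percent support
  NumVotes/NumClassifications.
* **Validation** — comparison against expert gold-standard labels: overall
  and per-species accuracy, the mismatch taxonomy (impossible / missed /
  extra / wrong species), count-bin agreement (exact and within ±1 bin),
  and the evenness separation between correct and incorrect answers.
* **Capture histories** — site × time-bin search-effort (trap-days) and
  species detection matrices, plus relative abundance per 100 trap-days,
  the inputs occupancy and N-mixture models expect.
* **A volunteer simulator** — synthetic scenes and volunteers with
  confusion matrices, difficulty-coupled errors, blank-when-unsure
  behaviour and ordinal count noise, so the full pipeline is testable
  without the multi-million-row survey download.

I/O uses plain CSV mirroring the public Snapshot Serengeti release schemas
(`raw_data.csv`, `consensus_data.csv`, `gold_standard_data.csv`,
`search_effort.csv`, `all_images.csv`) byte-compatibly.

## Worked example

`camvote.examples` bundles the published per-volunteer classification
streams for three reference image sets. Two of them, replayed through the
retirement engine and the consensus algorithm:

```python
from camvote import aggregate_capture_event, run_stream
from camvote.examples import giraffe_stream, hyena_stream

events = giraffe_stream() + hyena_stream()
for cid, out in run_stream(events).items():
    print(f"{cid}: retired as {out.status} after {out.n_consumed} classifications")

for rec in aggregate_capture_event(hyena_stream()):
    print(f"{rec.capture_event_id}: {rec.species} (count {rec.count}), "
          f"{rec.num_votes}/{rec.num_classifications} votes, "
          f"evenness {rec.evenness:.3f}, support {rec.percent_support:.3f}")
```

prints

```
ASG0010cz5: retired as Consensus after 10 classifications
ASG0000009: retired as Consensus after 14 classifications
ASG0000009: spotted hyena (count 1), 10/14 votes, evenness 0.646, support 0.714
```

The giraffe image set collects its 10th matching classification and
retires on the spot. The hyena image set needed 14 answers before any
species set reached 10 votes; the plurality answer is a single spotted
hyena, but the scattered warthog/jackal/wildcat votes leave a non-zero
evenness of 0.646 and percent support of 0.714 — exactly the signals an
analyst would use to decide whether such records need expert review.

The same machinery is available from the shell:

```sh
camvote --seed 1 simulate --scenes 1000 --per-event 20 raw.csv gold.csv
camvote aggregate raw.csv consensus.csv
camvote validate consensus.csv gold.csv report.txt
camvote history consensus.csv effort.csv wildebeest out --mode counts
```

Subcommands are deterministic given inputs and `--seed`; every output
carries a provenance comment header unless `--no-provenance` is given.

## Layout

| module | contents |
|---|---|
| `camvote.tables_io` | readers/writers for the five CSV schemas, domain types |
| `camvote.normalize` | duplicate-species merging within a classification |
| `camvote.retirement` | streaming stopping rules |
| `camvote.consensus` | plurality algorithm and certainty metrics |
| `camvote.validation` | gold-standard comparison and reports |
| `camvote.capture_history` | effort matrices, detection histories, RAI |
| `camvote.simulate` | synthetic scenes, volunteers, gold tables |
| `camvote.cli` | `camvote` command group |
| `camvote.examples` | published worked-example streams |

See `docs/methods.md` for the full account of the algorithms, the
simulator's error model and its limitations.
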