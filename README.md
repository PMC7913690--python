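# snstrace

Toolkit for tracing the origin of silencing small RNAs with single-nucleotide
substitution (SNS) markers, and for reading out the DNA methylation they
induce.

## The problem

RNA silencing pathways produce two kinds of small RNA (sRNA): **primary**
sRNAs diced directly from the silencing trigger (e.g. a recombinant virus in
VIGS), and **secondary** sRNAs amplified from the target itself by
RNA-dependent RNA polymerases. Sequenced sRNAs from the two sources are
normally indistinguishable because trigger and target share the same
sequence. The marker strategy breaks this symmetry: the trigger is rebuilt
with single-nucleotide substitutions at regular intervals — spacing *s*
guarantees every sRNA of length *L* carries at least ⌊*L*/*s*⌋ − 1 (and for
*s* ≤ *L*, at least one) marker mismatch — so after sequencing, reads that
match only the marked reference are primary, reads that match only the
wild-type reference are secondary. Transition markers (A↔G, C↔T) preserve
pairing to the target through G:U wobble on one sRNA polarity; transversion
markers (A↔T, G↔C) do not.

The toolkit covers the full desk-side workflow:

* **`snstrace.triggers`** — design SNS-marked trigger variants, verify the
  per-read mismatch guarantee by window enumeration, annotate G:U wobble
  polarity, and project the markers onto a full-length locus to build the
  variant reference.
* **`snstrace.tracing`** — adapter-trim, size-select (21–24 nt), exactly map
  reads against both references, classify primary/secondary/ambiguous/
  unmapped, and report counts, per-position strand-resolved profiles and a
  transitivity score (fraction of non-primary coverage outside the trigger
  window — spread of amplification beyond the targeted region).
* **`snstrace.methylation`** — call cytosine methylation from bisulfite
  Sanger clones by bisulfite-aware global alignment, summarised per
  CG/CHG/CHH context with Wilson 95% score intervals, plus replicate-level
  t-tests between samples.
* **`snstrace.stats`** — Wilson intervals and the flowering-time partition
  (early ≤ 16, intermediate 17–22, late ≥ 23 rosette leaves at bolting) used
  as the phenotypic read-out of FWA promoter silencing.
* **`snstrace.simulate`** — seeded generators for loci, marked primary reads,
  secondary reads with configurable transitivity, and bisulfite clones with
  per-context methylation probabilities and conversion-failure noise.

## Worked example

```python
import snstrace as st

locus, windows = st.make_locus_fixture(seed=42)
w0, w1 = windows["promoter"]
fragment = st.TargetFragment(id="promoter_frag", sequence=locus[w0 - 1 : w1])
trigger = st.design_marked_trigger(fragment, st.SNSDesign(spacing=10))
print("SNS positions:", trigger.sns_positions())
print("guaranteed mismatches per 21-24 nt sRNA:",
      st.min_mismatches_per_read(trigger, {21, 22, 23, 24}))

variant_locus = st.project_sns_onto_locus(locus, trigger)
primary = st.simulate_primary_reads(trigger, variant_locus,
                                    st.SimConfig(seed=1, n_reads=2000))
secondary = st.simulate_secondary_reads(locus, (w0, w1),
    st.SimConfig(seed=2, n_reads=2000, transitivity_fraction=0.5))
report, classified, dropped = st.trace_library(
    primary + secondary, locus, variant_locus, trigger_window=(w0, w1))
print("class totals:", report.class_totals())
print(f"transitivity: {report.transitivity:.3f}")

clones, truth = st.simulate_bisulfite_clones(
    fragment.sequence, st.BisulfiteConfig(n_clones=12), seed=3)
matrix, summary, rejected = st.call_sample(fragment.sequence, clones)
print(summary.round(3))
```

prints

```
SNS positions: (5, 15, 25, 35, 45, 55, 65, 75, 85, 95, 105, 115)
guaranteed mismatches per 21-24 nt sRNA: 2
class totals: {'primary': 2000.0, 'secondary': 1000.0, 'ambiguous': 1000.0, 'unmapped': 0.0}
transitivity: 0.500
           m    n  proportion  wilson_low  wilson_high
context
CG       101  120       0.842       0.766        0.896
CHG       38   72       0.528       0.414        0.639
CHH       35  108       0.324       0.243        0.417
total    174  300       0.580       0.523        0.634
```

A spacing-10 design on a 120-nt fragment places 12 markers, so every 21–24 nt
sRNA carries at least two mismatches. All 2000 simulated trigger-derived
reads classify as primary; of the 2000 target-derived reads, the half
simulated inside the trigger window match only the wild-type reference
(secondary) while the half outside match both references (ambiguous — the
two references are identical there), and the transitivity score recovers the
simulated 0.5 spread. The clone summary recovers the generator's per-context
methylation probabilities (0.8 / 0.6 / 0.3) within their Wilson intervals:
for example 101 of 120 informative CG calls methylated, proportion 0.842,
95% interval (0.766, 0.896).

The same steps are available from the shell: `snstrace design`,
`snstrace trace`, `snstrace methyl`, `snstrace phenotype` and
`snstrace simulate locus|reads|clones` (see `--help` on each).

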