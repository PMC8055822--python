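# phosphoshift

Quantitative SILAC proteome/phosphoproteome analysis for nominating
bacterial kinase substrates from a knockout-vs-wild-type comparison
across a metabolic shift.

## The problem

When a poorly characterized protein kinase (here: *E. coli* YeaG, a
Ser/Thr kinase with a growth phenotype during the glucose→malate
shift) is knocked out, its substrates should lose or attenuate their
condition-dependent phosphorylation. Triple-SILAC labeling
(Lys0/Lys4/Lys8) lets wild type and knockout be quantified together:

* **Experiment 1**: WT·glucose (Lys0) + WT·malate (Lys4)
* **Experiment 2**: WT·glucose (Lys0) + ΔyeaG·glucose (Lys4) + ΔyeaG·malate (Lys8)

The WT·glucose Lys0 channel is the **common reference** that places
both mixes on one ratio scale. For each phosphosite the pipeline
computes per-strain shift ratios and their difference — a
ratio of ratios on the log scale:

```
S_WT  = log2( I(WT, malate)  / I(WT, glucose) )
S_KO  = log2( I(ΔyeaG, malate) / I(ΔyeaG, glucose) )
Δ     = S_KO − S_WT
```

(each S is the mean of per-replicate log2 ratios). The sign and size
of Δ splits sites into scenarios:

| scenario | rule | reading |
|---|---|---|
| `independent` | \|Δ − mean\| ≤ t | kinase has no influence on the site |
| `candidate_direct` | Δ − mean < −t | shift attenuated in the knockout: likely direct substrate |
| `candidate_indirect` | Δ − mean > +t | shift amplified: kinase normally restrains another kinase |
| `wt_only` | site never detected in the knockout, detected in WT in both conditions | presence/absence evidence, strongest candidates |

The threshold t is 2 population SDs of the Δ distribution by default
(`sd_based`), or a fixed log2 value for small fixtures. The same 2-SD
convention calls differentially expressed proteins on the
protein-level shift axes. Upstream of all this sit QC gates (label
incorporation ≥ 94 %, a 1:1 mixing check, replicate Pearson
correlation) and downstream a Fisher-exact / Bonferroni GO-term
enrichment of any protein subset against the detected background.

Because the original raw data are not publicly deposited, the package
bundles the published result tables (36 sites quantified in both
strains; 15 wild-type-only sites) as plain-text reference fixtures and
provides a seeded synthetic triple-SILAC generator with planted ground
truth, so the whole pipeline runs and is tested entirely offline.

## Worked example

Classify the bundled reference tables (inverted into noiseless channel
intensities in-process):

```sh
phosphoshift classify --reference-fixture --out demo/
```

`demo/sites_quantified_both.tsv` begins:

```
protein	site	residue	wt_shift	ko_shift	delta	scenario	threshold_used
GlyA	55	Y	-3.39	7.58	10.97	candidate_indirect	4.59
AceB	467	T	-0.60	5.01	5.61	independent	4.59
SerA	61	S	-0.42	4.11	4.53	independent	4.59
```

GlyA Y55 drops 3.39 log2 units on malate in the wild type but *rises*
7.58 in the knockout — Δ = 10.97, far beyond the 4.59 threshold
(2 SD of this 36-site Δ distribution), so it is flagged
`candidate_indirect`. With the wider fixed threshold of 1.0 log2 units
the three narrated exemplars separate cleanly: GlyA Y55 →
`candidate_indirect`, YjhQ T11 (Δ = −1.83) → `candidate_direct`,
Hfq T49 (Δ = 0.03) → `independent`.

`demo/sites_wt_only.tsv` lists the presence/absence candidates,
including isocitrate lyase:

```
protein	site	residue	wt_shift	scenario
AcnB	244	S	1.20	wt_only
AceA	398	S	0.94	wt_only
```

AceA S398 was detected in the wild type in both conditions (shift
+0.94) and never in the knockout — the class from which AceA was later
validated as a direct substrate.

A fully synthetic end-to-end run with a manifest of content digests:

```sh
phosphoshift all --seed 7 --out run/
```

which simulates a study-scale dataset (~1772 proteins, ~127 sites),
runs QC, quantification and classification, and writes
`run/manifest.json`; two runs with the same seed produce byte-identical
manifests.

## Layout

* `src/phosphoshift/design.py` — SILAC designs, common-reference
  integration, shift-ratio / delta algebra
* `src/phosphoshift/tables_io.py` — TSV quantification dialect,
  MaxQuant adapter, GAF reader, report writers
* `src/phosphoshift/qc.py` — incorporation, mixing, replicate
  correlation
* `src/phosphoshift/differential.py` — 2-SD proteome calls, scenario
  classification, wild-type-only detection
* `src/phosphoshift/enrichment.py` — Fisher exact GO enrichment,
  Bonferroni (optional BH)
* `src/phosphoshift/synthetic.py` — seeded generator with planted
  effects; printed-table inversion
* `src/phosphoshift/cli.py` — `simulate | qc | quantify | classify |
  enrich | report | all`

See `docs/methods.md` for the model, parameter defaults and known
limitations.
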