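# htfc — high-throughput flow-cytometry surface-antigen screening

`htfc` implements the analysis half of a plate-based cell-surface
screening platform: antibodies against hundreds of surface antigens are
arrayed one-per-well in 96-well plates ("an antibody array"), cells are
added, and a flow cytometer with a plate loader acquires every well. The
package turns the resulting per-well event data into percent-positive
marker profiles and the statistics built on them, and ships a synthetic
event generator so the entire pipeline is testable without an instrument.

It is aimed at cytometry and biomarker-discovery groups who want the
screen's informatics — gating, screening criteria, clustering — to be
reproducible and scriptable rather than manual.

## What it computes

For each well, events are filtered through a fixed gate chain and
summarised as a percent-positive value:

1. **Viability**: events with viability-dye (DAPI) signal above the
   control threshold are dead and excluded.
2. **Singlets**: doublets double their forward-scatter area and pulse
   width at unchanged height; events with FSC-W > 1.5 × median FSC-W are
   excluded.
3. **Positivity**: the threshold for each fluorescence channel is the
   99.9th percentile of an unstained fluorescence-minus-one (FMO)
   control well; *percent positive* = 100 × (viable singlet events above
   threshold) / (viable singlet events).

On the resulting sample × antigen matrix **P** the package provides:

- **Detectability**: antigen *a* is detected in a sample when
  P[s, a] ≥ 1% (the nominal limit of detection).
- **Treatment lability**: for untreated/treated percent pairs (u, t),
  Δ = |t − u| and fold = max(u′, t′)/min(u′, t′) with u′, t′ clamped
  below at the 1% limit. An antigen is *altered* by a preparation step
  (enzymatic digestion, fixation, cryopreservation) when Δ ≥ 5
  percentage points **and** fold ≥ 2; the one-criterion categories
  (`abs_only`, `fold_only`) are reported separately.
- **Reproducibility**: Spearman rank correlation ρ between replicate
  profiles (exact permutation p-value for n ≤ 8).
- **Lineage deconvolution**: ordered co-stain rules (CD45⁺ immune;
  CD45⁻CD31⁺CD34⁺ endothelial; CD45⁻TE7⁺ fibroblast; quad-negative
  cancer) split a heterogeneous sample into subpopulation-specific
  profiles.
- **Candidate markers**: antigens with mean ≥ 50% in a pure reference
  population and mean ≤ 20% in a comparison fraction, ranked by the
  difference.
- **Profile analytics**: k-NN imputation (k = 10), column mean
  centering, PCA, and hierarchical clustering with the Pearson
  correlation distance d = 1 − r under complete linkage, exported as
  Newick dendrograms.

The synthetic generator plants known truth — population abundances,
per-antigen positive fractions, dead/doublet rates, spillover, per-well
intensity jitter, treatment effects — so every stage is validated by
recovery of what was planted.

## Worked example

Run the full demo screen (24-antigen panel, one untreated and one
enzyme-digested sample, 10,000 events/well, master seed 1):

```bash
htfc all --seed 1 --out demo_out
```

or in Python:

```python
from htfc.pipeline import PipelineConfig, run_all
out = run_all(PipelineConfig(out_dir="demo_out", seed=1))
print(out["matrix"].loc[:, ["CD45", "CD44", "CD24", "CD326"]].round(1))
print(out["summary"]["counts"])
```

which prints

```
           CD45  CD44  CD24  CD326
sample
untreated  34.2  80.4  43.5   43.0
digested   35.8  81.0   8.9    8.2
{'undetected': 1, 'unaffected': 18, 'abs_only': 0, 'fold_only': 0, 'both': 5}
```

Reading: CD45 and CD44 are unchanged by digestion (34→36%, 80→81%),
while CD24 and CD326 (EpCAM) collapse from ~43% to ~9% positive — a
~35-point, ~5-fold loss. The category counts show 5 of the 23 detectable
antigens met both lability criteria (`both`); these are exactly the five
antigens the simulation perturbed (CD24, CD49f, CD54, CD166, CD326).
One antigen (CD144) sits below the 1% detection limit in both
conditions and is excluded from the denominator. `demo_out/` contains
the gate summaries, percent-positive matrix, screen results CSV, QC
report and a Newick dendrogram, each stamped with the config hash and
seed; reruns are byte-identical.

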