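# emtkit

Analysis toolkit for stimulus-dependent epithelial–mesenchymal transition
(EMT) signalling in breast-cancer cell models, built for two linked
questions:

1. **Which signalling pathways and network modules are dysregulated when
   EMT is induced** (by EGF or hypoxia), and which of the affected proteins
   are druggable?  From per-gene differential-expression tables, emtkit runs
   χ²-based pathway over-representation analysis (ORA), scores
   protein–protein interaction (PPI) network nodes with a beta-uniform
   mixture (BUM) model of the p-value distribution, extracts the
   top-scoring connected subnetwork per stimulus, merges the stimulus
   networks, and ranks drug-targetable nodes by degree.
2. **How well do kinase inhibitors revert the EMT phenotype** in a
   high-content screen?  From per-cell immunofluorescence tables, emtkit
   trains a decision-tree vimentin⁺/vimentin⁻ classifier on control wells,
   summarizes wells, computes percent inhibition, fits 4-parameter logistic
   dose–response curves with range-censored IC50s, and quantifies drug
   combinations with the Chou–Talalay median-effect combination index.

Because the underlying study's RNA-seq and screen images are not publicly
deposited, the package ships a first-class synthetic-data generator
(`emtkit.simulate`) that emulates every input — DE tables, GMT gene sets,
SIF networks, drug–target tables, 384-well per-cell plate tables and
combination grids — with recorded ground truth, so the entire pipeline is
testable at desk scale.

## The models in brief

* **ORA.** For each pathway, a 2×2 Pearson χ² (1 df, no continuity
  correction) compares observed vs expected differentially expressed
  transcripts (q < 0.01 by default) among the measured genes; raw p-values
  are Bonferroni-multiplied by the size of the signalling-map family (22 in
  the emulated design).
* **BUM node scores.** P-values are modelled as
  f(p) = λ + (1−λ)·a·p^(a−1).  Given a target FDR, τ is the largest
  threshold whose BUM-estimated FDR stays below it and each gene scores
  s(p) = (a−1)(ln p − ln τ); the maximum-score connected subgraph is found
  by an exact dynamic program on forests and a deterministic greedy
  heuristic otherwise (oracle-bounded against exhaustive enumeration in the
  tests).
* **Screen quantification.** Percent inhibition is
  100·(1 − (x − mean(x_pos))/(mean(x_neg) − mean(x_pos))); the IC50 is the
  absolute 50%-inhibition crossing of a 4PL fit of inhibition vs
  log₁₀(dose), reported as ">MAX"/"<MIN" when outside the tested range.
* **Synergy.** Single agents are linearized through the median-effect
  equation fa/fu = (D/Dm)^m; a combination point (dA, dB, fa) gets
  CI = dA/DxA + dB/DxB with Dx_i = Dm_i·(fa/(1−fa))^(1/m_i)
  (CI < 0.9 synergistic, 0.9–1.1 additive, > 1.1 antagonistic by default).

## Worked example

Simulate one EGF-stimulated MDA-MB-468 plate for a synthetic inhibitor
with planted IC50s (0.5 µM for %vimentin⁺, 2.0 µM for cell count) and
quantify it end to end:

```python
from emtkit import SimulationConfig, simulate_screen_plate, quantify_plate

cfg = SimulationConfig(seed=1)
plate = simulate_screen_plate(cfg, "KIN-1", "EGF")
out = quantify_plate(plate.cells, plate.wells)
for readout in ("pct_vim_pos", "cell_count"):
    fit = out["results"][readout]
    print(f"{readout}: IC50 = {fit.ic50:.3f} uM "
          f"(midpoint {fit.midpoint:.3f}, hill {fit.hill:.2f}, "
          f"top {fit.top:.1f}%)")
```

prints

```
pct_vim_pos: IC50 = 0.484 uM (midpoint 0.446, hill 1.52, top 97.6%)
cell_count: IC50 = 2.146 uM (midpoint 2.059, hill 3.99, top 89.2%)
```

i.e. the pipeline (classifier → well summaries → percent inhibition → 4PL
→ censored IC50) recovers the planted 0.5 µM and 2.0 µM within sampling
error of a single plate.

The full pipeline is also exposed as a CLI over a YAML config:

```sh
emtkit all --outdir results --seed 1        # simulate → ora → network →
                                            # rank → screen → synergy → report
emtkit simulate --outdir inputs --seed 7    # just the synthetic inputs
```

Each stage writes TSV/CSV/SIF/GMT artifacts with JSON sidecars; reruns
with an identical configuration are byte-identical.

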