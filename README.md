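# netkappa

Within-subject hub-disruption analysis of longitudinal functional brain
networks.

Resting-state fMRI studies that scan the same people under several
conditions (here: rested wakefulness **RW**, one night of total sleep
deprivation **TSD**, and five nights of chronic sleep restriction **CSR**)
need a way to quantify how a brain network reorganizes *within* a person.
`netkappa` implements that pipeline end to end:

1. **Wavelet connectivity** — regional BOLD series are decomposed with the
   maximal overlap discrete wavelet transform (MODWT, least-asymmetric
   length-8 filter) and interregional coupling is estimated as the Pearson
   correlation of level-3 detail coefficients, the ~0.05–0.1 Hz band at
   TR = 1.25 s.
2. **Graph construction** — each correlation matrix becomes a binarized
   graph with a fixed edge budget (e.g. 400 of the 3916 possible edges on an
   89-region parcellation, a 10 % graph cost), anchored on the minimum
   spanning tree of the distance `1 − |r|` so every graph is connected.
3. **Topology metrics** — nodal degree centrality (max-degree normalized),
   local clustering, closeness; global efficiency, average clustering,
   average path length, modularity, mean between-community geodesic
   distance.
4. **Hub Disruption Index (κ)** — for a nodal metric *m* over *N* regions,
   the within-subject HDI is the slope of

   &nbsp;&nbsp;&nbsp;&nbsp; *m*ᵢ⁽ˢ'ᵗ⁾ − *m*ᵢ⁽ˢ'ʳᵉᶠ⁾ = κ⁽ˢ'ᵗ'ʳᵉᶠ⁾ · *m*ᵢ⁽ˢ'ʳᵉᶠ⁾ + εᵢ

   using each subject's own baseline scan as the reference. κ ≈ 0 means
   preserved topology; κ < 0 means former hubs lost centrality while
   peripheral nodes gained it.
5. **Permutation validation** — three cohort-level tests (node-label
   shuffling, subject-pairing breaks, within-subject condition-label swaps)
   plus generic paired/unpaired permutation comparisons, all with add-one
   p-values and null-referenced Cohen's *d*.
6. **Covariate-constrained manifold learning (CCML)** — an ISOMAP-style
   stress-minimizing embedding whose first coordinate is clamped to
   α·κ, with a centroid-distance permutation test and leave-one-out
   stability diagnostics.
7. **Reporting** — Benjamini–Hochberg FDR within families (q = 0.05 global,
   q = 0.1 nodal) and tidy CSV/JSON outputs.

Because raw fMRI is not required, the package ships a first-class
**synthetic cohort generator**: multi-subject, multi-condition regional time
series (or graph cohorts directly) with core–periphery hub structure and an
implanted, recoverable disruption of known slope κ — the test bed for every
claim the pipeline makes.

## Worked example

```python
import netkappa as nk

spec = nk.CohortSpec(seed=1)          # 28 subjects x (RW, TSD, CSR), 89 regions
graphs = {}
for ts in nk.generate_cohort(spec):   # 84 synthetic scans, 8 min at TR = 1.25 s
    cm = nk.wavelet_correlation_matrix(ts, scale=3)
    graphs[(ts.subject_id, ts.condition)] = nk.build_graph(cm, 400)

nodal = nk.nodal_metric_table(graphs)
kappas = nk.hdi_table(nodal)
deg = kappas[kappas.metric == "degree"]
print(deg.groupby("comparison")["kappa"].mean().round(3))
```

prints (seed 1):

```
comparison
CSR_vs_RW    -0.410
CSR_vs_TSD   -0.415
TSD_vs_RW    -0.654
```

Every mean κ is negative: both deprivation conditions reorganize hubness
relative to baseline (the implanted targets are −0.3 for CSR and −0.5 for
TSD; measured values overshoot slightly because estimation noise on a
flattened degree profile pushes slopes toward −1), and the two deprived
states also differ from *each other* — their disruptions are divergent, not
nested. The condition-label permutation test on the same cohort gives
p < 10⁻⁴ with Cohen's d ≈ −4.9.

A command-line interface chains the same stages over on-disk text formats:

```bash
netkappa simulate --out run --seed 1
netkappa connectivity --out run
netkappa graph --out run --edges 400
netkappa metrics --out run
netkappa hdi --out run
netkappa permtest --out run
netkappa ccml --out run --comparison TSD_vs_CSR
netkappa report --out run
```

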