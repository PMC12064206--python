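# leisurenet

Social-network analysis of adolescent leisure-activity diaries,
stratified by subjective well-being (SWB).

Time-use diaries record which leisure activities each respondent
performed over a day and for how long. `leisurenet` turns such diaries
into **activity co-participation networks** — one per (SWB group × day
type) — and compares their structure. The workflow:

1. **Grouping.** Respondents are split on joint score criteria
   (both scales scored so that *higher is worse*):
   high-SWB = SWB 1–4 **and** health 1–2; low-SWB = SWB 5–7 **and**
   health 3–5; everyone else is excluded. Ages outside 10–19, duplicate
   rows and incomplete records are filtered with a per-rule report.
2. **2-mode → 1-mode projection.** The persons × activities incidence
   matrix (binary or minute-weighted) is projected onto the activity
   mode with cosine similarity,
   `s(a,b) = ⟨x_a, x_b⟩ / (‖x_a‖‖x_b‖)`, where `x_a` is activity *a*'s
   person-indexed participation vector. Edges keep `s ≥ τ` (default
   τ = 0.3); activities with fewer than 2 participants are dropped
   beforehand; nodes failing the threshold everywhere stay as isolates.
3. **Distribution indices.** Density `2E/(N(N−1))`, inclusiveness
   `(N − isolates)/N`, mean shortest-path distance over mutually
   reachable pairs, and the exact isolated-node census.
4. **Degree centrality** `deg(v)/(N−1)`, rounded to 2 d.p. and ranked
   with competition ranking (ties share the smallest rank), with tie-aware
   top-*k* reporting.
5. **Cohesive subgroups** via greedy modularity maximisation on edge
   weights (Louvain-style and connected-component detectors available),
   with adjusted-Rand comparison of partitions.
6. **QAP correlation** between any two networks: Pearson correlation of
   the off-diagonal cells with a permutation null built by relabelling
   one matrix's rows and columns simultaneously; add-one p-values.

Because the national survey microdata is access-restricted, the package
ships a synthetic diary generator (`leisurenet.simulate`) whose default
design — two groups of 241 adolescents, 49 activity items, diverse
high-SWB participation vs concentrated, segment-structured low-SWB
participation — reproduces the qualitative contrast the analysis
targets: denser, better-connected high-SWB networks and fragmented
low-SWB networks with many isolates.

## Worked example

```python
from leisurenet import LeisureNetworkModel

model = LeisureNetworkModel.from_simulation(seed=42)  # default design
results = model.fit(seed=42)
print(results.summary())
```

prints (abridged):

```
Network distribution indices
         network  n_nodes  n_edges  density  inclusiveness  mean_distance  isolated_nodes  n_subgroups
high_swb_weekday       49      658    0.560          1.000          1.451               0            3
 low_swb_weekday       49      104    0.088          0.612          1.778              19            5
high_swb_weekend       49      888    0.755          1.000          1.245               0            2
 low_swb_weekend       49       94    0.080          0.551          1.732              22            4

QAP correlations (pairwise, permutation p-values)
       network_a        network_b     r  p_value
high_swb_weekday  low_swb_weekday 0.285    0.001
high_swb_weekday high_swb_weekend 0.815    0.001
...
 low_swb_weekday  low_swb_weekend 0.885    0.001
```

Reading: the high-SWB networks are denser (0.56/0.76 vs ≈0.08), fully
inclusive, shorter-distance and less fragmented (2–3 cohesive subgroups
vs 4–5) than the low-SWB networks, which leave ~20 of 49 activities
isolated. The very high weekday–weekend QAP correlation *within* the
low-SWB group (r = 0.885) says its activity repertoire barely changes at
the weekend, while the high-SWB group broadens its repertoire
(weekday–weekend r = 0.815 with a much denser weekend network).

The same run is available from the shell:

```sh
leisurenet simulate --seed 42 --out diary.csv
leisurenet run-all --diary diary.csv --seed 42 --out out/
leisurenet tau-sweep --seed 42          # threshold sensitivity report
```

`run-all` writes GraphML + edge lists, the index table, centrality and
partition CSVs, the QAP table, and a manifest with SHA-256 checksums.

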