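# phosphonet

Quantitative downstream analysis for SILAC phosphoproteomics: differential
phosphosite calling, kinase attribution by sequence-motif counting, and
protein-network topology with betweenness-based hub selection validated
against degree-preserving random-network null models.

It is written for proteomics and systems-biology analysts who already have a
site-level quantification table (e.g. a MaxQuant "Phospho (STY)Sites"-style
export with per-replicate normalized SILAC ratios) and want a reproducible,
scriptable version of the classic threshold-based workflow — for example to
contrast the signaling downstream of two receptors, such as the chemokine
receptor CCR5 versus the atypical scavenger receptor ACKR2, at several
stimulation time points.

## The analysis

**Regulation calls.** Per condition-replicate column, ratios *r* are
normalized so that median(log2 *r*) = 0. A site is positively quantified for
a comparison when present in at least 2 of 3 replicates; its fold change is
the geometric mean of the present replicate ratios,

&nbsp;&nbsp;&nbsp;&nbsp;GM(r₁…r_k) = exp( (1/k) Σᵢ ln rᵢ ),

and it is called **up** if GM > 1.5, **down** if GM < 0.67 (a >50% change,
strict inequalities), otherwise unchanged. A protein is differentially
phosphorylated (DPP) iff at least one of its sites is regulated; conflicting
site directions are reported as such.

**Kinase motifs.** Regulated sites' 13-mer sequence windows (positions
−6…+6 around the phosphoacceptor) are matched against a kinase consensus
library (e.g. basophilic `R-R-x-S*`, proline-directed `S*-P`, acidophilic
`S*-x-x-E`). For kinase *k* with count c_A(k) out of total attributions T_A
in receptor A, the cross-receptor statistic is the percentage ratio
[c_A(k)/T_A] / [c_B(k)/T_B]; values above 1 mark kinases relatively more
active downstream of receptor A.

**Network topology.** STRING-like edges are kept when the *experiments*
channel score is ≥ 0.15 or the *databases* score is ≥ 0.35; signaling
networks use signed activation/inhibition (directed) and docking
(undirected) relations. On the induced DPP network the ten-centrality
battery (betweenness, bridging, centroid, closeness, eccentricity,
eigenvector, radiality, stress, in-degree, out-degree) is computed; **hubs**
are nodes whose betweenness strictly exceeds the network mean. Significance
is assessed against degree-preserving double-edge-swap randomized networks
with add-one empirical p-values, (1 + #{null ≥ observed}) / (n_random + 1).

A fully seeded synthetic-data generator (planted up/down sites, planted
motifs, planted high-betweenness connector nodes, recorded ground truth)
makes every stage testable without any external download.

## Worked example

```python
import phosphonet as pn

cfg = pn.SimulationConfig(n_sites=500, n_proteins=150, frac_up=0.1, frac_down=0.1,
                          noise_sigma=0.2, missing_rate=0.1, seed=42)
table, truth = pn.generate_phosphosite_table(cfg)
comp = pn.ComparisonDesign("stim_vs_ctrl", "stim", "ctrl")
sites, proteins = pn.call_sites_and_proteins(pn.normalize_ratios(table), [comp], pn.Thresholds())
print(sites["label"].value_counts().to_dict())
print("DPPs:", int(proteins["regulated"].sum()))

edges, net_truth = pn.generate_network(60, model="scale_free", model_params={"m": 2},
                                       n_planted_connectors=1, seed=7)
net = pn.build_network(net_truth.nodes, pn.filter_edges(edges))
profiles = pn.compute_centralities(net)
hubs = pn.select_hubs(profiles)
null = pn.null_distribution(net, n_random=100, seed=1)
print("nodes", net.n_nodes, "edges", net.n_edges, "hubs", len(hubs))
print("connector p:", round(float(null.node_stats.loc[net_truth.connectors[0], "empirical_p"]), 4))
```

prints

```
{'unchanged': 356, 'not_quantified': 55, 'down': 45, 'up': 44}
DPPs: 68
nodes 60 edges 116 hubs 15
connector p: 0.0099
```

Of 500 simulated sites (10% planted up at ratio 2.0, 10% down at 0.5, σ =
0.2 lognormal noise, 10% replicate dropout), 55 fail the 2-of-3 presence
filter and 89 are called regulated, implicating 68 proteins. On the
synthetic 60-node network the planted community connector lands in the
15-node above-mean-betweenness hub set, and its betweenness exceeds all 100
degree-preserving rewired replicates (add-one p = 1/101 ≈ 0.0099).

The same analysis runs end to end from one YAML config via the CLI
(`phosphonet run --config run.yaml`; subcommands `simulate`, `call`,
`motifs`, `network` run stage subsets), writing per-stage TSV artifacts, a
GraphML/SIF network export, a violin-plot-ready null-distribution table and
a manifest with the config hash and per-stage counts.

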