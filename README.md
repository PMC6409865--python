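# netloci

**Where do disease genes sit in an interactome?**

`netloci` is a small analysis package for systems biologists who want to
characterize the network *location* of a gene set. Given an undirected
interactome (a two-column edge list of gene symbols) and one or more gene
sets, it computes four classic topological parameters per gene —

- degree `k(v)`,
- average shortest path length `aspl(v) = mean_j d(v, j)` over reachable
  partners `j ≠ v` (BFS hop distances),
- local clustering coefficient `cc(v) = 2n / (k(k−1))` with `n` the edge
  count among `v`'s neighbors,
- normalized betweenness centrality
  `bc(v) = [Σ_{{i,j}} σ_ij(v)/σ_ij] / [(N−1)(N−2)/2]` (Brandes
  accumulation, unordered pairs, endpoints excluded) —

and then asks whether the gene set occupies distinctive positions:
it contrasts the set against equal-size **random gene sets** drawn from
the same network and against its own **first-order neighbors**, using
two-sided Mann–Whitney U tests (exact for small tie-free samples,
tie-corrected normal approximation otherwise), and measures the mutual
redundancy of the four parameters with tie-aware **Spearman rank
correlations** (Pearson on average ranks — with tied data the familiar
`1 − 6Σd²/(n(n²−1))` shortcut is wrong and is deliberately not used).

The recurring empirical picture this tooling targets: disease genes tend
to show **higher betweenness, shorter path lengths and lower clustering**
than random genes, **without** being degree hubs. A seeded synthetic
interactome generator (preferential attachment with triadic closure,
plus planted "connector" genes carrying exactly that signature) makes the
entire pipeline testable with no downloads; see `docs/methods.md`.

## Worked example

Simulate a synthetic interactome with a planted disease set, then run the
full analysis:

```bash
netloci simulate --seed 1 --out-network net.tsv --out-genes disease.txt
netloci run --network net.tsv --genes disease=disease.txt --out-dir out --seed 1
```

`out/disease_metrics.tsv` holds the per-gene parameters of the planted
genes:

```text
gene    degree  aspl     cc  bc
DG01    4       3.66983  0   0.0191195
DG02    4       3.60333  0   0.0217845
DG03    4       3.71971  0   0.0219005
...
```

and `out/summary.md` condenses the comparison (from
`disease_random_tests.json`):

```text
### Disease vs pooled random null (Mann-Whitney, two-sided)

| parameter | direction | U    | p        |
|---|---|---|---|
| degree    | 0         | 2024 | 0.178    |
| aspl      | -         | 533  | 1.68e-09 |
| cc        | -         | 154  | 2.46e-13 |
| bc        | +         | 4666 | 7.35e-13 |
```

Read: the 22 planted genes have significantly *shorter* average paths
(median 3.70 vs ≈ 4.1 in random sets), *lower* clustering (median 0 vs
≈ 0.33) and *higher* betweenness (median 0.020 vs ≈ 0.005) than pooled
random gene sets, while their degree (all exactly 4, the null median) is
indistinguishable — high-betweenness bottlenecks without being hubs.
The correlations output flags pairs involving the constant degree and
clustering columns as undefined (`null`) rather than reporting a
spurious 0.

The same machinery works from Python:

```python
import netloci as nl

table = nl.table2_fixture()            # published ten-gene topology table
aspl = [m.aspl for m in table]
cc = [m.cc for m in table]
print(round(nl.spearman_rho(aspl, cc), 3))   # -0.994
```

That −0.994 is the tie-aware Spearman correlation between the ASPL and
clustering columns of the packaged published table of the ten most
intensively studied disease genes; the tie-free shortcut formula would
report ≈ −0.982 on the same rounded columns.

Other subcommands: `netloci metrics` (per-gene table), `netloci compare`
/ `netloci neighbors` (single comparisons with TSV/JSON outputs),
`netloci correlate` (6 pairwise coefficients from a metrics table or
computed on the fly), and `netloci run --config run.yaml` for
file-driven configuration. All outputs are byte-identical under a fixed
`--seed`.

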