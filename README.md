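# panacea-rank

Personalized, network-based prioritization of anti-cancer drugs for a single
tumor sample.

## The problem

Given the somatic alterations of one tumor, which drugs are worth
considering? This package answers that by combining three inputs on a graph:

1. an undirected **protein interaction network** (PIN) — a TSV edge list in
   the STRING-links dialect (two node columns plus a `combined_score`) or a
   plain two-column BioGRID-style list; low-confidence interactions
   (combined score < 0.4 by default) are discarded;
2. a **drug → target-gene table** (DGIdb-export dialect); drugs are added to
   the PIN as extra nodes wired to their target genes (the *extended PIN*),
   and drugs targeting completely overlapping gene sets are merged into a
   single node (e.g. `D1/D2`);
3. per-gene **driverness scores** for the sample — probabilities in [0, 1]
   that each altered gene is a cancer driver, as produced upstream by a
   driver-prioritization classifier such as driveR.

Two scoring methods are provided.

**Distance-based.** Each drug *d* is scored against each altered gene *g* as

    s(d, g) = driver_g / (dist(d, g) + 1)²

where dist(d, g) is the shortest-path hop count on the extended PIN (drug
nodes are never intermediaries: a drug–target edge is a terminal hop). The
drug's score is the mean of s(d, g) over the altered genes with driverness
strictly above 0.05; unreachable genes contribute 0 but stay in the
denominator.

**Propagation.** Driverness scores form a prior vector Y over the extended
PIN (zero on unaltered genes and on drug nodes). The adjacency W is
Laplacian-normalized, W′ = D^(−1/2) W D^(−1/2), and a random walk with
restart is iterated from F(0) = Y:

    F(t) = (1 − α) W′ F(t−1) + α Y

until ‖F(t) − F(t−1)‖₂ < 10⁻⁴ or 1000 iterations, with restart parameter
α = 0.05 by default. A drug's score is its final propagation score F at the
drug node.

Ranked drug lists are then evaluated with tie-aware top-n selection (the top
n drugs *plus* every drug tying the n-th score) against a 10-level clinical
support taxonomy (1A approved for the cancer type … 6 no support) supplied
as a local `drug → tier` table.

## Worked example

Everything runs on synthetic data generated by the built-in fixture module —
no downloads. Generate a dataset (100-gene scale-free network, 20 drugs,
10 altered genes), score it, and evaluate the top 5:

```sh
panacea fixture --seed 42 --out fx
# wrote fixture to fx (100 genes, 196 edges, 20 drugs, 10 altered genes)

panacea score --pin fx/pin.tsv --drug-targets fx/drug_targets.tsv \
              --driver-scores fx/driver_scores.tsv \
              --method propagation --out scores.tsv
# wrote 18 drug scores (propagation) to scores.tsv
```

20 drugs collapse to 18 scored entries because two pairs shared identical
target sets and were merged. The output is a ranked table:

```
drug	score	rank
DRUG_010/DRUG_019	0.03813468372389404	1
DRUG_004	0.02922930086897362	2
DRUG_000	0.017945931360178524	3
```

Scores are the stationary propagation mass at each drug node: the top drug's
targets sit closest (in diffusion distance) to the high-driverness genes of
this sample. With a local tier table granting `DRUG_010` tier 1A and
`DRUG_004` tier 2B:

```sh
panacea rank --scores scores.tsv --top-n 5 --tiers tiers.tsv
```

```json
{
  "n_selected": 5,
  "selected": [
    {"drug": "DRUG_010/DRUG_019", "tier": "1A"},
    {"drug": "DRUG_004", "tier": "2B"},
    {"drug": "DRUG_000", "tier": "6"},
    {"drug": "DRUG_011", "tier": "6"},
    {"drug": "DRUG_007", "tier": "6"}
  ],
  "supported": 0.4,
  "approved_or_trial": 0.4
}
```

The merged drug resolves to the best tier among its members (1A from
`DRUG_010`); `supported` is the proportion of selected drugs in tiers 1–5.
Use `--method distance` for the distance-based scorer, and `panacea sweep`
to emit one ranked table per restart parameter α.

The same pipeline is available as a library:

```python
import panacea as p

net, drugs, drivers = p.generate_fixture(p.FixtureSpec(seed=42))
xnet = p.extend_network(net, p.merge_equivalent_drugs(drugs))
scores = p.score_propagation(xnet, drivers, alpha=0.05)
print(scores.ranked().head())
```

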