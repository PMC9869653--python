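# Methods

## Model

Both scorers operate on the *extended PIN*: an undirected protein
interaction network whose edges have passed a confidence filter, augmented
with one node per drug connected to that drug's target genes. Gene–gene
edges are exactly those of the filtered PIN; extension never adds gene–gene
edges. Confidence scores are used only for edge filtering, never as path
weights or propagation weights — both methods treat the graph as unweighted
once it is built.

### Distance-based scorer

For drug *d* and altered gene *g*,

    s(d, g) = driver_g / (dist(d, g) + 1)²,
    score_d = (1/|G*|) Σ_{g ∈ G*} s(d, g),

where G* is the set of altered genes with driverness strictly greater than
a threshold (default 0.05) that are present in the network. dist(d, g) is a
hop count with drug nodes excluded as intermediaries: it equals 1 plus the
minimum gene-graph BFS distance from any of the drug's in-network targets
to *g*, so a direct target sits at distance 1. The +1 in the denominator
guards division by zero; the square makes contributions decay quickly with
distance, emphasizing genes near the drug's targets.

Reading choices where the formula alone is ambiguous:

* **Unreachable genes** contribute 0 to the sum (the dist → ∞ limit of the
  formula) but still count in the |G*| denominator, which is the only
  reading consistent with dividing by the full altered-gene set.
* **Genes above the threshold but absent from the PIN** are excluded from
  G* with a logged warning — they have no node, so no distance exists.
* The driverness cut is **strict** (> 0.05, not ≥) and applies to this
  method only; it is a parameter and can be disabled.
* An empty G* is not an error: every drug scores 0 and the result carries
  an `empty_driver_set` flag, since real cohorts contain samples with no
  gene above the cut.

### Propagation scorer

The 0/1 symmetric adjacency W of the extended network is normalized as
W′ = D^(−1/2) W D^(−1/2) with D the degree diagonal. Driverness scores form
the prior Y (zero for unaltered genes and all drug nodes; **no** driverness
threshold by default — the 0.05 cut belongs to the distance method), and

    F(t) = (1 − α) W′ F(t−1) + α Y,   F(0) = Y,

is iterated until ‖F(t) − F(t−1)‖₂ < tol or the iteration cap. Because W′
is a symmetric normalized adjacency its spectral radius is ≤ 1, so the map
is a contraction with factor ≤ (1 − α) and converges geometrically to
F* = α(I − (1 − α)W′)⁻¹Y. A drug's score is F at its node.

Drug–target edges conduct in both directions here. The shortest-path rule
of the distance method treats them as terminal hops, but the update above
has a single symmetric operator and no directionality mechanism, and
interaction directionality is not modeled anywhere in the package; we flag
this asymmetry between the two methods as a known modeling seam.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `min_confidence` | 0.4 | edge filter on the PIN's combined score (unit scale); a `string1000` dialect flag divides integer scores by 1000 first |
| `driver_threshold` | 0.05 | strict driverness cut for the distance method's gene set |
| `alpha` | 0.05 | RWR restart parameter; `panacea sweep` emits one ranked table per α for manual inspection, automatic selection is out of scope |
| `tol` | 1e-4 | L2 stopping threshold of the iteration |
| `max_iter` | 1000 | iteration cap; hitting it returns a `converged=False` result with a warning rather than raising, since non-convergence signals pathological input worth inspecting |

All scores and driverness values are unitless (probabilities or
probability-weighted means).

## Numerical choices

* **Node ordering** is fixed and deterministic — sorted gene symbols, then
  sorted namespaced drug nodes — so propagation results are bit-reproducible.
* **Isolated nodes** (degree 0) make D^(−1/2) undefined; they get zero
  rows/columns in W′ and therefore neither send nor receive signal. An
  orphan drug (no in-network target) thus scores exactly 0 under both
  methods, which keeps the "every drug gets a score" contract total.
* **Ties** in drug scores are real, not numerical noise: the distance
  method produces exact ties for drugs with identical distance/driverness
  patterns. Tie comparisons therefore use exact floating equality, top-n
  selection is tie-inclusive, ranks use the min-rank convention, and
  within-list ordering breaks ties lexicographically by drug name for
  determinism.
* **Degenerate inputs** fail loudly and distinctly: an edgeless extended
  network ("no interactions to propagate over"), an identically zero prior
  ("no prior signal"), an empty network after confidence filtering, and
  malformed TSV rows (with line numbers) each raise a dedicated exception.
* Self-loops and duplicate edge rows are removed at load: both are
  meaningless for hop distances and would double-count degrees in the
  normalization. Duplicate edge rows keep the maximum confidence seen.
* Merged drug names are the sorted member names joined by `/`, with a merge
  ledger kept so per-drug tier annotations remain resolvable; a merged
  drug takes the best (most clinically advanced) member tier, since the
  merged node represents any member being prescribable.
* Gene symbols are matched case-sensitively after whitespace trimming; no
  alias resolution is attempted.

## Synthetic data

The fixture generator emulates the three real input kinds without network
access. Defaults, chosen once as representative of the real inputs at desk
scale: 100 genes in a scale-free graph with attachment 2 (interaction
networks are heavy-tailed), per-edge confidences uniform in [0.4, 1] (all
above the default filter, so written fixtures reload losslessly), 20 drugs
with 1–3 uniform-random targets, 20% of drugs arranged in pairs sharing an
identical target set (exercises merging), 10% of target slots drawn from
symbols outside the network (exercises orphan handling), and 10 altered
genes of which 80% score uniformly in [0, 0.05] and 20% in [0.5, 1] — the
sparse profile a driver-prioritization classifier produces, and one that
exercises the distance method's filter path meaningfully. All randomness
flows from one seed through a single generator; identical seed and spec
give byte-identical TSVs.

A separate planted-signal fixture places one drug directly on the unique
high-driverness gene (0.95) of a fixed 10-gene tree while every decoy's
targets lie ≥ 3 hops from it; seeds only permute labels, and both scorers
are label-permutation invariant, so both must rank the planted drug first
on every seed.

What the generator does **not** emulate: the degree distribution and scale
of real interaction databases (10⁴ nodes, 10⁵–10⁶ edges), drug-name
vocabulary variants (salts, brands), gene-identifier aliasing, and any
correlation between driverness and network position. Passing tests
therefore demonstrate algorithmic correctness and contract behavior, not
biological performance on real cohorts.

## Verification strategy and problem sizes

Every numerical claim is checked against an independent route: the
distance scorer against a Floyd–Warshall all-pairs oracle (and a second,
literal oracle that materializes the extended graph and deletes the other
drug nodes per query) on 100 random networks of up to 50 genes and 10
drugs; the propagation iteration against a dense closed-form resolvent
solve on 50 fixtures of up to ~200 nodes, where it must also converge well
under the iteration cap; monotonicity (in driverness and in edge addition)
by randomized property testing; and two hand-computed toys to six decimals.
These sizes keep the whole suite and the acceptance script in the
seconds-to-a-minute range on one CPU while still covering multi-component
graphs, merged drugs, orphan drugs and tied scores.

## Known limitations

* Drug–target edges are directional in spirit (drugs act on targets) but
  symmetric in the propagation operator; see the modeling seam above.
* Eq.-level parity with any other implementation of the same formulas is
  not guaranteed where the published description is ambiguous (e.g. the
  aggregation denominator is read as the cardinality |G*|).
* Tier tables are local inputs; building them from drug-annotation
  services is deliberately out of scope, as is the upstream computation of
  driverness scores and any weighted-shortest-path or alternative
  normalization variant.
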