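# Methods

## Model and procedure

The toolkit operationalizes a similarity-network view of a small
compound library. The pipeline is:

1. **Ingest.** SMILES are parsed and canonicalized with RDKit, keeping
   stereochemistry (isomeric SMILES), because natural-product inventories
   routinely distinguish stereoisomers. Invalid rows are skipped with a
   warning and logged to a JSON rejects file rather than aborting the
   batch; duplicate identifiers abort, since silently dropping one would
   corrupt every downstream mapping.
2. **Fingerprints.** Hashed Morgan circular fingerprints, radius 2,
   1024 bits, as explicit binary vectors. Binary (not counted) vectors
   are used throughout so that one representation feeds both the
   similarity matrix and the embedding.
3. **Similarity.** Dice coefficient `2|a∩b|/(|a|+|b|)` on set bits. The
   coefficient on two empty vectors is an error, not a convention: a
   valid molecule always sets at least one bit, so reaching that case
   means something upstream is broken. An agglomerative clustering
   (average linkage on `1 − dice`) provides the leaf order for heatmap
   rendering.
4. **Network.** Pairs with similarity strictly greater than the
   threshold (default 0.45) form edges. Node coordinates come from t-SNE
   on the bit vectors, min–max rescaled per axis to [0, 1]; molecules
   with no qualifying edge are recorded as isolated and excluded from
   the node set. A classic threshold CSN (same edges, seeded spring
   layout, coordinates flagged non-semantic) is available for
   comparison.
5. **Grouping.** Edges longer than an edge-length threshold are
   dropped; connected components of the remainder are candidate groups;
   components smaller than `min_group_size` (default 3) become
   unassigned. Per member, `MWGS = (Σᵢ Sᵢ − 1)/(n − 1)` — the mean Dice
   similarity to the other members — and the maximizer is the group's
   representative compound. Groups are labelled "<representative name>
   group".
6. **IFP analysis.** Independently of steps 1–5, binary
   compounds × residue-contact tables (contact vocabulary PO, Ak, HD,
   HA, SF; header cells `RESIDUE:TYPE`) are summarized into per-column
   frequencies, consensus key residues, and group-vs-group deltas.

## Parameters

| parameter | default | units / range | rationale |
| --- | --- | --- | --- |
| fingerprint radius | 2 | bonds | standard ECFP4-equivalent environment size; suits terpenoid ring topologies |
| fingerprint length | 1024 | bits | enough to keep hash collisions rare at natural-product sizes |
| similarity threshold | 0.45 | Dice, strict `>` | edge-formation cut for sparse, heterogeneous libraries |
| t-SNE perplexity | `min(10, (n−1)/3)`, floor 2 | — | small-sample stability; must be < n |
| t-SNE initialization | PCA, seeded | — | deterministic and reproducible; random (seeded) when embedding precomputed 1 − Dice distances, which sklearn requires |
| t-SNE iterations | 1000 | — | comfortably past convergence at n ≤ a few hundred |
| edge-length threshold | 80th percentile of embedded edge lengths | normalized coordinate units | prunes long inter-cluster bridges while keeping local structure; an absolute override exists |
| min group size | 3 | compounds | groups of 1–2 carry no consensus signal |
| MWGS denominator | `n − 1` | — | see below |
| key-residue threshold | fraction > 0.5, strict | — | operationalizes "contacted by most of the group" as a strict majority |

Coordinates are normalized to the unit square so the edge-length
threshold is transferable across datasets; raw t-SNE scales are
arbitrary.

## Design choices where the design was open

* **MWGS denominator.** The statistic's defining property — a group of
  fingerprint-identical molecules should score exactly 1 — forces the
  `(Σ Sᵢ − 1)/(n − 1)` reading (subtract the self-similarity, average
  over the other members). A `denominator="n"` switch provides the
  literal-n variant for comparison.
* **Automated grouping.** Proximity grouping is implemented as
  length-capped connected components. The inclusive `≤` on edge length
  (vs the strict `>` on similarity) makes the quantile default
  well-behaved: at quantile 1.0 the partition equals plain connected
  components.
* **Embedding distance.** Euclidean distance on the raw bit vectors is
  the default (simple, deterministic PCA initialization); a
  `metric="dice"` option embeds precomputed `1 − dice` distances since
  edges and coordinates are framed as two representations of the same
  fingerprint.
* **Determinism.** Every ordering in the toolkit (edge lists, group
  numbering, report rows, tie-breaks) is specified: numeric ids sort
  numerically, groups by descending size then smallest member, MWGS
  ties go to the smallest id (logged). Reruns with one seed are
  byte-identical; the per-run JSON manifest records config, seed and
  library versions.

## Synthetic benchmark

`csnkit.synthetic` builds labelled fixtures from scaffold templates plus
enumerated substituent decorations — not random SMILES mutation — because
a large shared scaffold bounds within-family similarity from below and
chemically distinct scaffolds bound between-family similarity from
above. The default preset has three families (19 molecules): dodecane
homologs/derivatives, 2-methoxynaphthalene ethers, and a decorated
decalin-based (terpene-like) fused-ring scaffold, mimicking the
structural classes of essential-oil inventories: long chains, aromatics,
and polycyclic terpenoids. Generation verifies within-family Dice ≥ 0.6
and between-family Dice ≤ 0.3 and regenerates (with a warning) on a
violation. Two properties of real data it deliberately does **not**
emulate: the long tail of singleton structures with no close neighbor
(real libraries leave compounds isolated at 0.45; the preset leaves
none), and families that overlap or bridge in chemical space. Passing the
recovery tests therefore shows the machinery is correct on separable
families, not that any real mixture will split as cleanly.

IFP fixtures are Bernoulli matrices with planted high-frequency columns
(bit probability `1 − noise_rate`) over a sparse background
(`noise_rate`); with 200 compounds and 20 % noise, majority-vote
key-residue calling recovers the planted columns in ≳99 % of seeds, as
the binomial tails predict.

Test and acceptance runs use desk-scale problems throughout — 19-molecule
fixtures, 5 recovery seeds, 100-graph and 1000-pair oracle sweeps —
sizes at which every oracle can be exhaustive.

## Numerical notes and degenerate inputs

* Unbranched alkane homologs beyond ~C7 have *identical* Morgan bit
  sets at radius 2 (every environment repeats), hence Dice exactly 1.
  This is a property of circular fingerprints, not a bug; it is why the
  chain family in the preset clusters so tightly.
* A degenerate embedding axis (all coordinates equal) maps to 0.5
  rather than dividing by zero.
* Dendrogram distances `1 − dice` are clipped at 0 to absorb floating
  rounding; the similarity matrix diagonal is set to exactly 1.0.
* Singleton MWGS is undefined and raises; the grouping layer never
  requests it because the size filter runs first (min size 3 ≥ 2).

## Known limitations

* t-SNE does not preserve global topology: structurally similar
  molecules can land on opposite sides of the plane ("spatial
  discontinuity"), in which case proximity grouping will split what the
  edge structure alone would join. No remedy is attempted.
* Exact node coordinates depend on the seed and perplexity; only
  seeded reproducibility is promised, not coordinate-level agreement
  with any external layout of the same library.
* The IFP module consumes already-extracted binary tables; docking,
  pose generation and contact perception are out of scope.
* Dice is the only similarity coefficient; the `SimilarityMatrix`
  container is coefficient-agnostic and is the extension point.
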