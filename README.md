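# csnkit

A toolkit for **t-SNE chemical space networks (t-SNE CSN)**: similarity
networks over small-molecule libraries in which both the edges *and* the
node positions carry structural-similarity information, plus automated
compound grouping and a binary protein–ligand interaction-fingerprint
analyzer. It is aimed at natural-product and mixture analysis — e.g.
classifying the terpene-rich compound inventories of essential oils —
where libraries are small (tens to low hundreds of compounds) and
structurally heterogeneous.

## The method

Each molecule is encoded as a hashed Morgan (ECFP-style) circular
fingerprint: atom-centered substructure environments up to radius 2,
hashed into an explicit 1024-bit vector. Pairwise structural similarity
is the Dice coefficient over set bits,

```
dice(a, b) = 2 |a ∩ b| / (|a| + |b|)      ∈ [0, 1]
```

Two views of the same fingerprint build the network:

1. **Edges** — every pair with `dice > 0.45` (strict) forms an edge.
   Molecules with no qualifying edge are *isolated* and do not
   participate in the network.
2. **Coordinates** — t-SNE reduces the 1024-bit vectors to 2-D node
   positions, rescaled so each axis spans [0, 1]. Unlike a classic
   coordinate-free threshold CSN (also provided, with a force-directed
   layout, for comparison), spatial proximity is therefore meaningful
   and an **edge length** can be thresholded.

Compound families are then the connected components of the subgraph that
keeps only *short* edges (by default, edges up to the 80th percentile of
embedded edge lengths); components with fewer than 3 members are left
unassigned. Within each surviving group, every member's **mean
within-group similarity**

```
MWGS = (Σᵢ Sᵢ − 1) / (n − 1)
```

is its average Dice similarity to the other n − 1 members (the self term
of 1 is subtracted), and the member maximizing MWGS is the group's
**representative compound** — the natural query ligand for downstream
target prediction.

Separately, the `ifp` module summarizes binary **interaction-fingerprint
tables** (compounds × residue contacts, contact types PO / Ak / HD / HA /
SF) produced by post-processing docking poses of a compound group:
per-contact frequencies, consensus *key residues* (contacted by a strict
majority of the group), and group-vs-group comparisons.

## Worked example

Generate the built-in synthetic benchmark (three structurally distinct
families — chain homologs, naphthalene ethers, a terpene-like fused-ring
scaffold — 19 molecules with known family labels) and run the full
pipeline:

```
$ csn simulate --seed 0 --out fixture.csv
19 molecules in 3 families -> fixture.csv

$ csn run --input fixture.csv --out-dir results --seed 0
19 molecules: 19 in network, 3 groups covering 19 compounds -> results
```

All 19 molecules have at least one edge above 0.45, and proximity
grouping recovers exactly the three planted families. `results/groups.tsv`
lists each member's MWGS and flags the representative:

```
group_id  mol_id  name      mwgs      is_representative
1         1       chain-1   0.920635  true
1         2       chain-2   0.920635  false
...
2         10      aromatic-3 0.782644 true
```

(`chain-1` ties several identical-fingerprint homologs at MWGS 0.92; ties
go to the smallest id and are logged.) The bundle also contains the
similarity matrix CSV, the network in GraphML and node-link JSON, figures,
and `manifest.json` recording the config, seed, library versions and the
stage counts (19 input = 19 participating + 0 isolated; 19 participating
= 19 grouped + 0 unassigned), so a rerun reproduces every table
byte-identically.

Summarizing a published-style interaction-fingerprint table of a
10-compound group docked into the vitamin-D-binding-protein pocket:

```
$ csn ifp --table data/ifp_alpha_pinene_dbp.tsv --out freq.tsv
key residue F36: fraction 1.00 via PO
key residue V88: fraction 1.00 via Ak
key residue M107: fraction 1.00 via Ak
key residue H89: fraction 0.90 via PO
10 compounds x 11 contacts -> freq.tsv
```

All 10 compounds share the F36 pi-orbital contact and the V88/M107
alkyl-pi contacts — the consensus residues for group-wide binding.

## Layout

| module | contents |
| --- | --- |
| `csnkit.io` | molecule-table reading/validation/canonicalization, group report TSV |
| `csnkit.fingerprints` | Morgan bit vectors, Dice similarity, similarity matrix, heatmap ordering |
| `csnkit.network` | threshold edges, t-SNE embedding, t-SNE CSN and threshold CSN assembly, GraphML/JSON export |
| `csnkit.grouping` | proximity-constrained grouping, MWGS, representative selection |
| `csnkit.ifp` | interaction-fingerprint tables, contact frequencies, key residues |
| `csnkit.synthetic` | seeded generators for labelled molecule fixtures and IFP matrices |
| `csnkit.pipeline` / `csnkit.cli` | end-to-end runs with manifests; `csn` command-line app |

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
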