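# Methods

`catsom` implements a ligand-based target-profiling workflow for
combinatorial compound libraries: enumerate a virtual library from
filtered building blocks, embed all compounds in a topological
pharmacophore space, organize an annotated reference collection on a
toroidal self-organizing map (SOM), and transfer target-class hypotheses
to library compounds that co-locate with enriched reference clusters.
This note records the models, the defaults and why they are what they
are, and what the synthetic data can and cannot show.

## Molecular standardization and properties

SMILES/SDF input is parsed with RDKit. Standardization keeps the largest
covalent fragment (salt/counterion stripping) and neutralizes simple
charged acids and bases via RDKit's `Uncharger`; tautomer
canonicalization is deliberately not attempted — the descriptor below is
insensitive to most tautomer choices, and canonicalization schemes are
toolkit-specific and unstable across versions.

Scalar properties: average molecular weight uses standard atomic
weights with implicit hydrogens; the protonated monoisotopic ion adds
1.00728 to the monoisotopic mass and is reported to two decimals, the
convention of HR-MS software. `alogp` is the Wildman–Crippen
atomic-contribution estimate as implemented in the pinned RDKit release —
a fixed, documented contribution table, so values are reproducible for a
given environment.

Topological distances are shortest paths in bonds over the heavy-atom
graph (RDKit's distance matrix, integer-cast). Atom indices are 0-based
everywhere.

## Building-block selection

Two reactive roles are detected by SMARTS:

- **aldehyde** — `[CX3H1](=O)[#6]`: one carbonyl H and a carbon
  substituent. Formaldehyde, formates and formamides are excluded; both
  aromatic and aliphatic aldehydes qualify.
- **1,3-dicarbonyl** — `C(=O)-CH2-C(=O)X` with `X ∈ {C, O-linked,
  N-linked}`: 1,3-diketones, β-ketoesters, β-ketoamides. One carbonyl
  must bear a carbon substituent (a ketone): only a ketone can condense
  into the ring, so malonate-type diesters are not accepted. Symmetric
  motifs match once (matches are deduplicated on the three core atoms).

The selection filter keeps blocks with MW < 300 Da, alogP < 2, no Br or
I, and a single functionality — exactly one site of the block's own role
and none of the other (a molecule carrying both roles is ambiguous and
rejected). All thresholds are strict. Rejections report the first
failing criterion, checked in the order: forbidden elements, MW, alogP,
functionality — element membership is the cheapest, most clear-cut test,
so it reports first.

## Virtual Biginelli enumeration

Each (aldehyde, dicarbonyl) pair yields exactly one
3,4-dihydropyrimidin-2(1H)-one; urea is hard-coded as the third
component and appears only on the product side. Graph assembly joins the
fragments with a fresh urea unit (N1, C2=O, N3) into the ring
N1(H)–C2(=O)–N3(H)–C4(H)(R_ald)–C5=C6, deletes the two carbonyl oxygens
lost as water, and makes the C5=C6 double bond. Heavy-atom bookkeeping:
product = aldehyde + dicarbonyl + 4 (urea C, N, N, O) − 2 (oxygens).

Regiochemistry for asymmetric dicarbonyls: the carbonyl whose
substituent has fewer heavy atoms becomes ring atom C6 (the methyl
ketone wins), ester/amide carbonyls never enter the ring, ties break on
the lower atom index. This matches classical Biginelli selectivity and
keeps enumeration counts exactly |aldehydes| × |dicarbonyls|. Products
from distinct pairs are not deduplicated by default (`dedup` option
available). No stereocenter is assigned at C4: the downstream descriptor
is 2D, and the reaction is run racemic in practice.

## CATS descriptor

Every heavy atom receives zero or more potential-pharmacophore-point
types: **D** (O/N bearing H), **A** (O not in nitro; N that is not
positively charged, not pyrrole-type aromatic, not amide), **P**
(positive formal charge, aliphatic amine N, amidine/guanidine center),
**N** (negative formal charge; carboxylic/sulfonic/phosphonic acid,
acylsulfonamide, tetrazole centers), **L** (C/S/Cl with only C/S/H
neighbors). The rules live in a versioned data file
(`data/pharmacophore_types.yaml`); editing them is a breaking change
because every descriptor value depends on them. "Pyrrole-type or amide"
exclusion is applied to all such nitrogens regardless of substitution
(an N-methyl pyrrole nitrogen is no more an acceptor than an N–H one).

For every unordered atom pair at topological distance 1–9 bonds, each
(type-on-i, type-on-j) combination increments its pair/distance bin; at
distance 0 each unordered pair of *distinct* types on a single atom
counts once (a lone occurrence is not a pair). 15 unordered type pairs ×
10 distances = 150 bins, ordered DD, DA, DN, DP, DL, AA, … LL with
distance fastest (`DD_00` … `LL_09`).

Frequency scaling divides every bin of pair {t1, t2} by
(n_t1 + n_t2), the summed occurrence counts of the two types (0/0 := 0);
for a same-type pair the denominator is 2·n_t. This damps the
size-dependence of raw counts. Raw integer counts are retained as a mode
for testing and inspection.

The absolute bin values of any CATS implementation depend on the exact
typing rules, which differ between published variants; the contract this
package tests is the *relative* structure (cluster separation,
invariances, oracle-equality of the pair counting), not agreement with
any specific historical implementation's numbers.

## Toroidal self-organizing map

A W×H rectangular grid with wrap-around on both axes; grid distance
between neurons is Euclidean on the torus, so the maximum possible
distance is √((W/2)² + (H/2)²) and no neuron is privileged by a boundary.
Weights are initialized uniformly within the per-dimension data envelope
(seeded). Training is online Kohonen: at step s a random data row is
drawn, its best-matching unit (BMU; Euclidean in descriptor space, ties
to the smallest linear index y·W + x) found, and every neuron updated by

    w_u ← w_u + α(s) · exp(−g²/(2σ(s)²)) · (v − w_u)

with g the toroidal grid distance to the BMU. Both schedules decay
exponentially: α from 0.5 to 0.01, σ from its initial value to 0.5 by
default. Defaults follow the reference setup for drug-like collections:
15 × 20 neurons, σ₀ = 7, 10⁶ cycles (one cycle = one sample
presentation). The α schedule and σ_end are this package's own choices —
exponential decay is the standard Kohonen recipe and the values are
unremarkable; all are configurable. Tests and examples use 10⁴–10⁵
cycles on smaller grids, which this descriptor space needs for
convergence at the problem sizes used.

Toroidality affects only the neighborhood geometry; BMU search happens
in descriptor space. Models serialize to JSON with hex-encoded doubles,
so a round trip is bit-exact.

## Profiling and enrichment

A "cluster" is a single neuron, reported 0-based as "(x/y)" =
(column/row). Reference compounds may carry several class labels and
count once per class. For a cluster, a class's fraction is (members
carrying the class)/(reference members); its fold over-representation is
that fraction divided by a background fraction. The default background
basis is the *compound* basis — the class's fraction among all reference
compounds — which is self-consistent: the whole map shows fold 1.0 for
every class, and the maximum attainable fold for a class equals the
reciprocal of its background fraction. Backgrounds computed over a
target catalogue instead (the *target* basis, useful when annotations
come as per-target ligand lists) can be supplied explicitly. A zero
background makes the fold undefined; the package reports
not-computable rather than infinity.

Candidate selection mirrors practice: the neuron most densely populated
with the class of interest is the target cluster; library compounds
assigned there are returned nearest-first; the reference compound
closest to the neuron's weight vector (equivalently, the member with the
smallest stored BMU distance) is the cluster's centroid representative.
Feature maps expose one descriptor bin across the grid, by default as
the neuron-weight plane (the map's "common pharmacophore" view), with a
per-cluster compound-mean option — both are legitimate readings, and the
weight plane is the one that exists even for empty neurons.

## Synthetic data

Real building-block stocks and annotated reference collections are
proprietary, so the package generates stand-ins.

**Building blocks** come from fixed grammars (substituted benzaldehydes
plus aliphatic aldehydes; β-ketoamides, β-ketoesters, 1,3-diketones),
enumerated deterministically, passed through the real selection filter,
deduplicated canonically, then subsampled with a seeded shuffle.
Requesting more than the filter-passing capacity (currently 241
aldehydes, 64 dicarbonyls) raises an error naming the maximum. The
substituent alphabets lean polar because the benzaldehyde core alone
sits near Crippen logP 1.5 against the < 2 cutoff.

**Reference libraries** are built from `ClassSpec`s: each target class
is a scaffold family (templates with `{R}` slots filled from a
decoration alphabet) whose pharmacophore-pair signature is distinct by
construction — e.g. the default `kinase_like` family (aminopyrimidines,
aryl ureas) is rich in short-range donor–acceptor pairs, while the
default `gpcr_like` family (lipophilic tertiary amines) populates
positive–lipophilic bins. A `purity` parameter (default 1.0) mixes in
neutral filler scaffolds to weaken the signal when a harder instance is
wanted. The default recovery experiment uses 125 signal + 375 background
compounds: because the compound-basis fold is capped at 1/background
fraction, a balanced 50/50 design could never exceed 2-fold, whereas the
25% design caps at 4-fold and leaves the ≥3-fold recovery criterion
meaningful.

What passing on this synthetic data shows: the full chain — typing,
descriptor, map training, enrichment arithmetic, candidate selection —
recovers planted class structure that is visible to the descriptor. What
it does not show: performance on real annotated collections, whose
classes overlap, are multi-label, span hundreds of targets and are not
cleanly separable in CATS space; nor fidelity of any specific historical
map layout, which depends on unpublished training schedules and data.

## Numerical choices and degenerate inputs

- BMU and top-cluster ties break toward the smallest linear index
  y·W + x (first-minimum/first-maximum semantics); centroid and
  candidate ties break on compound id.
- Empty clusters: class fractions return an empty mapping (not NaN);
  centroid extraction on an empty cluster is an error; candidate lists
  may be empty.
- Zero-variance descriptor columns initialize all neurons to the
  constant value; training on a single vector converges to it (checked
  to 1e-6 after 10⁴ cycles).
- Disconnected atom pairs carry a −1 sentinel in the distance matrix and
  never contribute to descriptor bins (standardization makes them
  unreachable in practice).
- Non-finite descriptor values abort training before any update.
- TSV writers use enough significant digits for exact float round trips
  (`%.17g` for assignments; readers request round-trip float parsing).

## Pipeline determinism

`run_pipeline` expands one global seed into per-stage seeds via
SHA-256 of `"<seed>:<stage>"` reduced mod 2³¹, recorded in the run
manifest together with every parameter and input path, so any stage can
be rerun in isolation and a rerun of the same configuration is
byte-identical in all artifacts. Problem sizes in the shipped tests and
examples (10×10 maps, 10⁴–10⁵ cycles, 500-compound reference sets,
libraries up to 78×56) were chosen as the smallest instances at which
the planted-structure experiments are stable across seeds.

## Known limitations

- Standardization is simpler than vendor "wash" routines; exotic salts
  or zwitterions may standardize differently.
- The typing rules are one defensible reading of the CATS scheme;
  absolute bin values are not comparable across CATS implementations.
- Regiochemistry uses a size heuristic; genuinely ambiguous diketones
  (two same-size different ketone substituents) resolve by atom index,
  and the alternative regioisomer is not emitted unless requested.
- Enrichment folds come without significance estimates (no
  hypergeometric p-values); with 300 neurons and hundreds of classes,
  raw folds on small clusters can be noisy.
- Online SOM training is stochastic in its sample order; different seeds
  give different (equally valid) layouts. Only seeded runs are
  comparable.
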