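# Methods

This note documents the models, parameter choices and numerical conventions
behind `nactk`, and what the synthetic-data generators do and do not emulate.

## Coordinates and I/O conventions

Intervals are 0-based half-open internally and 1-based inclusive in every
report. FASTA is parsed with Biopython and newick with dendropy; residues are
uppercased on read, one terminal `*` in protein FASTA is stripped, and one
terminal stop codon is tolerated (and stripped) when checking that a CDS
translates to its protein. An `X` in a protein matches any residue in the
translation check and any fixed-residue element in motif matching; it carries
no mass (molecular weight is undefined for X-containing proteins) and no
emission information in the NLS HMM.

## Domain confirmation by signature motifs

NAC domains are confirmed by their short consensus motifs rather than by a
profile HMM: the shipped catalog (`src/nactk/data/nac_motifs.tsv`, editable)
lists eight core motifs in their canonical N→C order. The pattern grammar is
PROSITE-flavoured (`x`, `x(n)`, `x(n,m)`, `[..]`, `{..}`, with `A/B`
normalized to `[AB]`); compiled patterns are matched as regular expressions
with greedy wildcard repeats, one hit per start position, and the engine is
continuously validated against a naive backtracking matcher.

A **domain instance** is called where at least `min_core_motifs` (default 3
of 8) distinct core motifs co-occur in canonical order within a 200-residue
window; instances are selected greedily left-to-right (leftmost start, then
longest) and never overlap. The threshold of 3 is an empirical compromise:
no published rule says how many signature motifs "confirm" a domain, so the
default is justified by a permutation null — residue-shuffled,
composition-matched NAC proteins produce a domain call in under 1% of trials
— while remaining low enough that partial domains are still countable by
lowering the threshold in configuration. Non-NAC catalog patterns (role
`partner`) hitting outside called instances flag chimeric architectures.
The nuclear export signal is the hydrophobic `L-V-F-Y` motif plus its
substitution class `L-[VI]-[FM]-[YM]`.

## Molecular weight, pI, transmembrane segments

Molecular weight is the sum of standard average residue masses plus one
water. The water mass is fixed at 18.02 Da so that the condensation identity
`mw(a⊕b) = mw(a) + mw(b) − 18.02` holds exactly; at report precision (two
decimals) this is indistinguishable from the usual 18.0153.

Net charge at a given pH is the Henderson–Hasselbalch sum over the termini
and the ionizable side chains (D, E, C, Y negative; K, R, H positive). The
pI is found by bisection on [0, 14]; the charge is strictly decreasing in pH
and changes sign across that range, so the root is unique. Sixty bisection
steps put the result far below the 10⁻⁴ pH reporting tolerance, and
|charge(pI)| < 10⁻³ for peptides of ordinary length. pKa values are data,
not code: the default `emboss` table and an alternative `sillero` table ship
in `pka_tables.tsv`, because published pI calculators differ only in this
table. Proteins are classed acidic when pI < 7.0 (configurable; the
literature is ambiguous between 7.0 and 7.4).

Transmembrane segments are called with a deliberately simple, documented
stand-in for trained topology predictors: maximal unions of 19-residue
windows whose mean Kyte–Doolittle hydropathy is ≥ 1.6. The output column is
named `tm_segments_hydropathy` so downstream users cannot mistake it for a
probabilistic topology model; externally computed TM calls can be merged via
TSV instead. On synthetic data the planted 23-residue hydrophobic stretches
are recovered at 100% with ≤ 1% false positives on shuffled decoys.

## NLS detection: 2-state HMM

Detection uses a static (untrained) two-state HMM — background vs NLS —
decoded by Viterbi (log space, ties toward background) or by posterior
(forward–backward with per-position scaling) against a cutoff of 0.4, with
runs shorter than 4 residues dropped. `min_len = 4` matches the shortest
taxonomy class (monopartite class II spans four positions). The shipped
default parameters (editable TSV, any file with the same section/key/value
layout loads) encode the one structural fact that matters: the NLS state
strongly prefers K and R (emission 0.30 each, background uniform 0.05), is
rare a priori (initial 0.01, entry rate 0.01) and persists once entered
(self-transition 0.90, mean length 10).

These dynamics set a physical sensitivity floor: segments whose best basic
run is ≥ 4 residues are reliably called (100% of such planted signals are
overlapped by a call at the defaults), while patterns carrying only 2–3
basic residues (monopartite class II and the non-canonical classes) peak
near posterior 0.25 and are below the 0.4 cutoff — a genuine property of
this detector configuration, not of the implementation. Classification is
therefore exercised both on detector output and directly on segments.
When the two decoders disagree, both call sets are reported; no merge policy
is imposed.

## NLS taxonomy

Classes are decided in a fixed order — pattern-defined classes first, so the
cluster-geometry rules cannot absorb them:

1. class III: `K-R-x-[WFY]-x(2)-A-F`
2. class IV: `[PR]-x(2)-K-R-[KR]`
3. multipartite: ≥ 3 basic clusters
4. bipartite: 2 clusters with a linker of 8–24 residues
5. monopartite class I: a single run of ≥ 4 consecutive K/R (open-ended
   upper bound; runs up to 15 are observed in real data)
6. monopartite class II: `K-[KR]-x-[KR]`

Basic clusters start as maximal K/R runs of length ≥ 2. A run merges into an
adjacent run when they are separated by ≤ 4 non-basic residues **and** at
least one of the pair is an anchor run of length ≥ 3; two lone pairs never
seed a merge. The anchor condition is what makes the canonical bipartite
exemplar `K-R-P-A-A-T-K-K-A-G-Q-A-K-K-K-K` read as two clusters
(`KR` | `KK`+`KKKK`): both of its gaps are exactly 4, so an unconditional
gap rule would collapse everything into one cluster. The bipartite linker is
measured between the *core* runs (longest constituent run) of the two
clusters, which scores the exemplar's linker as the classical 10 residues;
the accepted range [8, 24] extends the canonical 10–12 to the longest
linkers observed in plant NAC data. An alternative multipartite reading
(2 clusters with ≥ 6 central basics) exists in the literature; the ≥ 3
cluster rule is implemented and the threshold is configurable.

Signatures collapse linkers: every non-K/R residue is deleted (idempotent).
The census counts unique signatures per terminal region; an NLS is
N-terminal when its interval midpoint falls in the first half of the protein
(the exact boundary is a convention — nothing in the underlying biology
defines where the "N-terminal region" ends).

## Codon usage

RSCU for codon c in synonymous family F is `count(c)/(total(F)/|F|)`, so
family means are exactly 1 whenever the family is observed and single-codon
families (AUG, UGG) are 1 when present. Stop codons are excluded from RSCU
and abundance (61 sense codons) but still counted; ambiguous codons are
skipped, never imputed; output labels use the RNA alphabet. Per-species
"present in N species" columns are computed against the actual species set
supplied, since published denominators vary without explanation.

## Substitution patterns, trees, reconciliation

**TN93 estimation.** Pair counts are pooled over every sequence pair
(composite style) with pairwise deletion of gap/N columns; base frequencies
come from the same pooled counts. From the pooled transition proportions P1
(A↔G), P2 (C↔T) and transversion proportion Q, the standard TN93 logarithmic
inversions give branch-scale components α₁t, α₂t, βt; k1 = α₁/β,
k2 = α₂/β, and the overall bias R = (π_Aπ_G k1 + π_Cπ_T k2)/(π_Rπ_Y). The
rate table entries are proportional to π_j times the class rate and are
normalized so the 12 off-diagonal percentages sum to 100. Degenerate inputs
degrade gracefully: identical sequences give an all-zero table with NaN
ratios; absent transversions give infinite ratios; saturation (non-positive
log arguments) raises with a clear message. The TN93 distance is the
expected substitutions per site implied by the same components and equals
the standard closed form; it is never smaller than the p-distance.

**Neighbour joining.** Saitou–Nei NJ with deterministic tie-breaking
(smallest index pair) and negative limb lengths clamped to zero with the
deficit moved to the sibling limb. On additive matrices NJ is consistent:
topology and branch lengths are recovered exactly (property-tested against
random binary trees and cross-checked against scikit-bio's implementation).
Distances feed NJ as p or TN93; a "GTR distance" is not a standard NJ input
and is out of scope. Bootstrap support resamples alignment columns with
replacement and reports, per internal split of the full-data tree, the
fraction of replicate trees containing it (deterministic given the seed).

**Reconciliation.** Rooted binary gene and species trees are reconciled by
LCA mapping: a gene node is a duplication when it maps to the same species
node as one of its children; losses are species-path lengths minus one for
speciation nodes and the full path for duplication nodes; paralogs are gene
leaves under at least one duplication. Gene ids map to species by the prefix
before `|` unless an explicit map is given. NJ trees are unrooted, so
reconciliation roots them at the midpoint by default; midpoint rooting does
not necessarily minimize duplications, and `--root-all-search` enumerates
all rootings to find the minimizing one (intended for small trees). Losses
are always computed and reported rather than assumed zero.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of spec + seed; each record draws from its own
child generator (seeded by record index) so inserting a record never
reshuffles the others, and identical seeds give byte-identical output.

- **Proteomes** (defaults: domain-count weights 0.85/0.09/0.04/0.02 for 1–4
  domains, 9% TM fraction, 5% chimeric, lengths 280–650, eight plants of
  each NLS class) plant *exact* motif instances in canonical order, NLS
  segments of every taxonomy class at recorded coordinates, 23-residue
  hydrophobic stretches and partner motifs, padded with linker residues
  drawn from an alphabet (A,G,S,T,Q,N) that can neither extend a basic
  cluster nor create a non-canonical NLS pattern. Decoys are
  composition-matched shuffles of NAC proteins, which makes false-positive
  rates meaningful. Not modelled: motif degeneracy/mutation, indels inside
  domains, realistic background composition. Passing recovery tests
  therefore demonstrates correctness of the calling logic, not robustness to
  divergent real sequences.
- **CDS** are back-translations sampling synonymous codons with target
  weights (uniform by default), plus a terminal stop; round-tripping the
  RSCU estimator recovers the target within 0.05 (worst codon) at the
  4×10⁵-codon scale used in validation — sampling noise for a six-codon
  family at that depth is σ ≈ 0.016 per codon.
- **Alignments** evolve sites independently down a tree under the TN93
  generator (matrix exponential per branch, normalized to one expected
  substitution per unit length). The estimator-accuracy condition is a
  two-taxon tree with 0.05-length branches (0.1 total divergence, typical
  for intra-family comparisons), 50 kb, k1 = 4, k2 = 2, equal frequencies.
  No rate heterogeneity across sites, no indels.
- **Gene families** grow forward on the species tree: each duplication
  event picks a uniform species-tree edge and a uniform gene lineage on it,
  so LCA reconciliation of a loss-free family recovers exactly the planted
  event count. With losses, leaves are pruned independently and the truth
  reports surviving duplications and pruned-leaf counts; reconciliation
  losses are a different (inferred) quantity, so exact-recovery claims are
  restricted to loss-free histories.

## Problem sizes and determinism

The validation suite runs the pattern engine against its brute-force oracle
on 10⁴ random cases, the HMM decoders against exhaustive enumeration on 10³
instances (L ≤ 10), NLS classification on 510 plantings, TN93 recovery on
100 × 50 kb replicates, NJ on 200 random additive matrices (n ≤ 12),
reconciliation on 200 loss-free families (d ≤ 5), and pI against a 10⁻⁴-step
grid on 10³ peptides — sizes chosen so the whole suite completes in well
under a minute per property on one core. All randomness flows from explicit
seeds; pipeline reports contain no timestamps, and rerunning with the same
configuration and seed reproduces every output byte for byte.

## Known limitations

- Domain confirmation is motif-based; highly diverged NAC domains that a
  profile HMM would find can be missed, and the 3-of-8 threshold is a
  configuration choice, not a learned boundary.
- The NLS HMM parameters are an interpretable static prior, not trained
  frequencies; sensitivity below 4-residue basic runs is limited by design.
- TM calling is hydropathy-only (no topology, no signal-peptide
  discrimination).
- GTR-based distances, maximum-likelihood trees, model selection and
  rearrangement-mode reconciliation are out of scope.
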