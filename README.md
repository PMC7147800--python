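# nactk

Genome-scale characterization of **NAC transcription factors** (NAM / ATAF1,2 /
CUC2), one of the largest plant transcription-factor families. Starting from
per-species protein and CDS FASTA, `nactk` runs the full census a comparative
survey needs:

- **Domain confirmation** — a PROSITE-style pattern engine with the NAC
  consensus-motif catalog (`P-G-F-R-F-H-P-T-D-[DE]-L-[IV]`, `E-W-Y-F-F`,
  `T-x-W-x-M-H-E-Y`, ...). A NAC domain is called when enough core motifs
  co-occur in canonical order; multi-domain (2–4 tandem NAC domains) and
  chimeric architectures are flagged, and the hydrophobic `L-V-F-Y` nuclear
  export signal is detected.
- **Physicochemical profiling** — average molecular weight, isoelectric point
  (bisection root of the Henderson–Hasselbalch net charge), acidic/basic
  classification, and Kyte–Doolittle hydropathy-window transmembrane calls.
- **NLS detection and taxonomy** — a 2-state hidden Markov model (background
  vs NLS) decoded by Viterbi or posterior with a 0.4 cutoff, then classified
  into monopartite class I/II, bipartite, non-canonical class III/IV and
  multipartite signals; linker residues are collapsed to basic-residue
  signatures (`KRPAATKKAGQAKKKK` → `KRKKKKKK`) and censused per terminal
  region.
- **Codon usage** — per-gene and per-species codon counts, presence across
  species, average abundance, and relative synonymous codon usage
  (RSCU<sub>c</sub> = observed / expected under uniform use within the
  synonymous family).
- **Evolution** — Tamura–Nei (TN93) substitution-pattern estimation from
  pooled pair counts with pairwise deletion (purine/pyrimidine
  transition-transversion ratios k1, k2 and overall bias R), p/TN93 distance
  matrices, Saitou–Nei neighbour-joining trees with bootstrap support, and
  LCA gene-tree/species-tree reconciliation counting duplications, losses and
  paralogs.
- **Synthetic data** — seeded generators for proteomes with planted motifs,
  NLS and TM stretches, codon-biased CDS, TN93-evolved alignments and gene
  families with known duplication histories; every generator ships its ground
  truth.

## Worked example

Simulate a small proteome with ground truth and run the whole pipeline:

```bash
nactk simulate proteome --n-nac 5 --n-decoys 2 --seed 3 --out p.faa --truth t.tsv
nactk simulate cds --proteome p.faa --seed 3 --out c.fna
printf '((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);' > tree.nwk
nactk simulate alignment --tree tree.nwk --length 2000 --seed 2 --out aln.fna
printf '((A,B),(C,D));' > sp.nwk
nactk simulate family --species-tree sp.nwk --duplications 2 --seed 4 --out genes.nwk

cat > run.cfg <<EOF
species = spA
spA.proteome = p.faa
spA.cds = c.fna
spA.alignment = aln.fna
spA.gene_tree = genes.nwk
species_tree = sp.nwk
EOF
nactk all --config run.cfg --outdir out
cat out/species_report.tsv
```

prints the census row

```
species_id  total_nac  n_double_domain  n_chimeric  n_tm_bound  n_with_nls  nls_class_histogram                                 duplications  losses
spA         5          1                0           0           5           mono_I:21,mono_II:1,multipartite:2,unclassified:1   2             0
```

All 5 planted NAC proteins are confirmed (one carries two tandem domains),
every protein has at least one detected NLS — most detector calls are the
basic cores, hence the mono_I-heavy histogram — and reconciling the gene tree
against the species tree recovers exactly the 2 planted duplications with no
losses. Per-protein tables (motif hits, MW/pI, NLS calls and signatures,
codon usage with RSCU, the TN93 rate table) are written next to the report.

In the library, the same stages are plain functions:

```python
>>> from nactk.nls_classify import classify_nls, collapse_linkers
>>> classify_nls("KRPAATKKAGQAKKKK")
'bipartite'
>>> collapse_linkers("KRPAATKKAGQAKKKK")
'KRKKKKKK'
```

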