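# tsakit

Simultaneous plastid and mitochondrial genome assembly from a single
mixed-organelle sequencing library, at desk scale.

Plant total-DNA shotgun libraries mix three genome compartments with wildly
different copy numbers: plastid DNA (ptDNA) at hundreds to thousands of copies
per nuclear copy, mitochondrial DNA (mtDNA) at tens, and nuclear DNA (ncDNA)
at one. `tsakit` implements the two computational pillars that make one
organelle-enriched library sufficient for *both* organelle genomes:

1. **VCQA** (vector-control quantitative analysis) — quantify the sample's
   ptDNA/ncDNA and mtDNA/ncDNA copy folds from qPCR on marker genes
   (*rpoB* plastid, *ccmB* mitochondrial, *β-actin* nuclear), and size the
   sequencing dataset those folds require.
2. **TSA** (two-step assembly) — assemble the deep plastid stratum first with
   a high kmer-frequency threshold; remove every read pair with at least one
   end matching the finished plastid exactly; assemble the mitochondrion from
   the remainder; close the gaps that plastid-read removal necessarily opens
   in plastid-homologous mitochondrial tracts, by strict iterative anchored
   gap filling.

Everything is exercised end-to-end against synthetic mixed-organelle
libraries with known truth (the `simgen` module), so every stage — kmer
filtering, exact-match pair removal, reference-guided drafting, iterative
closure — is auditable without any external data.

## The model

**Copy folds from qPCR.** For a gene with amplification efficiency `E`
(`E = 1` is perfect doubling) measured on a control vector (CT_control) and on
the DNA sample (CT_sample), the efficiency-corrected relative quantity is

    Q = (1 + E)^(CT_control − CT_sample)

The copy fold of an organelle is the ratio of its marker's `Q` to the nuclear
marker's `Q`. A dataset of `G·D / fold` bases (nuclear genome size `G`) covers
the organelle `D` layers; a plastid at fold ~1900 needs only tens of
megabases for a deep assembly.

**Depth-stratified assembly.** On canonical kmers, a count threshold sitting
between the mitochondrial and plastid strata removes every kmer not belonging
to the plastid; unitigs of the thresholded de Bruijn graph are the plastid
scaffolds. The quadripartite plastid (LSC + IRa + SSC + IRb, IRb the reverse
complement of IRa) collapses its inverted repeat into one double-depth
contig, which carries no reference-unique anchors and is therefore left
unplaced; the IR regions re-enter as reference-sized gaps and are rebuilt
base-by-base from reads during closure.

**The homology trap.** Mitochondrial genomes carry tracts nearly identical to
plastid sequence. Exact plastid-pair removal deletes those tracts' coverage,
so the mitochondrial draft has gaps exactly there. Closure therefore maps the
*full* clean read pool to the draft each cycle, keeps pairs with one end
anchored exactly, positions the partner mate by insert geometry, and extends
gap flanks under a strict-majority vote — repeating until no gap extends.

## Worked example

Copy folds and dataset sizing from a qPCR table:

```python
from tsakit import vcqa

actin = vcqa.QpcrMeasurement("actin", "nuclear",       1.124, 17.79, 23.70)
ccmb  = vcqa.QpcrMeasurement("ccmB",  "mitochondrial", 1.060, 17.64, 17.87)
rpob  = vcqa.QpcrMeasurement("rpoB",  "plastid",       1.042, 17.76, 13.40)
rep = vcqa.purity_report([actin, ccmb, rpob], nuclear_genome_size=1.2e9,
                         target_depth=50, dataset_bases=1.2e9)
print(rep.to_tsv())
```

```
gene    relative_quantity
actin   0.0117
ccmB    0.8469
rpoB    22.4824
copy_fold_mt    72
copy_fold_pt    1922
required_bases_mt       8.333e+08
required_bases_pt       3.122e+07
dataset_sufficient      True
```

The mitochondrion sits at 72 copies per nuclear copy and the plastid at 1922;
a 1.2 Gb run (one nuclear layer) gives them 72 and 1922 layers respectively,
comfortably past the ~50 layers a clean de novo assembly wants — so the
planned dataset is sufficient, with the mitochondrion the binding constraint
(`8.33e8` bases needed).

A full two-step assembly on a synthetic mixed library (compact sizes; a
600 nt plastid tract planted in the mitochondrion):

```python
from tsakit import simgen, pipeline, equal_up_to_rotation_strand
from tsakit.assembler import AssemblyParams

g = simgen.make_genomes(lsc=3000, ssc=1200, ir=800, mito=6000, nuclear=8000,
                        homology_tract=600, seed=1)
pairs, truth = simgen.sample_read_pairs(
    g, simgen.ReadSimParams(total_pairs=14000, copy_folds=(100, 10, 1), seed=2))
cfg = pipeline.PipelineConfig(
    step1=AssemblyParams(min_kmer_freq=80, min_edge_cov=80, min_contig_len=500),
    step2=AssemblyParams(min_kmer_freq=12, min_edge_cov=12, min_contig_len=500))
res = pipeline.run_tsa(pairs, g.plastid, g.mito, cfg)
```

The run report shows the mechanism at work — the plastid assembles into 3
scaffolds of which the 2 single-copy ones place (the IR contig is repeat-only
and unplaceable), leaving 2 IR gaps that closure fills; plastid-pair removal
keeps 1,274 of 14,000 pairs; the mitochondrial draft opens 1 gap at the
planted tract and the strict closure needs 2 cycles (1,109 then 1,553 anchored
pairs) to fill it:

```
plastid: {'scaffolds_total': 3, 'scaffolds_aligned': 2, 'gaps_total': 2,
          'gaps_filled': 2, 'residual_gaps': [], 'length': 5800, ...}
removal: {'pairs_removed': 12726, 'pairs_kept': 1274, 'kept_fraction': 0.091}
mito:    {'scaffolds_total': 1, 'scaffolds_aligned': 1, 'gaps_total': 1,
          'gaps_filled': 1, 'residual_gaps': [], 'length': 6000,
          'iterations': [{'iteration': 1, 'pairs_mapped': 1109, 'bases_extended': 807},
                         {'iteration': 2, 'pairs_mapped': 1553, 'bases_extended': 1074}]}
depth:   {'plastid_unique': {...,'depth': 548}, 'mito_unique': {...,'depth': 43}}
```

Both returned genomes equal the simulation truth exactly (up to rotation and
strand), and the realised mitochondrial unique-region depth (43) matches the
copy-fold expectation.

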