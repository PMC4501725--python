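# zdosage

Simulation and analysis toolkit for detecting failed Z-chromosome dosage
compensation in pooled-embryo transcriptomes of a female-heterogametic
(WZ/ZZ) species.

The package covers the full computational chain:

- **`zdosage.simulate`** — synthetic reference gene models (proteins +
  CDSs with chromosome labels), transcript contigs, and pooled-RNA count
  matrices under an explicit gene-dose model: Z-linked genes have copy
  number 2 in ZZ males and 1 in WZ females, active dosage compensation
  halves male Z output, and a *compensation-failure factor* `f ∈ [1, 2]`
  restores it in infected males. A single Z-linked "masc-like" regulator
  follows a unimodal time profile peaking at 6 h post-oviposition and is
  knocked down by a factor `d` in infected pools. Counts are
  negative-binomial (variance `mu + dispersion * mu^2`). The module also
  simulates qPCR Ct tables for molecular sexing and protein alignments
  evolved along known trees.
- **`zdosage.homology`** — affine-gap global (Needleman–Wunsch/Gotoh)
  and local (Smith–Waterman) protein alignment against BLOSUM62,
  Karlin–Altschul E-values, and best-hit chromosome assignment of
  six-frame-translated contigs.
- **`zdosage.dosage`** — CPM and median-of-ratios normalization
  (optionally anchored on autosomal contigs), per-contig log2
  infected/uninfected ratios (M/A), per-chromosome median + quartile
  summaries, and a one-sided permutation test for a Z-specific shift.
- **`zdosage.sexing`** — efficiency-corrected relative-dose molecular
  sexing from two Z-linked genes (Tpi, kettin) against an autosomal
  normalizer (EF1a), plus exact two-sided binomial tests on brood sex
  ratios.
- **`zdosage.phylo`** — domain-window extraction, p-distances,
  neighbor joining (exact on additive matrices), column-resampling
  bootstrap supports, and newick read/write.
- **`zdosage.pipeline` / `zdosage.cli`** — end-to-end orchestration with
  a JSON config, per-stage logging, and a reproducibility manifest;
  reruns with the same config and seed are byte-identical.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the eight end-to-end acceptance
criteria (dose-model recovery, null calibration of the permutation test,
alignment-oracle equivalence, chromosome-assignment recovery, NJ
exactness against an exhaustive least-squares oracle, bootstrap split
recovery, sexing recovery, and the brood-test closed form). The
acceptance report script:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(The one externally comparable target requires downloading a sequence
database accession and is omitted when offline; see the script's
docstring.)

## CLI

```sh
# generate a complete synthetic input set
zdosage simulate --config design.json --seed 1 --outdir sim/

# assign contigs to chromosomes by best protein-level hit
zdosage assign --contigs sim/contigs.fasta \
    --reference-proteins sim/reference_proteins.fasta \
    --gene-table sim/gene_table.tsv --out assignments.tsv

# per-timepoint Z-shift analysis
zdosage dosage --counts sim/counts.tsv --samples sim/samples.tsv \
    --assignments assignments.tsv --outdir dosage_out/

# molecular sexing from a qPCR Ct table
zdosage sex --ct-table sim/ct_table.tsv --out sex_calls.tsv

# NJ tree with bootstrap supports from an aligned FASTA
zdosage phylo --alignment aln.fasta --bootstrap 1000 --out tree.nwk

# everything end to end (simulates inputs when given a simulate block)
zdosage run-all --config pipeline.json --seed 1 --outdir out/
```

A minimal `pipeline.json`:

```json
{
  "seed": 1,
  "simulate": {
    "n_chromosomes": 5,
    "genes_per_chromosome": 100,
    "male_fraction": 0.5,
    "compensation_failure_factor": 2.0,
    "masc_knockdown": 0.2,
    "dispersion": 0.05,
    "library_size": 1000000,
    "timepoints": [0.0, 12.0, 24.0, 36.0, 48.0],
    "failure_onset_hpo": 24.0
  },
  "normalization": "median",
  "n_permutations": 999,
  "bootstrap_replicates": 100
}
```

Outputs are plain text (FASTA / TSV / newick / JSON). `manifest.json`
records the seed and every parameter needed to reproduce each file.
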