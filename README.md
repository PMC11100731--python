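# bmpcrep

Single-cell BCR repertoire analysis of bone-marrow plasma cells (BMPCs),
built around one question: did a given plasma cell arise from a recalled
memory B cell (MBC) or directly from a germinal center (GC)? The two
ancestries leave different fingerprints in paired VDJ + gene-expression +
CITE-seq data, and this package computes all of them:

* **Cell QC** — retain cells with mitochondrial fraction < 5%, 200–4,000
  total RNAs, and zero counts of non-plasma-cell lineage markers
  (*CD3E*, *NKG7*, *PRF1*, *S100A9*, *FCGR3A*, *CD14*, *COL1A1*, *APOE*,
  *CSF3R*, *HBB*).
* **Isotype assignment** — a VDJ constant-region call wins outright;
  otherwise the cell is assigned the IGHC subclass holding a strict
  majority (> 1/2) of summed IGHC transcript counts with strictly more
  than 20 counts, else left unassigned. A benchmark harness measures the
  GEX-only rules against VDJ truth.
* **SHM** — percent mismatch between the heavy-chain nucleotide sequence
  and its inferred germline over all comparable (unambiguous, ungapped)
  aligned positions.
* **Clonotyping** — cells sharing IGHV gene, IGHJ gene and CDR3 length
  are single-linkage clustered on normalized CDR3 amino-acid hamming
  distance (default: join at ≥ 0.85 similarity, i.e. distance ≤ 0.15).
* **Clonal structure** — expanded clones with ≥ 2 unique heavy-chain
  sequences are *heterogenic* (read: direct GC export), expanded clones
  with one shared sequence are *isogenic* (read: MBC recall), unexpanded
  cells are *singlets*.
* **CD19/SHM binning and statistics** — antibody-capture CD19 counts are
  log-transformed and Z-scored per batch; cells are ranked 30/40/30 into
  low/mid/high bins (same rule for SHM). Group comparisons use
  Mann-Whitney (2 groups), Kruskal-Wallis (≥ 3) and Friedman (related
  groups), exact by enumeration for small tie-free samples, with Dunn-type
  all-vs-all post-hoc tests under Holm adjustment.

Because raw human data of this kind is rarely shareable, the package
ships a **synthetic-repertoire generator** that plants the two
ancestries explicitly — MBC clones copy one sequence identically, GC
clones carry shared trunk plus private per-cell mutations, CD19 and a
designated association gene (*JCHAIN*) are shifted between origins — and
emits full ground truth, so every stage of the pipeline is verifiable
end to end.

## Worked example

```python
import bmpcrep as b

sim = b.simulate_repertoire(b.SimConfig(n_cells=2000, seed=1))
res = b.run_pipeline(b.PipelineConfig(seed=1),
                     vdj=sim.vdj, cells=sim.cells, meta=sim.meta)

pc = res.per_cell
print(int(pc["qc_pass"].sum()), res.qc_removals)
print(pc.groupby("cd19_bin")["shm_percent"].median().round(2))
print(pc.groupby("structure")["shm_percent"].median().round(2))
```

prints

```
1880 {'mito': 40, 'rna': 40, 'lineage': 40}
cd19_bin
high    8.47
low     4.02
mid     5.42
structure
heterogenic    8.53
isogenic       3.91
singlet        5.90
```

1,880 of 2,000 cells pass QC (the generator plants 2% mito, 2% RNA-count
and 2% lineage failures). Median SHM rises monotonically across CD19
bins (4.0% → 5.4% → 8.5%; Kruskal-Wallis H ≈ 612, p ≈ 1e-133 in
`res.tests_table`) and heterogenic clones are far more mutated than
isogenic ones — exactly the signatures expected if CD19-high BMPCs are
GC exports and CD19-low BMPCs are MBC progeny. The same run reports a
Spearman correlation of ≈ 0.64 between normalized CD19 and SHM.

The command-line interface mirrors the library:

```bash
bmpcrep simulate --n-cells 2000 --seed 1 --outdir sim_out
bmpcrep run-all --vdj-path sim_out/vdj.tsv --counts-path sim_out/counts.tsv \
    --metadata-path sim_out/metadata.tsv --outdir results
```

`run-all` writes `per_cell.tsv`, `per_clone.tsv`, `tests.tsv` (one row
per statistical test), per-analysis tables under `stats/`, and a JSON
manifest recording the configuration hash and seed. Every
`PipelineConfig` field is also a CLI flag overriding the `--config` YAML
file.

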