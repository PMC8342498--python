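# brewptm

Site-specific PTM quantification pipeline for DIA/SWATH bottom-up
proteomics of beverages (built around barley/yeast beer proteomes).

Starting from a protein FASTA and a long-format peptide quantification
table (peptide form × sample × technical replicate), the pipeline:

1. locates every peptide form in its protein, classifies its cleavage
   state (full/semi/non-tryptic) and parses its modification annotation
   (Lys glycation Hex1–10, Ser/Thr O-glycosylation Hex1–10,
   N-glycosylation HexNAc1–2(+Hex0–10) at N-X-S/T sequons, plus common
   deamidation/oxidation);
2. re-filters peptide intensities at a 1% peptide FDR cutoff and
   collapses technical replicates;
3. groups all forms sharing a full-tryptic backbone anchor into a
   *peptide family* (anchor = the minimal containing full-tryptic
   peptide with ≤ 2 missed cleavages) and normalizes each member to the
   family total, yielding within-family proportions;
4. summarizes per-sample occupancy (total = sum of per-family modified
   proportions, average = their mean) for glycosylation, glycation, and
   proteolysis;
5. recomputes protein abundance as the sum of all retained peptides,
   normalized either to total protein abundance per sample or to
   trypsin self-digest peptide abundance;
6. runs PCA (centered, unscaled, with explained-variance reporting) and
   hierarchical clustering with Cluster-3.0 semantics (uncentered
   correlation distance, complete linkage, deterministic tie-breaking,
   Newick export);
7. computes two-group differential abundance (Welch t-test per feature
   + Benjamini–Hochberg; positive log2FC = higher in the first-named
   group) and ordinary-least-squares regressions of protein-class
   abundance (NLTPs, serpins, seripauperins) against foam measurements.

A synthetic-data module generates complete, structurally valid bundles
(FASTA + quant + metadata + foam tables) with recorded ground truth
(planted occupancies, abundances, group effects, foam couplings) so
every stage is testable for parameter recovery without external data.

## CLI

```sh
# make a synthetic dataset
brewptm generate --seed 1 --outdir demo

# full pipeline: all result tables + provenance JSON
brewptm run --fasta demo/proteins.fasta --quant demo/quant.tsv \
    --metadata demo/metadata.tsv --foam demo/foam.tsv --outdir demo/out

# individual stages
brewptm occupancy --fasta ... --quant ... --metadata ... --kind proteolysis
brewptm cluster   --fasta ... --quant ... --metadata ... --axis cols
brewptm compare   --fasta ... --quant ... --metadata ... --groups scale \
    --order independent,multinational
brewptm foamreg   --fasta ... --quant ... --metadata ... --foam demo/foam.tsv
```

Shared flags: `--fdr` (cutoff, default 0.01), `--mode` (`total` |
`trypsin` normalization), `--seed`, `--config` (pipeline YAML; see
`brewptm.interface.PipelineConfig` for keys).

## Input formats

- **FASTA**: one record per protein; the species tag
  (`barley|yeast|contaminant|trypsin`) is read from a `species=<tag>`
  token in the header, or from a sidecar mapping passed via the API.
- **Quant table** (TSV): columns `sample_id, replicate, accession,
  peptide, prev_aa, next_aa, mods, intensity, fdr`. Flanking residues
  use `-` at protein termini. `mods` grammar (semicolon-separated):
  `unmodified`, `Hex(3)@K2`, `Hex(2)@S5`, `Hex(3)@undetermined`,
  `HexNAc(1)@N7`, `HexNAc(2)Hex(5)@N7`, `Deamidated@N3`, `Oxidized@M5`.
- **Metadata** (TSV): `sample_id, brewery, style, scale, ...`.
- **Foam table** (TSV): `sample_id, max_foam_volume, foam_lifetime,
  drainage, bubbles_small, bubbles_medium, bubbles_large`.

Vendor exports are out of scope: map a PeakView-style export to the
quant-table columns above (one row per peptide form, sample, and
injection; peptide-level q-value in `fdr`).

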