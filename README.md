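# cliffscape

Structure–activity landscape and structure–mechanism analysis for chemical
activity tables. From a CSV/TSV of chemicals (SMILES + log-AC50 + hit calls +
assay endpoint), the pipeline:

1. **curates** the dataset (salt stripping, mixture/invalid rejection,
   per-endpoint structural deduplication, removal of ring-free chemicals);
2. converts activities to **pAC50** (`pAC50 = 6 − modl_ga`, with `modl_ga` the
   log10 AC50 in µM) and builds the full pairwise **ECFP4 Tanimoto /
   activity-difference table**;
3. partitions pairs on the **SAS map** (similarity threshold 0.35, activity
   threshold 2 log units) and extracts **activity cliffs** (region III) and
   **activity cliff generators** (chemicals in ≥ 5 cliff pairs);
4. generates **matched molecular pairs** by exhaustive 1–3-bond
   fragmentation/indexing (including hydrogen substitution), applies four
   size-restriction criteria, and calls **MMP-cliffs** (ΔpAC50 ≥ 2);
5. classifies each cliff into one of **seven structural types** from
   Bemis–Murcko scaffolds, cyclic skeletons, R-groups and R-group topology;
6. labels structurally similar dual-endpoint (agonist + antagonist) pairs as
   **strong MOA-cliff / same MOA / weak MOA-cliff**.

A seeded synthetic-data generator plants cliffs, MMPs, cliff generators and
MOA relationships with exact, derivable ground truth, so every stage is
testable offline.

## CLI

```bash
cliffscape curate   --input table.csv --endpoint agonist --out out/
cliffscape pairs    --dataset out/curated.csv --out out/pairs.csv
cliffscape sasmap   --pairs out/pairs.csv --sim-threshold 0.35 --act-threshold 2.0 --out out/
cliffscape mmp      --dataset out/curated.csv --max-cuts 3 --out out/
cliffscape classify --cliffs out/cliffs.csv --dataset out/curated.csv --out out/
cliffscape moa      --agonists ago.csv --antagonists ant.csv --out out/
cliffscape synth    --seed 1 --families 4 --out out/
cliffscape run-all  --input table.csv --endpoint agonist --out out/   # full pipeline + manifest
```

Input schema (configurable via `column_map` in the API): columns
`chem_id,name,smiles,modl_ga,hit_c,endpoint` with `hit_c` ∈ {0,1} and
`endpoint` ∈ {agonist, antagonist}.

## Package layout

| module | role |
| --- | --- |
| `cliffscape.dataset_io` | table parsing, structure standardization, curation cascade |
| `cliffscape.activity_metrics` | modl_ga ↔ pAC50 conversion, activity differences |
| `cliffscape.similarity` | ECFP4 fingerprints, Tanimoto, pairwise table, threshold diagnostic |
| `cliffscape.sas_landscape` | SAS regions, activity cliffs, cliff generators, map rendering |
| `cliffscape.mmp_engine` | fragmentation, MMP indexing, size restrictions, MMP-cliffs |
| `cliffscape.cliff_classifier` | scaffold/skeleton/R-group decomposition, seven-type labels |
| `cliffscape.moa_classifier` | dual-endpoint intersection and MOA pair labels |
| `cliffscape.synthetic_data` | ground-truth dataset generator and micro-fixtures |
| `cliffscape.cli_pipeline` / `cliffscape.cli` | orchestration, manifest, console script |
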