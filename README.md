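# mzmerge

Post-extraction toolkit for untargeted LC/MS metabolomics feature tables.
Given feature tables (m/z, retention time in seconds, one intensity column
per LC/MS profile) extracted from the same runs at different peak-detection
parameter settings, mzmerge can:

- **merge** the tables into one optimized table: features are grouped by a
  ppm m/z tolerance (sorted single-linkage chaining), sub-grouped by an RT
  tolerance, and each redundant sub-group is collapsed to its most
  reproducible member (minimum median PID/CV); a paired t-test per
  redundant pair is reported and can optionally veto collapsing;
- **score quality**: mean pairwise Pearson correlation among a biological
  sample's analytical replicates (sample quality) and percent intensity
  difference (duplicates) or coefficient of variation (triplicates+) per
  feature (feature quality), plus the corresponding filters;
- **match feature lists** across datasets by m/z (and optionally RT),
  report unique features, Venn region counts for up to three datasets, and
  rare features consistent within individuals;
- **optimize settings**: rank every single setting and merged setting-pair
  by the score `S = N − w·medianPID`;
- **annotate** m/z values against a local compound database through adduct
  mass arithmetic (M+H, M+H−H2O, ...) within a ppm window, with text and
  HTML reports; a small demo compound database is bundled;
- **simulate** two-setting extraction pairs with known ground truth for
  testing and benchmarking.

## File formats

- *Feature table*: delimited text (tab or comma, auto-detected), header
  `mz`, `time`, then one column per profile. RT is in seconds. By default a
  stored intensity of `0` is treated as missing (the convention of
  extractors that emit 0 for absent features); pass `--zeros-observed` /
  `zero_as_missing=False` to disable.
- *Replicate design*: two-column text mapping `profile_id` to `sample_id`.
- *Compound database*: TSV with `id`, `name`, `monoisotopic_mass` and
  optional identifier columns (`kegg_id`, `hmdb_id`, `pubchem_cid`,
  `chebi_id`, `cas`, `lipidmaps_id`).

## CLI

```sh
mzmerge simulate --seed 7 --out-dir demo          # synthetic fixture pair
mzmerge qc --table demo/setting1.tsv --design demo/design.tsv --out-dir qc
mzmerge merge --tables demo/setting1.tsv --tables demo/setting2.tsv \
    --design demo/design.tsv --ppm 5 --rt-tol 30 --out-dir merged
mzmerge overlap --table1 demo/setting1.tsv --table2 demo/setting2.tsv
mzmerge venn --tables a.tsv --tables b.tsv --tables c.tsv --out venn.json
mzmerge rare --table demo/setting1.tsv --design demo/design.tsv \
    --min-samps 1 --min-reps 100
mzmerge optimize --tables demo/setting1.tsv --tables demo/setting2.tsv \
    --design demo/design.tsv --w 30 --w 100
mzmerge annotate --table merged/merged.tsv --ppm 5 --out-dir annotation
mzmerge pipeline --config pipeline.yaml          # full workflow
```

`mzmerge pipeline` runs quality → filters (sample correlation < 0.7 and
median PID/CV ≥ 30 % by default) → merge → quality-on-merged → optional
annotation, and writes a JSON manifest with sha256 hashes of every
artifact. Runs with the same config are byte-identical (timestamps are
confined to `run.log`).

Exit codes: 0 success, 2 validation error, 3 I/O error, 4 computation
error.

A pipeline config is plain YAML:

```yaml
tables: [setting1.tsv, setting2.tsv]
design: design.tsv
samp_filt_thresh: 0.7     # null disables
feat_filt_thresh: 30.0    # null disables
ppm: 5.0
rt_tol: 30.0
annotate: true
```

## Python API

```python
import mzmerge as mm

t1 = mm.read_feature_table("setting1.tsv")
t2 = mm.read_feature_table("setting2.tsv")
design = mm.read_replicate_design("design.tsv")
merged, report = mm.merge_results([t1, t2], design, mm.MergeConfig(5.0, 30.0))
```

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the scoring-function targets from the
published per-candidate inputs and writes them as JSON. Note: two entries
of the published score table are internally inconsistent with their
printed inputs (a medianPID typo); the corresponding two acceptance-suite
cases fail by design rather than being patched.
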