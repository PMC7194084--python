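# svmeld

Integrate structural-variant (SV) predictions from multiple callers into a
single high-confidence call set, annotate the merged SVs against gene
models, and visualize their genome-wide distribution.

Supported caller outputs (native formats, no re-running of callers needed):

| caller      | input                           | SV types        | quality gates (defaults)            |
|-------------|---------------------------------|-----------------|-------------------------------------|
| BreakDancer | single tab-delimited file       | del, inv        | score >= 60, read pairs >= 3        |
| Pindel      | per-type files (`_D/_TD/_INV`)  | del, dup, inv   | split reads >= 3                    |
| CNVnator    | directory of per-chrom files    | del, dup        | (read-depth caller: size only)      |
| DELLY       | VCF                             | del, dup, inv   | PE + SR >= 3                        |
| SVseq2      | deletion summary text           | del             | split reads >= 3                    |
| Lumpy       | VCF or BEDPE                    | del, dup, inv   | SU >= 3                             |
| SoftSearch  | VCF                             | del, dup, inv   | split reads >= 3 AND pairs >= 3     |

All callers additionally pass a global size window (100 bp – 10 Mb on the
magnitude of the reported size, falling back to the coordinate span).
Overlapping predictions from a single caller are resolved in favor of the
best-supported record.

Filtered call sets are merged per SV type: two calls cluster when their
reciprocal coordinate overlap strictly exceeds the threshold (default 80%),
clusters are the single-linkage components of that relation, clusters
supported by fewer than 2 distinct callers are discarded, and the rest
become one SV each with start/end the rounded means of the member
coordinates and a `Caller1:Caller2` provenance string.

## CLI

```sh
# simulate a benchmark: truth SVs + all caller dialects + manifest
svmeld simulate --genome sizes.tsv --seed 1 --out-dir sim/

# read one caller (normalized per-type TSVs + filter log)
svmeld read --caller breakdancer --input sim/breakdancer.txt --out-prefix bd

# integrate two or more callers
svmeld merge --breakdancer sim/breakdancer.txt --pindel sim/pindel \
             --delly sim/delly.vcf --lumpy sim/lumpy.vcf \
             --out merged.tsv            # also: --format vcf|bed

# annotate against gene models (GFF3); one nine-column TSV per SV type
svmeld annotate --merged merged.tsv --gff genes.gff3 --out-prefix ann

# genome-wide windowed density plot (circular or linear) and a region view
svmeld plot-genome --merged merged.tsv --chrom-sizes sizes.tsv --out genome.svg
svmeld plot-region --merged merged.tsv --gff genes.gff3 \
                   --region chr1:100000-200000 --out region.svg

# score a merged set against a simulation manifest
svmeld evaluate --merged merged.tsv --manifest sim/manifest.tsv

# everything end to end
svmeld run-all --genome sizes.tsv --seed 1 --out-dir demo/
```

`--config cfg.yaml` accepts a YAML file mirroring the merge parameters
(`overlap_frac`, `min_methods`, `min_size`, `max_size`, and per-caller
thresholds under `callers:`); individual flags override it. Exit codes:
0 success, 2 configuration error, 1 data error.

`sizes.tsv` is a headerless two-column TSV of chromosome name and length.

## Library use

```python
from svmeld import MergeParams, methods_merge
from svmeld.readers import read_breakdancer, read_delly

params = MergeParams(overlap_frac=0.8, min_methods=2)
bd, bd_report = read_breakdancer("breakdancer.txt", params)
dl, dl_report = read_delly("delly.vcf", params)
merged = methods_merge([bd, dl], params)   # {"del": [...], "dup": [...], "inv": [...]}
```

Coordinates are 1-based inclusive throughout; readers convert from each
format's native convention on ingest.
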