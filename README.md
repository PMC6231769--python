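# regmap

Mapping and annotation of accessible chromatin elements from ATAC-seq and
capped nuclear RNA signal, with temporal clustering and TF-binding
enrichment.  A seeded synthetic-data module generates toy genomes, planted
regulatory elements and signal tracks with known ground truth, so the whole
pipeline runs and is tested without any downloads.

## What it does

1. **Peak calling** (`regmap.peaks`, `regmap.idr`) — candidate accessible
   sites are maximal concave regions (negative smoothed second derivative)
   of the cross-stage mean ATAC coverage; each candidate is scored per
   sample by the magnitude of the sample-specific smoothed second
   derivative at the summit; per-stage replicate score pairs go through a
   two-component Gaussian copula mixture (irreproducible discovery rate)
   and candidates reproducible in at least one stage (IDR <= 0.001) become
   sites with fixed `[summit-75, summit+76)` boundaries.  Multi-source peak
   sets merge successively, earlier sets winning overlaps.
2. **Transcription evidence** (`regmap.transcription`) — per site, strand
   and stage: the *jump* test (NB Wald test for more long-cap 5' ends in
   the downstream `[+75,+250)` window than the upstream `[-250,-75)`
   window; pass at lfc > 1.5 and BH padj < 0.1) and the deterministic
   *incr* rule (0 upstream reads, >= 1 downstream in both replicates, >= 3
   total); plus pooled short-cap initiation calls (signal reproducible in
   >= 2 replicates within 125 bp; mode = maximal reproducible position,
   else a best-guess 60 bp downstream).
3. **Classification** (`regmap.classify`) — promoter criteria (initiation +
   elongation, initiation mode upstream of the closest first exon or within
   the 5' UTR, no intervening non-first exon 5' end, and for distal sites
   continuous long-cap coverage across the outron), a low-confidence rescue
   pass for genes without promoters, non-coding-RNA proximity, unassigned
   promoters, per-stage label aggregation by priority ranking, strand
   combination into the final element type, overlap-based gene association
   and promoter directionality.
4. **Dynamics** (`regmap.dynamics`) — NB differential accessibility between
   all time-point pairs of a course (regulated: |fold| >= 2, padj < 0.01),
   relative accessibility `log2(c+1) - log2(mean(c)+1)`, and k-medoids
   (PAM: BUILD + seeded-restart SWAP descent) clustering of regulated
   promoter profiles; promoter-accessibility/expression correlation.
5. **Enrichment** (`regmap.enrichment`) — TF peak summits assigned to
   400 bp element-centered windows; HOT elements (>= 19 factors) masked;
   per factor x cluster odds ratio with two-sided Fisher exact test
   (kept: > 200 peaks on non-HOT elements, p < 0.01 somewhere, max OR > 2);
   tissue-bias calls (fold >= 3, padj < 0.01, pseudo-value 0.1); IUPAC
   consensus scanning and CpG density.
6. **Synthetic data** (`regmap.synthetic`) — deterministic toy genome with
   trans-spliced (outron) gene geometry, planted elements from four
   temporal archetypes, NB-noise signal tracks, TF peak sets with planted
   cluster enrichment and a gene x tissue expression table.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (end-to-end
planted-element recovery on a 2 Mb fixture, statistical calibration of the
jump test, exact oracles for the incr rule / PAM / Fisher p-values, IDR
parameter recovery, exact-arithmetic checks, byte-level determinism).  The
full suite takes a few minutes; the 2 Mb fixture runs once per session.

## CLI

```sh
regmap run-all --config config.yaml --out-dir out/   # simulate + full pipeline
regmap simulate --out-dir sim/                        # write synthetic dataset
regmap call-peaks --manifest manifest.yaml --out sites.tsv
regmap transcription-evidence --sites sites.tsv \
    --scap-manifest scap.yaml --lcap-manifest lcap.yaml --out evidence.tsv
regmap classify --sites sites.tsv --evidence evidence.tsv \
    --genome genome.tsv --lcap-cov-manifest cov.yaml --out annot.tsv
regmap dynamics --counts counts.tsv --course development --k 16 --out dyn.tsv
regmap enrich --clusters clusters.tsv --tf-bed peaks.bed --out enrich.tsv
```

`run-all` writes `sites.tsv`, `annot.tsv`, `dynamics.tsv`,
`enrichment.tsv` and `config.yaml`, each table headed by the config hash;
identical config + seed give byte-identical outputs.  Manifests are small
YAML files mapping stages/strands/replicates to bedGraph paths (see the
CLI `--help` of each subcommand).

## Conventions

All coordinates are 0-based half-open.  Strand-relative windows use the
offset `o = (pos - summit) * sign`; "downstream" means increasing
coordinate on `+` and decreasing on `-`.  The 11 canonical stages are
`wt_emb, wt_l1..wt_ya, glp1_d1..glp1_d13`; the development course is the
six `wt_*` stages and the ageing course the five `glp1_*` stages.
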