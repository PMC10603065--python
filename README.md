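# abselect

NGS-guided antibody lead selection for in-vitro display campaigns.

Display selections (phage panning followed by yeast sorting at decreasing
antigen concentration) produce polyclonal outputs whose diversity far exceeds
what colony picking can sample. Long-read amplicon sequencing of the scFv
pool captures that diversity — but inflated by PCR and sequencing errors, and
with no direct readout of which clones bind. `abselect` is a toolkit for
turning such sequencing output into ranked lead candidates:

* **Read processing** — Phred filtering (all bases >= Q40 by default) and
  demultiplexing by inline terminal 8-mer barcodes (<= 2 of 8 mismatches per
  end).
* **Annotation** — scaffold-anchored extraction of the six CDRs and
  framework regions from VL-linker-VH amplicons built on fixed scaffolds,
  condensed into unique full-length clones with per-population read counts.
* **AbScan clustering** — density clustering of a chosen region of interest
  (HCDR3, HCDR3+LCDR3, concatenated CDRs, or full length): sequences are
  reduced to an 11-letter physicochemical alphabet, pairwise Levenshtein
  distances feed OPTICS (min_pts = 2, max_eps = 10 x the k-distance elbow,
  xi = 0.01), clustering is iterated over a descending relative-abundance
  schedule seeded at 0.005%, and residual noise is rescued by pooled count
  (>= 2) or 90% same-length identity. Traditional clonotyping (same length,
  same scaffold call, >= 90% identity) and 100%-identity grouping are
  included as baselines.
* **Quantification** — per-population relative frequencies
  (`100 * count / total` after condensing identical ROIs), early-to-late fold
  enrichment, and correction factors for ROIs absent from one round (round
  minimum count divided by 2 when absent early, by 10 when absent late, so
  depletion is penalised more heavily).
* **Diversity modelling** — seeded subsampling accumulation curves and the
  nonlinear fit of `reads = C * D^k` predicting the read depth required for a
  target diversity `D`.
* **Ranking** — per-cluster representative selection, liability-reduced
  alternatives, epitope-bin concordance of clusters, the 0.005% abundance
  binder heuristic, and an XGBoost binder classifier / affinity regressor on
  NGS-derived features with bootstrap evaluation.
* **Simulation** — a seeded campaign generator (Zipf clonal abundance,
  per-base substitution errors, latent affinities with configurable coupling
  to late-round enrichment) providing ground truth for every stage.

The fit-shaped cores follow scikit-learn conventions (`AbScanClusterer`,
`TraditionalClonotyper`, `IdentityClusterer`, `PowerLawModel` expose
`fit`/`fit_predict`/`predict` and fitted `*_` attributes) and compose with
sklearn tooling; everything is also reachable through plain functions and the
`abselect` command line.

## Worked example

Simulate a small campaign with known ground truth, run the pipeline, and
recover the clonal families:

```python
from abselect import CampaignConfig, simulate_campaign, run_pipeline
from abselect.simulate import EARLY, LATE, clustering_ari
from abselect.quantify import population_roi_stats

cfg = CampaignConfig(seed=42, n_families=20, reads_per_population=5000)
campaign = simulate_campaign(cfg)

reads = campaign.reads[EARLY] + campaign.reads[LATE]
result = run_pipeline(reads, campaign.barcodes, campaign.scaffolds, roi="HCDR3")

print(f"reads in          : {len(reads)}")
print(f"quality rejected  : {result.n_quality_rejected}")
print(f"unique clones     : {len(result.clones)}")
print(f"AbScan clusters   : {result.clusterer.n_clusters_}  (true families: {cfg.n_families})")
print(f"ARI vs truth      : {clustering_ari(campaign.truth, result.read_to_cluster()):.4f}")

stats = population_roi_stats(result.clones, "HCDR3", EARLY, LATE)
top = stats.sort_values("rel_freq_late", ascending=False).head(3)
print(top.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
```

prints

```
reads in          : 10000
quality rejected  : 182
unique clones     : 3383
AbScan clusters   : 20  (true families: 20)
ARI vs truth      : 1.0000
    roi_value  rel_freq_early  rel_freq_late corrected  enrichment
   VQKFYHLIFK          45.466         45.917      none       1.010
VHWTHLMSQVIMK          16.575         15.868      none       0.957
 EEHVAGCNGSNS           8.182          8.588      none       1.050
```

Read it as: 0.1%/nt sequencing errors inflate 10,000 reads into 3,383
distinct full-length sequences, yet AbScan collapses the HCDR3 space back to
exactly the 20 true families (adjusted Rand index 1.0 against ground truth).
The enrichment table shows each dominant HCDR3's share of the early (10 nM)
and late (1 nM) sort rounds and their fold ratio — with the simulator's
default `beta = 0` no family gains a late-round advantage, so folds hover
around 1.

The same flow is available from the shell:

```bash
abselect simulate --seed 42 --outdir sim/
abselect filter sim/10nM.fastq --min-phred 40 --out filtered.fastq
abselect demux filtered.fastq --barcodes sim/barcodes.tsv --outdir pops/
abselect annotate pops/10nM.fastq pops/1nM.fastq --scaffolds sim/scaffolds.json --out clones.tsv
abselect cluster clones.tsv --roi HCDR3 --method abscan --out clusters.tsv
abselect quantify clones.tsv --early 10nM --late 1nM --out stats.tsv
abselect diversity clones.tsv --population 1nM --out curve.tsv
```

`docs/methods.md` documents the models, conventions, default parameters and
the simulator's idealisations in detail.

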