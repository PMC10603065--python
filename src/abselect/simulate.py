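"""Synthetic selection-campaign generator with known ground truth.

Emulates the statistical structure of a two-round display campaign sorted at
a 10 nM (early) and a 1 nM (late) antigen concentration: clonal families with
power-law (Zipf) abundance on a small set of fixed scaffolds, a handful of
true sequence variants per family, per-base substitution errors that inflate
the raw sequence diversity, inline 8-mer barcodes, a latent per-family
affinity and a configurable coupling (beta) between affinity and late-round
sampling weight.  beta defaults to 0 -- abundance carries no affinity signal
unless a test explicitly asks for it.

Everything is drawn from one seeded generator, so outputs are byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

import edlib

from .annotation import AA20, CDR_ORDER, ScaffoldRef, write_scaffolds
from .io_ngs import BarcodeSpec, SeqRead, reverse_complement, write_barcode_table, write_fastq

EARLY, LATE = "10nM", "1nM"

# one codon per amino acid keeps reverse translation deterministic per draw
_CODONS = {
    "A": ("GCT", "GCC", "GCA"), "C": ("TGT", "TGC"), "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"), "F": ("TTT", "TTC"), "G": ("GGT", "GGC", "GGA"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC"), "K": ("AAA", "AAG"),
    "L": ("CTT", "CTG", "CTC"), "M": ("ATG",), "N": ("AAT", "AAC"),
    "P": ("CCT", "CCA"), "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "AGA"),
    "S": ("TCT", "AGC"), "T": ("ACT", "ACC"), "V": ("GTT", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}
_BASES = "ACGT"

_CDR_LENGTH_RANGES = {
    "LCDR1": (6, 12), "LCDR2": (3, 7), "LCDR3": (8, 11),
    "HCDR1": (7, 9), "HCDR2": (7, 10), "HCDR3": (10, 16),
}
_FR_LENGTHS_VL = (23, 15, 32, 10)
_FR_LENGTHS_VH = (25, 14, 32, 11)
_LINKER = "GGGGSGGGGSGGGGS"

_MIN_INTERFAMILY_HCDR3_DIST = 5


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions of one simulated campaign."""

    seed: int
    n_scaffolds: int = 4
    n_families: int = 50
    zipf_exponent: float = 1.5
    intra_family_edits: int = 2
    max_clones_per_family: int = 4
    nt_error_rate: float = 0.001
    reads_per_population: int = 50_000
    affinity_mean_log10_kd: float = -8.5
    affinity_sd_log10_kd: float = 2.0
    beta: float = 0.0
    frac_low_quality: float = 0.02
    barcode_error_rate: float = 0.001
    n_epitope_bins: int = 5
    n_characterized: int = 200
    characterize_per_family: int = 1  # 0 = no per-family cap (redundant clones allowed)
    kd_clone_jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("nt_error_rate", "frac_low_quality", "barcode_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_families < 2:
            raise ValueError("need at least 2 families")


@dataclass
class GroundTruth:
    """Complete truth mapping for every emitted read."""

    families: pd.DataFrame  # family_id, scaffold, log10_kd, epitope_bin, weights + prototype CDRs
    clones: pd.DataFrame    # clone_uid, family_id, aa_full, nt_seq, weight_in_family
    read_family: dict[str, int]
    read_clone: dict[str, str]


@dataclass
class Campaign:
    config: CampaignConfig
    scaffolds: list[ScaffoldRef]
    barcodes: list[BarcodeSpec]
    reads: dict[str, list[SeqRead]]  # population -> raw barcoded reads
    truth: GroundTruth
    characterization: pd.DataFrame  # clone_uid, sequence_aa, target, kd_molar, epitope_bin


def _random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), length))


def _random_nt_barcode(rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, 8))


def _reverse_translate(rng: np.random.Generator, aa: str) -> str:
    return "".join(
        _CODONS[res][rng.integers(0, len(_CODONS[res]))] for res in aa
    )


def _mutate_nt(rng: np.random.Generator, seq: str, n_errors: int) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_errors, replace=False)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _make_scaffolds(rng: np.random.Generator, n: int) -> list[ScaffoldRef]:
    return [
        ScaffoldRef(
            name=f"IGHV{i + 1}-SIM::IGKV{i + 1}-SIM",
            vl_frameworks=tuple(_random_aa(rng, L) for L in _FR_LENGTHS_VL),
            vh_frameworks=tuple(_random_aa(rng, L) for L in _FR_LENGTHS_VH),
            linker=_LINKER,
        )
        for i in range(n)
    ]


def _make_families(rng: np.random.Generator, cfg: CampaignConfig,
                   scaffolds: list[ScaffoldRef]) -> list[dict]:
    families = []
    hcdr3s: list[str] = []
    for fid in range(cfg.n_families):
        cdrs = {r: _random_aa(rng, int(rng.integers(lo, hi + 1)))
                for r, (lo, hi) in _CDR_LENGTH_RANGES.items()}
        # keep families separable in HCDR3 space: resample close prototypes
        for _ in range(200):
            if all(edlib.align(cdrs["HCDR3"], h)["editDistance"]
                   >= _MIN_INTERFAMILY_HCDR3_DIST for h in hcdr3s):
                break
            lo, hi = _CDR_LENGTH_RANGES["HCDR3"]
            cdrs["HCDR3"] = _random_aa(rng, int(rng.integers(lo, hi + 1)))
        hcdr3s.append(cdrs["HCDR3"])
        families.append({
            "family_id": fid,
            "scaffold": scaffolds[rng.integers(0, len(scaffolds))],
            "cdrs": cdrs,
            "log10_kd": float(rng.normal(cfg.affinity_mean_log10_kd,
                                         cfg.affinity_sd_log10_kd)),
            "epitope_bin": f"bin{int(rng.integers(0, cfg.n_epitope_bins))}",
        })
    return families


def _make_clones(rng: np.random.Generator, cfg: CampaignConfig,
                 families: list[dict]) -> list[dict]:
    clones = []
    for fam in families:
        n_clones = int(rng.integers(1, cfg.max_clones_per_family + 1))
        weights = rng.dirichlet(np.ones(n_clones))
        seen = set()
        for ci in range(n_clones):
            cdrs = {r: v for r, v in fam["cdrs"].items()}
            if ci > 0:
                for _ in range(int(rng.integers(1, cfg.intra_family_edits + 1))):
                    region = CDR_ORDER[rng.integers(0, len(CDR_ORDER))]
                    s = list(cdrs[region])
                    pos = int(rng.integers(0, len(s)))
                    s[pos] = AA20[rng.integers(0, len(AA20))]
                    cdrs[region] = "".join(s)
            aa_full = fam["scaffold"].assemble(cdrs)
            if aa_full in seen:
                continue
            seen.add(aa_full)
            clones.append({
                "clone_uid": f"f{fam['family_id']:03d}c{ci}",
                "family_id": fam["family_id"],
                "cdrs": cdrs,
                "aa_full": aa_full,
                "nt_seq": _reverse_translate(rng, aa_full),
                "weight_in_family": float(weights[ci]),
                "log10_kd": fam["log10_kd"]
                + float(rng.normal(0.0, cfg.kd_clone_jitter_sd)),
                "epitope_bin": fam["epitope_bin"],
            })
    return clones


def simulate_campaign(cfg: CampaignConfig, outdir: str | Path | None = None) -> Campaign:
    """Generate one campaign; optionally write its files under ``outdir``.

    Early-population families are drawn with Zipf weights; late-population
    weights are the early weights tilted by exp(-beta * log10 KD) and
    renormalised, so beta > 0 makes high-affinity (low KD) families enrich.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffolds = _make_scaffolds(rng, cfg.n_scaffolds)
    families = _make_families(rng, cfg, scaffolds)
    clones = _make_clones(rng, cfg, families)

    ranks = rng.permutation(cfg.n_families) + 1
    early_w = ranks ** (-cfg.zipf_exponent)
    early_w /= early_w.sum()
    kd = np.array([f["log10_kd"] for f in families])
    late_w = early_w * np.exp(-cfg.beta * kd)
    late_w /= late_w.sum()
    fam_weights = {EARLY: early_w, LATE: late_w}

    barcodes = [
        BarcodeSpec(pop, _random_nt_barcode(rng), _random_nt_barcode(rng))
        for pop in (EARLY, LATE)
    ]
    bc_of = {b.population: b for b in barcodes}

    clone_w = np.array([
        c["weight_in_family"] for c in clones
    ])
    clone_fam = np.array([c["family_id"] for c in clones])

    reads: dict[str, list[SeqRead]] = {}
    read_family: dict[str, int] = {}
    read_clone: dict[str, str] = {}
    for pop in (EARLY, LATE):
        weights = clone_w * fam_weights[pop][clone_fam]
        weights /= weights.sum()
        counts = rng.multinomial(cfg.reads_per_population, weights)
        bc = bc_of[pop]
        tail = reverse_complement(bc.bc3)
        pop_reads: list[SeqRead] = []
        serial = 0
        for clone, count in zip(clones, counts):
            if count == 0:
                continue
            insert = clone["nt_seq"]
            L = len(insert)
            n_ins_err = rng.binomial(L, cfg.nt_error_rate, size=count)
            n_bc_err = rng.binomial(16, cfg.barcode_error_rate, size=count)
            low_q = rng.random(count) < cfg.frac_low_quality
            clean = bc.bc5 + insert + tail
            clean_phred = np.full(len(clean), 40, dtype=np.uint8)
            for i in range(count):
                seq = clean
                if n_ins_err[i]:
                    seq = bc.bc5 + _mutate_nt(rng, insert, int(n_ins_err[i])) + tail
                if n_bc_err[i]:
                    head_tail = _mutate_nt(rng, bc.bc5 + tail, int(n_bc_err[i]))
                    seq = head_tail[:8] + seq[8:-8] + head_tail[8:]
                phred = clean_phred
                if low_q[i]:
                    phred = clean_phred.copy()
                    phred[rng.integers(0, len(phred))] = rng.integers(2, 40)
                rid = f"{pop}_{serial:06d}"
                serial += 1
                pop_reads.append(SeqRead(rid, seq, phred))
                read_family[rid] = int(clone["family_id"])
                read_clone[rid] = clone["clone_uid"]
        order = rng.permutation(len(pop_reads))
        reads[pop] = [pop_reads[i] for i in order]

    fam_df = pd.DataFrame([
        {
            "family_id": f["family_id"],
            "scaffold": f["scaffold"].name,
            "log10_kd": f["log10_kd"],
            "epitope_bin": f["epitope_bin"],
            "early_weight": float(early_w[f["family_id"]]),
            "late_weight": float(late_w[f["family_id"]]),
            **{r.lower(): f["cdrs"][r] for r in CDR_ORDER},
        }
        for f in families
    ])
    clone_df = pd.DataFrame([
        {k: c[k] for k in
         ("clone_uid", "family_id", "aa_full", "nt_seq", "weight_in_family",
          "log10_kd", "epitope_bin")}
        for c in clones
    ])
    truth = GroundTruth(fam_df, clone_df, read_family, read_clone)

    # characterise the most abundant clones (pooled expected share); the
    # default keeps one non-redundant representative per family, mirroring a
    # top-representative-per-cluster synthesis strategy
    pooled = clone_w * (fam_weights[EARLY][clone_fam] + fam_weights[LATE][clone_fam])
    ranked = sorted(range(len(clones)), key=lambda i: (-pooled[i], clones[i]["clone_uid"]))
    top: list[int] = []
    per_family: dict[int, int] = {}
    for i in ranked:
        fam = clones[i]["family_id"]
        if cfg.characterize_per_family and per_family.get(fam, 0) >= cfg.characterize_per_family:
            continue
        per_family[fam] = per_family.get(fam, 0) + 1
        top.append(i)
        if len(top) >= cfg.n_characterized:
            break
    characterization = pd.DataFrame([
        {
            "clone_uid": clones[i]["clone_uid"],
            "sequence_aa": clones[i]["aa_full"],
            "target": "antigen",
            "kd_molar": float(10.0 ** clones[i]["log10_kd"]),
            "epitope_bin": clones[i]["epitope_bin"],
        }
        for i in top
    ])

    campaign = Campaign(cfg, scaffolds, barcodes, reads, truth, characterization)
    if outdir is not None:
        _write_campaign(campaign, Path(outdir))
    return campaign


def _write_campaign(campaign: Campaign, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for pop, pop_reads in campaign.reads.items():
        write_fastq(pop_reads, outdir / f"{pop}.fastq")
    write_barcode_table(campaign.barcodes, outdir / "barcodes.tsv")
    write_scaffolds(campaign.scaffolds, outdir / "scaffolds.json")
    campaign.truth.families.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)
    campaign.truth.clones.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(rid, fam, campaign.truth.read_clone[rid])
         for rid, fam in campaign.truth.read_family.items()],
        columns=["read_id", "family_id", "clone_uid"],
    ).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    campaign.characterization.to_csv(outdir / "characterization.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ground-truth recovery metrics
# ---------------------------------------------------------------------------

def clustering_ari(truth: GroundTruth, read_to_cluster: Mapping[str, int]) -> float:
    """Adjusted Rand index between predicted clusters and true families over
    the reads present in ``read_to_cluster``.  Unknown read ids are an error."""
    unknown = [r for r in read_to_cluster if r not in truth.read_family]
    if unknown:
        raise ValueError(f"read ids not in ground truth: {unknown[:3]}...")
    rids = list(read_to_cluster)
    return float(adjusted_rand_score(
        [truth.read_family[r] for r in rids],
        [read_to_cluster[r] for r in rids],
    ))


def family_frequency_error(
    truth: GroundTruth,
    observed: Mapping[int, float],
    population: str = EARLY,
) -> float:
    """Total variation distance between observed family read fractions and
    the configured weights for one population."""
    col = "early_weight" if population == EARLY else "late_weight"
    expected = truth.families.set_index("family_id")[col]
    obs = np.array([observed.get(fid, 0.0) for fid in expected.index])
    obs_sum = obs.sum()
    if obs_sum > 0:
        obs = obs / obs_sum
    return float(0.5 * np.abs(obs - expected.to_numpy()).sum())


def enrichment_affinity_correlation(
    truth: GroundTruth,
    enrichment_by_aa: Mapping[str, float],
) -> float:
    """Spearman correlation between clone fold enrichment and affinity
    strength (-log10 KD); keys are full-length amino-acid sequences."""
    from scipy.stats import spearmanr

    merged = truth.clones[truth.clones["aa_full"].isin(enrichment_by_aa)]
    if len(merged) < 3:
        raise ValueError("too few clones with observed enrichment")
    enr = [enrichment_by_aa[aa] for aa in merged["aa_full"]]
    strength = -merged["log10_kd"].to_numpy()
    return float(spearmanr(enr, strength).statistic)


def truth_metrics(
    truth: GroundTruth,
    read_to_cluster: Mapping[str, int] | None = None,
    observed_family_freq: Mapping[int, float] | None = None,
    enrichment_by_aa: Mapping[str, float] | None = None,
    population: str = EARLY,
) -> dict:
    """Recovery report for a pipeline run on simulated data (deterministic
    for a fixed seed).  Sections are computed for whichever inputs are given."""
    report: dict = {}
    if read_to_cluster is not None:
        report["ari"] = clustering_ari(truth, read_to_cluster)
    if observed_family_freq is not None:
        report["family_freq_tvd"] = family_frequency_error(
            truth, observed_family_freq, population)
    if enrichment_by_aa is not None:
        report["enrichment_affinity_spearman"] = enrichment_affinity_correlation(
            truth, enrichment_by_aa)
    return report
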