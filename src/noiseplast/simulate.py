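"""Synthetic data generator with planted effect structure.

Emulates the four inputs of the analysis — gene table, regulator-mutant
compendium, transcript map, nucleosome occupancy track — on a synthetic
genome, planting the coupling structure the pipeline is built to
detect:

* chromatin regulation effect (CRE) rank-correlated with plasticity
  (Gaussian copula, so the Spearman target is exact in expectation);
* noise driven by translational efficiency in low-plasticity (LP) genes
  and by proximal occupancy x TATA x chromatin regulation in
  high-plasticity (HP) genes;
* translational efficiency declining with log ORF length;
* regulator mutants specific to LNHP (activators) or HNHP (repressors),
  general mutants that decrease expression genome-wide but hit LNHP
  harder, and a dual-action majority of histone mutants that decrease
  LNHP while increasing HNHP expression;
* intergenic distances with a configurable median, rank-correlated with
  plasticity, with small-gap divergent pairs flagged as bipromoters and
  a planted noise reduction in HP bipromoter genes;
* dubious/pseudogene/overlapping decoy transcripts to exercise the
  neighborhood filters.

Every latent variable and coefficient is exported in a truth record so
recovery tests can compare pipeline estimates against what was planted.
All outputs are byte-deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Compendium, OccupancyTrack, write_compendium, write_gene_table, \
    write_occupancy, write_transcripts
from .occupancy import promoter_windows

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_genes",
           "generate_genome", "generate_compendium", "generate_dataset"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Planted correlation targets default to the magnitudes the analysis
    is designed to detect (CRE-plasticity rho 0.57, LP noise-TE rho
    0.22, distance-plasticity rho 0.19, LP/HP TATA frequencies 5%/35%,
    median intergenic distance 204 bp).
    """

    n_genes: int = 2000
    seed: int = 1

    # compendium composition
    n_chromatin: int = 120
    n_general: int = 10
    n_histone: int = 40

    # planted correlation targets (Spearman)
    rho_cre_plasticity: float = 0.57
    rho_noise_te_lp: float = 0.22
    distance_plasticity_rho: float = 0.19

    # promoter structure
    tata_fraction_hp: float = 0.35
    tata_fraction_lp: float = 0.05
    tata_fraction_mid: float = 0.22
    occ_proximal_mean: float = -1.5
    occ_distal_mean: float = -1.2
    occ_sd: float = 0.5
    occ_tata_hp_boost: float = 0.7
    occ_bin_sd: float = 0.08

    # noise model
    noise_mean: float = 0.08
    noise_sd: float = 0.045
    noise_cre_interaction: float = 0.8
    bipromoter_noise_reduction: float = 0.5    # in SDs of noise, HP genes

    # regulator effects (units of per-entry SD before normalization)
    activator_effect_lnhp: float = 1.2
    repressor_effect_hnhp: float = 1.2
    general_effect: float = 0.8
    general_effect_lnhp: float = 1.6
    chromatin_specific_fraction: float = 0.4
    histone_dual_fraction: float = 0.81
    compendium_missing_fraction: float = 0.05

    # genome layout
    n_chromosomes: int = 16
    chromosome_length: int = 400_000
    median_intergenic: float = 204.0
    gap_log_sd: float = 0.8
    min_gap: int = 20
    noncoding_fraction: float = 0.15
    decoy_fraction: float = 0.05
    bipromoter_base: float = 0.9
    bipromoter_scale: float = 300.0

    # gene features
    orf_log_mean: float = 7.25
    orf_log_sd: float = 0.45
    essential_rate: float = 0.19
    complex_rate_essential: float = 0.5
    complex_rate_other: float = 0.2
    haplo_rate: float = 0.03
    essential_length_factor: float = 1.12
    te_missing_fraction: float = 0.1

    # class boundaries used for planting (must match the pipeline's)
    p_low: float = 25.0
    p_high: float = 75.0

    def __post_init__(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100 for recovery tests")
        for name in ("rho_cre_plasticity", "rho_noise_te_lp",
                     "distance_plasticity_rho"):
            if abs(getattr(self, name)) >= 0.99:
                raise ValueError(f"infeasible correlation target for {name}")
        for name in ("tata_fraction_hp", "tata_fraction_lp",
                     "tata_fraction_mid", "noncoding_fraction",
                     "decoy_fraction", "histone_dual_fraction",
                     "chromatin_specific_fraction", "te_missing_fraction",
                     "compendium_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def n_mutants(self) -> int:
        return self.n_chromatin + self.n_general + self.n_histone


def _spearman_to_pearson(rho: float) -> float:
    # bivariate-normal latent correlation giving Spearman rho on margins
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _blom(values: np.ndarray) -> np.ndarray:
    """Normal scores (Blom) of the ranks of ``values``."""
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def _folded_mean(mu: float, sd: float = 1.0) -> float:
    """E|N(mu, sd^2)|."""
    return (mu * (1 - 2 * sps.norm.cdf(-mu / sd))
            + 2 * sd * sps.norm.pdf(mu / sd))


# ---------------------------------------------------------------------------
# gene table

def generate_genes(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Gene-level table plus the truth record of every latent variable."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # plasticity: right-skewed marginal over a standard-normal latent
    z_plast = rng.standard_normal(n)
    plasticity = np.exp(1.0 * z_plast) * 0.04     # sum-of-squares-like scale

    # CRE latent via Gaussian copula against the plasticity latent
    r = _spearman_to_pearson(config.rho_cre_plasticity)
    z_cre = r * z_plast + math.sqrt(1 - r * r) * rng.standard_normal(n)
    cre_latent = np.exp(0.35 * z_cre)

    # provisional plasticity margins for planting (same quartile rule the
    # pipeline applies)
    p_lo = np.percentile(plasticity, config.p_low)
    p_hi = np.percentile(plasticity, config.p_high)
    lp = plasticity < p_lo
    hp = plasticity > p_hi

    tata_p = np.full(n, config.tata_fraction_mid)
    tata_p[lp] = config.tata_fraction_lp
    tata_p[hp] = config.tata_fraction_hp
    tata = rng.random(n) < tata_p

    essential = rng.random(n) < config.essential_rate
    complex_p = np.where(essential, config.complex_rate_essential,
                         config.complex_rate_other)
    complex_member = rng.random(n) < complex_p
    haplo = (rng.random(n) < config.haplo_rate) & (essential | complex_member)

    length_factor = np.where(essential, config.essential_length_factor, 1.0)
    orf_length = np.maximum(
        100, np.round(np.exp(rng.normal(config.orf_log_mean,
                                        config.orf_log_sd, n)) * length_factor)
    ).astype(int)

    fop = rng.beta(2.0, 4.0, n)

    # translational efficiency: declines with log ORF length, rises with
    # codon bias; residual keeps the length correlation near -0.58
    log_l = np.log(orf_length)
    te_raw = -(log_l - log_l.mean()) \
        + 0.25 * _standardize(fop) \
        + math.sqrt(0.337) * rng.standard_normal(n)
    te = 4.35 + 1.72 * _standardize(te_raw)
    ribosome_density = 0.53 + 0.31 * _standardize(
        0.8 * _standardize(te_raw) + 0.6 * rng.standard_normal(n))

    # promoter occupancy (log2): TATA+HP promoters sit higher (shallower NDR)
    z_occ = rng.standard_normal(n)
    prox_occ = config.occ_proximal_mean + config.occ_sd * z_occ \
        + config.occ_tata_hp_boost * (tata & hp)
    dist_occ = config.occ_distal_mean \
        + 0.4 * (0.5 * z_occ + math.sqrt(0.75) * rng.standard_normal(n))

    # noise regimes
    z_noise = rng.standard_normal(n)          # medium-plasticity baseline
    # LP: copula against TE within the LP subset
    r22 = _spearman_to_pearson(config.rho_noise_te_lp)
    z_te_lp = _blom(te_raw[lp])
    z_noise[lp] = r22 * z_te_lp \
        + math.sqrt(1 - r22 * r22) * rng.standard_normal(int(lp.sum()))
    # HP: occupancy plus a TATA x occupancy x CRE interaction
    z_cre_b = _blom(cre_latent)
    hp_drive = 0.35 * z_occ[hp] \
        + config.noise_cre_interaction * tata[hp] \
        * np.clip(z_occ[hp], 0, None) * z_cre_b[hp] \
        + 0.6 * rng.standard_normal(int(hp.sum()))
    z_noise[hp] = _standardize(hp_drive)
    noise_dm = config.noise_mean + config.noise_sd * z_noise

    divergence = 0.19 + 0.08 * _standardize(
        0.4 * z_noise + 0.3 * z_plast + 0.8 * rng.standard_normal(n))
    mrna_level = np.exp(rng.normal(0.9, 0.8, n))
    h2az = np.where(lp, 0.41, 0.12) + 0.3 * rng.standard_normal(n)
    initiation = np.where(rng.random(n) < np.where(hp & tata, 0.7, 0.25),
                          "SAGA", "TFIID")

    te_obs = te.copy()
    ribo_obs = ribosome_density.copy()
    missing = rng.random(n) < config.te_missing_fraction
    te_obs[missing] = np.nan
    ribo_obs[missing] = np.nan

    gene_ids = [f"SYN{g:04d}" for g in range(n)]
    table = pd.DataFrame({
        "gene_id": gene_ids,
        "noise_dm": noise_dm,
        "plasticity": plasticity,
        "divergence": divergence,
        "mrna_level": mrna_level,
        "tata": tata,
        "initiation_class": initiation,
        "orf_length": orf_length,
        "fop": fop,
        "translational_efficiency": te_obs,
        "ribosome_density": ribo_obs,
        "essential": essential,
        "complex_member": complex_member,
        "haploinsufficient": haplo,
        "h2az": h2az,
    })
    truth = {
        "z_plast": z_plast, "cre_latent": cre_latent, "z_noise": z_noise,
        "te_raw": te_raw, "prox_occ": prox_occ, "dist_occ": dist_occ,
        "lp_mask": lp, "hp_mask": hp,
        "rho_cre_plasticity": config.rho_cre_plasticity,
        "rho_noise_te_lp": config.rho_noise_te_lp,
    }
    return table, truth


# ---------------------------------------------------------------------------
# genome: transcripts + occupancy

def generate_genome(config: SyntheticConfig, gene_table: pd.DataFrame,
                    truth_genes: dict | None = None
                    ) -> tuple[pd.DataFrame, OccupancyTrack, dict]:
    """Place transcripts on synthetic chromosomes and build the track.

    Intergenic gaps are sampled log-normally (median =
    ``median_intergenic``) from a copula against plasticity; the gap
    before each transcript follows the gene(s) that claim it as their
    upstream region (the right gene when on +, the left gene when on -,
    averaged when both claim).  Divergent-facing pairs with small gaps
    are flagged bipromoter; decoy transcripts exercise the filters.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(gene_table)

    # per-gene upstream-gap latent, copula-coupled to plasticity ranks
    r19 = _spearman_to_pearson(config.distance_plasticity_rho)
    z_p = _blom(gene_table["plasticity"].to_numpy())
    z_gap = r19 * z_p + math.sqrt(1 - r19 * r19) * rng.standard_normal(n)

    order = rng.permutation(n)
    per_chrom = int(math.ceil(n / config.n_chromosomes))
    gene_ids = gene_table["gene_id"].to_numpy()
    orf_len = gene_table["orf_length"].to_numpy()
    if truth_genes is not None:
        prox_occ = truth_genes["prox_occ"]
        dist_occ = truth_genes["dist_occ"]
    else:
        prox_occ = np.full(n, config.occ_proximal_mean)
        dist_occ = np.full(n, config.occ_distal_mean)

    records = []          # transcript dicts
    noncod_counter = 0
    decoy_counter = 0
    bip_pairs = []

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        members = order[c * per_chrom:(c + 1) * per_chrom]
        # interleave noncoding transcripts
        items = []        # (kind, gene_index or None, strand, length, z_gap)
        for gi in members:
            if rng.random() < config.noncoding_fraction:
                noncod_counter += 1
                kind = "CUT" if rng.random() < 0.5 else "SUT"
                items.append((kind, None,
                              "+" if rng.random() < 0.5 else "-",
                              max(80, int(np.exp(rng.normal(5.8, 0.4)))),
                              rng.standard_normal()))
            items.append(("ORF_T", int(gi),
                          "+" if rng.random() < 0.5 else "-",
                          int(orf_len[gi]), float(z_gap[gi])))
        pos = 1000
        chrom_records = []
        for i, (kind, gi, strand, length, zg) in enumerate(items):
            claims = []
            if strand == "+":
                claims.append(zg)
            if i > 0 and items[i - 1][2] == "-":
                claims.append(items[i - 1][4])
            z = float(np.mean(claims)) if claims else rng.standard_normal()
            gap = max(config.min_gap,
                      int(round(config.median_intergenic
                                * math.exp(config.gap_log_sd * z))))
            start = pos + gap
            end = start + length - 1
            if end > config.chromosome_length:
                raise ValueError(
                    f"chromosome capacity exceeded on {chrom}; "
                    "increase chromosome_length")
            if kind == "ORF_T":
                tid = gene_ids[gi]
            else:
                tid = f"NC{noncod_counter:04d}-{len(chrom_records)}"
            rec = {"transcript_id": tid, "kind": kind, "chrom": chrom,
                   "strand": strand,
                   "tss": start if strand == "+" else end,
                   "tes": end if strand == "+" else start,
                   "status": "verified", "bipromoter": False,
                   "gene_index": gi, "gap": gap, "lo": start, "hi": end}
            # bipromoter: divergent-facing junction (left -, right +)
            if (i > 0 and strand == "+" and items[i - 1][2] == "-"
                    and rng.random() < config.bipromoter_base
                    * math.exp(-gap / config.bipromoter_scale)):
                rec["bipromoter"] = True
                chrom_records[-1]["bipromoter"] = True
                bip_pairs.append((chrom_records[-1]["transcript_id"], tid))
            chrom_records.append(rec)
            pos = end
        records.extend(chrom_records)

    ts = pd.DataFrame(records)

    # decoy insertion: dubious/pseudogene/overlapping transcripts directly
    # upstream of a random subset of + strand genes whose left neighbor is
    # also + (so only the focal gene's annotation is perturbed)
    idx_ts = ts.reset_index()
    eligible = []
    for i in range(1, len(ts)):
        row, prev = ts.iloc[i], ts.iloc[i - 1]
        if (row["kind"] == "ORF_T" and row["strand"] == "+"
                and prev["chrom"] == row["chrom"] and prev["strand"] == "+"
                and row["gap"] >= 120):
            eligible.append(i)
    n_decoy = int(round(config.decoy_fraction * n))
    chosen = rng.choice(len(eligible), size=min(n_decoy, len(eligible)),
                        replace=False) if eligible else []
    decoys = []
    truth_decoys = []
    for j in sorted(chosen):
        i = eligible[j]
        row = ts.iloc[i]
        u = rng.random()
        decoy_counter += 1
        if u < 0.7:
            status = "dubious" if u < 0.4 else "pseudogene"
            hi = int(row["lo"]) - 15
            lo = max(int(row["lo"]) - int(row["gap"]) + 10, hi - 60)
            reason = status + "_partner"
        else:
            status = "unknown"                # not a focal gene itself
            lo = int(row["lo"]) - 60
            hi = int(row["lo"]) + 20          # reaches into the focal span
            reason = "overlap"
        strand = "+" if rng.random() < 0.5 else "-"
        decoys.append({"transcript_id": f"DECOY{decoy_counter:04d}",
                       "kind": "ORF_T", "chrom": row["chrom"],
                       "strand": strand,
                       "tss": lo if strand == "+" else hi,
                       "tes": hi if strand == "+" else lo,
                       "status": status, "bipromoter": False,
                       "gene_index": -1, "gap": -1,
                       "lo": lo, "hi": hi})
        truth_decoys.append({"gene_id": row["transcript_id"],
                             "decoy": f"DECOY{decoy_counter:04d}",
                             "reason": reason})
    if decoys:
        ts = pd.concat([ts, pd.DataFrame(decoys)], ignore_index=True)
    ts = ts.sort_values(["chrom", "lo"], kind="stable").reset_index(drop=True)

    # occupancy track: 10 bp bins, background plus promoter windows set to
    # each gene's planted proximal/distal level
    bin_w = 10
    chroms = {}
    for chrom, sub in ts.groupby("chrom", sort=False):
        span_hi = int(sub["hi"].max()) + 500
        n_bins = span_hi // bin_w + 1
        vals = -0.3 + config.occ_bin_sd * rng.standard_normal(n_bins)
        for t in sub.itertuples(index=False):
            if t.kind != "ORF_T" or pd.isna(t.gene_index) or t.gene_index < 0:
                continue
            gi = int(t.gene_index)
            prox_iv, dist_iv = promoter_windows(t.strand, int(t.tss))
            for iv, level in ((prox_iv, prox_occ[gi]), (dist_iv, dist_occ[gi])):
                if iv is None:
                    continue
                b0, b1 = (iv[0] - 1) // bin_w, (iv[1] - 1) // bin_w
                m = b1 - b0 + 1
                vals[b0:b1 + 1] = level + config.occ_bin_sd \
                    * rng.standard_normal(m)
        starts = np.arange(n_bins) * bin_w + 1
        chroms[chrom] = pd.DataFrame({
            "start": starts, "end": starts + bin_w - 1, "value": vals})
    track = OccupancyTrack(chroms)

    truth = {"z_gap": z_gap, "bipromoter_pairs": bip_pairs,
             "decoys": pd.DataFrame(truth_decoys),
             "n_noncoding": noncod_counter}
    ts_out = ts[["transcript_id", "kind", "chrom", "strand", "tss", "tes",
                 "status", "bipromoter"]].copy()
    return ts_out, track, truth


# ---------------------------------------------------------------------------
# compendium

def generate_compendium(config: SyntheticConfig, gene_classes: pd.Series,
                        cre_latent: np.ndarray) -> tuple[Compendium, dict]:
    """Regulator-mutant compendium with class-specific planted effects.

    ``gene_classes`` maps gene_id to joint class (HNHP/LNHP/...).  Each
    gene's response magnitude is proportional to its CRE latent.  Within
    the chromatin class, LNHP-specific activators and HNHP-specific
    repressors are balanced, and non-target genes respond at a reduced
    scale chosen so the expected mean |response| of a planted gene over
    all chromatin mutants equals the unplanted baseline — the planted
    class structure therefore does not distort the CRE-plasticity
    coupling.
    """
    rng = np.random.default_rng(config.seed + 2)
    gene_ids = gene_classes.index.to_numpy()
    n = len(gene_ids)
    lnhp = (gene_classes == "LNHP").to_numpy()
    hnhp = (gene_classes == "HNHP").to_numpy()
    A = np.asarray(cre_latent, dtype=float)

    a = config.activator_effect_lnhp
    rr = config.repressor_effect_hnhp
    f_spec = config.chromatin_specific_fraction
    e0 = _folded_mean(0.0)
    # reduced baseline scale for planted genes on their non-specific
    # chromatin mutants (keeps E|response| equal to the unplanted e0)
    def weak_scale(effect: float) -> float:
        c = (e0 - f_spec * _folded_mean(effect)) / ((1 - f_spec) * e0)
        return max(c, 0.1)
    c_lnhp = weak_scale(a)
    c_hnhp = weak_scale(rr)

    n_spec = int(round(f_spec * config.n_chromatin))
    mutant_ids, classes, roles = [], [], []
    for i in range(config.n_chromatin):
        mutant_ids.append(f"chrom_mut{i:03d}")
        classes.append("chromatin")
        roles.append("lnhp_activator" if i < n_spec
                     else "hnhp_repressor" if i < 2 * n_spec
                     else "unspecific")
    for i in range(config.n_general):
        mutant_ids.append(f"taf_mut{i:02d}")
        classes.append("general")
        roles.append("general")
    n_dual = int(math.ceil(config.histone_dual_fraction * config.n_histone))
    for i in range(config.n_histone):
        mutant_ids.append(f"histone_mut{i:02d}")
        classes.append("histone")
        roles.append("histone_dual" if i < n_dual else "histone_down")

    cols = {}
    for mid, role in zip(mutant_ids, roles):
        z = rng.standard_normal(n)
        shift = np.zeros(n)
        scale = np.ones(n)
        if role == "lnhp_activator":
            shift[lnhp] = -a
            scale[hnhp] = c_hnhp
        elif role == "hnhp_repressor":
            shift[hnhp] = rr
            scale[lnhp] = c_lnhp
        elif role == "unspecific":
            scale[lnhp] = c_lnhp
            scale[hnhp] = c_hnhp
        elif role == "general":
            shift[:] = -config.general_effect
            shift[lnhp] = -config.general_effect_lnhp
        elif role == "histone_dual":
            shift[lnhp] = -a
            shift[hnhp] = rr
        elif role == "histone_down":
            shift[lnhp] = -a
            shift[hnhp] = -a
        cols[mid] = A * scale * (shift + z)

    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    if config.compendium_missing_fraction > 0:
        mask = rng.random(values.shape) < config.compendium_missing_fraction
        values = values.mask(mask)
    comp = Compendium(values=values,
                      mutant_class=pd.Series(classes, index=mutant_ids))
    truth = {"roles": pd.Series(roles, index=mutant_ids),
             "n_dual_histone": n_dual,
             "weak_scale_lnhp": c_lnhp, "weak_scale_hnhp": c_hnhp}
    return comp, truth


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SyntheticDataset:
    gene_table: pd.DataFrame
    transcripts: pd.DataFrame
    track: OccupancyTrack
    compendium: Compendium
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.gene_table, outdir / "gene_table.tsv")
        write_transcripts(self.transcripts, outdir / "transcripts.bed")
        write_occupancy(self.track, outdir / "occupancy.bedgraph")
        write_compendium(self.compendium, outdir / "compendium.tsv",
                         outdir / "mutant_classes.tsv")
        roles = self.truth["compendium"]["roles"]
        truth_df = pd.DataFrame({"mutant_id": roles.index, "role": roles.values})
        truth_df.to_csv(outdir / "truth_mutants.tsv", sep="\t", index=False)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate all four inputs with consistent planted structure.

    Order matters: the genome assigns bipromoters, after which the
    planted HP bipromoter noise reduction is applied to the gene table;
    joint classes are then computed from the final table (the same
    quartile rule the pipeline uses) and drive the compendium planting.
    """
    from .variability import classify_three_way, joint_class

    genes, truth_g = generate_genes(config)
    transcripts, track, truth_n = generate_genome(config, genes, truth_g)

    bip_ids = set(transcripts.loc[transcripts["bipromoter"], "transcript_id"])
    hp = truth_g["hp_mask"]
    is_bip = genes["gene_id"].isin(bip_ids).to_numpy()
    reduction = config.bipromoter_noise_reduction * genes["noise_dm"].std()
    genes.loc[hp & is_bip, "noise_dm"] -= reduction

    nc = classify_three_way(genes["noise_dm"], config.p_low, config.p_high)
    pc = classify_three_way(genes["plasticity"], config.p_low, config.p_high)
    jc = joint_class(nc, pc)
    jc.index = genes["gene_id"]

    comp, truth_c = generate_compendium(config, jc, truth_g["cre_latent"])

    truth = {"genes": truth_g, "genome": truth_n, "compendium": truth_c,
             "joint_class": jc, "bipromoter_ids": bip_ids}
    return SyntheticDataset(gene_table=genes, transcripts=transcripts,
                            track=track, compendium=comp, truth=truth)
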