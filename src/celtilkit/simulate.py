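"""Synthetic trial-shaped cohorts with planted biomarker structure.

The generator emulates the data layout of a window-of-opportunity
paired-biopsy trial in HR+/HER2- early breast cancer: a clinical table
with baseline and day-21 cellularity/TILs, a 192-gene panel count
matrix (185 analysis + 7 housekeeping genes), SEG-format copy-number
profiles over a 519-segment synthetic genome, and a MAF-like somatic
mutation table — together with the model files (subtype centroids,
signature weights, segment definitions, CN coefficients and cluster
centroids) needed to analyze them.

Planted structure, all seeded and recoverable by the pipeline:

* intrinsic-subtype mixture with module-structured expression
  (proliferation, luminal, basal, HER2-amplicon, immune modules);
* a latent 17q12 amplicon level that drives both normalized ERBB2
  expression and the 17q12 segment CN signal at a configurable Pearson
  correlation (default 0.55);
* TP53 mutation probability per subtype (Basal-like 1.0, Luminal A
  0.107 by default) plus background mutations in common breast-cancer
  genes;
* CelTIL response drawn from a logistic model on standardized
  proliferation, negative ERBB2 score and TP53 status, with day-21
  biopsies constructed so responders' scaled CelTIL increase
  concentrates at >= 20 points and non-responders' below;
* four CN clusters whose signature-space centroids are exactly the
  model's image of four archetypal segment profiles.

All numeric model values here are synthetic stand-ins with the same
schema as the published assays; they are not the proprietary
PAM50/HER2DX/DNADX coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from celtilkit import io as ckio
from celtilkit.celtil import RAW_RANGE, BiopsyAssessment, celtil_score
from celtilkit.copynumber import (
    CNSignatureModel,
    GeneAnnotation,
    SegmentProfile,
    SegmentRecord,
)
from celtilkit.expression import HOUSEKEEPING_GENES
from celtilkit.variants import VariantRecord

SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")
CLUSTERS = ("cluster1", "cluster2", "cluster3", "cluster4")

# expression modules over the analysis panel; a handful of real gene
# names anchor each module, the rest are synthetic filler ids
PROLIF_GENES = ["AURKA", "CCNE1", "MKI67", "BIRC5", "CDC20", "CCNB1", "UBE2C",
                "MYBL2", "RRM2", "TYMS", "CENPF", "EXO1", "ANLN", "CEP55", "KIF2C"]
LUMINAL_GENES = ["ESR1", "NAT1", "SLC39A6", "MAGED2", "THSD4", "PGR", "FOXA1",
                 "BCL2", "GPR160", "MAPT", "MLPH", "CXXC5", "BAG1", "MDM2", "AR"]
BASAL_GENES = ["KRT5", "KRT14", "KRT17", "SFRP1", "MIA", "FOXC1", "EGFR",
               "CDH3", "PHGDH", "ACTR3B"]
HER2_AMPLICON_GENES = ["ERBB2", "GRB7", "STARD3", "PGAP3", "MIEN1"]
IMMUNE_GENES = ["CD8A", "CD3D", "GZMB", "PRF1", "CD19", "IGKC", "CD79A",
                "PDCD1", "CTLA4", "FOXP3"]

#: background mutation rates for frequently mutated breast-cancer genes
BACKGROUND_MUTATION_RATES = {
    "PIK3CA": 0.33,
    "GATA3": 0.29,
    "ATM": 0.24,
    "CDH1": 0.20,
    "KMT2C": 0.16,
    "KMT2D": 0.16,
    "MAP3K1": 0.14,
    "ERBB2": 0.08,
}

N_ANALYSIS_GENES = 185
N_SEGMENTS = 519
N_CN_SIGNATURES = 150
GENES_PER_SEGMENT = 3
SEGMENT_17Q12 = "17q12"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 77
    seed: int = 0
    # HR+/HER2- early-disease mixture; Basal-like rare, Luminal A dominant
    subtype_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "LumA": 0.57, "LumB": 0.20, "Her2": 0.08, "Basal": 0.06, "Normal": 0.09
        }
    )
    expression_noise_sd: float = 0.5
    proliferation_jitter_sd: float = 0.5  # per-sample module-level variation
    erbb2_17q12_correlation: float = 0.55
    tp53_prob_by_subtype: Mapping[str, float] = field(
        default_factory=lambda: {
            "LumA": 0.107, "LumB": 0.12, "Her2": 0.30, "Basal": 1.0, "Normal": 0.15
        }
    )
    # logistic response model on (std proliferation, -std ERBB2, TP53)
    response_intercept: float = -1.24
    beta_proliferation: float = 0.8
    beta_neg_erbb2: float = 0.8
    beta_tp53: float = math.log(6.0)
    # baseline biopsy distributions (percent scale)
    cellularity_mean: float = 55.0
    cellularity_sd: float = 20.0
    tils_mean: float = 10.0
    tils_sd: float = 8.0
    # scaled-CelTIL change targets
    responder_delta_mean: float = 35.0
    responder_delta_sd: float = 8.0
    nonresponder_delta_mean: float = 4.0
    nonresponder_delta_sd: float = 8.0
    # CN cluster mixture and segment-level noise (log2-ratio scale)
    cluster_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "cluster1": 0.35, "cluster2": 0.30, "cluster3": 0.20, "cluster4": 0.15
        }
    )
    cn_noise_sd: float = 0.15
    n_segments: int = N_SEGMENTS
    n_cn_signatures: int = N_CN_SIGNATURES
    include_artifact_variants: bool = True
    # component toggles: large parameter-recovery runs only need the
    # clinical table and latent ground truth
    include_expression: bool = True
    include_copy_number: bool = True
    include_variants: bool = True
    model_seed: int = 797  # the "assay": fixed independently of the cohort seed

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not math.isclose(sum(self.subtype_mixture.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("subtype mixture proportions must sum to 1")
        if not math.isclose(sum(self.cluster_mixture.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("cluster mixture proportions must sum to 1")
        if not (-1.0 <= self.erbb2_17q12_correlation <= 1.0):
            raise ConfigError("erbb2_17q12_correlation must be in [-1, 1]")
        for st, p in self.tp53_prob_by_subtype.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"tp53 probability for {st} outside [0, 1]")
        if self.expression_noise_sd <= 0 or self.cn_noise_sd < 0:
            raise ConfigError("noise SDs must be positive")


@dataclass(frozen=True)
class SyntheticModels:
    """The synthetic 'assay': centroids, signatures, genome and CN model."""

    centroids: pd.DataFrame                      # genes x subtypes (log2 scale)
    signatures: dict[str, dict[str, float]]      # name -> gene -> weight
    annotation: GeneAnnotation                   # CN gene coordinates
    segment_definitions: dict[str, list[str]]    # segment -> member genes
    segment_coords: pd.DataFrame                 # segment -> chrom/start/end
    cn_model: CNSignatureModel
    cluster_archetypes: pd.DataFrame             # segments x clusters (true mu_k)
    gene_names: list[str]                        # 185 analysis genes


@dataclass(frozen=True)
class SyntheticBundle:
    clinical: tuple[BiopsyAssessment, ...]
    counts: pd.DataFrame | None                  # 192 genes x samples
    seg_profiles: tuple[SegmentProfile, ...]
    variants: tuple[VariantRecord, ...]
    models: SyntheticModels
    ground_truth: pd.DataFrame                   # per-sample latent variables


def _gene_panel() -> list[str]:
    named = (PROLIF_GENES + LUMINAL_GENES + BASAL_GENES + HER2_AMPLICON_GENES
             + IMMUNE_GENES)
    filler = [f"G{i:03d}" for i in range(1, N_ANALYSIS_GENES - len(named) + 1)]
    return named + filler


def build_models(cfg: CohortConfig) -> SyntheticModels:
    """Deterministic synthetic model files, seeded by ``cfg.model_seed``."""
    rng = np.random.default_rng(cfg.model_seed)
    genes = _gene_panel()

    base = pd.Series(rng.normal(6.0, 0.8, len(genes)), index=genes)
    shifts = {
        "LumA":   {"lum": 2.0, "prolif": -1.0, "basal": -1.5, "her2": 0.0, "imm": 0.0},
        "LumB":   {"lum": 1.5, "prolif": 1.0, "basal": -1.0, "her2": 0.0, "imm": 0.0},
        "Her2":   {"lum": 0.0, "prolif": 1.0, "basal": 0.0, "her2": 1.5, "imm": 0.5},
        "Basal":  {"lum": -2.0, "prolif": 1.5, "basal": 2.0, "her2": 0.0, "imm": 1.0},
        "Normal": {"lum": 0.0, "prolif": -1.0, "basal": 0.5, "her2": 0.0, "imm": 0.0},
    }
    modules = {
        "prolif": PROLIF_GENES,
        "lum": LUMINAL_GENES,
        "basal": BASAL_GENES,
        "her2": [g for g in HER2_AMPLICON_GENES if g != "ERBB2"],
        "imm": IMMUNE_GENES,
    }
    centroids = {}
    for st in SUBTYPES:
        v = base.copy()
        for mod, gene_list in modules.items():
            v[gene_list] = v[gene_list] + shifts[st][mod]
        centroids[st] = v
    centroid_df = pd.DataFrame(centroids)[list(SUBTYPES)]

    signatures: dict[str, dict[str, float]] = {
        "proliferation": {g: 1.0 for g in PROLIF_GENES},
        "luminal": {g: 1.0 for g in LUMINAL_GENES},
        "igg_immune": {g: 1.0 for g in IMMUNE_GENES},
        "her2_amplicon": {g: 1.0 for g in HER2_AMPLICON_GENES},
        "erbb2": {"ERBB2": 1.0},
    }

    # synthetic genome: segments laid out on 22 chromosomes, 3 genes each
    n_seg = cfg.n_segments
    seg_names, seg_rows, defs, ann_rows = [], [], {}, []
    per_chrom = math.ceil(n_seg / 22)
    seg_i = 0
    for chrom in range(1, 23):
        for k in range(per_chrom):
            if seg_i >= n_seg:
                break
            # reserve one segment on chr17 as the ERBB2 amplicon segment
            if chrom == 17 and k == 2:
                name = SEGMENT_17Q12
            else:
                name = f"chr{chrom}_s{k + 1}"
            start = k * 3_000_000 + 1
            end = (k + 1) * 3_000_000
            seg_names.append(name)
            seg_rows.append({"segment": name, "chromosome": f"chr{chrom}",
                             "start": start, "end": end})
            members = []
            for g in range(GENES_PER_SEGMENT):
                gid = "ERBB2" if name == SEGMENT_17Q12 and g == 0 else f"{name}_g{g + 1}"
                gs = start + 200_000 + g * 800_000
                ann_rows.append({"gene": gid, "chromosome": f"chr{chrom}",
                                 "start": gs, "end": gs + 100_000})
                members.append(gid)
            defs[name] = members
            seg_i += 1
    if SEGMENT_17Q12 not in defs:
        raise ConfigError("n_segments too small to include the 17q12 segment")
    segment_coords = pd.DataFrame(seg_rows).set_index("segment")
    annotation = GeneAnnotation(
        table=pd.DataFrame(ann_rows).set_index("gene")[["chromosome", "start", "end"]]
    )

    coeff = pd.DataFrame(
        rng.normal(0.0, 1.0, (cfg.n_cn_signatures, n_seg))
        * rng.binomial(1, 0.1, (cfg.n_cn_signatures, n_seg)),
        index=[f"cn_sig_{i + 1}" for i in range(cfg.n_cn_signatures)],
        columns=seg_names,
    )
    # archetypal segment profiles: distinct gain/loss blocks per cluster
    arch = np.zeros((n_seg, 4))
    block = n_seg // 8
    arch[0:block, 0] = 0.6
    arch[block:2 * block, 0] = -0.4
    arch[2 * block:3 * block, 1] = 0.6
    arch[3 * block:4 * block, 1] = -0.4
    arch[4 * block:5 * block, 2] = 0.6
    arch[5 * block:6 * block, 2] = -0.4
    arch[6 * block:7 * block, 3] = 0.6
    arch[7 * block:8 * block, 3] = -0.4
    # keep the amplicon segment out of the cluster blocks so its signal is
    # purely the planted ERBB2/17q12 latent
    arch[seg_names.index(SEGMENT_17Q12), :] = 0.0
    archetypes = pd.DataFrame(arch, index=seg_names, columns=list(CLUSTERS))
    centroids_cn = (coeff.to_numpy() @ arch).T  # clusters x signatures
    cn_model = CNSignatureModel(
        coefficients=coeff,
        centroids=pd.DataFrame(centroids_cn, index=list(CLUSTERS),
                               columns=coeff.index),
    )
    return SyntheticModels(
        centroids=centroid_df,
        signatures=signatures,
        annotation=annotation,
        segment_definitions=defs,
        segment_coords=segment_coords,
        cn_model=cn_model,
        cluster_archetypes=archetypes,
        gene_names=genes,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(cfg: CohortConfig = CohortConfig()) -> SyntheticBundle:
    """Draw one fully seeded synthetic cohort under ``cfg``."""
    models = build_models(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    subtype_names = list(cfg.subtype_mixture)
    subtype = rng.choice(
        subtype_names, size=n, p=[cfg.subtype_mixture[s] for s in subtype_names]
    )

    # latent amplicon level drives both ERBB2 expression and 17q12 CN
    rho = cfg.erbb2_17q12_correlation
    sgn = 1.0 if rho >= 0 else -1.0
    load = math.sqrt(abs(rho))
    z = rng.normal(0, 1, n)
    e_expr = rng.normal(0, 1, n)
    e_cn = rng.normal(0, 1, n)
    erbb2_latent = load * z + math.sqrt(1 - abs(rho)) * e_expr
    amp_cn_latent = sgn * load * z + math.sqrt(1 - abs(rho)) * e_cn

    # expression: subtype centroid + per-sample module jitter + gene noise
    genes = models.gene_names
    prolif_jitter = rng.normal(0, 1.0, n) * cfg.proliferation_jitter_sd
    gene_pos = {g: i for i, g in enumerate(genes)}
    counts = None
    if cfg.include_expression:
        mu = models.centroids[list(subtype)].to_numpy()  # genes x samples
        log_expr = mu + rng.normal(0, cfg.expression_noise_sd, (len(genes), n))
        prolif_rows = [gene_pos[g] for g in PROLIF_GENES]
        log_expr[prolif_rows, :] += prolif_jitter[None, :]
        # ERBB2 is amplicon-driven, constant in subtype mean
        log_expr[gene_pos["ERBB2"], :] = 6.0 + 1.2 * erbb2_latent

        hk_log = 6.0 + rng.normal(0, 0.05, (len(HOUSEKEEPING_GENES), n))
        counts_analysis = np.rint(np.exp2(np.clip(log_expr, 0, 20))).astype(np.int64)
        counts_hk = np.rint(np.exp2(hk_log)).astype(np.int64)
        counts = pd.DataFrame(
            np.vstack([counts_analysis, counts_hk]),
            index=genes + list(HOUSEKEEPING_GENES),
            columns=sample_ids,
        )

    # true covariate scores for the response model
    prolif_shift = {"LumA": -1.0, "LumB": 1.0, "Her2": 1.0, "Basal": 1.5, "Normal": -1.0}
    prolif_true = np.array([prolif_shift[s] for s in subtype]) + prolif_jitter
    prolif_std = _standardize(prolif_true)
    erbb2_std = _standardize(erbb2_latent)

    tp53 = np.array(
        [rng.random() < cfg.tp53_prob_by_subtype[s] for s in subtype], dtype=int
    )

    eta = (
        cfg.response_intercept
        + cfg.beta_proliferation * prolif_std
        + cfg.beta_neg_erbb2 * (-erbb2_std)
        + cfg.beta_tp53 * tp53
    )
    p_response = _sigmoid(eta)
    responder = rng.random(n) < p_response

    # paired biopsies: construct day-21 values to hit a target scaled delta
    base_cell = np.clip(rng.normal(cfg.cellularity_mean, cfg.cellularity_sd, n), 5, 95)
    base_tils = np.clip(rng.normal(cfg.tils_mean, cfg.tils_sd, n), 0, 60)
    delta_target = np.where(
        responder,
        rng.normal(cfg.responder_delta_mean, cfg.responder_delta_sd, n),
        rng.normal(cfg.nonresponder_delta_mean, cfg.nonresponder_delta_sd, n),
    )
    tils_rise = np.clip(
        rng.normal(0.9 * np.abs(delta_target), 5.0, n), 0, 100 - base_tils
    )
    # raw delta needed = scaled delta * (range/100); cell change balances TILs
    cell_change = (1.3 * tils_rise - delta_target * RAW_RANGE / 100.0) / 0.8
    day21_cell = np.clip(base_cell + cell_change, 0, 100)
    day21_tils = base_tils + tils_rise

    clinical = []
    for j, sid in enumerate(sample_ids):
        clinical.append(BiopsyAssessment(sid, "baseline",
                                         float(base_cell[j]), float(base_tils[j])))
        clinical.append(BiopsyAssessment(sid, "day21",
                                         float(day21_cell[j]), float(day21_tils[j])))

    # copy number: cluster archetype + noise; 17q12 tied to the amplicon latent
    cluster_names = list(cfg.cluster_mixture)
    cluster = rng.choice(
        cluster_names, size=n, p=[cfg.cluster_mixture[c] for c in cluster_names]
    )
    seg_names = list(models.segment_coords.index)
    i17 = seg_names.index(SEGMENT_17Q12)
    seg_profiles = []
    if cfg.include_copy_number:
        chroms = models.segment_coords["chromosome"].to_list()
        starts = models.segment_coords["start"].to_list()
        ends = models.segment_coords["end"].to_list()
        for j, sid in enumerate(sample_ids):
            mu = models.cluster_archetypes[cluster[j]].to_numpy(copy=True)
            sig = mu + rng.normal(0, cfg.cn_noise_sd, len(seg_names))
            sig[i17] = mu[i17] + 0.5 * amp_cn_latent[j]
            records = tuple(
                SegmentRecord(
                    chromosome=chroms[k],
                    start=int(starts[k]),
                    end=int(ends[k]),
                    cn_signal=float(sig[k]),
                )
                for k in range(len(seg_names))
            )
            seg_profiles.append(SegmentProfile(sample_id=sid, records=records))

    variants = (
        _draw_variants(rng, sample_ids, subtype, tp53, cfg)
        if cfg.include_variants
        else []
    )

    ground_truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtype,
            "cn_cluster": cluster,
            "tp53_mutant": tp53.astype(bool),
            "amplicon_latent": z,
            "erbb2_latent": erbb2_latent,
            "cn17q12_latent": amp_cn_latent,
            "proliferation_true": prolif_true,
            "linear_predictor": eta,
            "p_response": p_response,
            "responder": responder,
            "delta_celtil_target": delta_target,
        }
    ).set_index("sample_id")

    return SyntheticBundle(
        clinical=tuple(clinical),
        counts=counts,
        seg_profiles=tuple(seg_profiles),
        variants=tuple(variants),
        models=models,
        ground_truth=ground_truth,
    )


def _draw_variants(rng, sample_ids, subtype, tp53, cfg) -> list[VariantRecord]:
    chrom_for = {"TP53": "chr17", "PIK3CA": "chr3", "GATA3": "chr10", "ATM": "chr11",
                 "CDH1": "chr16", "KMT2C": "chr7", "KMT2D": "chr12",
                 "MAP3K1": "chr5", "ERBB2": "chr17"}
    bases = np.array(list("ACGT"))
    records = []

    def make(sid: str, gene: str, artifact: bool = False) -> VariantRecord:
        depth = int(rng.integers(200, 900))
        if artifact:
            vaf = float(rng.uniform(0.002, 0.03))
        else:
            vaf = float(rng.uniform(0.10, 0.50))
        alt_reads = max(1, int(round(vaf * depth)))
        if not artifact and alt_reads < 7:
            alt_reads = 7
        ref, alt = rng.choice(bases, size=2, replace=False)
        is_indel = rng.random() < 0.15
        return VariantRecord(
            sample_id=sid,
            gene=gene,
            chromosome=chrom_for.get(gene, "chr1"),
            position=int(rng.integers(1_000_000, 90_000_000)),
            ref=str(ref) if not is_indel else str(ref) * 3,
            alt=str(alt),
            variant_class="INDEL" if is_indel else "SNV",
            alt_reads=alt_reads,
            depth=depth,
            vaf=alt_reads / depth,
            population_af=None if rng.random() < 0.8 else float(rng.uniform(0, 5e-5)),
        )

    for j, sid in enumerate(sample_ids):
        if tp53[j]:
            records.append(make(sid, "TP53"))
        for gene, rate in BACKGROUND_MUTATION_RATES.items():
            if rng.random() < rate:
                records.append(make(sid, gene))
        if cfg.include_artifact_variants and rng.random() < 0.3:
            records.append(make(sid, "G001", artifact=True))
    return records


# ---------------------------------------------------------------- bundle I/O


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as plain-text files; byte-stable given the seed."""
    out = Path(out_dir)
    models_dir = out / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out / "clinical.csv",
        "counts": out / "counts.tsv",
        "seg": out / "copynumber.seg",
        "maf": out / "mutations.maf.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "centroids": models_dir / "subtype_centroids.tsv",
        "signatures": models_dir / "signature_weights.tsv",
        "annotation": models_dir / "gene_annotation.tsv",
        "segment_definitions": models_dir / "segment_definitions.tsv",
        "cn_coefficients": models_dir / "cn_coefficients.tsv",
        "cn_centroids": models_dir / "cn_centroids.tsv",
    }
    ckio.write_clinical(bundle.clinical, paths["clinical"])
    ckio.write_counts(bundle.counts, paths["counts"])
    ckio.write_seg(bundle.seg_profiles, paths["seg"])
    ckio.write_maf(bundle.variants, paths["maf"])
    bundle.ground_truth.to_csv(paths["ground_truth"], sep="\t")
    ckio.write_centroids(bundle.models.centroids, paths["centroids"])
    ckio.write_signatures(bundle.models.signatures, paths["signatures"])
    ckio.write_gene_annotation(bundle.models.annotation, paths["annotation"])
    ckio.write_segment_definitions(
        bundle.models.segment_definitions, paths["segment_definitions"]
    )
    ckio.write_cn_model(
        bundle.models.cn_model, paths["cn_coefficients"], paths["cn_centroids"]
    )
    return paths


def read_bundle_inputs(out_dir: str | Path) -> dict:
    """Re-read the observable files of a written bundle (not the ground truth)."""
    out = Path(out_dir)
    models_dir = out / "models"
    return {
        "clinical": ckio.read_clinical(out / "clinical.csv"),
        "counts": ckio.read_counts(out / "counts.tsv"),
        "seg": ckio.read_seg(out / "copynumber.seg"),
        "variants": ckio.read_maf(out / "mutations.maf.tsv"),
        "centroids": ckio.read_centroids(models_dir / "subtype_centroids.tsv"),
        "signatures": ckio.read_signatures(models_dir / "signature_weights.tsv"),
        "annotation": ckio.read_gene_annotation(models_dir / "gene_annotation.tsv"),
        "segment_definitions": ckio.read_segment_definitions(
            models_dir / "segment_definitions.tsv"
        ),
        "cn_model": ckio.read_cn_model(
            models_dir / "cn_coefficients.tsv", models_dir / "cn_centroids.tsv"
        ),
    }
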