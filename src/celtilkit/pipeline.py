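"""End-to-end orchestration: ingest → score → associate → report.

A run takes a clinical table, a panel count matrix and model files
(plus optional SEG and MAF inputs), computes CelTIL deltas and response
calls, subtype calls and signature scores, CN signature scores and
cluster calls, filtered variants, and the biomarker association tables,
writing per-stage TSVs plus a ``report.json`` into the output
directory.  Everything is deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from celtilkit import io as ckio
from celtilkit.celtil import SENSITIVITY_CUTOFFS, is_responder, score_pairs
from celtilkit.copynumber import score_cohort
from celtilkit.expression import (
    assign_subtype,
    fit_tertiles,
    apply_tertiles,
    normalize_counts,
    score_signature_matrix,
)
from celtilkit.sam import SAMConfig, sam_two_class
from celtilkit.stats import fisher_exact_2x2, logistic_fit, odds_ratio, roc_auc
from celtilkit.variants import (
    FilterThresholds,
    filter_variants,
    gene_response_table,
    mutation_frequency,
    mutation_status,
)

logger = logging.getLogger("celtilkit")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    clinical_path: str
    counts_path: str
    centroids_path: str
    signatures_path: str
    out_dir: str
    seg_path: str | None = None
    maf_path: str | None = None
    annotation_path: str | None = None
    segment_definitions_path: str | None = None
    cn_coefficients_path: str | None = None
    cn_centroids_path: str | None = None
    celtil_cutoff: float = 20.0
    fdr_threshold: float = 0.10
    n_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.celtil_cutoff not in SENSITIVITY_CUTOFFS:
            raise ValueError(
                f"celtil_cutoff must be one of {SENSITIVITY_CUTOFFS}"
            )
        required = [self.clinical_path, self.counts_path,
                    self.centroids_path, self.signatures_path]
        for p in required:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(cfg: RunConfig) -> str:
    # identifies the analytic configuration; the output location is not part of it
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir")
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage the inputs support and return the report dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.lock").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True)
    )
    report: dict = {
        "provenance": {"config_hash": _config_hash(cfg), "seed": cfg.seed},
        "stages": {},
    }

    # ---- CelTIL ----------------------------------------------------------
    stage_dir = out / "celtil"
    stage_dir.mkdir(exist_ok=True)
    try:
        assessments = ckio.read_clinical(cfg.clinical_path)
        results = score_pairs(assessments, cutoff=cfg.celtil_cutoff)
        celtil_df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in results],
                "baseline_scaled": [r.baseline_scaled for r in results],
                "day21_scaled": [r.day21_scaled for r in results],
                "delta": [r.delta for r in results],
                "responder": [r.responder for r in results],
            }
        ).set_index("sample_id")
        celtil_df.to_csv(stage_dir / "celtil_scores.tsv", sep="\t")
    except Exception as exc:
        raise StageError("celtil", str(exc)) from exc
    n_resp = int(celtil_df["responder"].sum())
    report["stages"]["celtil"] = {
        "n_pairs": len(celtil_df),
        "n_responders": n_resp,
        "response_rate": n_resp / len(celtil_df) if len(celtil_df) else None,
        "mean_delta": float(celtil_df["delta"].mean()),
        "cutoff": cfg.celtil_cutoff,
    }

    # ---- expression ------------------------------------------------------
    stage_dir = out / "expression"
    stage_dir.mkdir(exist_ok=True)
    try:
        counts = ckio.read_counts(cfg.counts_path)
        centroids = ckio.read_centroids(cfg.centroids_path)
        signatures = ckio.read_signatures(cfg.signatures_path)
        normalized = normalize_counts(counts)
        calls = {s: assign_subtype(normalized[s], centroids) for s in normalized.columns}
        subtype_df = pd.DataFrame(
            {
                "subtype": {s: c.subtype for s, c in calls.items()},
                "tie": {s: c.tie for s, c in calls.items()},
            }
        )
        scores = score_signature_matrix(normalized, signatures)
        normalized.to_csv(stage_dir / "normalized.tsv", sep="\t", index_label="gene")
        subtype_df.to_csv(stage_dir / "subtypes.tsv", sep="\t", index_label="sample_id")
        scores.T.to_csv(stage_dir / "signature_scores.tsv", sep="\t",
                        index_label="sample_id")
    except Exception as exc:
        raise StageError("expression", str(exc)) from exc
    report["stages"]["expression"] = {
        "n_samples": int(normalized.shape[1]),
        "n_genes": int(normalized.shape[0]),
        "subtype_counts": subtype_df["subtype"].value_counts().to_dict(),
    }

    shared = celtil_df.index.intersection(normalized.columns)
    responder = celtil_df.loc[shared, "responder"].astype(int)

    # ---- tertiles on the ERBB2 score (reference = this cohort) -----------
    if "erbb2" in scores.index and len(shared) >= 3:
        erbb2 = scores.loc["erbb2", shared]
        tert = fit_tertiles(erbb2.to_list())
        labels = apply_tertiles(erbb2.to_list(), tert)
        pd.DataFrame({"sample_id": shared, "erbb2_tertile": labels}).to_csv(
            stage_dir / "erbb2_tertiles.tsv", sep="\t", index=False
        )
        report["stages"]["expression"]["erbb2_tertile_sizes"] = tert.group_sizes

    # ---- copy number -----------------------------------------------------
    if cfg.seg_path:
        stage_dir = out / "copynumber"
        stage_dir.mkdir(exist_ok=True)
        try:
            profiles = ckio.read_seg(cfg.seg_path)
            annotation = ckio.read_gene_annotation(cfg.annotation_path)
            defs = ckio.read_segment_definitions(cfg.segment_definitions_path)
            cn_model = ckio.read_cn_model(cfg.cn_coefficients_path,
                                          cfg.cn_centroids_path)
            segvecs, cn_scores, clusters = score_cohort(
                profiles, annotation, defs, cn_model
            )
            segvecs.to_csv(stage_dir / "segment_signals.tsv", sep="\t",
                           index_label="sample_id")
            cn_scores.to_csv(stage_dir / "cn_signature_scores.tsv", sep="\t",
                             index_label="sample_id")
            clusters.to_csv(stage_dir / "clusters.tsv", sep="\t",
                            index_label="sample_id")
        except Exception as exc:
            raise StageError("copynumber", str(exc)) from exc
        report["stages"]["copynumber"] = {
            "n_samples": len(clusters),
            "cluster_counts": clusters.value_counts().to_dict(),
        }
    else:
        report["stages"]["copynumber"] = {"status": "absent"}
        clusters = None

    # ---- variants --------------------------------------------------------
    if cfg.maf_path:
        stage_dir = out / "variants"
        stage_dir.mkdir(exist_ok=True)
        try:
            records = ckio.read_maf(cfg.maf_path)
            filt = filter_variants(records, FilterThresholds())
            ckio.write_maf(filt.kept, stage_dir / "filtered.maf.tsv")
            cohort_ids = sorted({r.sample_id for r in records} | set(celtil_df.index))
            freq = mutation_frequency(filt.kept, len(cohort_ids))
            pd.DataFrame(
                [{"gene": g, "n_mutated": k, "fraction": f} for g, (k, f) in freq.items()]
            ).to_csv(stage_dir / "mutation_frequency.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("variants", str(exc)) from exc
        report["stages"]["variants"] = {
            "n_input": len(records),
            "n_kept": len(filt.kept),
            "drop_counts": dict(filt.drop_counts),
        }
        kept = filt.kept
    else:
        report["stages"]["variants"] = {"status": "absent"}
        kept = None

    # ---- associations ----------------------------------------------------
    stage_dir = out / "associations"
    stage_dir.mkdir(exist_ok=True)
    assoc_rows = []
    try:
        # SAM on normalized expression vs response
        sam = sam_two_class(
            normalized[shared],
            responder.to_numpy(),
            SAMConfig(
                n_permutations=cfg.n_permutations,
                fdr_threshold=cfg.fdr_threshold,
                seed=cfg.seed,
            ),
        )
        pd.DataFrame(
            {"d_score": sam.d, "q_value": sam.qvalues,
             "significant": sam.d.index.isin(sam.significant)}
        ).to_csv(stage_dir / "sam_genes.tsv", sep="\t", index_label="gene")
        report["stages"]["associations"] = {
            "sam_significant": len(sam.significant),
            "sam_total_genes": len(sam.d),
            "sam_s0": sam.s0,
            "sam_fdr": sam.fdr,
        }

        # signature scores vs response: logistic OR + AUC
        for sig in scores.index:
            vals = scores.loc[sig, shared].to_numpy(dtype=float)
            if np.ptp(vals) == 0 or responder.nunique() < 2:
                continue
            lr = logistic_fit(responder.to_numpy(), vals, names=[sig])[0]
            auc = roc_auc(vals, responder.to_numpy())
            assoc_rows.append(
                {"biomarker": sig, "effect": lr.effect, "ci_low": lr.ci_low,
                 "ci_high": lr.ci_high, "p_value": lr.p_value,
                 "method": lr.method, "n": lr.n, "auc": auc.effect}
            )

        # TP53 x response 2x2
        if kept is not None and responder.nunique() == 2:
            status = mutation_status(kept, "TP53", list(shared))
            table = gene_response_table(status, responder.astype(bool).to_dict())
            orr = odds_ratio(table)
            p = fisher_exact_2x2(table)
            assoc_rows.append(
                {"biomarker": "TP53_mutation", "effect": orr.effect,
                 "ci_low": orr.ci_low, "ci_high": orr.ci_high, "p_value": p,
                 "method": "fisher+odds_ratio", "n": orr.n, "auc": np.nan}
            )
            report["stages"]["associations"]["tp53_table"] = table
    except Exception as exc:
        raise StageError("associations", str(exc)) from exc
    pd.DataFrame(assoc_rows).to_csv(stage_dir / "associations.tsv", sep="\t",
                                    index=False)

    report["response_rate"] = report["stages"]["celtil"]["response_rate"]
    ckio.write_json(report, out / "report.json")
    return report


def sensitivity_scan(cfg: RunConfig, cutoffs=SENSITIVITY_CUTOFFS) -> pd.DataFrame:
    """Re-run response classification and key associations per CelTIL cutoff."""
    cfg.validate()
    assessments = ckio.read_clinical(cfg.clinical_path)
    counts = ckio.read_counts(cfg.counts_path)
    signatures = ckio.read_signatures(cfg.signatures_path)
    normalized = normalize_counts(counts)
    scores = score_signature_matrix(normalized, signatures)

    base_results = score_pairs(assessments, cutoff=20.0)
    deltas = pd.Series({r.sample_id: r.delta for r in base_results})
    shared = deltas.index.intersection(normalized.columns)

    rows = []
    for cutoff in cutoffs:
        resp = pd.Series(
            {s: is_responder(deltas[s], cutoff) for s in shared}, dtype=int
        )
        row = {"cutoff": cutoff, "n_responders": int(resp.sum()),
               "n_total": len(resp)}
        if 0 < resp.sum() < len(resp):
            for sig in scores.index:
                vals = scores.loc[sig, shared].to_numpy(dtype=float)
                if np.ptp(vals) == 0:
                    continue
                lr = logistic_fit(resp.to_numpy(), vals, names=[sig])[0]
                row[f"log_or_{sig}"] = float(np.log(lr.effect))
                row[f"p_{sig}"] = lr.p_value
        rows.append(row)
    df = pd.DataFrame(rows)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "sensitivity_scan.tsv", sep="\t", index=False)
    return df
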