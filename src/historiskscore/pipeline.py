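"""End-to-end orchestration: generate/load -> score -> survival -> associate.

One reproducible run: a cohort comes either from CSV inputs (patch
scores, survival, signatures) or from the synthetic generator; cases
are scored and split into risk groups; the groups are evaluated
prognostically (Kaplan-Meier medians, log-rank, uni- and multivariate
Cox) and against the signatures (chi-square screen, Fisher odds ratios,
BH post-hoc).  Artifacts are plain CSV/JSON plus a consolidated JSON
report.

Development statistics (mu0, sigma0) for the risk threshold default to
the unadjusted scores of a synthetic development cohort generated with
a fixed packaged seed; out-of-distribution cohorts are corrected toward
that reference through the alpha term of the threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import reproduce_signature_screen
from .scoring import DecileSelection, score_cohort
from .survival import c_index, cox_fit, km_estimate, logrank
from .synthetic import SyntheticCohort, SyntheticCohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "development_s_u", "DEV_SEED"]

log = logging.getLogger("historiskscore")

#: packaged seed of the synthetic development split used for mu0/sigma0
DEV_SEED = 20230914
DEV_N_CASES = 150


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` (generator parameters) or
    ``input_dir`` (directory with patch_scores.csv, survival.csv and
    optionally signatures.csv) must be set.
    """

    out_dir: str | Path = "run_output"
    synthetic: SyntheticCohortConfig | None = None
    input_dir: str | Path | None = None
    r: int = 2
    m: int = 5
    dev_stats: str = "packaged"  # "packaged" | "self" | path to CSV of dev S_u
    seed: int = 0
    screen_alpha: float = 0.10
    fdr: float = 0.20

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of 'synthetic' or 'input_dir' must be provided"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticCohortConfig(**syn)
        return cls(synthetic=syn, **raw)


def development_s_u(r: int = 2, m: int = 5) -> np.ndarray:
    """Unadjusted scores of the packaged synthetic development split."""
    cfg = SyntheticCohortConfig(
        n_cases=DEV_N_CASES, patches_per_case=(200, 600), seed=DEV_SEED
    )
    cohort = generate_cohort(cfg)
    cases, _ = score_cohort(
        cohort.patch_scores, sel=DecileSelection(r=r, m=m), dev_s_u=[0.0, 0.0]
    )
    return cases["s_u"].to_numpy()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # output location is not part of the science
    blob = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(input_dir: Path) -> SyntheticCohort:
    patch_scores = pd.read_csv(input_dir / "patch_scores.csv")
    survival = pd.read_csv(input_dir / "survival.csv")
    sig_path = input_dir / "signatures.csv"
    signatures = (
        pd.read_csv(sig_path)
        if sig_path.exists()
        else pd.DataFrame(columns=["case_id", "signature", "value"])
    )
    return SyntheticCohort(
        patch_scores=patch_scores,
        survival=survival,
        signatures=signatures,
        latent_group=pd.DataFrame(columns=["case_id", "group"]),
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns the consolidated report (also written as ``report.json``).
    Stage failures abort with the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
    }

    # stage: inputs
    if config.synthetic is not None:
        syn_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(syn_cfg)
        cohort.write(out / "cohort")
        log.info("generated synthetic cohort with %d cases", syn_cfg.n_cases)
    else:
        cohort = _load_inputs(Path(config.input_dir))
        log.info("loaded cohort tables from %s", config.input_dir)

    # stage: scoring
    sel = DecileSelection(r=config.r, m=config.m)
    if config.dev_stats == "packaged":
        dev = development_s_u(r=config.r, m=config.m)
    elif config.dev_stats == "self":
        dev = None
    else:
        dev = pd.read_csv(config.dev_stats)["s_u"].to_numpy()
    try:
        cases, meta = score_cohort(cohort.patch_scores, sel=sel, dev_s_u=dev)
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc
    cases.to_csv(out / "case_scores.csv", index=False)
    tm = meta["threshold_model"]
    qc = meta["midrange_qc"]
    report["scoring"] = {
        "n_cases": len(cases),
        "risk_group_counts": cases["risk_group"].value_counts().to_dict(),
        "threshold_model": dataclasses.asdict(tm),
        "cohort_adjustment": dataclasses.asdict(meta["adjustment"]),
        "midrange_qc": dataclasses.asdict(qc),
        "r": config.r,
        "m": config.m,
        "dev_stats": str(config.dev_stats),
    }
    if not qc.passed:
        log.warning(
            "midrange QC failed: median MR_r=%.3f MR_m=%.3f (refs %.2f/%.2f)",
            qc.median_mr_r, qc.median_mr_m, qc.reference_mr_r, qc.reference_mr_m,
        )

    # stage: survival
    merged = cohort.survival.merge(
        cases[["case_id", "s_csd", "risk_group"]], on="case_id", how="inner"
    )
    surv_report: dict[str, Any] = {}
    try:
        if merged["event"].sum() >= 1 and merged["risk_group"].nunique() == 2:
            km = km_estimate(
                merged["time_months"], merged["event"], merged["risk_group"]
            )
            surv_report["km_median_months"] = {
                g: est.median for g, est in km.items()
            }
            chi2, p = logrank(
                merged["time_months"], merged["event"], merged["risk_group"]
            )
            surv_report["logrank"] = {"chi2": chi2, "p": p}
            uni = cox_fit(merged, covariates=["risk_group"])
            surv_report["cox_univariate"] = {
                "summary": uni.summary.to_dict(orient="index"),
                "aic": uni.aic,
                "bic": uni.bic,
            }
            multi_covs = ["risk_group"] + [
                c for c in ("age",) if c in merged.columns
            ]
            if len(multi_covs) > 1:
                multi = cox_fit(merged, covariates=multi_covs)
                surv_report["cox_multivariate"] = {
                    "summary": multi.summary.to_dict(orient="index"),
                    "aic": multi.aic,
                    "bic": multi.bic,
                    "vif": multi.vif.to_dict(),
                }
            surv_report["c_index"] = c_index(
                merged["s_csd"], merged["time_months"], merged["event"]
            )
        else:
            surv_report["skipped"] = "needs >=1 event and both risk groups"
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc
    report["survival"] = surv_report

    # stage: associations
    try:
        if len(cohort.signatures):
            risk = cases.set_index("case_id")["risk_group"]
            assoc = reproduce_signature_screen(
                risk,
                cohort.signatures,
                screen_alpha=config.screen_alpha,
                fdr=config.fdr,
            )
            report["associations"] = [dataclasses.asdict(a) for a in assoc]
        else:
            report["associations"] = []
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
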