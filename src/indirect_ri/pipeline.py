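"""End-to-end orchestration: simulate → clean → transfer → GMM/SOM → RI → bias.

A run is a pure function of its :class:`RunConfig`: all randomness derives
from ``config.seed``, and the machine-readable report embeds a hash of the
config so reruns can be verified.  Stage-wise record counts (the flow-chart
numbers of a cleaning protocol) are logged at INFO and stored in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cleaning, gmm, ri, som
from .data_model import Dataset, Stratum, cleaning_scheme, default_scheme
from .io import write_records
from .synthetic import default_study_spec, generate_direct, generate_lis
from .transference import roche_to_beckman, transfer_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    outdir: str = "indirect_ri_run"
    seed: int = 0
    n_direct: int = 5000         # direct subjects per stratum
    n_lis: int = 5000            # LIS subjects per stratum
    radical: bool = False        # radical multi-analyte outlier exclusion (LIS)
    gmm_tol: float = 1e-8
    gmm_max_iter: int = 500
    som_max_iter: int = 200
    som_kernel_width: float = 1.0
    skew_threshold: float = cleaning.DEFAULT_SKEW_THRESHOLD
    age_lo: float = 1.0
    age_hi: float = 17.0
    write_outputs: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Child seeds below 2^31, deterministic in the master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s >> 1) for s in state]


def _gmm_stage(lis_clean: Dataset, direct_transferred: Dataset,
               scheme: list[Stratum], config: RunConfig) -> tuple[Dataset, dict]:
    """Per-stratum GMM partitioning; returns the healthy Dataset and params."""
    selected = pd.Series(False, index=lis_clean.df.index)
    params: dict[str, dict] = {}
    for s in scheme:
        smask = lis_clean.mask_for(s)
        lis_vals = lis_clean.df.loc[smask, "value"].to_numpy(float)
        direct_vals = direct_transferred.values_for(s)
        if lis_vals.size < 50 or direct_vals.size < 20:
            logger.warning("GMM: stratum %r too small, skipped", s.label)
            continue
        fit, labels, mask = gmm.partition_stratum(
            lis_vals, direct_vals, tol=config.gmm_tol,
            max_iter=config.gmm_max_iter)
        idx = lis_clean.df.index[smask]
        selected.loc[idx[mask]] = True
        params[s.label] = {
            "weights": fit.weights.tolist(), "means": fit.means.tolist(),
            "sds": fit.sds.tolist(), "n_iter": fit.n_iter,
            "converged": bool(fit.converged),
            "healthy_fraction_of_input": float(mask.mean()),
        }
    return lis_clean.subset(selected), params


def _som_stage(lis_clean: Dataset, scheme: list[Stratum],
               config: RunConfig) -> tuple[Dataset, dict]:
    """Per-reporting-stratum SOM on renal triples; healthy Dataset + params.

    For each stratum the SOM is fitted on the complete (creatinine, urea,
    uric acid) triples of subjects inside the stratum's age/sex band; the
    middle node's subjects contribute their records of the stratum's analyte.
    """
    selected = pd.Series(False, index=lis_clean.df.index)
    params: dict[str, dict] = {}
    for s in scheme:
        band = lis_clean.mask_for(s, match_analyte=False)
        vectors = som.build_vectors(lis_clean.subset(band))
        if len(vectors) < 50:
            logger.warning("SOM: stratum %r too small, skipped", s.label)
            continue
        fit, healthy_ids = som.partition_triples(
            vectors, max_iter=config.som_max_iter,
            kernel_width0=config.som_kernel_width)
        df = lis_clean.df
        take = band & (df["analyte"] == s.analyte) & df["subject_id"].isin(healthy_ids)
        selected |= take
        counts = np.bincount(fit.assignments, minlength=3)
        params[s.label] = {
            "codebooks_scaled": fit.codebooks.tolist(),
            "codebooks_raw": som.inverse_scale(
                fit.codebooks, fit.center, fit.scale).tolist(),
            "node_counts": counts.tolist(), "n_iter": fit.n_iter,
            "converged": bool(fit.converged),
            "normal_fraction_of_input": float(len(healthy_ids) / len(vectors)),
        }
    return lis_clean.subset(selected), params


def run_all(config: RunConfig) -> dict:
    """Execute the full study emulation and return the report bundle.

    The bundle holds stage counts, per-stratum GMM/SOM parameters, selected
    healthy fractions (per analyte, measured against the generated LIS
    subjects), the comparison tables (summaries / intervals / bias / density
    curves) and the config hash.  With ``config.write_outputs`` the
    intermediate CSVs and a JSON report are written under ``config.outdir``.
    """
    scheme = default_scheme()
    spec = default_study_spec()
    s_direct, s_lis, s_ri = _derive_seeds(config.seed, 3)

    logger.info("stage 1/6: simulate (seed=%d)", config.seed)
    direct_raw, truth_direct = generate_direct(spec, config.n_direct, s_direct)
    lis_raw, truth_lis = generate_lis(spec, config.n_lis, s_lis)

    logger.info("stage 2/6: clean")
    clean_strata = cleaning_scheme()
    direct_clean, rep_direct = cleaning.clean_dataset(
        direct_raw, clean_strata, age_range=(config.age_lo, config.age_hi),
        skew_threshold=config.skew_threshold)
    lis_clean, rep_lis = cleaning.clean_dataset(
        lis_raw, clean_strata, age_range=(config.age_lo, config.age_hi),
        radical=config.radical, skew_threshold=config.skew_threshold)

    logger.info("stage 3/6: transference (Roche -> Beckman)")
    maps = [roche_to_beckman("creatinine"), roche_to_beckman("urea")]
    direct_transferred = transfer_dataset(direct_clean, maps)

    logger.info("stage 4/6: GMM partitioning")
    gmm_ds, gmm_params = _gmm_stage(lis_clean, direct_transferred, scheme, config)

    logger.info("stage 5/6: SOM partitioning")
    som_ds, som_params = _som_stage(lis_clean, scheme, config)

    logger.info("stage 6/6: reference intervals and bias")
    tables = ri.compare_report(direct_transferred, gmm_ds, som_ds, scheme,
                               seed=s_ri)

    n_subjects = int(lis_raw.df["subject_id"].nunique())
    fractions: dict[str, dict[str, float]] = {}
    for analyte in ("creatinine", "urea"):
        fractions[analyte] = {}
        for name, ds in (("gmm", gmm_ds), ("som", som_ds)):
            sub = ds.df.loc[ds.df["analyte"] == analyte, "subject_id"].nunique()
            fractions[analyte][name] = sub / n_subjects

    report = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "counts": {
            "direct": rep_direct, "lis": rep_lis,
            "lis_subjects_generated": n_subjects,
            "gmm_selected": len(gmm_ds), "som_selected": len(som_ds),
        },
        "healthy_fraction_of_generated": fractions,
        "gmm_params": gmm_params,
        "som_params": som_params,
        "tables": tables,
        "ground_truth_quantiles": {
            f"{k[0]}|{k[1]}": list(v)
            for k, v in truth_lis.healthy_quantiles.items()},
    }

    if config.write_outputs:
        _write_outputs(report, config, direct_transferred, lis_clean,
                       gmm_ds, som_ds, scheme)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_outputs(report: dict, config: RunConfig, direct_transferred: Dataset,
                   lis_clean: Dataset, gmm_ds: Dataset, som_ds: Dataset,
                   scheme: list[Stratum]) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_records(direct_transferred, out / "direct_transferred.csv")
    write_records(lis_clean, out / "lis_cleaned.csv")
    write_records(gmm_ds, out / "healthy_gmm.csv")
    write_records(som_ds, out / "healthy_som.csv")
    tables = report["tables"]
    for name in ("summaries", "intervals", "bias"):
        ri.round_report(tables[name], scheme).to_csv(
            out / f"table_{name}.csv", index=False)
    tables["density"].to_csv(out / "density_curves.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable({k: v for k, v in report.items() if k != "tables"}),
                  fh, indent=2, default=str)
    logger.info("wrote outputs to %s", out)
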