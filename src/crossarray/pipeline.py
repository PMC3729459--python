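"""End-to-end orchestration: simulate -> map -> normalize -> fit -> compare.

A run is described by a :class:`PipelineConfig` (loadable from YAML) and
produces a directory of TSV/JSON artifacts plus a run manifest recording the
seed, configuration, SHA-256 digests of every output, and the headline
numbers (probe-pair count m, significance threshold, d0/s0^2, pi0 and
significant-pair counts per coefficient).  Two runs with the same config and
seed produce byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, downstream, normalization, probe_mapping, synthetic_data
from .exceptions import ConsistencyError, InvalidArgumentError
from .probe_mapping import ProbePairTable
from .synthetic_data import AFFY25, ILMN50, SimulationConfig, StudyDesign, SyntheticTruth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "crossarray_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    K: int = 100
    mid_max: float = 24.0
    term_min: float = 37.0
    max_mismatch: int = 1
    location_threshold: int = 100
    probes_per_probeset: int = 11
    int_offset_c: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        # a single pipeline seed drives every source of randomness
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        designs = sim_raw.pop("study_designs", None)
        sim = SimulationConfig(**sim_raw)
        if designs is not None:
            sim.study_designs = [
                StudyDesign(
                    d["n_pe"],
                    d["n_np"],
                    ga_range_pe=_parse_range(d.get("ga_range_pe", (24.0, 39.0))),
                    ga_range_np=_parse_range(d.get("ga_range_np", (14.0, 42.0))),
                    study_shift_sd=d.get("study_shift_sd", 0.5),
                )
                for d in designs
            ]
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _parse_range(r):
    if isinstance(r, list) and r and isinstance(r[0], (list, tuple)):
        return [(float(a), float(b), int(n)) for a, b, n in r]
    return (float(r[0]), float(r[1]))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate catalog, probes, per-study matrices, metadata and truth."""
    sim = cfg.simulation
    catalog = synthetic_data.generate_catalog(sim.n_transcripts, sim.seq_length, sim.seed)
    affy = synthetic_data.generate_probes(
        catalog, AFFY25, probes_per_probeset=cfg.probes_per_probeset, seed=sim.seed
    )
    ilmn = synthetic_data.generate_probes(catalog, ILMN50, seed=sim.seed)
    matrices, metadata, truth = synthetic_data.generate_studies(catalog, sim)

    synthetic_data.write_catalog_fasta(catalog, outdir / "catalog.fasta")
    synthetic_data.write_probes_fasta(affy, outdir / "probes_affy.fasta")
    synthetic_data.write_probes_fasta(ilmn, outdir / "probes_ilmn.fasta")
    for s, mat in enumerate(matrices, start=1):
        synthetic_data.write_matrix_tsv(mat, outdir / f"study{s}_matrix.tsv")
    synthetic_data.write_metadata_tsv(metadata, outdir / "metadata.tsv")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "catalog": catalog,
        "affy_probes": affy,
        "ilmn_probes": ilmn,
        "matrices": matrices,
        "metadata": metadata,
        "truth": truth,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline, returning the manifest (also written to
    ``manifest.json`` in the output directory)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "outputs": {},
        "headline": {},
    }
    t0 = time.time()

    def stage_done(name):
        manifest["stages"][name] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.1fs", name, time.time() - t0)

    try:
        sim = simulate_stage(cfg, outdir)
        stage_done("simulate")

        pairs = probe_mapping.map_platform_pairs(
            sim["affy_probes"],
            sim["ilmn_probes"],
            sim["catalog"],
            max_mismatch=cfg.max_mismatch,
            location_threshold=cfg.location_threshold,
        )
        pairs.to_tsv(outdir / "probe_pairs.tsv")
        _write_json(pairs.summary(), outdir / "mapping_summary.json")
        stage_done("map")

        platforms = [AFFY25] * (len(sim["matrices"]) - 1) + [ILMN50]
        # quantile normalization precedes the INT passes as in the source
        # studies' extraction; the INT depends only on within-column ranks,
        # which it preserves, so it is procedural fidelity rather than a
        # numerical necessity here
        normalized = [
            normalization.double_int(normalization.quantile_normalize(m), c=cfg.int_offset_c)
            for m in sim["matrices"]
        ]
        pooled = normalization.align_to_pairs(normalized, pairs, platforms)
        normalization_log = {
            "n_dropped_pairs": pooled.attrs.get("n_dropped_pairs", 0),
            "int_offset_c": cfg.int_offset_c,
        }
        synthetic_data.write_matrix_tsv(pooled, outdir / "pooled_matrix.tsv")
        _write_json(normalization_log, outdir / "normalization_log.json")
        stage_done("normalize")

        design = diffexpr.build_design(sim["metadata"])
        fit = diffexpr.ebayes_moderate(diffexpr.fit_linear(pooled, design))
        m = pairs.m
        threshold, threshold_3sf = diffexpr.bonferroni_threshold(cfg.alpha, m)
        summary: dict = {
            "m": m,
            "alpha": cfg.alpha,
            "bonferroni_threshold": threshold,
            "bonferroni_threshold_3sf": threshold_3sf,
            "d0": fit.d0,
            "s0_sq": fit.s0_sq,
        }
        results = {}
        for coef in ("pe", "ga_weeks"):
            if coef not in fit.coef_names:
                continue
            frame = fit.coefficient_frame(coef, m=m, alpha=cfg.alpha)
            frame.to_csv(outdir / f"results_{coef}.tsv", sep="\t", float_format="%.6g")
            results[coef] = frame
            counts = diffexpr.summarize_transcript_level(frame, pairs, alpha=cfg.alpha)
            pi0 = diffexpr.estimate_pi0(frame["p"].to_numpy(), coefficient=coef)
            summary[coef] = {**counts, "pi0": pi0.pi0, "frac_de": 1.0 - pi0.pi0}

        # interaction model fitted separately; main effects always reported
        # from the no-interaction model
        design_int = diffexpr.build_design(sim["metadata"], include_interaction=True)
        fit_int = diffexpr.ebayes_moderate(diffexpr.fit_linear(pooled, design_int))
        if "pe_x_ga" in fit_int.coef_names:
            inter = fit_int.coefficient_frame("pe_x_ga", m=m, alpha=cfg.alpha)
            summary["pe_x_ga"] = {
                "n_significant_pairs": int((inter["bonferroni_p"] < cfg.alpha).sum())
            }
        _write_json(summary, outdir / "fit_summary.json")
        stage_done("fit")

        # GA model comparison on the control-only first study
        meta1 = sim["metadata"][sim["metadata"]["study"] == 1]
        study1_cols = [c for c in normalized[0].columns if c in set(meta1["sample_id"])]
        ga_cmp = downstream.compare_ga_models(
            normalized[0][study1_cols], meta1, mid_max=cfg.mid_max, term_min=cfg.term_min
        )
        ga_cmp.table.to_csv(outdir / "ga_comparison.tsv", sep="\t", float_format="%.6g")
        _write_json(
            {"pearson_r": ga_cmp.r, "n_features": ga_cmp.n_features,
             "n_excluded_samples": ga_cmp.n_excluded_samples},
            outdir / "ga_comparison.json",
        )
        stage_done("compare-ga")

        # cross-study concordance: per-study refits vs the pooled analysis
        study_of = pooled.attrs["study_of_sample"]
        conc: dict = {}
        for s, samples in study_of.items():
            sub_meta = sim["metadata"][sim["metadata"]["sample_id"].isin(samples)]
            sub_fit = downstream.per_study_fit(pooled[samples], sub_meta)
            for coef in ("pe", "ga_weeks"):
                if coef in sub_fit.coef_names and coef in fit.coef_names:
                    rep = downstream.concordance(sub_fit, fit, coefficient=coef, K=cfg.K)
                    conc[f"study{s}_vs_pooled_{coef}"] = {
                        "r": rep.r,
                        "shared_top_k": rep.shared_top_k,
                        "a_top_nominal_in_b": rep.a_top_nominal_in_b,
                        "K": rep.K,
                        "n_features": rep.n_features,
                    }
        _write_json(conc, outdir / "concordance.json")
        stage_done("concordance")
    except Exception as exc:
        manifest["failed_stage"] = _next_stage_name(manifest)
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(manifest, outdir / "manifest.json")
        raise

    manifest["headline"] = {
        "m": m,
        "bonferroni_threshold_3sf": threshold_3sf,
        "d0": fit.d0,
        "s0_sq": fit.s0_sq,
        **{
            f"{coef}_{k}": v
            for coef in ("pe", "ga_weeks")
            if coef in summary
            for k, v in summary[coef].items()
        },
        "ga_comparison_r": ga_cmp.r,
    }
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    _write_json(manifest, outdir / "manifest.json")
    return manifest


_STAGE_ORDER = ["simulate", "map", "normalize", "fit", "compare-ga", "concordance"]


def _next_stage_name(manifest: dict) -> str:
    done = set(manifest["stages"])
    for name in _STAGE_ORDER:
        if name not in done:
            return name
    return "finalize"


def evaluate_against_truth(
    results: pd.DataFrame,
    pairs: ProbePairTable,
    truth: SyntheticTruth,
    coefficient: str = "pe",
    alpha: float = 0.05,
) -> dict:
    """Score calls against simulation ground truth.

    ``results`` is a coefficient frame indexed by pair id with columns
    ``beta`` and ``bonferroni_p``.  Sensitivity is the fraction of truly-DE
    pairs called; FDR is the false fraction among Bonferroni-significant
    calls; both are ``None`` when their denominator is empty.  beta RMSE is
    over truly-DE pairs; the pi0 error compares the convex-density estimate
    (from the nominal p-values if present) with the truth.
    """
    lookup = pairs.table.copy()
    lookup.index = pairs.pair_ids
    lookup = lookup[~lookup.index.duplicated()]
    unknown = results.index.difference(lookup.index)
    if len(unknown):
        raise ConsistencyError(f"pair ids absent from pair table: {list(unknown[:5])}")

    tmap = dict(zip(truth.transcript_ids, range(len(truth.transcript_ids))))
    tids = lookup.loc[results.index, "transcript_id"]
    missing = [t for t in tids if t not in tmap]
    if missing:
        raise ConsistencyError(f"transcripts absent from truth: {missing[:5]}")
    idx = np.array([tmap[t] for t in tids])

    is_de = (truth.is_de_pe if coefficient == "pe" else truth.is_de_ga)[idx]
    beta_true = (truth.beta_pe if coefficient == "pe" else truth.beta_ga)[idx]
    called = (results["bonferroni_p"] < alpha).to_numpy()

    tp = int((called & is_de).sum())
    fp = int((called & ~is_de).sum())
    sensitivity = tp / int(is_de.sum()) if is_de.any() else None
    fdr = fp / (tp + fp) if (tp + fp) > 0 else None
    rmse = (
        float(np.sqrt(np.mean((results["beta"].to_numpy()[is_de] - beta_true[is_de]) ** 2)))
        if is_de.any()
        else None
    )
    out = {
        "coefficient": coefficient,
        "n_pairs": int(len(results)),
        "n_true_de": int(is_de.sum()),
        "n_called": int(called.sum()),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "beta_rmse_de": rmse,
    }
    if "p" in results.columns:
        pi0_hat = diffexpr.estimate_pi0(results["p"].to_numpy()).pi0
        pi0_true = 1.0 - float(is_de.mean())
        out["pi0_hat"] = pi0_hat
        out["pi0_true"] = pi0_true
        out["pi0_error"] = pi0_hat - pi0_true
    return out
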