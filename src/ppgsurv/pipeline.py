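"""End-to-end orchestration: simulate -> preprocess -> train -> fit -> evaluate.

A run is fully determined by a :class:`RunConfig` (sizes, seeds, model
list, comparison pairs).  Stages are leakage-disciplined by construction:
the extractor, the PCA, the covariate scalers and the ridge penalty see
only train/tune data, and the test split is touched exclusively by the
evaluation stage.  Every stage records the participant ids it consumed,
and :func:`assert_no_leakage` checks the discipline automatically.

Outputs are plain JSON/CSV files plus a manifest with config and
checksums; rerunning with the same config and seed reproduces them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from .cohort import (SimParams, SyntheticCohort, apply_inclusion_rules,
                     geographic_split, oracle_cstat, simulate_cohort)
from .extractor import (ExtractorConfig, PPG_FEATURES, PulseFeatureExtractor,
                        dls_feature_frame, fit_pca, project)
from .interpret import DlsWaveformScorer
from .morphology import morphology_table
from .survival import (FEATURE_SETS, DEFAULT_RIDGE_GRID,
                       resolve_feature_set, sbp140_score, tune_ridge)
from .waveform import pad_batch, preprocess_waves

DEFAULT_FEATURE_SETS = ("metadata", "office_refit_who", "dls")
DEFAULT_COMPARISONS = (("dls", "office_refit_who"),
                       ("metadata", "office_refit_who"))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n: int = 12000
    sim: dict = field(default_factory=dict)          # SimParams overrides
    extractor: dict = field(default_factory=dict)    # ExtractorConfig overrides
    ridge_grid: tuple = DEFAULT_RIDGE_GRID
    feature_sets: tuple = DEFAULT_FEATURE_SETS
    comparisons: tuple = DEFAULT_COMPARISONS
    margin: float = 2.5
    n_permutations: int = 1000
    n_bootstrap: int = 1000

    def validate(self) -> None:
        for name in self.feature_sets:
            if name not in FEATURE_SETS:
                raise ValueError(f"unknown feature set {name!r}")
        for new, ref in self.comparisons:
            for name in (new, ref):
                if name not in self.feature_sets and name != "sbp140":
                    raise ValueError(
                        f"comparison references unfitted model {name!r}")


def _stage_seed(seed: int, stage: str) -> int:
    """Named per-stage substream of the single global seed (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _ids_digest(ids) -> str:
    arr = np.sort(np.asarray(ids, dtype=np.int64))
    return hashlib.sha256(arr.tobytes()).hexdigest()[:16]


@dataclass
class RunResult:
    """Everything a completed run produced, in memory."""

    config: RunConfig
    cohort: SyntheticCohort
    splits: dict
    tables: dict                     # split -> feature DataFrame
    extractor_results: object
    pca: object
    models: dict                     # name -> (penalty, CoxRidgeResults)
    metrics: dict
    comparisons: dict
    provenance: dict                 # stage -> set of participant ids
    exclusion_log: dict
    timings: dict

    def scorer(self, at_age_years: float | None = None) -> DlsWaveformScorer:
        """Waveform-differentiable DLS log-partial-hazard scorer."""
        _, res = self.models["dls"]
        return DlsWaveformScorer.from_results(
            self.extractor_results.network, self.pca, res,
            at_age_years=at_age_years)


def assert_no_leakage(result: RunResult) -> None:
    """No test-split id may have reached a fitting stage."""
    test_ids = set(result.provenance["evaluate"])
    for stage in ("extractor_train", "extractor_tune", "pca",
                  "scaler", "ridge_tune"):
        overlap = test_ids & set(result.provenance[stage])
        if overlap:
            raise AssertionError(
                f"leakage: {len(overlap)} test ids reached stage {stage}")


def run_pipeline(config: RunConfig | None = None,
                 out_dir: str | Path | None = None,
                 verbose: bool = False) -> RunResult:
    """Execute the full pipeline; optionally write artifacts to out_dir."""
    cfg = config or RunConfig()
    cfg.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # -- simulate ----------------------------------------------------------
    sim = SimParams(n=cfg.n, seed=_stage_seed(cfg.seed, "simulate"),
                    **cfg.sim)
    cohort = simulate_cohort(sim)
    cohort, exclusion_log = apply_inclusion_rules(cohort)
    splits = geographic_split(cohort)
    timings["simulate"] = time.perf_counter() - t0

    # -- preprocess --------------------------------------------------------
    t1 = time.perf_counter()
    uniform = preprocess_waves(cohort.waves)
    batches = {name: pad_batch([uniform[i] for i in idx],
                               ids=cohort.table["id"].to_numpy()[idx])
               for name, idx in splits.items()}
    frames = {name: cohort.table.iloc[idx].reset_index(drop=True)
              for name, idx in splits.items()}
    timings["preprocess"] = time.perf_counter() - t1

    # -- train extractor ---------------------------------------------------
    t1 = time.perf_counter()
    ext_cfg = ExtractorConfig(seed=_stage_seed(cfg.seed, "extractor"),
                              **cfg.extractor)
    model = PulseFeatureExtractor(
        batches["train"], frames["train"]["time"], frames["train"]["event"],
        batches["tune"], frames["tune"]["time"], frames["tune"]["event"],
        config=ext_cfg)
    ext = model.fit(verbose=verbose)
    timings["train_extractor"] = time.perf_counter() - t1

    # -- embed + PCA + morphology ------------------------------------------
    t1 = time.perf_counter()
    emb = {name: ext.compute_embeddings(batches[name]) for name in batches}
    pca = fit_pca(emb["train"], k=5)
    need_morph = any(fs == "metadata_morph" for fs in cfg.feature_sets)
    for name in frames:
        scores = project(emb[name], pca)
        feats = dls_feature_frame(scores, frames[name]["pulse_rate"],
                                  frames[name]["id"])
        frames[name] = frames[name].merge(
            feats.drop(columns=["ppg_hr"]), on="id")
        if need_morph:
            idx = splits[name]
            morph = morphology_table(
                [uniform[i] for i in idx],
                cohort.table["id"].to_numpy()[idx],
                heights_m=cohort.table["height"].to_numpy()[idx])
            morph["notch_present"] = morph["notch_present"].astype(float)
            frames[name] = frames[name].merge(morph, on="id",
                                              suffixes=("", "_morph"))
    timings["embed"] = time.perf_counter() - t1

    # -- fit survival models ------------------------------------------------
    t1 = time.perf_counter()
    models: dict[str, tuple] = {}
    for name in cfg.feature_sets:
        fs = resolve_feature_set(name, frames["train"])
        if fs.rule is not None:
            models[name] = (None, None)
            continue
        lam, res, _ = tune_ridge(frames["train"], frames["tune"],
                                 list(fs.features), grid=cfg.ridge_grid,
                                 interactions=list(fs.interactions))
        models[name] = (lam, res)
    timings["fit"] = time.perf_counter() - t1

    # -- evaluate on test ---------------------------------------------------
    t1 = time.perf_counter()
    test = frames["test"]
    times_t = test["time"].to_numpy()
    events_t = test["event"].to_numpy()
    labels = M.ten_year_label(times_t, events_t)
    seed_eval = _stage_seed(cfg.seed, "evaluate")

    preds, lps = {}, {}
    for name, (lam, res) in models.items():
        if res is None:
            preds[name] = sbp140_score(test["sbp"])
            lps[name] = preds[name]
        else:
            preds[name] = res.predict_10yr_risk(test)
            lps[name] = res.predict_lp(test)

    sbp_rule = sbp140_score(test["sbp"])
    metrics_out: dict = {"oracle_c": oracle_cstat(cohort.subset(splits["test"])),
                         "oracle_c_metadata": oracle_cstat(
                             cohort.subset(splits["test"]), drop_latent=True)}
    per_model = {}
    for name in preds:
        entry = {}
        # complete-case evaluation subset for feature sets with missingness
        ok = np.isfinite(np.asarray(lps[name], dtype=float))
        entry["n_eval"] = int(ok.sum())
        c = M.harrell_c(times_t[ok], events_t[ok], lps[name][ok],
                        bootstrap=cfg.n_bootstrap, seed=seed_eval)
        entry["c_statistic"] = dataclasses.asdict(c)
        if models[name][1] is not None:
            entry["ridge_penalty"] = models[name][0]
            try:
                cal = M.calibration(preds[name][ok], times_t[ok],
                                    events_t[ok])
                entry["calibration_slope"] = cal.slope
                entry["calibration_mae"] = cal.mean_abs_error
            except ValueError:
                pass
            for target in ("sensitivity", "specificity"):
                thr = M.match_threshold(sbp_rule[ok], labels[ok],
                                        preds[name][ok], target=target)
                se, sp = M.sens_spec(labels[ok], preds[name][ok], thr)
                entry[f"matched_{target}_threshold"] = thr
                entry[f"sens_at_matched_{target}"] = se.estimate
                entry[f"spec_at_matched_{target}"] = sp.estimate
        per_model[name] = entry
    metrics_out["models"] = per_model

    comparisons = {}
    for new, ref in cfg.comparisons:
        # paired comparison on subjects where both scores are defined
        ok = (np.isfinite(np.asarray(lps[new], dtype=float))
              & np.isfinite(np.asarray(lps[ref], dtype=float)))
        comp = compare_models(lps[new][ok], lps[ref][ok], preds[new][ok],
                              preds[ref][ok], times_t[ok], events_t[ok],
                              labels[ok], sbp_rule[ok], margin=cfg.margin,
                              n_perm=cfg.n_permutations, seed=seed_eval)
        comp["n_eval"] = int(ok.sum())
        comparisons[f"{new}_vs_{ref}"] = comp
    timings["evaluate"] = time.perf_counter() - t1

    provenance = {
        "extractor_train": frames["train"]["id"].tolist(),
        "extractor_tune": frames["tune"]["id"].tolist(),
        "pca": frames["train"]["id"].tolist(),
        "scaler": frames["train"]["id"].tolist(),
        "ridge_tune": frames["tune"]["id"].tolist(),
        "evaluate": frames["test"]["id"].tolist(),
    }
    timings["total"] = time.perf_counter() - t0

    result = RunResult(config=cfg, cohort=cohort, splits=splits,
                       tables=frames, extractor_results=ext, pca=pca,
                       models=models, metrics=metrics_out,
                       comparisons=comparisons, provenance=provenance,
                       exclusion_log=exclusion_log, timings=timings)
    assert_no_leakage(result)
    if out_dir is not None:
        write_run(result, Path(out_dir))
    return result


def compare_models(lp_new, lp_ref, pred_new, pred_ref, times, events,
                   labels, sbp_rule, margin=2.5, n_perm=1000, seed=0) -> dict:
    """Paired comparison report: delta C, non-inferiority/superiority
    p-values, cfNRI components, and NRI at SBP-140-matched thresholds."""
    noninf = M.permutation_noninferiority(lp_ref, lp_new, times, events,
                                          margin=margin, n_perm=n_perm,
                                          seed=seed)
    overall, ev, ne = M.cfnri(lp_ref, lp_new, labels)
    out = {"delta_c_pct": noninf.delta,
           "p_noninferiority": noninf.p_noninferiority,
           "p_superiority": noninf.p_superiority,
           "margin_pct": margin,
           "cfnri_pct": overall, "cfnri_event_pct": ev,
           "cfnri_nonevent_pct": ne}
    for target in ("sensitivity", "specificity"):
        try:
            thr_new = M.match_threshold(sbp_rule, labels, pred_new, target)
            thr_ref = M.match_threshold(sbp_rule, labels, pred_ref, target)
        except ValueError:
            continue
        n_overall, n_ev, n_ne = M.cfnri(
            (np.asarray(pred_ref) >= thr_ref).astype(float),
            (np.asarray(pred_new) >= thr_new).astype(float), labels)
        out[f"nri_at_matched_{target}_pct"] = n_overall
        out[f"nri_event_at_matched_{target}_pct"] = n_ev
        out[f"nri_nonevent_at_matched_{target}_pct"] = n_ne
    return out


# ---------------------------------------------------------------------------
# Artifact writing / manifest
# ---------------------------------------------------------------------------

def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_run(result: RunResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = {"schema_version": 1, **result.metrics}
    (out_dir / "metrics.json").write_text(
        json.dumps(metrics, indent=2, default=float))
    (out_dir / "comparisons.json").write_text(
        json.dumps(result.comparisons, indent=2, default=float))
    (out_dir / "exclusions.json").write_text(
        json.dumps(result.exclusion_log, indent=2))
    test = result.tables["test"]
    median_event_age = float(
        result.tables["train"].loc[lambda d: d["event"] == 1, "age"].median())
    coefs = {"median_event_age": median_event_age}
    cal_rows = []
    for name, (lam, res) in result.models.items():
        if res is None:
            continue
        coefs[name] = {
            "model": res.to_dict(),
            "hazard_ratios_at_median_event_age":
                res.hazard_ratios(at_age_years=median_event_age).to_dict(),
        }
        preds = res.predict_10yr_risk(test)
        ok = np.isfinite(preds)
        try:
            cal = M.calibration(preds[ok], test["time"].to_numpy()[ok],
                                test["event"].to_numpy()[ok])
        except (ValueError, TypeError):
            continue
        for p, o in zip(cal.bin_pred, cal.bin_obs):
            cal_rows.append({"model": name, "predicted": p, "observed": o})
    (out_dir / "coefficients.json").write_text(
        json.dumps(coefs, indent=2, default=float))
    pd.DataFrame(cal_rows).to_csv(out_dir / "calibration_bins.csv",
                                  index=False)
    _write_km_curves(result, out_dir)


def _write_km_curves(result: RunResult, out_dir: Path) -> None:
    """Kaplan-Meier curves for DLS-defined high/low risk groups."""
    from .survival import kaplan_meier
    if "dls" not in result.models or result.models["dls"][1] is None:
        return
    test = result.tables["test"]
    entry = result.metrics["models"]["dls"]
    thr = entry.get("matched_specificity_threshold")
    if thr is None:
        return
    preds = result.models["dls"][1].predict_10yr_risk(test)
    rows = []
    for label, mask in (("high", preds >= thr), ("low", preds < thr)):
        if mask.sum() == 0:
            continue
        km = kaplan_meier(test["time"].to_numpy()[mask],
                          test["event"].to_numpy()[mask])
        for t, s in zip(km.x, km.y):
            rows.append({"risk_group": label, "time_days": t, "survival": s})
    pd.DataFrame(rows).to_csv(out_dir / "km_risk_groups.csv", index=False)
    result.extractor_results.training_log.to_csv(
        out_dir / "training_log.csv", index=False)
    prov_digest = {k: _ids_digest(v) for k, v in result.provenance.items()}
    manifest = {
        "config": dataclasses.asdict(result.config),
        "timings_s": {k: round(v, 2) for k, v in result.timings.items()},
        "provenance_id_digests": prov_digest,
        "split_sizes": {k: int(len(v)) for k, v in result.splits.items()},
        "files": {},
    }
    for f in sorted(out_dir.glob("*.json")) + sorted(out_dir.glob("*.csv")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _sha(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def verify_run(out_dir: Path) -> bool:
    """Re-check the manifest's file checksums."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        if _sha(out_dir / name) != digest:
            raise AssertionError(f"checksum mismatch for {name}")
    return True
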