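"""End-to-end cohort pipeline: preprocessing through group statistics.

``run_pipeline`` walks a manifest of recordings and runs, per recording and
for both the raw magnitude series and its median-binarized counterpart:
stationarity screening, multiscale entropy (ApEn/SampEn/expSampEn), DFA,
FNN (with a cohort-median delay per data type), and IAAFT surrogate
comparisons; it then assembles the cohort-level group statistics. Every
stage failure is recorded per recording rather than aborting the run, and
the whole pipeline is deterministic given the configuration seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dfa import dfa as run_dfa
from . import embedding, entropy, group_stats, io, stationarity, surrogate
from .errors import ParameterError, SleepdynError
from .preprocess import binarize_median, moving_average, preprocess_recording
from .synthetic import GeneratorConfig, gen_cohort

log = logging.getLogger("sleepdyn")


@dataclass
class PipelineConfig:
    """All pipeline constants, with the defaults used throughout the package."""

    # entropy
    m: int = 2
    r: float = 0.2
    scales: tuple = (30, 100, 300)
    # FNN
    fnn_threshold_A: float = 10.0
    fnn_threshold_B: float = 2.0
    fnn_d_max: int = 10
    run_fnn: bool = True
    # surrogates
    n_surrogates: int = 20
    surrogate_max_iter: int = 100
    run_surrogates: bool = True
    welch_segment: int = 2048
    welch_overlap: float = 0.5
    # DFA (5 min - 2 h at 1 Hz)
    dfa_fit_min: int = 300
    dfa_fit_max: int = 7200
    # preprocessing
    onset_threshold: float = 0.1
    onset_run: int = 600
    window_seconds: int = 28_800
    # statistics
    smoothing_window: int = 3600
    alpha_level: float = 0.05
    bins_raw: int = 5
    bins_binary: int = 2
    # reproducibility
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["scales"] = list(d["scales"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in data:
            data["scales"] = tuple(data["scales"])
        return cls(**data)


@dataclass
class CohortResult:
    status: pd.DataFrame
    stationarity: pd.DataFrame
    entropy: pd.DataFrame
    dfa: pd.DataFrame
    fnn: pd.DataFrame
    surrogate_tests: pd.DataFrame
    pointwise: dict            # (data_type, scale) -> PointwiseTestTrack
    representatives: pd.DataFrame
    representative_tests: pd.DataFrame
    spearman: pd.DataFrame
    tracks: dict               # (group, subject, night, data_type, scale) -> smoothed track

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("status", "stationarity", "entropy", "dfa", "fnn",
                     "surrogate_tests", "representatives",
                     "representative_tests", "spearman"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        rows = []
        for (data_type, scale), track in self.pointwise.items():
            for t, tt, p, sig in zip(track.time, track.t_stat, track.p_value,
                                     track.significant_lower_B):
                rows.append({"data_type": data_type, "scale": scale, "t": t,
                             "t_stat": tt, "p": p, "significant_lower_B": sig})
        pd.DataFrame(rows).to_csv(out / "pointwise.csv", index=False)


def _load_series(cfg: PipelineConfig, data_dir: Path, row) -> np.ndarray:
    path = data_dir / str(row["path"])
    if row["kind"] == io.KIND_RAW32:
        raw = io.read_raw_recording(path)
        return preprocess_recording(raw, duration=cfg.window_seconds,
                                    onset_threshold=cfg.onset_threshold,
                                    onset_run=cfg.onset_run).values
    values = io.read_series(path)
    if len(values) < cfg.window_seconds:
        raise SleepdynError(
            f"{path}: {len(values)} samples, expected >= {cfg.window_seconds}")
    return values[: cfg.window_seconds]


def run_pipeline(config: PipelineConfig, manifest: pd.DataFrame,
                 data_dir) -> CohortResult:
    if len(manifest) == 0:
        raise ParameterError("empty manifest")
    data_dir = Path(data_dir)

    status_rows = []
    stat_rows, ent_rows, dfa_rows, fnn_rows = [], [], [], []
    surrogate_metric_rows = []
    tracks = {}
    series_store = {}   # key -> {'raw': arr, 'thr': arr}
    spearman_recs = []

    # ---- per-recording stages (FNN deferred: needs the cohort median tau)
    for _, row in manifest.iterrows():
        key = (str(row["group"]), int(row["subject"]), int(row["night"]))
        t_start = time.time()
        try:
            values = _load_series(config, data_dir, row)
            binary = binarize_median(values)
            series_store[key] = {"raw": values, "thr": binary.values}

            for data_type, x, bins in (("raw", values, config.bins_raw),
                                       ("thr", binary.values, config.bins_binary)):
                res = stationarity.stationarity_chi2(x, bins)
                stat_rows.append({"group": key[0], "subject": key[1],
                                  "night": key[2], "data_type": data_type,
                                  "statistic": res.statistic, "p": res.p_value,
                                  "rejected": res.rejected})

                profile = entropy.multiscale_profile(
                    x, scales=config.scales, m=config.m, r=config.r)
                for _, prow in profile.iterrows():
                    scale = int(prow["scale"])
                    ent_rows.append({"group": key[0], "subject": key[1],
                                     "night": key[2], "data_type": data_type,
                                     "scale": scale, "apen": prow["apen"],
                                     "sampen": prow["sampen"]})
                    ese = prow["exp_sampen"]
                    if len(ese.values) >= config.smoothing_window:
                        smoothed = group_stats.smooth_60min(
                            ese.values, config.smoothing_window)
                        tracks[key + (data_type, scale)] = smoothed
                    spearman_recs.append(
                        {"key": key, "data_type": data_type, "scale": scale,
                         "series": x, "exp": ese.values})

                d_res = run_dfa(
                    x, fit_range=(config.dfa_fit_min, config.dfa_fit_max))
                dfa_rows.append({"group": key[0], "subject": key[1],
                                 "night": key[2], "data_type": data_type,
                                 "alpha": d_res.alpha,
                                 "r_squared": d_res.r_squared})

                if config.run_surrogates:
                    dt_idx = 0 if data_type == "raw" else 1
                    group_idx = 0 if key[0] == "A" else 1
                    sub_seed = int(np.random.SeedSequence(
                        [config.seed, 7, group_idx, key[1], key[2], dt_idx]
                    ).generate_state(1)[0] % (2 ** 31))
                    ens = surrogate.surrogate_ensemble(
                        x, n=config.n_surrogates, seed=sub_seed,
                        max_iter=config.surrogate_max_iter)
                    for scale in config.scales:
                        params = entropy.EntropyParams(
                            m=config.m, r=config.r, scale=int(scale))
                        orig = entropy.sampen(
                            moving_average(x, int(scale)), params)
                        surr = [entropy.sampen(
                            moving_average(s, int(scale)), params)
                            for s in ens.surrogates]
                        surrogate_metric_rows.append(
                            {"key": key, "data_type": data_type,
                             "scale": int(scale), "original": orig,
                             "surrogate_mean": float(np.mean(surr))})
            status_rows.append({"group": key[0], "subject": key[1],
                                "night": key[2], "status": "ok",
                                "seconds": round(time.time() - t_start, 2),
                                "error": ""})
            log.info("recording %s ok (%.1f s)", key, time.time() - t_start)
        except Exception as exc:  # noqa: BLE001 - robustness contract
            status_rows.append({"group": key[0], "subject": key[1],
                                "night": key[2], "status": "failed",
                                "seconds": round(time.time() - t_start, 2),
                                "error": f"{type(exc).__name__}: {exc}"})
            log.warning("recording %s failed: %s", key, exc)

    if not series_store:
        raise SleepdynError("every recording failed; nothing to analyze")

    # ---- FNN with cohort-median delay per data type ----------------------
    if config.run_fnn:
        for data_type in ("raw", "thr"):
            lags = []
            for key, chans in series_store.items():
                try:
                    lags.append(embedding.autocorr_time(chans[data_type]))
                except SleepdynError:
                    continue
            if not lags:
                continue
            tau = embedding.median_delay(lags)
            params = embedding.EmbeddingParams(
                tau=tau, d_max=config.fnn_d_max,
                threshold_A=config.fnn_threshold_A,
                threshold_B=config.fnn_threshold_B)
            for key, chans in series_store.items():
                try:
                    curve = embedding.fnn_fractions(chans[data_type], params)
                except SleepdynError as exc:
                    log.warning("FNN failed for %s/%s: %s", key, data_type, exc)
                    continue
                for d, t1, t2, comb in zip(curve.dimensions,
                                           curve.fraction_test1,
                                           curve.fraction_test2,
                                           curve.fraction_combined):
                    fnn_rows.append({"group": key[0], "subject": key[1],
                                     "night": key[2], "data_type": data_type,
                                     "tau": tau, "d": int(d),
                                     "test1": t1, "test2": t2,
                                     "combined": comb})

    # ---- surrogate group tests ------------------------------------------
    surr_test_rows = []
    if surrogate_metric_rows:
        sdf = pd.DataFrame(surrogate_metric_rows)
        for (data_type, scale), grp in sdf.groupby(["data_type", "scale"]):
            if len(grp) >= 3:
                cmp_res = surrogate.compare_original_vs_surrogates(
                    grp["original"].to_numpy(), grp["surrogate_mean"].to_numpy())
                surr_test_rows.append({"data_type": data_type, "scale": scale,
                                       "metric": "sampen",
                                       "t": cmp_res.t_stat, "p": cmp_res.p_value,
                                       "direction": cmp_res.direction})

    # ---- group statistics on the smoothed expSampEn tracks ---------------
    pointwise = {}
    rep_rows, rep_test_rows = [], []
    groups = sorted({k[0] for k in series_store})
    for data_type in ("raw", "thr"):
        for scale in config.scales:
            scale = int(scale)
            per_subject = {}   # (group, subject) -> list of tracks
            for key, chans in series_store.items():
                track = tracks.get(key + (data_type, scale))
                if track is None:
                    continue
                per_subject.setdefault((key[0], key[1]), []).append(track)
            subj_tracks = {k: np.mean(np.stack(v), axis=0)
                           for k, v in per_subject.items()}
            by_group = {g: [v for (gg, _), v in sorted(subj_tracks.items())
                            if gg == g] for g in groups}
            if len(groups) == 2 and all(len(by_group[g]) >= 3 for g in groups):
                ga, gb = groups
                pointwise[(data_type, scale)] = group_stats.pointwise_group_ttest(
                    np.stack(by_group[ga]), np.stack(by_group[gb]),
                    alpha=config.alpha_level)
            if data_type == "thr":
                rep_by_group = {g: {"p90": [], "p10": []} for g in groups}
                for (g, subject), track in sorted(subj_tracks.items()):
                    rep = group_stats.representative_values(track, scale=scale)
                    rep_rows.append({"group": g, "subject": subject,
                                     "scale": scale, "p90": rep.p90,
                                     "p10": rep.p10})
                    rep_by_group[g]["p90"].append(rep.p90)
                    rep_by_group[g]["p10"].append(rep.p10)
                if len(groups) == 2 and all(
                        len(rep_by_group[g]["p90"]) >= 3 for g in groups):
                    ga, gb = groups
                    for which in ("p90", "p10"):
                        t, p = group_stats.representative_ttest(
                            rep_by_group[ga][which], rep_by_group[gb][which])
                        rep_test_rows.append({"scale": scale, "which": which,
                                              "t": t, "p_one_tailed": p})

    # ---- Spearman cross-measure table ------------------------------------
    spearman_frames = []
    sp_df = pd.DataFrame(spearman_recs) if spearman_recs else pd.DataFrame()
    if len(sp_df):
        for scale, grp in sp_df.groupby("scale"):
            recs = []
            for key, sub in grp.groupby("key"):
                chans = {}
                for _, r in sub.iterrows():
                    chans[r["data_type"]] = r["series"]
                    chans[f"{r['data_type']}_exp"] = r["exp"]
                recs.append(chans)
            table = group_stats.spearman_table(
                recs, smoothing=config.smoothing_window)
            table.insert(0, "scale", int(scale))
            spearman_frames.append(table)
    spearman = (pd.concat(spearman_frames, ignore_index=True)
                if spearman_frames else pd.DataFrame())

    return CohortResult(
        status=pd.DataFrame(status_rows),
        stationarity=pd.DataFrame(stat_rows),
        entropy=pd.DataFrame(ent_rows),
        dfa=pd.DataFrame(dfa_rows),
        fnn=pd.DataFrame(fnn_rows),
        surrogate_tests=pd.DataFrame(surr_test_rows),
        pointwise=pointwise,
        representatives=pd.DataFrame(rep_rows),
        representative_tests=pd.DataFrame(rep_test_rows),
        spearman=spearman,
        tracks=tracks,
    )


def make_synthetic_demo(out_dir, seed: int | None,
                        n_subjects_per_group: int = 4,
                        nights_per_subject: int = 1,
                        series_length: int = 7200) -> pd.DataFrame:
    """Generate a small synthetic cohort on disk; returns the manifest."""
    if seed is None:
        raise ParameterError("an explicit seed is required")
    gen_cfg = GeneratorConfig(n_subjects_per_group=n_subjects_per_group,
                              nights_per_subject=nights_per_subject,
                              series_length=series_length, seed=seed)
    cohort = gen_cohort(gen_cfg)
    return io.write_cohort(cohort, out_dir)
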