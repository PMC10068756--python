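"""Config-driven orchestration of the full analysis chain.

``run_pipeline`` generates (or loads) paired sessions, computes the
requested stages in dependency order and writes flat TSV/JSON outputs plus
a manifest with content hashes and the seed chain, so identical configs
reproduce identical runs bit for bit.

Stage graph::

    simulate -> fc_static
             -> fc_dynamic -> multimodal
             -> gradients
             -> eeg       -> eeg_stats -> multimodal
    report (reads everything written before it)
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg_stats as es
from . import fc_dynamic as fd
from . import fc_static as fs
from . import gradients as gr
from . import multimodal as mm
from .containers import CORTICAL_NETWORKS, TRANSMODAL_NETWORKS
from .eeg_features import (
    BANDS, epoch_band_power, irasa, band_power, lz_diversity, traveling_waves,
)
from .montage import build_adjacency
from .synthetic import SimConfig, simulate_session, subject_ids

ALL_STAGES = ("fc_static", "fc_dynamic", "gradients", "eeg", "eeg_stats",
              "multimodal", "report")

_KNOWN_KEYS = {
    "out_dir", "seed", "stages", "simulation", "window", "gradient",
    "n_permutations", "gsr", "irasa_factors", "irasa_channels",
    "waves", "multimodal_measures", "post_window_volumes",
}


@dataclass
class RunConfig:
    """Resolved run configuration; unknown keys are rejected up front."""

    out_dir: str = "results/run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    simulation: dict = field(default_factory=dict)
    window: dict = field(default_factory=dict)
    gradient: dict = field(default_factory=dict)
    n_permutations: int = 1000
    gsr: bool = False
    irasa_factors: tuple | None = None
    irasa_channels: tuple | None = None
    waves: bool = True
    multimodal_measures: tuple = ("alpha", "lz")
    post_window_volumes: int = fs.POST_WINDOW_VOLUMES

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.simulation)

    def window_spec(self) -> fd.WindowSpec:
        return fd.WindowSpec(**self.window)

    def gradient_config(self) -> gr.GradientConfig:
        return gr.GradientConfig(**self.gradient)


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------

def subject_features(cfg: SimConfig, run: RunConfig, subject: str) -> dict:
    """All per-subject derived quantities needed by the group stages.

    Raw sessions are generated, reduced, and discarded to bound memory.
    """
    bundle = simulate_session(cfg, subject)
    out: dict = {"subject": subject, "receptor": bundle.receptor_map,
                 "intensity_drug": bundle.intensity_drug,
                 "intensity_placebo": bundle.intensity_placebo}
    part = cfg.partition
    window = slice(cfg.injection_index,
                   min(cfg.injection_index + run.post_window_volumes, cfg.n_volumes))
    baseline = slice(0, cfg.injection_index)
    templates = fs.network_templates(part)
    need_bold = {"fc_static", "fc_dynamic", "gradients", "multimodal"} & set(run.stages)
    need_eeg = {"eeg", "eeg_stats", "multimodal"} & set(run.stages)

    for cond in ("drug", "placebo"):
        if need_bold:
            bold = getattr(bundle, f"bold_{cond}")
            if run.gsr:
                bold = fs.global_signal_regress(bold)
            fc = fs.pairwise_fc(bold, window)
            out[f"fc_{cond}"] = fc
            out[f"gfc_{cond}"] = fs.gfc(fc, part)
            integ = fs.integrity_dual_regression(bold, templates,
                                                 part.present_networks, window)
            out[f"integrity_{cond}"] = integ.pe
            cortical = [n for n in part.present_networks if n in CORTICAL_NETWORKS]
            rows = [part.present_networks.index(n) for n in cortical]
            out[f"segregation_{cond}"] = fs.segregation(
                integ.stage1_timeseries[rows], cortical)
            if "fc_dynamic" in run.stages or "multimodal" in run.stages:
                dfc = fd.dynamic_fc(bold, run.window_spec())
                dg = fd.dynamic_gfc(dfc, part)
                out[f"dgfc_{cond}"] = dg
        if need_eeg:
            eeg = getattr(bundle, f"eeg_{cond}")
            from .eeg_features import DEFAULT_FACTORS

            factors = run.irasa_factors or DEFAULT_FACTORS
            decomp_post = irasa(eeg, window, factors, channels=run.irasa_channels)
            decomp_base = irasa(eeg, baseline, factors, channels=run.irasa_channels)
            out[f"bandpower_{cond}"] = band_power(decomp_post, BANDS, baseline=decomp_base)
            lz_post = lz_diversity(eeg, window)
            lz_base = lz_diversity(eeg, baseline)
            out[f"lzs_{cond}"] = lz_post.lzs - lz_base.lzs
            out[f"lzc_{cond}"] = lz_post.lzc - lz_base.lzc
            out[f"epoch_power_{cond}"] = epoch_band_power(eeg)
            out[f"epoch_lz_{cond}"] = lz_diversity(eeg).counts
            if run.waves and "eeg" in run.stages:
                ws = traveling_waves(
                    eeg, rng=np.random.default_rng([cfg.seed, 77,
                                                    int(subject.split("-")[-1]),
                                                    cond == "drug"]))
                post_t = ws.window_times >= cfg.injection_index * cfg.tr_seconds
                out[f"waves_{cond}"] = {
                    "fw_post": float(ws.fw_db[post_t].mean()),
                    "bw_post": float(ws.bw_db[post_t].mean()),
                    "fw_base": float(ws.fw_db[~post_t].mean()),
                    "bw_base": float(ws.bw_db[~post_t].mean()),
                }
    return out


# ---------------------------------------------------------------------------
# group-level assembly
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _cluster_summary(result) -> dict:
    return {
        "n_permutations": result.n_permutations,
        "threshold": result.threshold,
        "clusters": [
            {"members": list(c.members), "mass": c.mass, "p": c.p_value}
            for c in result.clusters
        ],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the run manifest."""
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.sim_config()
    stages = set(config.stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "multimodal" in stages:
        missing = {"fc_dynamic", "eeg", "eeg_stats"} - stages
        if missing:
            raise ValueError(f"multimodal requires stages {sorted(missing)}")
    if "eeg_stats" in stages and "eeg" not in stages:
        raise ValueError("eeg_stats requires the eeg stage")

    _write_json({"config": _config_dict(config)}, out_dir / "config_resolved.json")
    rng = np.random.default_rng([config.seed, 999])
    subjects = subject_ids(cfg)
    timings = {}
    t0 = time.time()
    feats = [subject_features(cfg, config, s) for s in subjects]
    timings["subjects"] = time.time() - t0
    part = cfg.partition
    nets = part.present_networks
    written: list[Path] = []

    def save_frame(frame: pd.DataFrame, name: str):
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    def save_json(obj, name: str):
        path = out_dir / name
        _write_json(obj, path)
        written.append(path)

    contrasts = {}

    if "fc_static" in stages:
        t0 = time.time()
        integ = pd.DataFrame([
            {"subject": f["subject"], "condition": c, "network": n,
             "pe": f[f"integrity_{c}"][n]}
            for f in feats for c in ("drug", "placebo") for n in nets
        ])
        save_frame(integ, "integrity.tsv")
        drug = np.array([[f["integrity_drug"][n] for n in nets] for f in feats])
        plac = np.array([[f["integrity_placebo"][n] for n in nets] for f in feats])
        res = fs.paired_contrast(drug, plac, nets, family="integrity_networks")
        contrasts["integrity"] = res.to_frame().to_dict("records")

        region_d = np.stack([f["gfc_drug"].region_gfc for f in feats])
        region_p = np.stack([f["gfc_placebo"].region_gfc for f in feats])
        save_frame(pd.DataFrame(region_d - region_p, columns=part.region_labels)
                   .assign(subject=subjects), "gfc_regions.tsv")
        res = fs.paired_contrast(region_d, region_p, part.region_labels,
                                 family="gfc_regions")
        contrasts["gfc_regions"] = res.to_frame().to_dict("records")
        gmap = fs.network_gfc_frame({
            (f["subject"], c): f[f"gfc_{c}"] for f in feats for c in ("drug", "placebo")
        })
        save_frame(gmap, "gfc_networks.tsv")
        wb_d = np.array([[f["gfc_drug"].whole_brain] for f in feats])
        wb_p = np.array([[f["gfc_placebo"].whole_brain] for f in feats])
        res = fs.paired_contrast(wb_d, wb_p, ["whole_brain"], family="gfc_whole_brain")
        contrasts["gfc_whole_brain"] = res.to_frame().to_dict("records")

        cortical = [n for n in nets if n in CORTICAL_NETWORKS]
        iu = np.triu_indices(len(cortical), 1)
        seg_d = np.stack([f["segregation_drug"].to_numpy()[iu] for f in feats])
        seg_p = np.stack([f["segregation_placebo"].to_numpy()[iu] for f in feats])
        pair_names = [f"{cortical[i]}-{cortical[j]}" for i, j in zip(*iu)]
        res = fs.paired_contrast(seg_d, seg_p, pair_names, family="segregation_pairs")
        contrasts["segregation"] = res.to_frame().to_dict("records")
        seg_long = pd.DataFrame(
            {"pair": pair_names * (2 * len(feats)),
             "subject": np.repeat(subjects * 2, len(pair_names)),
             "condition": np.repeat(["drug"] * len(feats) + ["placebo"] * len(feats),
                                     len(pair_names)),
             "pe": np.concatenate([seg_d.ravel(), seg_p.ravel()])})
        save_frame(seg_long, "segregation.tsv")
        timings["fc_static"] = time.time() - t0

    lmm_region = None
    if "fc_dynamic" in stages:
        t0 = time.time()
        centers = feats[0]["dgfc_drug"].window_centers
        inj_sec = cfg.injection_index * cfg.tr_seconds
        cov = np.stack([
            fd.intensity_to_window_grid(
                f["intensity_drug"], centers, inj_sec, cfg.tr_seconds)
            - fd.intensity_to_window_grid(
                f["intensity_placebo"], centers, inj_sec, cfg.tr_seconds)
            for f in feats
        ])
        dgfc_diff = np.stack([
            f["dgfc_drug"].region - f["dgfc_placebo"].region for f in feats
        ])
        lmm_region = fd.lmm_vs_covariate(dgfc_diff, cov, subjects,
                                          part.region_labels, family="regions")
        save_frame(lmm_region.to_frame(), "lmm_results.tsv")
        net_diff = np.stack([
            np.stack([f["dgfc_drug"].network[n] - f["dgfc_placebo"].network[n]
                      for n in nets]) for f in feats
        ])
        lmm_net = fd.lmm_vs_covariate(net_diff, cov, subjects, nets,
                                       family="networks")
        save_frame(lmm_net.to_frame(), "lmm_networks.tsv")

        cluster_out = {}
        wb_d = np.stack([f["dgfc_drug"].whole_brain for f in feats])
        wb_p = np.stack([f["dgfc_placebo"].whole_brain for f in feats])
        cluster_out["whole_brain"] = _cluster_summary(fd.timepoint_cluster_contrast(
            wb_d, wb_p, n_permutations=config.n_permutations, rng=rng))
        for n in nets:
            td = np.stack([f["dgfc_drug"].network[n] for f in feats])
            tp = np.stack([f["dgfc_placebo"].network[n] for f in feats])
            cluster_out[n] = _cluster_summary(fd.timepoint_cluster_contrast(
                td, tp, n_permutations=config.n_permutations, rng=rng))
        save_json(cluster_out, "dgfc_clusters.json")

        r, p = fd.receptor_association(
            lmm_region.beta, feats[0]["receptor"], part.region_labels,
            n_permutations=config.n_permutations, rng=rng)
        contrasts["receptor_association"] = {"r": r, "p": p}
        timings["fc_dynamic"] = time.time() - t0

    if "gradients" in stages:
        t0 = time.time()
        gcfg = config.gradient_config()
        all_fc = [f[f"fc_{c}"] for f in feats for c in ("drug", "placebo")]
        template = gr.group_template(all_fc, gcfg)
        aligned = {
            (f["subject"], c): gr.procrustes_align(
                gr.gradients_from_fc(f[f"fc_{c}"], gcfg), template)
            for f in feats for c in ("drug", "placebo")
        }
        rows = []
        for (subj, cond), gset in aligned.items():
            for k in range(gset.n_components):
                for u, lab in enumerate(gset.unit_labels):
                    rows.append((subj, cond, k + 1, lab, gset.scores[u, k]))
        save_frame(pd.DataFrame(
            rows, columns=["subject", "condition", "component", "unit", "score"]),
            "gradients.tsv")
        contrast = gr.gradient_contrast(
            [aligned[(s, "drug")] for s in subjects],
            [aligned[(s, "placebo")] for s in subjects], part)
        comp = contrast.compression
        sd_d = comp.query("condition == 'drug'")["sd"].to_numpy()
        sd_p = comp.query("condition == 'placebo'")["sd"].to_numpy()
        rng_d = comp.query("condition == 'drug'")["range"].to_numpy()
        rng_p = comp.query("condition == 'placebo'")["range"].to_numpy()
        contrasts["gradient_compression"] = {
            "sd": fs.paired_t(sd_d, sd_p).__dict__,
            "range": fs.paired_t(rng_d, rng_p).__dict__,
        }
        save_json({
            "network_means": contrast.network_means.to_dict("records"),
            "compression": comp.to_dict("records"),
            "unit_stats": contrast.unit_stats.to_dict("records"),
        }, "gradient_contrast.json")
        timings["gradients"] = time.time() - t0

    band_diffs = {}
    lz_diff = None
    if "eeg" in stages:
        t0 = time.time()
        channels = (list(config.irasa_channels) if config.irasa_channels
                    else cfg.eeg_channels)
        rows = []
        for band in BANDS:
            d = np.stack([f["bandpower_drug"][band] for f in feats])
            p = np.stack([f["bandpower_placebo"][band] for f in feats])
            band_diffs[band] = d - p
            for ci, ch in enumerate(channels):
                for si, s in enumerate(subjects):
                    rows.append((s, ch, band, d[si, ci], p[si, ci]))
        save_frame(pd.DataFrame(
            rows, columns=["subject", "channel", "band", "drug", "placebo"]),
            "bandpower.tsv")
        lzs_d = np.stack([f["lzs_drug"] for f in feats])
        lzs_p = np.stack([f["lzs_placebo"] for f in feats])
        lz_diff = lzs_d - lzs_p
        save_frame(pd.DataFrame({
            "subject": subjects,
            "lzc_drug": [f["lzc_drug"] for f in feats],
            "lzc_placebo": [f["lzc_placebo"] for f in feats]}), "lz.tsv")
        res = fs.paired_t([f["lzc_drug"] for f in feats],
                          [f["lzc_placebo"] for f in feats])
        contrasts["lzc"] = res.__dict__
        if config.waves:
            wave_rows = [
                {"subject": f["subject"], "condition": c, **f[f"waves_{c}"]}
                for f in feats for c in ("drug", "placebo")
            ]
            save_frame(pd.DataFrame(wave_rows), "waves.tsv")
            asym = {
                c: np.array([f[f"waves_{c}"]["fw_post"] - f[f"waves_{c}"]["bw_post"]
                             - (f[f"waves_{c}"]["fw_base"] - f[f"waves_{c}"]["bw_base"])
                             for f in feats])
                for c in ("drug", "placebo")
            }
            contrasts["wave_asymmetry"] = fs.paired_t(
                asym["drug"], asym["placebo"]).__dict__
        timings["eeg"] = time.time() - t0

    eeg_cluster_results = {}
    if "eeg_stats" in stages:
        t0 = time.time()
        channels = (list(config.irasa_channels) if config.irasa_channels
                    else cfg.eeg_channels)
        neighbors = build_adjacency(channels)
        cluster_json = {}
        for band, diff in band_diffs.items():
            res = es.channel_cluster_permutation(
                diff, neighbors, n_permutations=config.n_permutations, rng=rng)
            eeg_cluster_results[band] = res
            cluster_json[band] = _cluster_summary(res)
        res = es.channel_cluster_permutation(
            lz_diff, build_adjacency(cfg.eeg_channels),
            n_permutations=config.n_permutations, rng=rng)
        eeg_cluster_results["lz"] = res
        cluster_json["lz"] = _cluster_summary(res)

        # dynamic EEG-intensity association (alpha band + LZ, full channel set)
        inj_sec = cfg.injection_index * cfg.tr_seconds
        epoch_times = (np.arange(cfg.n_volumes) + 0.5) * cfg.tr_seconds
        cov_ep = np.stack([
            np.interp(epoch_times, inj_sec + f["intensity_drug"].times * 60.0,
                      f["intensity_drug"].ratings)
            - np.interp(epoch_times, inj_sec + f["intensity_placebo"].times * 60.0,
                        f["intensity_placebo"].ratings)
            for f in feats
        ])
        full_neighbors = build_adjacency(cfg.eeg_channels)
        dyn_json = {}
        for name, key in (("alpha", "epoch_power_"), ("lz", "epoch_lz_")):
            md = np.stack([
                (f[key + "drug"]["alpha"] if name == "alpha" else f[key + "drug"])
                - (f[key + "placebo"]["alpha"] if name == "alpha" else f[key + "placebo"])
                for f in feats
            ])
            _, res = es.dynamic_eeg_correlation(
                md, cov_ep, full_neighbors,
                n_permutations=config.n_permutations, rng=rng)
            dyn_json[name] = _cluster_summary(res)
        save_json({"condition_clusters": cluster_json,
                   "intensity_correlation_clusters": dyn_json}, "clusters.json")
        timings["eeg_stats"] = time.time() - t0

    if "multimodal" in stages:
        import warnings as _warnings

        from .containers import Cluster, ClusterTestResult

        def selectable(res):
            """Fallback when no cluster formed: rank every channel by |t|."""
            if res.clusters:
                return res
            _warnings.warn("no supra-threshold cluster; selecting the "
                           "top-|t| electrode over the whole montage",
                           RuntimeWarning)
            allc = Cluster(tuple(range(res.t_values.size)), 0.0, 1.0)
            return ClusterTestResult([allc], res.t_values, res.threshold,
                                     res.n_permutations)

        t0 = time.time()
        centers = feats[0]["dgfc_drug"].window_centers
        dgfc_diff = np.stack([
            f["dgfc_drug"].region - f["dgfc_placebo"].region for f in feats
        ])
        fusion_frames = []
        for measure in config.multimodal_measures:
            if measure == "lz":
                res = selectable(eeg_cluster_results["lz"])
                electrodes = mm.select_electrodes(res, cfg.eeg_channels)
                idx = [cfg.eeg_channels.index(e) for e in electrodes]
                traces = {
                    c: [np.nanmean(f[f"epoch_lz_{c}"][idx], axis=0) for f in feats]
                    for c in ("drug", "placebo")
                }
            else:
                res = selectable(eeg_cluster_results[measure])
                channels = (list(config.irasa_channels) if config.irasa_channels
                            else cfg.eeg_channels)
                electrodes = mm.select_electrodes(res, channels)
                # per-epoch power is computed on the full montage
                idx = [cfg.eeg_channels.index(e) for e in electrodes]
                traces = {
                    c: [np.nanmean(f[f"epoch_power_{c}"][measure][idx], axis=0)
                        for f in feats]
                    for c in ("drug", "placebo")
                }
            fused = []
            for si in range(len(feats)):
                fd_ = mm.eeg_to_bold_timecourse(
                    traces["drug"][si], cfg.epoch_seconds, centers,
                    measure=measure, subject=subjects[si])
                fp_ = mm.eeg_to_bold_timecourse(
                    traces["placebo"][si], cfg.epoch_seconds, centers,
                    measure=measure, subject=subjects[si])
                fused.append(mm.FusedTrace(
                    fd_.values - fp_.values, fd_.valid & fp_.valid,
                    centers, measure=measure, subject=subjects[si]))
            lmm = mm.eeg_fmri_lmm(fused, dgfc_diff, part.region_labels, subjects,
                                  family=f"regions_{measure}")
            fusion_frames.append(lmm.to_frame().assign(measure=measure))
            net_traces, net_names = mm.network_dgfc(dgfc_diff, part)
            lmm_net = mm.eeg_fmri_lmm(fused, net_traces, net_names, subjects,
                                      family=f"networks_{measure}")
            fusion_frames.append(lmm_net.to_frame().assign(measure=f"{measure}_networks"))
            contrasts[f"fusion_{measure}"] = {
                "electrodes": electrodes,
                "transmodal_mean_beta": float(np.mean(
                    lmm.beta[part.indicator(TRANSMODAL_NETWORKS)])),
                "n_significant": int((lmm.q < 0.05).sum()),
            }
        save_frame(pd.concat(fusion_frames, ignore_index=True), "fusion_lmm.tsv")
        timings["multimodal"] = time.time() - t0

    save_json(contrasts, "contrasts.json")
    manifest = {
        "seed": config.seed,
        "stages": sorted(stages),
        "n_subjects": cfg.n_subjects,
        "timings_seconds": {k: round(v, 2) for k, v in timings.items()},
        "elapsed_seconds": round(time.time() - t_start, 2),
        "outputs": {p.name: _hash_file(p) for p in sorted(written)},
    }
    _write_json(manifest, out_dir / "manifest.json")
    if "report" in stages:
        make_report(out_dir)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    return d


def make_report(run_dir) -> dict:
    """Summarize a completed run: effect directions and significant families.

    Writes ``report.json`` and a human-readable ``report.txt``; regeneration
    is idempotent.
    """
    run_dir = Path(run_dir)
    contrasts_path = run_dir / "contrasts.json"
    if not contrasts_path.exists():
        raise FileNotFoundError("incomplete run: contrasts.json missing")
    contrasts = json.loads(contrasts_path.read_text())
    report: dict = {"signs": {}, "significant": {}}
    lines = ["analysis summary", "================"]

    if "integrity" in contrasts:
        recs = contrasts["integrity"]
        down = sum(1 for r in recs if r["mean_diff"] < 0)
        sig = sum(1 for r in recs if r["q"] < 0.05)
        report["signs"]["integrity_networks_reduced"] = down
        report["significant"]["integrity"] = sig
        lines.append(f"integrity: {down}/{len(recs)} networks reduced under drug, "
                     f"{sig} significant (q<0.05)")
    if "gfc_whole_brain" in contrasts:
        r = contrasts["gfc_whole_brain"][0]
        report["signs"]["whole_brain_gfc_increase"] = r["mean_diff"] > 0
        lines.append(f"whole-brain GFC: t={r['t']:.2f}, q={r['q']:.4f}, "
                     f"mean diff {r['mean_diff']:+.4f}")
    if "gradient_compression" in contrasts:
        sd = contrasts["gradient_compression"]["sd"]
        report["signs"]["gradient_sd_reduced"] = sd["mean_diff"] < 0
        lines.append(f"principal-gradient SD: mean diff {sd['mean_diff']:+.4f} "
                     f"(t={sd['t']:.2f}, p={sd['p']:.4f})")
    if "lzc" in contrasts:
        r = contrasts["lzc"]
        report["signs"]["lzc_increase"] = r["mean_diff"] > 0
        lines.append(f"LZc (baseline-subtracted): mean diff {r['mean_diff']:+.3f} "
                     f"(t={r['t']:.2f}, p={r['p']:.4f})")
    if "receptor_association" in contrasts:
        r = contrasts["receptor_association"]
        report["receptor_association"] = r
        lines.append(f"receptor-density association: r={r['r']:.3f}, p={r['p']:.4f}")
    for key, val in contrasts.items():
        if key.startswith("fusion_"):
            report[key] = val
            lines.append(f"{key}: electrodes {val['electrodes']}, "
                         f"transmodal mean beta {val['transmodal_mean_beta']:+.4f}")
    _write_json(report, run_dir / "report.json")
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
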