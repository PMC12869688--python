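"""Config-driven orchestration of the full analysis chain.

Stages: ``simulate`` (synthetic cohort to disk), ``preprocess`` + ``spectra``
(time-series mode only), ``maps`` (cohort stack), ``stats`` (permutation-Z
with FDR + blob correction), ``consistency``, ``clinical`` (regression,
variance hotspots, PLS), ``cluster`` (PCA + gap + k-means + MANOVA/ANOVA)
and ``report``.  Every stage writes its artifacts plus a manifest (params,
seed, input hashes, output hashes) so a re-run with unchanged inputs is
bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin_mod
from . import clustering, consistency, io, permstats, preprocess, spectral, synthetic
from .mapping import assemble_power_map, stack_cohort, variance_map
from .types import DEFAULT_FREQS

STAGES = ("simulate", "preprocess", "spectra", "maps", "stats", "consistency",
          "clinical", "cluster", "report", "all")

#: stages whose outputs each stage requires
_REQUIRES = {
    "maps": ["simulate"],
    "stats": ["maps"],
    "consistency": ["maps"],
    "clinical": ["maps", "simulate"],
    "cluster": ["maps", "simulate"],
    "report": ["stats"],
}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults match the analysis conventions
    (1,000-permutation nulls, alpha 0.05, 2-electrode x 3-Hz blobs, top/bottom
    10% variance features, gap statistic over k = 1..10)."""

    out_dir: str = "results/pipeline"
    mode: str = "maps"  # maps | timeseries
    n_subjects: int = 20
    region: str = "cortex"
    montage: str = "ecog_adjacent_7"
    duration_s: float = 60.0
    rate_hz: float = 2400.0
    n_perm: int = 1000
    alpha: float = 0.05
    blob_channels: int = 2
    blob_hz: int = 3
    pls_fraction: float = 0.10
    pls_n_perm: int = 1000
    k_max: int = 10
    gap_b_ref: int = 50
    var_target: float = 0.80
    noise_sd: float = 0.15
    hotspots: list = field(default_factory=list)  # [[ch_lo, ch_hi, f_lo, f_hi, sd], ...]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if not (0 < cfg.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        return cfg

    def cohort_spec(self) -> synthetic.CohortSpec:
        hotspots = [synthetic.Hotspot(int(h[0]), int(h[1]), float(h[2]), float(h[3]),
                                      float(h[4])) for h in self.hotspots]
        return synthetic.CohortSpec(n_subjects=self.n_subjects, noise_sd=self.noise_sd,
                                    hotspots=hotspots, seed=self.seed)

    def stage_seed(self, stage: str) -> int:
        """Stage-specific substream of the master seed (stable across runs)."""
        tag = zlib.crc32(stage.encode()) % 10007
        return int(np.random.default_rng([self.seed % (2 ** 31), tag])
                   .integers(2 ** 31 - 1))


def _manifest(out: Path, stage: str, cfg: PipelineConfig, outputs: list[Path]) -> None:
    man = {
        "stage": stage,
        "params": dataclasses.asdict(cfg),
        "seed": cfg.stage_seed(stage),
        "outputs": {p.name: io.file_hash(p) for p in outputs if p.exists()},
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(man, indent=1, sort_keys=True))


def _require(out: Path, stage: str) -> None:
    for dep in _REQUIRES.get(stage, []):
        if not (out / f"manifest_{dep}.json").exists():
            raise RuntimeError(f"stage {stage!r} requires stage {dep!r} to run first")


def run_stage(cfg: PipelineConfig, stage: str) -> list[Path]:
    """Run one stage (or ``all``); returns the files written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        written: list[Path] = []
        seq = ["simulate", "maps", "stats", "consistency", "clinical", "cluster", "report"]
        if cfg.mode == "timeseries":
            seq = ["simulate", "preprocess", "spectra"] + seq[1:]
        for s in seq:
            written += run_stage(cfg, s)
        return written
    fn = _STAGE_FNS[stage]
    outputs = fn(cfg, out)
    _manifest(out, stage, cfg, outputs)
    return outputs


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    spec = cfg.cohort_spec()
    outputs: list[Path] = []
    stack, clin, gt = synthetic.simulate_map_cohort(spec, region=cfg.region)
    io.save_stack(stack, out / "cohort_maps.npz")
    io.write_clinical_table(clin, out / "clinical.csv")
    io.write_ground_truth(gt, out / "ground_truth.json")
    outputs += [out / "cohort_maps.npz", out / "clinical.csv", out / "ground_truth.json"]
    if cfg.mode == "timeseries":
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for s in range(cfg.n_subjects):
            ecog, dbs, _ = synthetic.simulate_timeseries_subject(
                spec, s, duration_s=cfg.duration_s, rate_hz=cfg.rate_hz)
            outputs.append(io.write_recording(ecog, rec_dir / f"sub{s:03d}_ecog"))
            outputs.append(io.write_recording(dbs, rec_dir / f"sub{s:03d}_dbs"))
            if s == 0:
                io.write_channel_table(ecog, out / "channels_ecog.tsv")
                io.write_channel_table(dbs, out / "channels_dbs.tsv")
    return outputs


def _stage_preprocess(cfg: PipelineConfig, out: Path) -> list[Path]:
    rec_dir = out / "recordings"
    if not rec_dir.exists():
        raise RuntimeError("stage 'preprocess' requires stage 'simulate' (timeseries mode)")
    clean_dir = out / "clean"
    clean_dir.mkdir(exist_ok=True)
    outputs = []
    log = {}
    for p in sorted(rec_dir.glob("*_ecog.bin")):
        rec = io.read_recording(p)
        bip, mask = preprocess.preprocess_recording(rec, cfg.montage)
        np.save(clean_dir / (p.stem + "_bipolar.npy"), bip.samples)
        log[p.stem] = {"n_flagged": mask.n_flagged, "labels": bip.labels,
                       "rate_hz": bip.rate_hz}
        outputs.append(clean_dir / (p.stem + "_bipolar.npy"))
    for p in sorted(rec_dir.glob("*_dbs.bin")):
        rec = io.read_recording(p)
        bip, mask = preprocess.preprocess_recording(rec, "dbs_adjacent")
        np.save(clean_dir / (p.stem + "_bipolar.npy"), bip.samples)
        log[p.stem] = {"n_flagged": mask.n_flagged, "labels": bip.labels,
                       "rate_hz": bip.rate_hz}
        outputs.append(clean_dir / (p.stem + "_bipolar.npy"))
    (out / "artifact_log.json").write_text(json.dumps(log, indent=1))
    return outputs + [out / "artifact_log.json"]


def _stage_spectra(cfg: PipelineConfig, out: Path) -> list[Path]:
    clean_dir = out / "clean"
    if not clean_dir.exists():
        raise RuntimeError("stage 'spectra' requires stage 'preprocess'")
    maps = []
    sids = []
    for p in sorted(clean_dir.glob("*_ecog_bipolar.npy")):
        x = np.load(p)
        spectra = []
        for ch in range(x.shape[0]):
            s = spectral.multitaper_psd(x[ch], rate_hz=cfg.rate_hz)
            s = spectral.normalize_spectrum(s)
            fit = spectral.fit_aperiodic(s)
            spectra.append(spectral.remove_aperiodic(s, fit))
        m = assemble_power_map(spectra, [f"ch{c}" for c in range(x.shape[0])])
        maps.append(m)
        sids.append(p.stem.split("_")[0])
    stack = stack_cohort(maps, sids)
    io.save_stack(stack, out / "cohort_maps_timeseries.npz")
    return [out / "cohort_maps_timeseries.npz"]


def _stage_maps(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "maps")
    stack = io.load_stack(out / "cohort_maps.npz")
    io.stack_to_tidy(stack).to_csv(out / "cohort_maps.tsv", sep="\t", index=False)
    vm = variance_map(stack)
    io.map_to_tidy(vm).to_csv(out / "variance_map.tsv", sep="\t", index=False)
    return [out / "cohort_maps.tsv", out / "variance_map.tsv"]


def _stage_stats(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "stats")
    stack = io.load_stack(out / "cohort_maps.npz")
    null = permstats.spatial_shuffle_null(stack, n_perm=cfg.n_perm,
                                          seed=cfg.stage_seed("stats"))
    sm = permstats.pixel_z_test(stack, null, alpha=cfg.alpha,
                                min_channels=cfg.blob_channels, min_hz=cfg.blob_hz,
                                n_perm=cfg.n_perm)
    df = pd.DataFrame({
        "channel": np.repeat(stack.channels, stack.freqs.size),
        "frequency_hz": np.tile(stack.freqs, len(stack.channels)),
        "z": sm.z.ravel(), "p_raw": sm.p_raw.ravel(), "p_fdr": sm.p_fdr.ravel(),
        "sig_pre_blob": sm.sig_pre_blob.ravel(), "sig_post_blob": sm.sig_post_blob.ravel(),
    })
    df.to_csv(out / "pixel_stats.tsv", sep="\t", index=False)
    summary = {"n_sig_pre_blob": int(sm.sig_pre_blob.sum()),
               "n_sig_post_blob": int(sm.sig_post_blob.sum()),
               "n_perm": cfg.n_perm, "alpha": cfg.alpha}
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=1))
    return [out / "pixel_stats.tsv", out / "stats_summary.json"]


def _stage_consistency(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "consistency")
    stack = io.load_stack(out / "cohort_maps.npz")
    rep = consistency.correlation_suite(stack)
    p_map, pct = consistency.pixel_signed_rank(stack, alpha=cfg.alpha)
    obs, ctrl, p_paired = consistency.ci_containment(stack, seed=cfg.stage_seed("consistency"))
    summary = {"pct_pixels_significant": pct,
               "mean_containment_pct": float(np.mean(obs)),
               "mean_control_containment_pct": float(np.mean(ctrl)),
               "containment_paired_p": p_paired,
               "mean_rho_vs_grand_average": rep.tests["rho_mean"],
               "mean_cross_subject_rho": rep.tests["offdiag_mean"]}
    (out / "consistency_summary.json").write_text(json.dumps(summary, indent=1))
    return [out / "consistency_summary.json"]


def _stage_clinical(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "clinical")
    stack = io.load_stack(out / "cohort_maps.npz")
    clin = io.read_clinical_table(out / "clinical.csv")
    reg = clin_mod.pixel_multiple_regression(stack, clin, alpha=cfg.alpha)
    seed = cfg.stage_seed("clinical")
    Y = clin_mod._clinical_matrix(clin, stack.subject_ids)
    results = {}
    flat = stack.data.reshape(stack.n_subjects, -1)
    for which in ("top", "bottom"):
        idx = clin_mod.select_variance_pixels(stack, cfg.pls_fraction, which)
        model = clin_mod.pls_fit(flat[:, idx], Y, n_lv=10, feature_idx=idx)
        model = clin_mod.pls_permutation_validate(model, flat[:, idx], Y,
                                                  n_perm=cfg.pls_n_perm, seed=seed)
        results[which] = model
    cmp_df = clin_mod.compare_top_bottom(results["top"], results["bottom"])
    cmp_df.to_csv(out / "pls_top_vs_bottom.tsv", sep="\t", index=False)
    summary = {"regression_pct_sig_by_freq_max": float(reg.pct_by_freq.max()),
               "pls_top_lv1_r": float(results["top"].r_obs[0]),
               "pls_top_lv1_p": float(results["top"].p_perm[0]),
               "pls_bottom_lv1_r": float(results["bottom"].r_obs[0]),
               "pls_bottom_lv1_p": float(results["bottom"].p_perm[0])}
    (out / "clinical_summary.json").write_text(json.dumps(summary, indent=1))
    return [out / "pls_top_vs_bottom.tsv", out / "clinical_summary.json"]


def _stage_cluster(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "cluster")
    stack = io.load_stack(out / "cohort_maps.npz")
    clin = io.read_clinical_table(out / "clinical.csv")
    red = clustering.pca_reduce(stack, var_target=cfg.var_target)
    seed = cfg.stage_seed("cluster")
    k_max = min(cfg.k_max, stack.n_subjects - 1)
    curve = clustering.gap_statistic(red.scores, k_max=k_max, b_ref=cfg.gap_b_ref, seed=seed)
    sol = clustering.kmeans_cluster(red.scores, max(curve.k_star, 2), seed=seed)
    manova_p = clustering.manova_profiles(sol, clin)
    anova = clustering.anova_subscores(sol, clin, alpha=cfg.alpha)
    pd.DataFrame({"subject_id": stack.subject_ids, "cluster": sol.labels}
                 ).to_csv(out / "cluster_assignments.csv", index=False)
    anova.to_csv(out / "anova_targets.tsv", sep="\t", index=False)
    summary = {"k_star": curve.k_star, "k_used": sol.k, "manova_p": manova_p,
               "n_components": red.scores.shape[1]}
    (out / "cluster_summary.json").write_text(json.dumps(summary, indent=1))
    return [out / "cluster_assignments.csv", out / "anova_targets.tsv",
            out / "cluster_summary.json"]


def _stage_report(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "report")
    parts = ["# Spatio-spectral pipeline report\n"]
    for name in ("stats_summary", "consistency_summary", "clinical_summary",
                 "cluster_summary"):
        p = out / f"{name}.json"
        if p.exists():
            parts.append(f"## {name}\n```json\n{p.read_text()}\n```\n")
    stack = io.load_stack(out / "cohort_maps.npz")
    fig_path = out / "group_mean_map.png"
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 3))
        m = stack.mean_map()
        im = ax.imshow(m.values, aspect="auto", origin="lower",
                       extent=[m.freqs[0], m.freqs[-1], 0, len(m.channels)])
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("channel")
        fig.colorbar(im, ax=ax, label="power (a.u.)")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        parts.append(f"![group mean map]({fig_path.name})\n")
    except Exception:
        pass
    (out / "report.md").write_text("\n".join(parts))
    return [out / "report.md", fig_path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "spectra": _stage_spectra,
    "maps": _stage_maps,
    "stats": _stage_stats,
    "consistency": _stage_consistency,
    "clinical": _stage_clinical,
    "cluster": _stage_cluster,
    "report": _stage_report,
}


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Schema check of the on-disk inputs; returns a list of violations."""
    out = Path(cfg.out_dir)
    issues: list[str] = []
    clin_path = out / "clinical.csv"
    stack_path = out / "cohort_maps.npz"
    if not clin_path.exists():
        issues.append("missing clinical table clinical.csv")
    if not stack_path.exists():
        issues.append("missing cohort stack cohort_maps.npz")
    if issues:
        return issues
    clin = io.read_clinical_table(clin_path)
    for col in io.CLINICAL_TABLE_COLUMNS:
        if col not in clin.columns:
            issues.append(f"clinical table missing column {col!r}")
    stack = io.load_stack(stack_path)
    if "subject_id" in clin.columns:
        known = set(clin["subject_id"].astype(str))
        for sid in stack.subject_ids:
            if sid not in known:
                issues.append(f"subject {sid!r} absent from clinical table")
    for p in (out / "recordings").glob("*.json") if (out / "recordings").exists() else []:
        meta = json.loads(p.read_text())
        if meta.get("rate_hz") != cfg.rate_hz:
            issues.append(f"{p.name}: rate {meta.get('rate_hz')} != configured {cfg.rate_hz}")
    return issues
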