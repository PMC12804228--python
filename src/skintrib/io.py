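"""Formats, configuration and the end-to-end simulated-study report.

Force recordings travel as CSV (``time_s, normal_N, lateral_N`` with
``# key=value`` metadata header lines), AE waveforms as 32-bit float WAV
or raw float32 binary with a JSON sidecar, questionnaires as long-format
CSV.  :func:`run_report` ties the stages together: simulate -> friction ->
acoustic -> sensory -> statistics, writing every table, figure and the
resolved configuration needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import acoustic, friction, sensory, stats, synthgen
from .errors import NotSegmentableError, ParseError, SkintribError

logger = logging.getLogger(__name__)

FORCE_COLUMNS = ("time_s", "normal_N", "lateral_N")
SENSORY_COLUMNS = ("panellist", "material", "attribute", "rating")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_force_csv(rec: friction.ForceRecording, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={rec.rate}\n")
        for k, v in rec.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write(",".join(FORCE_COLUMNS) + "\n")
        for t, nf, lf in zip(rec.time, rec.normal_force, rec.lateral_force):
            fh.write(f"{float(t)!r},{float(nf)!r},{float(lf)!r}\n")
    return path

def _parse_meta_lines(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_force_csv(path) -> friction.ForceRecording:
    """Read a force recording; raises :class:`ParseError` on schema faults."""
    path = Path(path)
    meta = _parse_meta_lines(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in FORCE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = df[FORCE_COLUMNS[0]].isna() | df[FORCE_COLUMNS[1]].isna() \
        | df[FORCE_COLUMNS[2]].isna()
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()
        raise ParseError(f"{path}: malformed row(s) at line(s) {lines[:10]}")
    rate = float(meta.pop("rate", 40.0))
    try:
        return friction.ForceRecording(
            time=df["time_s"].to_numpy(),
            normal_force=df["normal_N"].to_numpy(),
            lateral_force=df["lateral_N"].to_numpy(),
            rate=rate,
            meta=meta,
        )
    except SkintribError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ae_wav(rec: acoustic.AERecording, path) -> Path:
    """32-bit float WAV; metadata goes to a ``.meta.json`` sidecar."""
    path = Path(path)
    wavfile.write(path, int(rec.rate), rec.samples.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(rec.meta))
    return path


def read_ae_wav(path) -> acoustic.AERecording:
    path = Path(path)
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise ParseError(f"{path}: expected a single channel, got {data.shape[1]}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return acoustic.AERecording(samples=data, rate=float(rate), meta=meta)


def write_ae_raw(rec: acoustic.AERecording, path) -> Path:
    """Raw little-endian float32 + JSON sidecar ``{rate, dtype, meta}``."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"rate": rec.rate, "dtype": "float32", "meta": rec.meta})
    )
    return path


def read_ae_raw(path) -> acoustic.AERecording:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ParseError(f"{path}: missing JSON sidecar {sidecar.name}")
    info = json.loads(sidecar.read_text())
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return acoustic.AERecording(
        samples=samples, rate=float(info["rate"]), meta=info.get("meta", {})
    )


def write_sensory_csv(table: sensory.SensoryTable, path) -> Path:
    path = Path(path)
    table.records.to_csv(path, index=False)
    return path


def read_sensory_csv(path) -> sensory.SensoryTable:
    path = Path(path)
    df = pd.read_csv(path)
    for col in SENSORY_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return sensory.SensoryTable(df)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: The study's printed parameter values; kept alongside any override in the
#: resolved configuration written with every report.
STUDY_DEFAULTS = {
    "loads_N": [2.0, 3.0, 4.0],
    "duration_s": 30.0,
    "repeats": 3,
    "force_rate_hz": 40.0,
    "ae_rate_hz": 2e6,
    "rms_window_samples": 20000,
    "rms_window_seconds": 0.01,
    "band_hz": [120000.0, 160000.0],
    "band_percentile": 90.0,
    "static_percentile": 95.0,
    "smoothing_prominence": [0.01, 0.1],
    "smoothing_min_height": 0.015,
    "smoothing_min_distance_points": 50000,
    "alpha": 0.05,
    "n_panellists": 8,
}

_TUPLE_FIELDS = {"materials", "loads", "band", "smoothing_prominence"}


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of one simulated study.

    Trial sizes default to a desk-scale study — 6 s trials at 0.4 MSa/s AE
    (0.01 s RMS windows preserved, the 120-160 kHz band still within
    Nyquist) with 3 participants — so a full report runs in minutes;
    thresholds default to the study values in :data:`STUDY_DEFAULTS`.
    """

    materials: tuple = tuple(synthgen.PRESETS)
    loads: tuple = (2.0, 3.0, 4.0)
    repeats: int = 3
    participants: int = 3
    duration: float = 6.0
    n_strokes: int = 8
    force_rate: float = 40.0
    ae_rate: float = 4e5
    rms_window_seconds: float = 0.01
    min_normal: float = 0.2
    hysteresis: float = 0.05
    min_stroke_duration: float = 0.25
    trim_fraction: float = 0.05
    band: tuple = (120_000.0, 160_000.0)
    band_percentile: float = 90.0
    smoothing_prominence: tuple = (0.01, 0.1)
    smoothing_min_height: float = 0.015
    smoothing_min_distance_hz: float = 1670.0
    valley_fraction: float = 0.2
    alpha: float = 0.05
    n_panellists: int = 8
    sensory_noise_sd: float = 0.8
    participant_mu_sd: float = 0.05
    participant_ae_sd: float = 0.10
    include_ae: bool = True
    make_figures: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in _TUPLE_FIELDS:
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in _TUPLE_FIELDS:
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(
            {"config": self.to_dict(), "study_defaults": STUDY_DEFAULTS},
            sort_keys=True,
        ))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data["config"] if "config" in data else data)


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------

@dataclass
class ReportResult:
    """In-memory handles on everything :func:`run_report` wrote."""

    outdir: Path
    cof_features: pd.DataFrame
    cof_summary: pd.DataFrame
    band_table: pd.DataFrame
    ae_features: pd.DataFrame
    sensory_table: "sensory.SensoryTable"
    sensory_pca: "stats.PCAModel"
    ellipsoids: list
    tukey_cof: "stats.TukeyTable"
    tukey_ae: "stats.TukeyTable | None"
    combined_model: "stats.PCAModel | None"
    combined_overlays: "pd.DataFrame | None"
    correlations: "pd.DataFrame | None"
    ae_skipped: bool = False


def _trial_iter(config: PipelineConfig):
    for p in range(config.participants):
        for m in config.materials:
            for load in config.loads:
                for rep in range(config.repeats):
                    yield f"P{p + 1:02d}", m, float(load), rep + 1


def run_report(config: PipelineConfig, outdir) -> ReportResult:
    """Run the full simulated study and write its analysis surface.

    Deterministic given ``config.seed``: per-trial seeds are spawned from
    one root seed sequence, so two runs with the same configuration
    produce identical CSV outputs.  Any stage failure aborts with the
    stage name and the offending trial id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("skintrib")
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.DEBUG)
    try:
        result = _run_report_inner(config, outdir)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    return result


def _run_report_inner(config: PipelineConfig, outdir: Path) -> ReportResult:
    config.to_yaml(outdir / "resolved_config.yaml")
    trials = list(_trial_iter(config))
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(trials) + 2)
    part_rng = np.random.default_rng(children[-1])

    # participant-level multiplicative effects on friction and AE output
    part_mu = {}
    part_ae = {}
    for p in range(config.participants):
        pid = f"P{p + 1:02d}"
        part_mu[pid] = float(np.clip(
            1.0 + config.participant_mu_sd * part_rng.standard_normal(), 0.5, 1.5))
        part_ae[pid] = float(np.clip(
            1.0 + config.participant_ae_sd * part_rng.standard_normal(), 0.3, 2.0))

    window_samples = int(round(config.ae_rate * config.rms_window_seconds))
    cof_rows, ae_rows, band_rows = [], [], []
    ae_skip_notes = []

    for k, (pid, mname, load, rep) in enumerate(trials):
        trial_id = f"{pid}/{mname}/{load:g}N/r{rep}"
        try:
            base = synthgen.preset(mname)
            mat = replace(
                base,
                mu_static=base.mu_static * part_mu[pid],
                mu_dynamic=base.mu_dynamic * part_mu[pid],
                ae_band_level=base.ae_band_level * part_ae[pid],
            )
            seed = int(children[k].generate_state(1)[0] % (2**31))
            plan = synthgen.TrialPlan(
                target_load=load, duration=config.duration,
                n_strokes=config.n_strokes, force_rate=config.force_rate,
                ae_rate=config.ae_rate, seed=seed,
            )
            meta = {"participant": pid, "repeat": rep}
            rec, _truth = synthgen.synthesize_force_recording(mat, plan, meta=meta)
        except SkintribError as exc:
            raise SkintribError(f"stage=simulate trial={trial_id}: {exc}") from exc

        try:
            feats, strokes, _series = friction.analyze_force_recording(
                rec, config.min_normal, config.hysteresis,
                config.min_stroke_duration, config.trim_fraction,
            )
            cof_rows.append(feats)
        except SkintribError as exc:
            raise SkintribError(f"stage=friction trial={trial_id}: {exc}") from exc

        if not config.include_ae:
            continue
        try:
            ae_rec = synthgen.synthesize_ae_recording(mat, plan, _truth, meta=meta)
            sp = acoustic.compute_fft_spectrum(ae_rec)
            sp_smooth = acoustic.smooth_spectrum(
                sp,
                prominence_range=config.smoothing_prominence,
                min_height=config.smoothing_min_height,
                min_distance_hz=config.smoothing_min_distance_hz,
            )
            band_rows.append(
                dict(participant=pid, material=mname, target_load=load,
                     repeat=rep,
                     band_p90=acoustic.band_percentile(
                         sp_smooth, config.band, config.band_percentile))
            )
            profile = acoustic.compute_rms_profile(ae_rec, window_samples)
            # RMS stroke features only where the profile is friction-like
            # (the planar anchors are not): probe with self-segmentation,
            # extract with the synchronized force strokes.
            try:
                acoustic.segment_rms_strokes(
                    profile, mode="self",
                    valley_fraction=config.valley_fraction,
                )
            except NotSegmentableError as exc:
                ae_skip_notes.append(f"{trial_id}: {exc}")
                logger.info("AE RMS features skipped for %s: %s", trial_id, exc)
            else:
                ae_feats = acoustic.analyze_ae_recording(
                    ae_rec, window_samples, mode="transfer",
                    force_strokes=strokes, force_rate=config.force_rate,
                )
                ae_rows.append(ae_feats)
        except SkintribError as exc:
            raise SkintribError(f"stage=acoustic trial={trial_id}: {exc}") from exc

    cof_features = pd.concat(cof_rows, ignore_index=True)
    cof_features.to_csv(outdir / "cof_features.csv", index=False)
    cof_summary = friction.summarize_features(
        cof_features, ["material"], "dynamic_cof"
    )
    cof_summary.to_csv(outdir / "cof_summary.csv", index=False)

    band_table = pd.DataFrame(band_rows)
    ae_features = (
        pd.concat(ae_rows, ignore_index=True) if ae_rows else pd.DataFrame()
    )
    ae_skipped = not config.include_ae
    if config.include_ae:
        band_table.to_csv(outdir / "band_percentiles.csv", index=False)
        ae_features.to_csv(outdir / "ae_features.csv", index=False)
        if ae_skip_notes:
            (outdir / "ae_rms_skipped.txt").write_text("\n".join(ae_skip_notes) + "\n")
    else:
        (outdir / "AE_SKIPPED.txt").write_text(
            "Acoustic-emission inputs disabled: friction-only report.\n"
        )
        logger.warning("AE stage skipped: friction-only report")

    # ----- sensory + statistics --------------------------------------------
    try:
        mats = [synthgen.preset(m) for m in config.materials]
        sens_seed = int(children[-2].generate_state(1)[0] % (2**31))
        stable = synthgen.generate_sensory_responses(
            mats, config.n_panellists, config.sensory_noise_sd, seed=sens_seed
        )
        report = sensory.validate_questionnaire(stable)
        if not report.ok:
            raise SkintribError(f"generated questionnaire invalid: {report.errors}")
        write_sensory_csv(stable, outdir / "sensory_ratings.csv")
    except SkintribError as exc:
        raise SkintribError(f"stage=sensory: {exc}") from exc

    wide = stable.to_wide()
    pca = stats.run_pca(wide, mode="covariance")
    pca.variance_table().to_csv(outdir / "pca_variance.csv", index=False)
    pca.loadings.to_csv(outdir / "pca_loadings.csv")
    scores = pd.DataFrame(
        pca.scores, index=wide.index, columns=pca.loadings.columns
    )
    scores.to_csv(outdir / "pca_scores.csv")

    ellipsoids = []
    for mname in config.materials:
        pts = scores.xs(mname, level="material").to_numpy()[:, :3]
        ellipsoids.append(
            stats.concentration_ellipsoid(pts, level=0.95, dims=3, group=mname)
        )
    (outdir / "ellipsoids.json").write_text(json.dumps([
        dict(group=e.group, n=e.n, level=e.level, degenerate=e.degenerate,
             center=e.center.tolist(), radii=e.radii.tolist(),
             axes=e.axes.tolist())
        for e in ellipsoids
    ], indent=1))

    cof_groups = {
        m: g["dynamic_cof"].to_numpy()
        for m, g in cof_features.groupby("material")
    }
    tukey_cof = stats.tukey_kramer(cof_groups, alpha=config.alpha)
    tukey_cof.table.to_csv(outdir / "tukey_dynamic_cof.csv", index=False)

    tukey_ae = None
    combined_model = combined_overlays = correlations = None
    if config.include_ae and not ae_features.empty:
        ae_groups = {
            m: g["dynamic_rms"].to_numpy()
            for m, g in ae_features.groupby("material")
        }
        if len(ae_groups) >= 2:
            tukey_ae = stats.tukey_kramer(ae_groups, alpha=config.alpha)
            tukey_ae.table.to_csv(outdir / "tukey_dynamic_rms.csv", index=False)

        trib = (
            cof_features.groupby(["material", "participant"])[
                ["static_cof", "dynamic_cof"]].mean()
            .join(
                ae_features.groupby(["material", "participant"])[
                    ["static_rms", "dynamic_rms"]].mean(),
                how="inner",
            )
        )
        sens_means = (
            stable.records.pivot_table(
                index=["material", "panellist"], columns="attribute",
                values="rating",
            )
            .rename_axis(index=["material", "participant"])
            .reindex(columns=list(synthgen.ATTRIBUTES))
        )
        common = trib.index.intersection(sens_means.index)
        if len(common) >= 3:
            combined_model, combined_overlays = stats.combined_pca(
                trib.loc[common], sens_means.loc[common]
            )
            combined_overlays.to_csv(outdir / "combined_pca_overlays.csv")
            combined_model.variance_table().to_csv(
                outdir / "combined_pca_variance.csv", index=False
            )
            joint = trib.loc[common].join(sens_means.loc[common])
            correlations = stats.correlation_signs(
                joint,
                [
                    ("dynamic_cof", "rough"),
                    ("dynamic_cof", "soft"),
                    ("dynamic_rms", "pleasant"),
                    ("dynamic_rms", "slippery"),
                ],
            )
            correlations.to_csv(outdir / "correlation_signs.csv", index=False)

    if config.make_figures:
        _make_figures(outdir, config, cof_features, ae_features, band_table,
                      stable, scores, ellipsoids)

    return ReportResult(
        outdir=outdir, cof_features=cof_features, cof_summary=cof_summary,
        band_table=band_table, ae_features=ae_features, sensory_table=stable,
        sensory_pca=pca, ellipsoids=ellipsoids, tukey_cof=tukey_cof,
        tukey_ae=tukey_ae, combined_model=combined_model,
        combined_overlays=combined_overlays, correlations=correlations,
        ae_skipped=ae_skipped,
    )


def _make_figures(outdir, config, cof_features, ae_features, band_table,
                  stable, scores, ellipsoids):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    def boxplot(df, value, title, fname):
        fig, ax = plt.subplots(figsize=(7, 4))
        groups = [(m, g[value].to_numpy()) for m, g in df.groupby("material")]
        ax.boxplot([v for _, v in groups], tick_labels=[m for m, _ in groups])
        ax.set_ylabel(value)
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(figdir / fname, dpi=110)
        plt.close(fig)

    boxplot(cof_features, "dynamic_cof", "Dynamic COF per material",
            "box_dynamic_cof.png")
    if not ae_features.empty:
        boxplot(ae_features, "dynamic_rms", "Dynamic AE RMS per material",
                "box_dynamic_rms.png")
    if not band_table.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        med = band_table.groupby("material")["band_p90"].median()
        ax.bar(med.index, med.to_numpy())
        ax.set_ylabel("90th-pct band magnitude (a.u.)")
        ax.set_title(f"{config.band[0] / 1e3:g}-{config.band[1] / 1e3:g} kHz "
                     "band percentile")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(figdir / "band_percentiles.png", dpi=110)
        plt.close(fig)

    # 3-D sensory-score scatter with material centroids
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for e in ellipsoids:
        pts = scores.xs(e.group, level="material").to_numpy()[:, :3]
        ax.scatter(*pts.T, label=e.group, s=12)
        ax.scatter(*e.center, marker="o", s=60)
    ax.set_xlabel("PC1"); ax.set_ylabel("PC2"); ax.set_zlabel("PC3")
    ax.legend(fontsize="x-small")
    fig.tight_layout()
    fig.savefig(figdir / "pca_scores_3d.png", dpi=110)
    plt.close(fig)

    first = stable.panellists[0]
    ax = sensory.plot_radar(sensory.radar_profile(stable, first),
                            title=f"Panellist {first}")
    ax.figure.savefig(figdir / "radar_first_panellist.png", dpi=110,
                      bbox_inches="tight")
    plt.close(ax.figure)
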