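"""End-to-end orchestration: synthesize -> features -> spectral -> sync -> compare.

A :class:`RunConfig` bundles every tunable with defaults matching the
analysis being reproduced (180 s windows sliding by 1 s, 7:3 split, GBR
scoring model, 30 deg/s I-VT threshold).  ``run_all`` executes the five
stages over a cohort and writes six artifacts to the output directory:

* ``manifest.json`` — session labels and ground-truth couplings
* ``features.csv`` — dense 60 Hz eye-feature traces
* ``band_ratios.csv`` — tidy per-window band-ratio series, both modalities
* ``sync_results.csv`` — per-session, per-triple regression scores
* ``comparisons.csv`` — condition comparison with exclusion verdicts
* ``quadrant_report.json`` — retained triples per valence-arousal quadrant

plus ``run_log.json``.  Every artifact embeds the config hash; re-running
with an identical config reproduces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .comparison import build_comparisons, comparisons_to_frame, quadrant_report
from .eye_features import extract_features
from .io import EEGRecording, GazeRecording, SessionLabel
from .spectral import (EEG_SCHEME, EYE_SCHEME, BandRatioSeries, bandpass,
                       sliding_band_ratios)
from .sync import RegressionSpec, results_to_frame, run_sync_matrix
from .synthetic import SyntheticConfig, iter_sessions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the reference analysis."""

    synthetic: SyntheticConfig | None = None
    data_dir: str | None = None
    outdir: str = "eyesync_out"
    window_s: float = 180.0
    slide_s: float = 1.0
    ivt_threshold: float = 30.0
    min_fixation_ms: float = 60.0
    blink_pad_ms: float = 100.0
    eeg_prefilter: tuple[float, float] = (1.0, 50.0)
    model: str = "gbr"
    split_mode: str = "chronological"
    split_fraction: float = 0.7
    seed: int = 0
    max_bad_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.synthetic is None and self.data_dir is None:
            raise ValueError("config needs either a synthetic section or "
                             "a data_dir")
        if self.window_s <= 0 or self.slide_s <= 0:
            raise ValueError("window_s and slide_s must be positive")

    @classmethod
    def test_profile(cls, n_subjects: int = 2, n_videos: int = 8,
                     **kwargs) -> "RunConfig":
        """Small-scale profile (20 s windows, 60 s sessions) for fast runs."""
        synth = kwargs.pop("synthetic", None) or SyntheticConfig(
            n_subjects=n_subjects, n_videos=n_videos, duration_s=60.0,
            seed=kwargs.get("seed", 0))
        return cls(synthetic=synth, window_s=20.0, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        # hash the analysis settings; the output location is not one
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synthetic", None)
        if synth is not None:
            from .synthetic import CouplingSpec
            synth = dict(synth)
            synth["couplings"] = tuple(
                CouplingSpec(**c) for c in synth.get("couplings", ()))
            if synth.get("condition_labels") is not None:
                synth["condition_labels"] = tuple(
                    tuple(lab) for lab in synth["condition_labels"])
            synth = SyntheticConfig(**synth)
        if "eeg_prefilter" in d:
            d["eeg_prefilter"] = tuple(d["eeg_prefilter"])
        return cls(synthetic=synth, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# per-session processing
# ---------------------------------------------------------------------------

def process_session(eeg: EEGRecording, gaze: GazeRecording, cfg: RunConfig,
                    channels: list[str] | None = None,
                    features: list[str] | None = None,
                    ) -> tuple[dict[str, BandRatioSeries],
                               dict[str, BandRatioSeries]]:
    """Eye-feature extraction and band-ratio series for one session.

    Returns ``(eye_ratio_series, eeg_ratio_series)`` keyed by feature and
    channel name.  ``channels`` / ``features`` restrict the computation.
    """
    if eeg.duration < cfg.window_s or gaze.duration < cfg.window_s:
        raise ValueError(
            f"session shorter than the analysis window "
            f"({min(eeg.duration, gaze.duration):.1f}s < {cfg.window_s}s)")
    feats = extract_features(gaze, velocity_threshold=cfg.ivt_threshold,
                             min_fixation_ms=cfg.min_fixation_ms,
                             pad_ms=cfg.blink_pad_ms)
    if features is not None:
        feats = {k: v for k, v in feats.items() if k in features}
    eye_ratios = {
        name: sliding_band_ratios(
            s.values, s.rate, EYE_SCHEME, cfg.window_s, cfg.slide_s,
            source=name, bad_mask=s.blink_mask, max_bad_frac=cfg.max_bad_frac)
        for name, s in feats.items()}
    eeg_ratios = {}
    lo, hi = cfg.eeg_prefilter
    for ch in (channels if channels is not None else eeg.channels):
        filtered = bandpass(eeg.channel(ch), eeg.rate, lo, hi)
        eeg_ratios[ch] = sliding_band_ratios(
            filtered, eeg.rate, EEG_SCHEME, cfg.window_s, cfg.slide_s,
            source=ch)
    return eye_ratios, eeg_ratios


def sync_for_triples(eeg: EEGRecording, gaze: GazeRecording, label,
                     triples: list[tuple[str, str, str]], cfg: RunConfig,
                     spec: RegressionSpec) -> list:
    """Score only the requested (eye_feature, channel, band) triples.

    Cheaper than the full 288-triple matrix when a study targets specific
    pairings; used heavily on synthetic cohorts with planted couplings.
    """
    from .spectral import align_ratio_series
    from .sync import fit_sync

    features = sorted({t[0] for t in triples})
    channels = sorted({t[1] for t in triples})
    eye_ratios, eeg_ratios = process_session(eeg, gaze, cfg,
                                             channels=channels,
                                             features=features)
    results = []
    aligned: dict[tuple[str, str], tuple] = {}
    for feature, channel, band in triples:
        key = (feature, channel)
        if key not in aligned:
            aligned[key] = align_ratio_series(eye_ratios[feature],
                                              eeg_ratios[channel])
        _, xr, yr = aligned[key]
        j = eye_ratios[feature].scheme.names.index(band)
        results.append(fit_sync(
            xr[:, j], yr[:, j], spec, eye_feature=feature, channel=channel,
            band=band, subject_id=label.subject_id, video_id=label.video_id,
            condition=label.condition, quadrant=label.quadrant))
    return results


def load_cohort(data_dir: str | Path):
    """Yield sessions from an on-disk cohort written by ``generate_cohort``."""
    from .io import read_eeg, read_gaze

    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    for entry in manifest["sessions"]:
        label = SessionLabel(empathic=entry["empathic"],
                             valence=entry["valence"],
                             arousal=entry["arousal"],
                             subject_id=entry["subject_id"],
                             video_id=entry["video_id"])
        eeg = read_eeg(data_dir / entry["eeg_path"])
        gaze = read_gaze(data_dir / entry["gaze_path"])
        yield eeg, gaze, label


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute the five-stage pipeline and write all artifacts.

    Deterministic under a fixed config: result CSVs are byte-identical
    across re-runs.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    timings: dict[str, float] = {}
    excluded_windows: dict[str, int] = {}

    if cfg.synthetic is not None:
        if cfg.synthetic.duration_s < cfg.window_s:
            raise ValueError(
                f"synthetic duration_s={cfg.synthetic.duration_s} is shorter "
                f"than window_s={cfg.window_s}")
        sessions = iter_sessions(cfg.synthetic)
        manifest_sessions = None
    else:
        sessions = load_cohort(cfg.data_dir)
        manifest_sessions = json.loads(
            (Path(cfg.data_dir) / "manifest.json").read_text())["sessions"]

    spec = RegressionSpec(model=cfg.model, split_mode=cfg.split_mode,
                          split_fraction=cfg.split_fraction, seed=cfg.seed)

    feature_rows = []
    ratio_frames = []
    all_results = []
    manifest_entries = []
    t0 = time.perf_counter()
    for session in sessions:
        if isinstance(session, tuple):
            eeg, gaze, label = session
            truth_couplings = []
        else:
            eeg, gaze, label = session.eeg, session.gaze, session.label
            truth_couplings = [vars(c) | {} for c in session.truth.couplings]
        sid = f"subject {label.subject_id} video {label.video_id}"
        try:
            eye_ratios, eeg_ratios = process_session(eeg, gaze, cfg)
        except ValueError as err:
            raise RuntimeError(f"stage features failed on {sid}: {err}") from err
        n_excl = sum(int(r.excluded.sum()) for r in eye_ratios.values())
        excluded_windows[sid] = n_excl
        logger.info("%s: %d excluded eye windows", sid, n_excl)

        feats = extract_features(gaze, velocity_threshold=cfg.ivt_threshold,
                                 min_fixation_ms=cfg.min_fixation_ms,
                                 pad_ms=cfg.blink_pad_ms)
        for name, s in feats.items():
            feature_rows.append(pd.DataFrame({
                "subject_id": label.subject_id, "video_id": label.video_id,
                "feature": name,
                "time_s": gaze.time, "value": s.values,
                "blink": s.blink_mask.astype(int)}))
        for series in list(eye_ratios.values()) + list(eeg_ratios.values()):
            frame = series.to_frame()
            frame.insert(0, "subject_id", label.subject_id)
            frame.insert(1, "video_id", label.video_id)
            ratio_frames.append(frame)
        try:
            all_results.extend(run_sync_matrix(eye_ratios, eeg_ratios, spec,
                                               label=label))
        except ValueError as err:
            raise RuntimeError(f"stage sync failed on {sid}: {err}") from err
        manifest_entries.append({
            "subject_id": label.subject_id, "video_id": label.video_id,
            "empathic": label.empathic, "valence": label.valence,
            "arousal": label.arousal, "couplings": truth_couplings})
    timings["features+spectral+sync"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results_df = results_to_frame(all_results)
    comps = build_comparisons(results_df)
    report_data = quadrant_report(comps)
    timings["compare"] = time.perf_counter() - t0

    paths = {
        "manifest": outdir / "manifest.json",
        "features": outdir / "features.csv",
        "band_ratios": outdir / "band_ratios.csv",
        "sync_results": outdir / "sync_results.csv",
        "comparisons": outdir / "comparisons.csv",
        "quadrant_report": outdir / "quadrant_report.json",
        "run_log": outdir / "run_log.json",
    }
    manifest = {"config_hash": h, "config": cfg.to_dict(),
                "sessions": manifest_sessions or manifest_entries}
    paths["manifest"].write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True, default=str))
    _write_csv(pd.concat(feature_rows, ignore_index=True), paths["features"], h)
    _write_csv(pd.concat(ratio_frames, ignore_index=True),
               paths["band_ratios"], h)
    _write_csv(results_df, paths["sync_results"], h)
    _write_csv(comparisons_to_frame(comps), paths["comparisons"], h)
    quad_json = {
        "config_hash": h,
        "quadrants": {
            q: [vars(c) for c in summary.triples]
            for q, summary in report_data.items()},
    }
    paths["quadrant_report"].write_text(
        json.dumps(quad_json, indent=2, sort_keys=True, default=str))

    import numpy
    import scipy
    import sklearn

    run_log = {
        "eyesync_version": __version__,
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__,
                     "pandas": pd.__version__},
        "seed": cfg.seed,
        "config_hash": h,
        "config": cfg.to_dict(),
        "timings_s": timings,
        "excluded_windows": excluded_windows,
    }
    paths["run_log"].write_text(json.dumps(run_log, indent=2, default=str))
    return paths


def report(outdir: str | Path) -> str:
    """Human-readable summary of a finished run's comparisons."""
    outdir = Path(outdir)
    comps_path = outdir / "comparisons.csv"
    if not comps_path.exists():
        raise FileNotFoundError(f"no comparisons.csv in {outdir}")
    df = pd.read_csv(comps_path, comment="#")
    lines = []
    retained = df[df["retained"] == True]  # noqa: E712
    if retained.empty:
        lines.append("No triples retained: zero retained triples after "
                     "exclusion criteria.")
    for quadrant, g in retained.groupby("quadrant"):
        lines.append(f"\n== {quadrant}: {len(g)} retained triple(s) ==")
        for _, row in g.sort_values(["eye_feature", "channel", "band"]).iterrows():
            mark = ("*" if row["p_value"] < 0.01
                    else "**" if row["p_value"] < 0.05 else "")
            lines.append(
                f"  {row['eye_feature']} ~ {row['channel']} [{row['band']}] "
                f"({row['hemisphere_tag']}): "
                f"emp {row['mean_emp']:.4f} ± {row['std_emp']:.4f} vs "
                f"non {row['mean_non']:.4f} ± {row['std_non']:.4f} "
                f"(p={row['p_value']:.2g}){mark}")
    return "\n".join(lines) if lines else "No comparisons."
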