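"""Formats, configuration and pipeline orchestration.

On-disk layout:

- HDF5 container: one group per subject holding the region x time
  array plus fs/label attributes; root attributes carry the seed and
  the config hash so mismatched stage inputs are detectable.
- TSV for all tabular exchange (metadata, features, statistics).
- YAML pipeline configuration with strict (unknown keys rejected)
  parsing; its SHA-256 hash is embedded in every output.
- EDF/BDF recordings are read through MNE with units coerced to uV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from oscillome.bands import DEFAULT_BANDS
from oscillome.preprocess import Recording
from oscillome.source import ROITimeSeries


# ---------------------------------------------------------------- config


@dataclass
class PipelineConfig:
    """Serializable stage parameters for a full run."""

    # simulation
    simulate: bool = True
    n_per_group: dict = field(default_factory=lambda: {"HC": 10, "PKD": 10})
    duration: float = 60.0
    fs: float = 500.0
    n_regions: int = 20
    effects: list = field(default_factory=list)   # EffectSpec kwargs dicts
    # spectral
    psd_window: float = 2.0
    psd_overlap: float = 1.0
    norm_range: tuple = (2.0, 90.0)
    morlet_fc: float = 1.0
    morlet_fwhm_tc: float = 3.0
    # preprocessing
    epoch_len: float = 2.0
    rejection_threshold_uv: float = 100.0
    # source
    lambda2: float = 1.0 / 9.0
    # pec
    pec_bands: list = field(default_factory=lambda: ["high_gamma"])
    pec_subsample: int = 10
    pec_env_samples_per_point: int = 4
    # stats
    n_perm: int = 1000
    alpha: float = 0.05
    robustness_replicates: int = 100
    subsample_fraction: float = 0.95
    # cpm
    run_cpm: bool = False
    cpm_p_threshold: float = 0.3
    cpm_groups: list = field(default_factory=list)  # the two labels CPM contrasts
    # global
    paradigm: str = "eyes_closed"
    seed: int = 0

    def __post_init__(self) -> None:
        self.norm_range = tuple(self.norm_range)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["norm_range"] = list(d["norm_range"])
        return d

    def hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record: hashes, seed, and per-stage counts."""

    config_hash: str
    seed: int
    software_version: str
    input_hashes: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------- container


def write_cohort(
    path,
    subjects: list[ROITimeSeries],
    metadata: pd.DataFrame,
    seed: int | None = None,
    config_hash: str = "",
) -> None:
    """Write a cohort of ROI time series to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        if seed is not None:
            f.attrs["seed"] = int(seed)
        f.attrs["metadata_json"] = metadata.to_json(orient="records")
        for sub in subjects:
            g = f.create_group(f"subjects/{sub.subject_id}")
            g.create_dataset("roi", data=sub.data)
            g.attrs["fs"] = sub.fs
            g.attrs["group"] = sub.group
            g.attrs["region_names"] = [n.encode() for n in sub.region_names]
            g.attrs["network_labels"] = [n.encode() for n in sub.network_labels]


def read_cohort(path) -> tuple[list[ROITimeSeries], pd.DataFrame]:
    with h5py.File(path, "r") as f:
        from io import StringIO

        meta = pd.read_json(StringIO(f.attrs["metadata_json"]), orient="records")
        subjects = []
        for sid in meta["subject_id"]:
            g = f[f"subjects/{sid}"]
            subjects.append(
                ROITimeSeries(
                    data=g["roi"][()],
                    fs=float(g.attrs["fs"]),
                    region_names=[
                        n.decode() if isinstance(n, bytes) else str(n)
                        for n in g.attrs["region_names"]
                    ],
                    network_labels=[
                        n.decode() if isinstance(n, bytes) else str(n)
                        for n in g.attrs["network_labels"]
                    ],
                    subject_id=str(sid),
                    group=str(g.attrs["group"]),
                )
            )
    return subjects, meta


def write_recording(path, rec: Recording, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        g = f.create_group("recording")
        g.create_dataset("data", data=rec.data)
        g.attrs["fs"] = rec.fs
        g.attrs["subject_id"] = rec.subject_id
        g.attrs["paradigm"] = rec.paradigm
        g.attrs["channel_labels"] = [c.encode() for c in rec.channel_labels]


def read_recording(path, format: str | None = None) -> Recording:
    """Read a sensor recording from EDF/BDF (via MNE) or the HDF5 container.

    EDF values are converted from MNE's volts to microvolts; a missing
    sampling rate or unreadable header is an error, never a guess.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".edf": "edf", ".bdf": "bdf", ".h5": "container", ".hdf5": "container"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if format == "container":
        with h5py.File(path, "r") as f:
            g = f["recording"]
            return Recording(
                data=g["data"][()],
                fs=float(g.attrs["fs"]),
                channel_labels=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in g.attrs["channel_labels"]
                ],
                subject_id=str(g.attrs["subject_id"]),
                paradigm=str(g.attrs["paradigm"]),
            )
    if format in ("edf", "bdf"):
        import mne

        reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_bdf
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as err:
            raise ValueError(f"failed to parse {format.upper()} file {path}: {err}")
        return Recording(
            data=raw.get_data() * 1e6,  # MNE volts -> uV
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            subject_id=path.stem,
        )
    raise ValueError(f"unsupported format {format!r}")


def write_features_tsv(path, features: np.ndarray, subject_ids, feature_names) -> None:
    df = pd.DataFrame(features, index=list(subject_ids), columns=list(feature_names))
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------- pipeline


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Simulate -> features -> statistics (-> CPM), writing all outputs.

    Stages run in order on a simulated cohort (raw-data ingestion goes
    through :func:`read_cohort` + the same feature functions).  The
    manifest reconciles per-stage record counts; reruns with the same
    config are deterministic.
    """
    from oscillome import __version__
    from oscillome.bands import get_band
    from oscillome.pec import pec_matrix, vectorize_pec, znorm_features
    from oscillome.spectral import band_envelope_coefficients, band_power, welch_psd, znorm_psd
    from oscillome.stats import RobustnessConfig, compare_groups
    from oscillome.synth import EffectSpec, SynthCohortConfig, gen_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    counts: dict = {}

    input_hashes: dict = {}
    if not config.simulate:
        with h5py.File(out / "cohort.h5", "r") as f:
            input_hashes["cohort.h5"] = str(f.attrs.get("config_hash", ""))
        subjects, meta = read_cohort(out / "cohort.h5")
    else:
        effects = tuple(EffectSpec(**e) for e in config.effects)
        synth_cfg = SynthCohortConfig(
            n_per_group=dict(config.n_per_group),
            fs=config.fs,
            duration=config.duration,
            n_regions=config.n_regions,
            effects=effects,
            paradigm=config.paradigm,
            seed=config.seed,
        )
        subjects, meta = gen_cohort(synth_cfg)
        write_cohort(out / "cohort.h5", subjects, meta, seed=config.seed, config_hash=chash)
    counts["subjects"] = len(subjects)
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)

    # band-power features
    bp_rows = []
    for sub in subjects:
        psd = znorm_psd(
            welch_psd(sub, window=config.psd_window, overlap=config.psd_overlap),
            norm_range=tuple(config.norm_range),
        )
        bp_rows.append(band_power(psd).ravel())
    band_names = [b.name for b in DEFAULT_BANDS]
    bp_names = [
        f"{r}:{b}" for r in subjects[0].region_names for b in band_names
    ]
    bp = np.asarray(bp_rows)
    write_features_tsv(out / "band_power.tsv", bp, meta["subject_id"], bp_names)
    counts["band_power_features"] = bp.shape[1]

    # PEC features for the configured bands
    pec_feats = {}
    for band_name in config.pec_bands:
        band = get_band(band_name)
        mats = []
        for sub in subjects:
            coeffs = band_envelope_coefficients(sub, band)
            mats.append(
                pec_matrix(
                    coeffs,
                    env_samples_per_point=config.pec_env_samples_per_point,
                    subsample=config.pec_subsample,
                )
            )
        pec_feats[band_name] = np.asarray([vectorize_pec(m, include_diagonal=False) for m in mats])
        counts[f"pec_features_{band_name}"] = pec_feats[band_name].shape[1]

    # group statistics on band power, per band, first two groups
    groups = list(dict.fromkeys(meta["group"]))[:2]
    sel = meta["group"].isin(groups).to_numpy()
    labels = meta["group"].to_numpy()[sel]
    rob = RobustnessConfig(
        n_replicates=config.robustness_replicates,
        subsample_fraction=config.subsample_fraction,
        alpha=config.alpha,
    )
    stats_frames = []
    for j, band_name in enumerate(band_names):
        feats = bp[sel][:, j::len(band_names)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = compare_groups(
                feats, labels, n_perm=config.n_perm, alpha=config.alpha,
                robustness=rob, seed=config.seed + 1,
            )
        frame = comp.to_frame(feature_names=subjects[0].region_names)
        frame.insert(0, "band", band_name)
        stats_frames.append(frame)
    stats_df = pd.concat(stats_frames, ignore_index=True)
    stats_df.to_csv(out / "band_power_stats.tsv", sep="\t", index=False)
    counts["significant_band_power"] = int(stats_df["significant"].sum())

    # optional CPM on z-scored PEC features
    if config.run_cpm and config.cpm_groups:
        from oscillome.cpm import CPMClassifier

        ga, gb = config.cpm_groups
        m = meta["group"].isin([ga, gb]).to_numpy()
        y = (meta["group"].to_numpy()[m] == gb).astype(int)
        X = znorm_features(np.hstack([pec_feats[b][m] for b in config.pec_bands]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = CPMClassifier(p_threshold=config.cpm_p_threshold).fit(X, y)
        pd.DataFrame(
            {
                "metric": ["train_accuracy", "train_auc", "n_pos", "n_neg"],
                "value": [
                    model.train_accuracy_,
                    model.train_auc_,
                    len(model.pos_features_),
                    len(model.neg_features_),
                ],
            }
        ).to_csv(out / "cpm_metrics.tsv", sep="\t", index=False)
        counts["cpm_selected"] = len(model.pos_features_) + len(model.neg_features_)

    manifest = RunManifest(
        config_hash=chash,
        seed=config.seed,
        software_version=__version__,
        input_hashes=input_hashes,
        stage_counts=counts,
    )
    manifest.write(out / "manifest.json")
    return manifest
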