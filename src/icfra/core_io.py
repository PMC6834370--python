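"""Domain types, table IO, configuration and logging.

The analysis operates on background-subtracted ROI fluorescence traces
acquired at a fixed frame interval (114.4 ms by default) while a grid of
pure tones (19 frequencies x 6 intensities, 1 s duration, 1.5 s
inter-stimulus interval) is presented in pseudorandom order.  This module
holds the stimulus protocol, the per-ROI session container, and readers and
writers for the flat CSV tables the pipeline consumes and emits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnalysisConfig",
    "StimulusProtocol",
    "RoiSession",
    "SourceDataTable",
    "SCHEMAS",
    "SchemaError",
    "build_default_protocol",
    "read_source_table",
    "write_source_table",
    "load_config",
    "save_config",
    "config_hash",
    "get_logger",
    "write_provenance",
    "write_session",
    "read_session",
]

GENOTYPES = ("GP4.3", "Gad2;Ai96")
FRA_TYPES = ("onset", "sustained", "inhibited", "offset", "mixed", "none")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Pipeline-wide defaults.

    Attributes
    ----------
    frame_interval_ms : imaging frame interval in milliseconds.
    bootstrap_n : number of bootstrap draws for the trial-correlation null.
    alpha : family-wise significance level for the Holm step-down test.
    rho_cross_threshold : neighbour cross-correlation needed to include a
        significant stimulus in response classification.
    class_fraction : fraction of significant responses a class must reach
        to name the FRA after it (two or more classes above it -> mixed).
    sustained_tau_ms : onset time constant above which an excitatory FRA is
        called sustained rather than onset.
    movement_r : Pearson-r threshold for movement-correlated cells.
    baseline_sd_mode : "trials" uses the s.d. across per-trial baseline
        means as the classification dispersion; "frames" uses the
        frame-wise s.d. within the baseline window.
    diameter_formula : "circle" -> d = 2*sqrt(A/pi); "4_over_pi" ->
        d = (4/pi)*sqrt(A).
    """

    frame_interval_ms: float = 114.4
    bootstrap_n: int = 30000
    alpha: float = 0.05
    rho_cross_threshold: float = 0.12
    class_fraction: float = 0.25
    sustained_tau_ms: float = 1000.0
    movement_r: float = 0.25
    baseline_sd_mode: str = "trials"
    diameter_formula: str = "circle"
    movement_tau_bounds_ms: tuple[float, float] = (300.0, 3000.0)
    log_base: str = "log10_hz"

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval_ms / 1000.0


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a key-value (YAML) config file, filling unset keys with defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "movement_tau_bounds_ms" in raw:
        raw["movement_tau_bounds_ms"] = tuple(raw["movement_tau_bounds_ms"])
    return AnalysisConfig(**raw)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["movement_tau_bounds_ms"] = list(d["movement_tau_bounds_ms"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_hash(cfg: AnalysisConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["movement_tau_bounds_ms"] = list(d["movement_tau_bounds_ms"])
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# Logging / provenance
# --------------------------------------------------------------------------

def get_logger(name: str = "icfra") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def write_provenance(path: str | Path, cfg: AnalysisConfig, seeds: dict) -> None:
    """Record config hash, seeds and library versions for a pipeline run."""
    import scipy

    record = {
        "config_hash": config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "seeds": seeds,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    record["config"]["movement_tau_bounds_ms"] = list(
        record["config"]["movement_tau_bounds_ms"]
    )
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# Stimulus protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """The tone grid (frequency x intensity) and its presentation schedule.

    ``order`` holds, per presentation, the flat stimulus index
    ``i_freq * n_intensities + i_intensity``.
    """

    frequencies_khz: np.ndarray
    intensities_db: np.ndarray
    duration_s: float
    isi_s: float
    n_reps: int
    order_seed: int
    order: np.ndarray = field(repr=False)

    def __post_init__(self):
        f = np.asarray(self.frequencies_khz, float)
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_reps < 2:
            raise ValueError(
                "n_reps must be >= 2 (the trial-correlation statistic needs pairs)"
            )

    @property
    def n_freqs(self) -> int:
        return len(self.frequencies_khz)

    @property
    def n_intensities(self) -> int:
        return len(self.intensities_db)

    @property
    def n_stimuli(self) -> int:
        return self.n_freqs * self.n_intensities

    @property
    def n_presentations(self) -> int:
        return len(self.order)

    @property
    def period_s(self) -> float:
        """Seconds from one tone onset to the next (duration + ISI)."""
        return self.duration_s + self.isi_s

    def grid_position(self, stim_index: int) -> tuple[int, int]:
        """(frequency index, intensity index) of a flat stimulus index."""
        return divmod(stim_index, self.n_intensities)

    def stimulus_freq_khz(self, stim_index) -> np.ndarray:
        return np.asarray(self.frequencies_khz)[
            np.asarray(stim_index) // self.n_intensities
        ]

    def stimulus_intensity_db(self, stim_index) -> np.ndarray:
        return np.asarray(self.intensities_db)[
            np.asarray(stim_index) % self.n_intensities
        ]

    def onset_frames(self, frame_interval_s: float, start_s: float = 2.0) -> np.ndarray:
        """Frame index of each tone onset on a regular presentation clock."""
        t = start_s + np.arange(self.n_presentations) * self.period_s
        return np.round(t / frame_interval_s).astype(int)


def build_default_protocol(n_reps: int = 10, order_seed: int = 0) -> StimulusProtocol:
    """The standard 19 x 6 tone grid: 1-64 kHz at 3 steps/octave, 30-80 dB SPL
    in 10 dB steps, 1 s tones, 1.5 s inter-stimulus interval, each stimulus
    repeated ``n_reps`` times in a seeded pseudorandom order."""
    if not 2 <= n_reps <= 50:
        raise ValueError("n_reps must be in [2, 50]")
    freqs = 2.0 ** (np.arange(19) / 3.0)  # kHz, 1 .. 64
    intens = np.arange(30.0, 81.0, 10.0)
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(np.repeat(np.arange(19 * 6), n_reps))
    return StimulusProtocol(
        frequencies_khz=freqs,
        intensities_db=intens,
        duration_s=1.0,
        isi_s=1.5,
        n_reps=n_reps,
        order_seed=order_seed,
        order=order,
    )


# --------------------------------------------------------------------------
# ROI session container
# --------------------------------------------------------------------------

@dataclass
class RoiSession:
    """One ROI's background-subtracted trace plus spatial metadata.

    Coordinates live in the common IC frame: origin at the superior/inferior
    colliculus contact point at the midline, x in µm medial->lateral, y in µm
    posterior->anterior, depth in µm from the pia.
    """

    roi_id: str
    trace: np.ndarray
    frame_interval_s: float
    stim_onset_frames: np.ndarray
    stim_index: np.ndarray
    x_um: float = np.nan
    y_um: float = np.nan
    depth_um: float = np.nan
    area_um2: float = np.nan
    genotype: str = "GP4.3"

    def __post_init__(self):
        self.trace = np.asarray(self.trace, float)
        self.stim_onset_frames = np.asarray(self.stim_onset_frames, int)
        self.stim_index = np.asarray(self.stim_index, int)
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not np.isnan(self.depth_um) and self.depth_um < 0:
            raise ValueError("depth_um must be >= 0")
        if len(self.stim_onset_frames) != len(self.stim_index):
            raise ValueError("stim_onset_frames and stim_index length mismatch")


# --------------------------------------------------------------------------
# Source-data tables
# --------------------------------------------------------------------------

class SchemaError(ValueError):
    """A table does not satisfy its declared schema."""


#: Required columns per schema (canonical names).
SCHEMAS: dict[str, tuple[str, ...]] = {
    "kinetics": ("tau_onset_ms", "tau_decay_ms", "genotype", "fra_type"),
    "roi_area": ("area_um2", "diameter_um", "genotype", "fra_type"),
    "groundtruth": (
        "f0",
        "f_1ap",
        "t_rise_ms",
        "tau_decay_ms",
        "variance_explained",
        "genotype",
        "fra_type",
    ),
    "cf_distribution": (
        "x_um",
        "y_um",
        "depth_um",
        "projected_r_um",
        "cf_khz",
        "genotype",
        "fra_type",
    ),
    "movement": ("x_um", "y_um", "depth_um", "genotype", "fra_type", "r_move"),
}

#: Header synonyms seen in deposited tables, already case/punctuation
#: normalized.  Extendable by the caller of read_source_table.
DEFAULT_ALIASES: dict[str, str] = {
    "x": "x_um",
    "y": "y_um",
    "z": "depth_um",
    "depth": "depth_um",
    "projected_distance": "projected_r_um",
    "projected_distance_um": "projected_r_um",
    "r": "projected_r_um",
    "cf": "cf_khz",
    "cf_hz": "cf_khz",
    "characteristic_frequency": "cf_khz",
    "area": "area_um2",
    "roi_area": "area_um2",
    "diameter": "diameter_um",
    "estimated_diameter": "diameter_um",
    "d": "diameter_um",
    "fra": "fra_type",
    "type": "fra_type",
    "type_of_fra": "fra_type",
    "response_class": "fra_type",
    "genotype_of_animal": "genotype",
    "line": "genotype",
    "f1ap": "f_1ap",
    "delta_f_1ap": "f_1ap",
    "trise": "t_rise_ms",
    "t_rise": "t_rise_ms",
    "tau_decay": "tau_decay_ms",
    "taudecay": "tau_decay_ms",
    "tau_onset": "tau_onset_ms",
    "tauonset": "tau_onset_ms",
    "variance": "variance_explained",
    "var_explained": "variance_explained",
    "r_movement": "r_move",
    "movement_r": "r_move",
}

_NUMERIC_COLUMNS = {
    "x_um", "y_um", "depth_um", "projected_r_um", "cf_khz", "area_um2",
    "diameter_um", "f0", "f_1ap", "t_rise_ms", "tau_decay_ms", "tau_onset_ms",
    "variance_explained", "r_move",
}


def _normalize(name: str) -> str:
    s = re.sub(r"[^0-9a-zA-Z]+", "_", str(name).strip().lower()).strip("_")
    return s


@dataclass
class SourceDataTable:
    schema_name: str
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def read_source_table(
    path: str | Path,
    schema_name: str,
    aliases: dict[str, str] | None = None,
) -> SourceDataTable:
    """Read a comma-separated table and validate it against a named schema.

    Column headers are matched case-insensitively; synonyms are mapped to
    canonical names through an alias table (caller entries extend the
    defaults).  Unknown extra columns are preserved untouched.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    alias = dict(DEFAULT_ALIASES)
    if aliases:
        alias.update({_normalize(k): v for k, v in aliases.items()})
    rename = {}
    for col in df.columns:
        norm = _normalize(col)
        rename[col] = alias.get(norm, norm)
    df = df.rename(columns=rename)

    required = SCHEMAS[schema_name]
    for col in required:
        if col not in df.columns:
            raise SchemaError(
                f"schema {schema_name!r}: required column {col!r} missing "
                f"(have {list(df.columns)})"
            )
    for col in df.columns:
        if col in _NUMERIC_COLUMNS:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise SchemaError(
                    f"column {col!r}: non-numeric value at row "
                    f"{int(np.flatnonzero(bad)[0])}"
                )
            df[col] = coerced
    if "cf_khz" in required and (df["cf_khz"].dropna() <= 0).any():
        raise SchemaError("cf_khz must be positive")
    return SourceDataTable(schema_name=schema_name, rows=df)


def write_source_table(table: SourceDataTable, path: str | Path) -> None:
    """Write a table back to CSV; numeric values keep >= 6 significant digits."""
    table.rows.to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# Session IO (trace matrix + sidecar metadata + manifest)
# --------------------------------------------------------------------------

def write_session(
    sessions: list[RoiSession],
    out_dir: str | Path,
    protocol: StimulusProtocol | None = None,
) -> None:
    """Persist a list of ROI sessions sharing one frame clock and schedule.

    Layout: ``traces.csv`` (frames x ROIs), ``rois.csv`` (spatial metadata),
    ``schedule.csv`` (per presentation onset frame and stimulus index) and a
    ``manifest.yaml`` with the clock and, when given, the protocol grid.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = max(len(s.trace) for s in sessions)
    mat = pd.DataFrame(
        {s.roi_id: np.pad(s.trace, (0, n - len(s.trace)), constant_values=np.nan)
         for s in sessions}
    )
    mat.to_csv(out / "traces.csv", index=False, float_format="%.8g")
    meta = pd.DataFrame(
        [
            {
                "roi_id": s.roi_id,
                "x_um": s.x_um,
                "y_um": s.y_um,
                "depth_um": s.depth_um,
                "area_um2": s.area_um2,
                "genotype": s.genotype,
            }
            for s in sessions
        ]
    )
    meta.to_csv(out / "rois.csv", index=False)
    s0 = sessions[0]
    pd.DataFrame(
        {"onset_frame": s0.stim_onset_frames, "stim_index": s0.stim_index}
    ).to_csv(out / "schedule.csv", index=False)
    manifest = {"frame_interval_s": float(s0.frame_interval_s)}
    if protocol is not None:
        manifest["protocol"] = {
            "frequencies_khz": [float(f) for f in protocol.frequencies_khz],
            "intensities_db": [float(i) for i in protocol.intensities_db],
            "duration_s": float(protocol.duration_s),
            "isi_s": float(protocol.isi_s),
            "n_reps": int(protocol.n_reps),
            "order_seed": int(protocol.order_seed),
        }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_session(in_dir: str | Path) -> tuple[list[RoiSession], StimulusProtocol | None]:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    traces = pd.read_csv(in_dir / "traces.csv")
    meta = pd.read_csv(in_dir / "rois.csv").set_index("roi_id")
    sched = pd.read_csv(in_dir / "schedule.csv")
    protocol = None
    if "protocol" in manifest:
        p = manifest["protocol"]
        rng = np.random.default_rng(p["order_seed"])
        n_stim = len(p["frequencies_khz"]) * len(p["intensities_db"])
        order = rng.permutation(np.repeat(np.arange(n_stim), p["n_reps"]))
        protocol = StimulusProtocol(
            frequencies_khz=np.asarray(p["frequencies_khz"]),
            intensities_db=np.asarray(p["intensities_db"]),
            duration_s=p["duration_s"],
            isi_s=p["isi_s"],
            n_reps=p["n_reps"],
            order_seed=p["order_seed"],
            order=order,
        )
    sessions = []
    for roi_id in traces.columns:
        trace = traces[roi_id].to_numpy(float)
        trace = trace[~np.isnan(trace)]
        row = meta.loc[roi_id] if roi_id in meta.index else None
        sessions.append(
            RoiSession(
                roi_id=roi_id,
                trace=trace,
                frame_interval_s=manifest["frame_interval_s"],
                stim_onset_frames=sched["onset_frame"].to_numpy(int),
                stim_index=sched["stim_index"].to_numpy(int),
                x_um=float(row["x_um"]) if row is not None else np.nan,
                y_um=float(row["y_um"]) if row is not None else np.nan,
                depth_um=float(row["depth_um"]) if row is not None else np.nan,
                area_um2=float(row["area_um2"]) if row is not None else np.nan,
                genotype=str(row["genotype"]) if row is not None else "GP4.3",
            )
        )
    return sessions, protocol
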