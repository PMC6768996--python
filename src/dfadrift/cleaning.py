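"""Cleaning and segmentation of raw buoy transmission tables.

The pipeline is: basic filters (duplicates, single-position and short
tracks, unrealistic implied speeds) -> per-position kinematic features ->
at-sea/on-board classification (random forest trained on synthetic ground
truth, or a speed/port fallback rule) -> desegmentation smoothing of
isolated labels -> splitting into drift segments whose first position is
the deployment.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .geo import LandMask, haversine_km, initial_bearing_deg, normalize_lon

__all__ = [
    "FEATURE_COLUMNS",
    "DriftSegment",
    "PositionClassifier",
    "SpeedPortRule",
    "CleaningResult",
    "basic_filters",
    "compute_features",
    "train_position_classifier",
    "classify_positions",
    "desegment",
    "split_segments",
    "clean_and_segment",
]

FEATURE_COLUMNS = ["dt_h", "speed_kmh", "accel_kmh2", "heading_change_deg",
                   "dist_to_port_km"]

AT_SEA = "at_sea"
ON_BOARD = "on_board"


@dataclass
class DriftSegment:
    """A maximal run of at-sea positions of one buoy; the first position is
    the deployment."""

    buoy_id: str
    segment_index: int
    times: np.ndarray       # datetime64[ns]
    lons: np.ndarray
    lats: np.ndarray

    def __len__(self):
        return len(self.times)

    @property
    def deployment(self):
        return float(self.lons[0]), float(self.lats[0]), self.times[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"buoy_id": self.buoy_id,
                             "segment_index": self.segment_index,
                             "timestamp": self.times,
                             "lon": self.lons, "lat": self.lats})


# ---------------------------------------------------------------------------
# Basic filters
# ---------------------------------------------------------------------------

def basic_filters(tracks: pd.DataFrame, min_duration_h: float = 24.0,
                  max_speed_kmh: float = 30.0):
    """Remove duplicates, speed spikes, single-position and short tracks.

    Returns (kept, rejections); every rejected row carries a reason code in
    {duplicate, excess_speed, single_position, short_duration}.
    """
    cols = ["buoy_id", "timestamp", "lon", "lat"]
    if tracks.empty:
        empty = tracks.reindex(columns=cols)
        rej = empty.copy()
        rej["reason"] = pd.Series(dtype=object)
        return empty, rej
    df = tracks[cols].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["lon"] = normalize_lon(df["lon"].to_numpy(float))
    df = df.sort_values(["buoy_id", "timestamp"], kind="stable").reset_index(drop=True)

    rejections = []

    dup = df.duplicated(subset=["buoy_id", "timestamp"], keep="first")
    if dup.any():
        r = df[dup].copy()
        r["reason"] = "duplicate"
        rejections.append(r)
        df = df[~dup].reset_index(drop=True)

    kept_parts = []
    for _, g in df.groupby("buoy_id", sort=False):
        t = g["timestamp"].to_numpy()
        lon = g["lon"].to_numpy()
        lat = g["lat"].to_numpy()
        dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
        d_km = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        speeds = np.divide(d_km, dt_h, out=np.full_like(d_km, np.inf),
                           where=dt_h > 0)
        keep = np.ones(len(g), dtype=bool)
        if np.any(speeds > max_speed_kmh):
            # greedy scan: drop a position if its speed from the previous
            # *kept* position is unrealistic
            last = 0
            for i in range(1, len(g)):
                dt = (t[i] - t[last]).astype("timedelta64[s]").astype(float) / 3600.0
                sp = haversine_km(lon[last], lat[last], lon[i], lat[i]) / max(dt, 1e-9)
                if sp > max_speed_kmh:
                    keep[i] = False
                else:
                    last = i
        if not keep.all():
            r = g[~keep].copy()
            r["reason"] = "excess_speed"
            rejections.append(r)
            g = g[keep]
        if len(g) <= 1:
            r = g.copy()
            r["reason"] = "single_position"
            rejections.append(r)
            continue
        span_h = (g["timestamp"].iloc[-1] - g["timestamp"].iloc[0]).total_seconds() / 3600.0
        if span_h < min_duration_h:
            r = g.copy()
            r["reason"] = "short_duration"
            rejections.append(r)
            continue
        kept_parts.append(g)

    kept = (pd.concat(kept_parts, ignore_index=True) if kept_parts
            else df.iloc[0:0].copy())
    rej = (pd.concat(rejections, ignore_index=True) if rejections
           else df.iloc[0:0].assign(reason=pd.Series(dtype=object)))
    return kept, rej


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def compute_features(track: pd.DataFrame,
                     ports: Optional[np.ndarray] = None,
                     mask: Optional[LandMask] = None) -> pd.DataFrame:
    """Kinematic features per position of one cleaned track.

    dt (h), speed (km/h), acceleration (km/h^2), heading change (deg in
    [0, 180]) and distance to the nearest major port (km).  Undefined
    derivatives on the first/second rows are filled with 0.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 positions to compute features")
    t = pd.to_datetime(track["timestamp"]).to_numpy()
    lon = normalize_lon(track["lon"].to_numpy(float))
    lat = track["lat"].to_numpy(float)
    n = len(t)

    dt_h = np.zeros(n)
    dt_h[1:] = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
    if np.any(dt_h[1:] <= 0):
        raise ValueError("timestamps must be strictly increasing")

    speed = np.zeros(n)
    speed[1:] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) / dt_h[1:]
    accel = np.zeros(n)
    accel[2:] = np.diff(speed)[1:] / dt_h[2:]

    heading = np.zeros(n)
    heading[1:] = initial_bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
    hchange = np.zeros(n)
    raw = np.abs(np.diff(heading)[1:])
    hchange[2:] = np.minimum(raw, 360.0 - raw)
    # stationary fixes have no defined heading; zero the change there
    hchange[2:] = np.where((speed[2:] == 0) | (speed[1:-1] == 0), 0.0, hchange[2:])

    if ports is None and mask is not None:
        ports = mask.ports
    if ports is not None and len(ports):
        ports = np.asarray(ports, float).reshape(-1, 2)
        dport = haversine_km(lon[:, None], lat[:, None],
                             ports[None, :, 0], ports[None, :, 1]).min(axis=1)
        dport = np.minimum(dport, 20000.0)
    else:
        dport = np.full(n, 20000.0)

    return pd.DataFrame({
        "dt_h": dt_h, "speed_kmh": speed, "accel_kmh2": accel,
        "heading_change_deg": hchange, "dist_to_port_km": dport,
    }, index=track.index)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class PositionClassifier:
    """A fitted ensemble-of-trees at-sea/on-board classifier."""

    model: RandomForestClassifier
    feature_names: list
    holdout_accuracy: float
    rng_seed: int

    def predict_labels(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(float)
        proba = self.model.predict_proba(X)
        on_board_col = list(self.model.classes_).index(ON_BOARD)
        return np.where(proba[:, on_board_col] >= 0.5, ON_BOARD, AT_SEA)

    def save(self, path):
        joblib.dump({"model": self.model, "feature_names": self.feature_names,
                     "holdout_accuracy": self.holdout_accuracy,
                     "rng_seed": self.rng_seed}, path)

    @classmethod
    def load(cls, path) -> "PositionClassifier":
        d = joblib.load(path)
        return cls(**d)


@dataclass
class SpeedPortRule:
    """Threshold fallback: on-board when moving at vessel-like speed or when
    sitting close to a major port."""

    speed_threshold_kmh: float = 7.0
    port_dist_km: float = 10.0

    def predict_labels(self, features: pd.DataFrame) -> np.ndarray:
        on_board = (features["speed_kmh"].to_numpy() > self.speed_threshold_kmh) | \
                   (features["dist_to_port_km"].to_numpy() < self.port_dist_km)
        return np.where(on_board, ON_BOARD, AT_SEA)


def train_position_classifier(features: pd.DataFrame, labels,
                              rng_seed: int = 0, holdout_fraction: float = 0.25,
                              n_estimators: int = 100) -> PositionClassifier:
    """Train the random-forest at-sea/on-board classifier on labelled rows;
    reports held-out accuracy.  Raises on a single-class training set."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = features[FEATURE_COLUMNS].to_numpy(float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=rng_seed, stratify=y)
    rf = RandomForestClassifier(n_estimators=n_estimators,
                                random_state=rng_seed, n_jobs=1)
    rf.fit(X_tr, y_tr)
    acc = float((rf.predict(X_te) == y_te).mean())
    return PositionClassifier(rf, FEATURE_COLUMNS, acc, rng_seed)


def classify_positions(features: pd.DataFrame, model) -> np.ndarray:
    """Label positions at_sea/on_board with a trained classifier or the
    fallback rule (anything exposing predict_labels)."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"features missing columns {missing}")
    return model.predict_labels(features)


# ---------------------------------------------------------------------------
# Desegmentation
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray):
    edges = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(labels)]])
    return list(zip(starts, ends))


def desegment(labels, min_run: int = 3) -> np.ndarray:
    """Remove isolated label runs shorter than `min_run`.

    The shortest (leftmost on ties) offending run is flipped to its
    neighbours' label and merged, repeatedly, until every remaining run has
    length >= min_run or a single run remains.  Idempotent by construction.
    """
    lab = np.asarray(labels).copy()
    if len(lab) == 0:
        return lab
    while True:
        runs = _runs(lab)
        if len(runs) <= 1:
            return lab
        lengths = [e - s for s, e in runs]
        short = [i for i, L in enumerate(lengths) if L < min_run]
        if not short:
            return lab
        # interior runs first: they sit between agreeing neighbours
        interior = [i for i in short if 0 < i < len(runs) - 1]
        pool = interior if interior else short
        i = min(pool, key=lambda j: (lengths[j], j))
        s, e = runs[i]
        neighbour = runs[i - 1][0] if i > 0 else runs[i + 1][0]
        lab[s:e] = lab[neighbour]


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def split_segments(track: pd.DataFrame, labels) -> list:
    """One DriftSegment per maximal at-sea run; on-board positions are
    excluded from every segment."""
    lab = np.asarray(labels)
    t = pd.to_datetime(track["timestamp"]).to_numpy()
    lon = normalize_lon(track["lon"].to_numpy(float))
    lat = track["lat"].to_numpy(float)
    buoy = str(track["buoy_id"].iloc[0]) if len(track) else ""
    segments = []
    k = 0
    for s, e in _runs(lab):
        if lab[s] != AT_SEA:
            continue
        k += 1
        segments.append(DriftSegment(buoy, k, t[s:e], lon[s:e], lat[s:e]))
    return segments


@dataclass
class CleaningResult:
    """Output of the full cleaning pipeline with conservation accounting."""

    segments: list
    labels: pd.DataFrame          # buoy_id, timestamp, lon, lat, label
    rejections: pd.DataFrame      # ... , reason
    n_input: int = 0

    def accounting(self) -> dict:
        n_seg = int(sum(len(s) for s in self.segments))
        n_board = int((self.labels["label"] == ON_BOARD).sum())
        return {"input": self.n_input, "rejected": len(self.rejections),
                "on_board": n_board, "in_segments": n_seg,
                "balance": self.n_input - len(self.rejections) - n_board - n_seg}


def clean_and_segment(tracks: pd.DataFrame, model, *,
                      ports: Optional[np.ndarray] = None,
                      mask: Optional[LandMask] = None,
                      min_duration_h: float = 24.0,
                      max_speed_kmh: float = 30.0,
                      min_run: int = 3) -> CleaningResult:
    """Full cleaning pipeline: filters -> features -> classify -> desegment
    -> drift segments.  Every input position ends up rejected (with reason),
    labelled on-board, or in exactly one drift segment."""
    n_input = len(tracks)
    kept, rejections = basic_filters(tracks, min_duration_h, max_speed_kmh)
    label_parts = []
    segments = []
    extra_rej = []
    for _, g in kept.groupby("buoy_id", sort=False):
        if len(g) < 3:
            r = g.copy()
            r["reason"] = "too_few_positions"
            extra_rej.append(r)
            continue
        feats = compute_features(g, ports=ports, mask=mask)
        raw = classify_positions(feats, model)
        lab = desegment(raw, min_run=min_run)
        out = g.copy()
        out["label"] = lab
        label_parts.append(out)
        segments.extend(split_segments(g, lab))
    labels = (pd.concat(label_parts, ignore_index=True) if label_parts
              else kept.iloc[0:0].assign(label=pd.Series(dtype=object)))
    if extra_rej:
        rejections = pd.concat([rejections] + extra_rej, ignore_index=True)
    # re-number segment indices per buoy in chronological order
    return CleaningResult(segments, labels, rejections, n_input)
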