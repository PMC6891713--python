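"""Synthetic SisFall-like accelerometer recordings and delimited-file I/O.

The generator emulates the structure of a waist-worn triaxial accelerometer
study: sessions recorded at 200 Hz from a cohort of adults and elderly
participants, with per-sample labels in {BKG, ALERT, FALL}.  BKG covers
activities of daily living (rest, walking, sit-stand transfers, jumps) and
the time spent lying after a fall; ALERT covers fall hazards (the unstable
phase before an impact, or a stumble the subject recovers from); FALL covers
the impact itself — a short transient whose vector magnitude exceeds 2.5 g,
followed by a sustained orientation change.

Every fall event is therefore structured as  ALERT (hazard) -> FALL (impact)
-> BKG (lying), and a hazard-without-fall event as ALERT -> BKG (recovery).
The class mix this produces is strongly imbalanced (BKG >> FALL > ALERT at
block level), which is the regime a fall detector must cope with.

Units are g throughout (gravity = 1.0); conversion from raw ADC counts is
confined to :class:`FileDialect`.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Class order used everywhere in the package (relevance ascends rightward).
CLASSES = ("BKG", "ALERT", "FALL")

_LABEL_DTYPE = "<U5"

# Event morphology (seconds).  Hazard and impact bounds are drawn uniformly
# per event; lying/recovery are BKG by definition.
HAZARD_DURATION_S = (0.5, 1.5)
IMPACT_DURATION_S = (0.2, 0.4)
LYING_DURATION_S = (2.0, 5.0)
RECOVERY_DURATION_S = (0.5, 1.0)
IMPACT_PEAK_G = (2.5, 3.5)  # spike amplitude added on top of gravity


@dataclass
class Recording:
    """One labeled session from a waist-mounted triaxial accelerometer."""

    subject_id: str
    age_group: str  # "adult" | "elderly"
    sample_rate_hz: float
    samples: np.ndarray  # (T, 3) float64, g units
    labels: np.ndarray  # (T,) str in CLASSES
    recording_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=_LABEL_DTYPE)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (T, 3), got {self.samples.shape}")
        if len(self.samples) != len(self.labels):
            raise ValueError(
                f"samples ({len(self.samples)}) and labels ({len(self.labels)}) "
                "must have equal length"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration values must be finite")
        unknown = set(np.unique(self.labels)) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        if self.recording_id is None:
            self.recording_id = self.subject_id

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class GeneratorProfile:
    """Study conditions for the synthetic cohort.

    Defaults mirror the composition of the emulated study: 23 adults and
    15 elderly subjects, 60 s sessions sampled at 200 Hz, a couple of fall
    events and one avoided hazard per session, and 0.05 g sensor noise.
    """

    n_adults: int = 23
    n_elderly: int = 15
    recording_duration_s: float = 60.0
    sample_rate_hz: float = 200.0
    event_rates: dict = field(default_factory=lambda: {"fall": 2.0, "hazard": 1.0})
    adl_mix: dict = field(
        default_factory=lambda: {"rest": 0.4, "walk": 0.4, "sit-stand": 0.15, "jump": 0.05}
    )
    noise_sd_g: float = 0.05
    gravity_g: float = 1.0
    recordings_per_subject: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adults < 0 or self.n_elderly < 0:
            raise ValueError("subject counts must be non-negative")
        if not self.recording_duration_s > 0:
            raise ValueError(
                f"recording_duration_s must be positive, got {self.recording_duration_s}"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be non-negative")
        weights = list(self.adl_mix.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("adl_mix weights must be non-negative with at least one positive")
        unknown = set(self.adl_mix) - {"rest", "walk", "sit-stand", "jump"}
        if unknown:
            raise ValueError(f"unknown ADL activities: {sorted(unknown)}")
        for k in self.event_rates:
            if k not in ("fall", "hazard"):
                raise ValueError(f"unknown event type: {k!r}")
            if self.event_rates[k] < 0:
                raise ValueError("event rates must be non-negative")


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """One stream per subject: stable under changes to the subject count."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode())])
    )


# ---------------------------------------------------------------------------
# Signal synthesis


def _adl_segment(
    kind: str, n: int, rate: float, g_vec: np.ndarray, gravity: float, rng: np.random.Generator
) -> np.ndarray:
    """Acceleration for one background activity segment (no noise)."""
    t = np.arange(n) / rate
    out = np.tile(g_vec, (n, 1))
    vert = g_vec / max(np.linalg.norm(g_vec), 1e-12)
    if kind == "rest":
        pass
    elif kind == "walk":
        # gait oscillation: ~2 Hz vertical bounce plus a small lateral sway
        f = rng.uniform(1.8, 2.2)
        out += np.outer(0.25 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)), vert)
        lateral = np.array([1.0, 0.0, 0.0])
        out += np.outer(0.1 * np.sin(2 * np.pi * f / 2 * t), lateral)
    elif kind == "sit-stand":
        # one smooth vertical excursion spanning the segment
        amp = rng.choice([-0.4, 0.4])
        out += np.outer(amp * np.sin(np.pi * t / (n / rate)), vert)
    elif kind == "jump":
        # a single sub-threshold spike (< 2.5 g peak) inside a rest segment
        dur = max(2, int(0.15 * rate))
        start = rng.integers(0, max(1, n - dur))
        spike = 1.2 * np.sin(np.pi * np.arange(dur) / dur)
        out[start : start + dur] += np.outer(spike[: n - start], vert)
    else:  # pragma: no cover - profile validation rejects earlier
        raise ValueError(f"unknown ADL kind: {kind!r}")
    return out


def _hazard_segment(n: int, rate: float, g_vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Erratic stumble: fast moderate-amplitude oscillation on all axes."""
    t = np.arange(n) / rate
    out = np.tile(g_vec, (n, 1))
    for axis in range(3):
        f = rng.uniform(4.0, 6.0)
        out[:, axis] += 0.7 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _impact_segment(
    n: int, g_vec: np.ndarray, peak_g: float, rng: np.random.Generator
) -> np.ndarray:
    """Impact transient: half-sine spike along the current vertical."""
    vert = g_vec / max(np.linalg.norm(g_vec), 1e-12)
    spike = peak_g * np.sin(np.pi * np.arange(n) / max(n - 1, 1))
    spike[n // 2] = peak_g  # guarantee the peak is attained on the grid
    return np.tile(g_vec, (n, 1)) + np.outer(spike, vert)


def _lying_orientation(gravity: float, rng: np.random.Generator) -> np.ndarray:
    """Post-fall orientation: gravity moves to a horizontal axis."""
    axis = rng.integers(0, 2)  # x or y
    sign = rng.choice([-1.0, 1.0])
    g_vec = np.zeros(3)
    g_vec[axis] = sign * gravity
    return g_vec


def generate_recording(
    profile: GeneratorProfile,
    subject_id: str,
    age_group: str,
    rng_stream: np.random.Generator,
    recording_id: str | None = None,
) -> Recording:
    """Synthesize one labeled session for one subject.

    The session timeline alternates ADL filler (BKG) with events drawn from
    ``profile.event_rates`` (expected counts per recording, Poisson).  A fall
    event contributes ALERT (hazard phase), FALL (impact, peak magnitude
    >= 2.5 g) and BKG (lying at a changed orientation); a hazard event
    contributes ALERT then a BKG recovery.
    """
    rate = profile.sample_rate_hz
    n_total = int(round(profile.recording_duration_s * rate))
    if n_total <= 0:
        raise ValueError(
            f"recording duration {profile.recording_duration_s} s yields no samples"
        )
    rng = rng_stream
    gravity = profile.gravity_g
    upright = np.array([0.0, 0.0, gravity])

    # --- draw events -------------------------------------------------------
    n_falls = int(rng.poisson(profile.event_rates.get("fall", 0.0)))
    n_hazards = int(rng.poisson(profile.event_rates.get("hazard", 0.0)))
    events: list[tuple] = []  # (kind, [(phase_label, duration_s), ...])
    for _ in range(n_falls):
        events.append(
            (
                "fall",
                [
                    ("ALERT", rng.uniform(*HAZARD_DURATION_S)),
                    ("FALL", rng.uniform(*IMPACT_DURATION_S)),
                    ("LYING", rng.uniform(*LYING_DURATION_S)),
                ],
            )
        )
    for _ in range(n_hazards):
        events.append(
            (
                "hazard",
                [
                    ("ALERT", rng.uniform(*HAZARD_DURATION_S)),
                    ("RECOVER", rng.uniform(*RECOVERY_DURATION_S)),
                ],
            )
        )
    rng.shuffle(events)
    # drop events that no longer fit the session (rare at default rates)
    while events and sum(d for _, ph in events for _, d in ph) > 0.9 * profile.recording_duration_s:
        events.pop()

    event_time = sum(d for _, ph in events for _, d in ph)
    filler_time = profile.recording_duration_s - event_time
    # split BKG filler around the events
    shares = rng.dirichlet(np.ones(len(events) + 1)) if events else np.array([1.0])
    filler_durations = shares * filler_time

    # --- synthesize segments ------------------------------------------------
    adl_kinds = [k for k, w in profile.adl_mix.items() if w > 0]
    adl_w = np.array([profile.adl_mix[k] for k in adl_kinds], dtype=float)
    adl_w = adl_w / adl_w.sum()

    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    g_vec = upright.copy()

    def emit(values: np.ndarray, label: str) -> None:
        chunks.append(values)
        labels.append(np.full(len(values), label, dtype=_LABEL_DTYPE))

    def emit_filler(duration_s: float) -> None:
        remaining = int(round(duration_s * rate))
        while remaining > 0:
            kind = adl_kinds[rng.choice(len(adl_kinds), p=adl_w)]
            n = min(remaining, int(round(rng.uniform(2.0, 6.0) * rate)))
            if n <= 0:
                break
            emit(_adl_segment(kind, n, rate, g_vec, gravity, rng), "BKG")
            remaining -= n

    for i, (kind, phases) in enumerate(events):
        emit_filler(filler_durations[i])
        for phase, dur in phases:
            n = max(1, int(round(dur * rate)))
            if phase == "ALERT":
                emit(_hazard_segment(n, rate, g_vec, rng), "ALERT")
            elif phase == "FALL":
                emit(_impact_segment(n, g_vec, rng.uniform(*IMPACT_PEAK_G), rng), "FALL")
                g_vec = _lying_orientation(gravity, rng)  # the fall changes posture
            elif phase == "LYING":
                emit(np.tile(g_vec, (n, 1)), "BKG")
                g_vec = upright.copy()  # subject gets up afterwards
            elif phase == "RECOVER":
                emit(np.tile(g_vec, (n, 1)), "BKG")
    emit_filler(filler_durations[-1])

    samples = np.concatenate(chunks, axis=0) if chunks else np.tile(g_vec, (n_total, 1))
    label_arr = np.concatenate(labels) if labels else np.full(n_total, "BKG", dtype=_LABEL_DTYPE)
    # trim/pad rounding drift to the exact sample count
    if len(samples) >= n_total:
        samples, label_arr = samples[:n_total], label_arr[:n_total]
    else:
        pad = n_total - len(samples)
        samples = np.concatenate([samples, np.tile(g_vec, (pad, 1))])
        label_arr = np.concatenate([label_arr, np.full(pad, "BKG", dtype=_LABEL_DTYPE)])

    if profile.noise_sd_g > 0:
        samples = samples + rng.normal(0.0, profile.noise_sd_g, size=samples.shape)

    return Recording(
        subject_id=subject_id,
        age_group=age_group,
        sample_rate_hz=rate,
        samples=samples,
        labels=label_arr,
        recording_id=recording_id or subject_id,
    )


def generate_dataset(profile: GeneratorProfile) -> dict[str, list[Recording]]:
    """Generate the full cohort, keyed by subject id.

    Subject ids follow the SA/SE convention (adults/elderly).  The roster is
    a deterministic function of the subject counts alone; sample values
    depend on the profile seed through one random stream per subject.
    """
    if profile.n_adults + profile.n_elderly < 1:
        raise ValueError("at least one subject is required")
    roster = [(f"SA{i + 1:02d}", "adult") for i in range(profile.n_adults)]
    roster += [(f"SE{i + 1:02d}", "elderly") for i in range(profile.n_elderly)]
    dataset: dict[str, list[Recording]] = {}
    for subject_id, age_group in roster:
        rng = _subject_rng(profile.seed, subject_id)
        dataset[subject_id] = [
            generate_recording(
                profile, subject_id, age_group, rng, recording_id=f"{subject_id}_R{k + 1:02d}"
            )
            for k in range(profile.recordings_per_subject)
        ]
    return dataset


def expected_label_fractions(profile: GeneratorProfile) -> dict[str, float]:
    """Closed-form expected per-sample label fractions for a profile.

    Follows directly from the event rates and the uniform phase-duration
    bounds: each fall contributes E[impact] seconds of FALL and E[hazard]
    seconds of ALERT; each hazard event contributes E[hazard] of ALERT;
    everything else (including lying/recovery) is BKG.
    """
    dur = profile.recording_duration_s
    e_hazard = float(np.mean(HAZARD_DURATION_S))
    e_impact = float(np.mean(IMPACT_DURATION_S))
    rate_f = profile.event_rates.get("fall", 0.0)
    rate_h = profile.event_rates.get("hazard", 0.0)
    frac_fall = rate_f * e_impact / dur
    frac_alert = (rate_f + rate_h) * e_hazard / dur
    return {"BKG": 1.0 - frac_fall - frac_alert, "ALERT": frac_alert, "FALL": frac_fall}


# ---------------------------------------------------------------------------
# File I/O


@dataclass
class FileDialect:
    """Layout of a SisFall-style delimited text file.

    ``scale`` converts raw stored values to g (acceleration = raw * scale);
    files written with ``integer_raw`` store rounded ADC counts.  Columns
    beyond the three accelerometer ones (e.g. gyroscope) are parsed for
    well-formedness and discarded.
    """

    delimiter: str = ","
    n_columns: int = 3
    acc_columns: tuple = (0, 1, 2)
    scale: float = 1.0
    skip_header: int = 0
    integer_raw: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "FileDialect":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**dict(d))

    def __post_init__(self) -> None:
        if len(self.acc_columns) != 3:
            raise ValueError("acc_columns must name exactly three columns")
        if max(self.acc_columns) >= self.n_columns:
            raise ValueError("acc_columns exceed n_columns")
        if self.scale == 0:
            raise ValueError("scale must be nonzero")


def _label_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels")


def read_sisfall_like(
    path,
    dialect: FileDialect | Mapping,
    sample_rate_hz: float = 200.0,
    subject_id: str = "unknown",
    age_group: str = "adult",
) -> Recording:
    """Read one delimited recording file; labels come from a ``.labels``
    sidecar when present, otherwise every sample is BKG."""
    if not isinstance(dialect, FileDialect):
        dialect = FileDialect.from_dict(dialect)
    path = Path(path)
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for lineno, row in enumerate(reader, start=1):
            if lineno <= dialect.skip_header:
                continue
            # tolerate SisFall-style trailing ';' and blank lines
            row = [c.strip().rstrip(";") for c in row]
            row = [c for c in row if c != ""]
            if not row:
                continue
            if len(row) != dialect.n_columns:
                raise ValueError(
                    f"{path}, line {lineno}: expected {dialect.n_columns} fields, "
                    f"got {len(row)}"
                )
            try:
                rows.append([float(row[i]) for i in dialect.acc_columns])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric field ({exc})") from None
    samples = np.asarray(rows, dtype=float) * dialect.scale
    sidecar = _label_sidecar(path)
    if sidecar.exists():
        labels = np.array(
            [ln.strip() for ln in sidecar.read_text().splitlines() if ln.strip()],
            dtype=_LABEL_DTYPE,
        )
    else:
        labels = np.full(len(samples), "BKG", dtype=_LABEL_DTYPE)
    return Recording(
        subject_id=subject_id,
        age_group=age_group,
        sample_rate_hz=sample_rate_hz,
        samples=samples,
        labels=labels,
        recording_id=path.stem,
    )


def write_sisfall_like(
    recording: Recording, path, dialect: FileDialect | Mapping, write_labels: bool = True
) -> None:
    """Write a recording in the given delimited dialect (raw = g / scale)."""
    if not isinstance(dialect, FileDialect):
        dialect = FileDialect.from_dict(dialect)
    path = Path(path)
    raw = recording.samples / dialect.scale
    with open(path, "w", newline="") as fh:
        for row in raw:
            cells = ["0"] * dialect.n_columns
            for col, val in zip(dialect.acc_columns, row):
                cells[col] = str(int(round(val))) if dialect.integer_raw else repr(float(val))
            fh.write(dialect.delimiter.join(cells) + "\n")
    if write_labels:
        _label_sidecar(path).write_text("\n".join(recording.labels) + "\n")


def write_native(recording: Recording, csv_path) -> None:
    """Native format: CSV ``t,ax,ay,az,label`` plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    t = np.arange(len(recording)) / recording.sample_rate_hz
    df = pd.DataFrame(
        {
            "t": t,
            "ax": recording.samples[:, 0],
            "ay": recording.samples[:, 1],
            "az": recording.samples[:, 2],
            "label": recording.labels,
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "subject_id": recording.subject_id,
        "age_group": recording.age_group,
        "sample_rate_hz": recording.sample_rate_hz,
        "recording_id": recording.recording_id,
    }
    csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_native(csv_path) -> Recording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".meta.json").read_text())
    return Recording(
        subject_id=meta["subject_id"],
        age_group=meta["age_group"],
        sample_rate_hz=meta["sample_rate_hz"],
        samples=df[["ax", "ay", "az"]].to_numpy(),
        labels=df["label"].to_numpy(dtype=_LABEL_DTYPE),
        recording_id=meta.get("recording_id"),
    )
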