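"""Labeled ERP trial sets: container, text/archive I/O, and seeded subset selection.

An :class:`EpochSet` holds epoched EEG as a ``(trial, electrode, sample)``
array of amplitudes in microvolts, with one class label per trial (``P300``
or ``NONP300``), ordered electrode names, and the acquisition metadata
(sampling rate, epoch duration) needed downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "P300",
    "NONP300",
    "EpochSet",
    "load_epochs",
    "save_epochs",
    "random_subset",
    "EpochFormatError",
]

P300 = "P300"
NONP300 = "NONP300"
_LABELS = (P300, NONP300)


class EpochFormatError(ValueError):
    """Raised when an epochs file violates the declared dialect."""


@dataclass
class EpochSet:
    """Fixed-length labeled ERP trials across electrodes.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_electrodes, n_samples)``, microvolts.
    labels:
        One label per trial, each ``"P300"`` or ``"NONP300"``.
    electrode_names:
        Unique identifiers, one per electrode axis entry (e.g. ``"Cz"``).
    sampling_rate_hz:
        Digitization rate of the samples axis.
    epoch_duration_ms:
        Nominal epoch length; ``n_samples`` need not equal
        ``epoch_duration_ms * sampling_rate_hz / 1000`` exactly (flooring).
    """

    data: np.ndarray
    labels: np.ndarray
    electrode_names: tuple[str, ...]
    sampling_rate_hz: float
    epoch_duration_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.electrode_names = tuple(str(n) for n in self.electrode_names)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-axis (trial, electrode, sample); got ndim={self.data.ndim}"
            )
        if self.data.shape[0] > 0 and self.data.shape[2] < 2:
            raise ValueError("every trial needs at least 2 samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        bad = [l for l in self.labels if l not in _LABELS]
        if bad:
            raise ValueError(f"unknown label token(s): {sorted(set(map(str, bad)))}")
        if len(set(self.electrode_names)) != len(self.electrode_names):
            raise ValueError("electrode names must be unique")
        if len(self.electrode_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.electrode_names)} electrode names for "
                f"{self.data.shape[1]} electrode channels"
            )
        if self.sampling_rate_hz <= 0 or self.epoch_duration_ms <= 0:
            raise ValueError("sampling rate and epoch duration must be positive")

    # -- basic accessors -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def electrode_index(self, name: str) -> int:
        try:
            return self.electrode_names.index(name)
        except ValueError:
            raise KeyError(
                f"electrode {name!r} not in {self.electrode_names}"
            ) from None

    def label_indices(self, label: str) -> np.ndarray:
        """Trial indices carrying *label*, in storage order."""
        if label not in _LABELS:
            raise ValueError(f"unknown label {label!r}")
        return np.flatnonzero(self.labels == label)

    def select_trials(self, indices: Sequence[int]) -> "EpochSet":
        idx = np.asarray(indices, dtype=int)
        return EpochSet(
            self.data[idx],
            self.labels[idx],
            self.electrode_names,
            self.sampling_rate_hz,
            self.epoch_duration_ms,
        )

    def select_electrode(self, name: str) -> "EpochSet":
        """Restriction to a single named electrode (axis kept, length 1)."""
        c = self.electrode_index(name)
        return EpochSet(
            self.data[:, c : c + 1, :],
            self.labels,
            (name,),
            self.sampling_rate_hz,
            self.epoch_duration_ms,
        )

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.data, other.data, atol=0, rtol=0)
            and list(self.labels) == list(other.labels)
            and self.electrode_names == other.electrode_names
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.epoch_duration_ms == other.epoch_duration_ms
        )


# -- I/O -----------------------------------------------------------------
#
# Delimited dialect: UTF-8; '#' comment lines carry metadata
# (sampling_rate_hz, epoch_duration_ms); header `trial,electrode,label,s1..sT`;
# one row per (trial, electrode) with amplitudes as decimal text.
# Archive dialect: NumPy .npz container with the same five fields.


def save_epochs(epochs: EpochSet, path: str | Path, format: str = "delimited") -> None:
    """Write *epochs* to *path* in the ``delimited`` or ``archive`` dialect."""
    path = Path(path)
    if format == "archive":
        np.savez(
            path,
            data=epochs.data,
            labels=np.asarray([str(l) for l in epochs.labels]),
            electrode_names=np.asarray(epochs.electrode_names),
            sampling_rate_hz=epochs.sampling_rate_hz,
            epoch_duration_ms=epochs.epoch_duration_ms,
        )
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    T = epochs.n_samples if epochs.n_trials else 0
    buf = io.StringIO()
    buf.write(f"# sampling_rate_hz={epochs.sampling_rate_hz!r}\n")
    buf.write(f"# epoch_duration_ms={epochs.epoch_duration_ms!r}\n")
    buf.write(f"# electrodes={','.join(epochs.electrode_names)}\n")
    cols = ",".join(f"s{i + 1}" for i in range(T))
    buf.write(f"trial,electrode,label{',' if cols else ''}{cols}\n")
    for t in range(epochs.n_trials):
        for c, name in enumerate(epochs.electrode_names):
            row = ",".join(repr(float(v)) for v in epochs.data[t, c])
            buf.write(f"{t},{name},{epochs.labels[t]}{',' if row else ''}{row}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def load_epochs(path: str | Path, format: str = "delimited") -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`save_epochs`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epochs file not found: {path}")
    if format == "archive":
        with np.load(path, allow_pickle=False) as z:
            return EpochSet(
                z["data"],
                z["labels"].astype(object),
                tuple(str(n) for n in z["electrode_names"]),
                float(z["sampling_rate_hz"]),
                float(z["epoch_duration_ms"]),
            )
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, str, str, np.ndarray]] = []
    n_fields: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split(",")
            if header is None:
                if fields[:3] != ["trial", "electrode", "label"]:
                    raise EpochFormatError(
                        f"line {lineno}: malformed header {fields[:3]!r}; "
                        "expected trial,electrode,label,s1.."
                    )
                header = fields
                n_fields = len(fields)
                continue
            if len(fields) != n_fields:
                raise EpochFormatError(
                    f"line {lineno}: {len(fields)} fields, header has {n_fields}"
                )
            trial_s, electrode, label = fields[0], fields[1], fields[2]
            try:
                trial = int(trial_s)
            except ValueError:
                raise EpochFormatError(
                    f"line {lineno}: trial field {trial_s!r} is not an integer"
                ) from None
            if label not in _LABELS:
                raise EpochFormatError(
                    f"line {lineno}: unknown label token {label!r}"
                )
            try:
                samples = np.array([float(v) for v in fields[3:]])
            except ValueError:
                raise EpochFormatError(
                    f"line {lineno}: non-numeric amplitude value"
                ) from None
            rows.append((trial, electrode, label, samples))
    if header is None:
        raise EpochFormatError(f"{path}: no header line found")
    try:
        rate = float(meta["sampling_rate_hz"])
        dur = float(meta["epoch_duration_ms"])
    except KeyError as e:
        raise EpochFormatError(f"{path}: missing metadata comment {e}") from None
    electrodes = tuple(
        meta["electrodes"].split(",")
        if "electrodes" in meta and meta["electrodes"]
        else dict.fromkeys(r[1] for r in rows)
    )
    if not rows:
        T = (len(header) - 3) or 2
        return EpochSet(
            np.empty((0, len(electrodes), max(T, 2))), [], electrodes, rate, dur
        )
    trial_ids = sorted({r[0] for r in rows})
    trial_pos = {t: i for i, t in enumerate(trial_ids)}
    elec_pos = {e: i for i, e in enumerate(electrodes)}
    T = len(rows[0][3])
    data = np.full((len(trial_ids), len(electrodes), T), np.nan)
    labels: list[str | None] = [None] * len(trial_ids)
    for trial, electrode, label, samples in rows:
        if electrode not in elec_pos:
            raise EpochFormatError(
                f"trial {trial}: electrode {electrode!r} not declared in header metadata"
            )
        i, c = trial_pos[trial], elec_pos[electrode]
        if labels[i] is not None and labels[i] != label:
            raise EpochFormatError(
                f"trial {trial}: inconsistent labels {labels[i]!r} vs {label!r}"
            )
        labels[i] = label
        data[i, c] = samples
    if np.isnan(data).any():
        missing = [
            (trial_ids[i], electrodes[c])
            for i, c in zip(*np.nonzero(np.isnan(data).all(axis=2)))
        ]
        raise EpochFormatError(f"missing (trial, electrode) rows: {missing[:5]}")
    return EpochSet(data, labels, electrodes, rate, dur)


# -- seeded subset selection ---------------------------------------------


def random_subset(
    epochs: EpochSet,
    label: str,
    count: int,
    seed: int | np.random.SeedSequence,
    exclude: Sequence[int] | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Uniform sample without replacement of *count* trials with *label*.

    Deterministic for a fixed *seed*; returned indices (into the full trial
    axis of *epochs*) are disjoint from *exclude*.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    pool = epochs.label_indices(label)
    if exclude is not None:
        pool = np.setdiff1d(pool, np.asarray(list(exclude), dtype=int))
    if count > pool.size:
        raise ValueError(
            f"requested {count} {label} trials, only {pool.size} eligible"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(pool, size=count, replace=False))
    return epochs.select_trials(chosen), chosen
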