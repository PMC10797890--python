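"""Shared in-memory containers for EEG records and per-subject feature tables."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NeurofuseError

MODALITY_SEP = "__"


@dataclass
class EEGRecording:
    """A multichannel EEG record.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Electrode labels (10-20 system), one per row of ``data``.
    subject_id, group : str, optional
        Cohort bookkeeping.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise NeurofuseError("EEG data must be a 2-D channels x samples matrix")
        if np.isnan(self.data).any():
            raise NeurofuseError("EEG data contains NaN")
        if not self.fs > 0:
            raise NeurofuseError(f"sampling rate must be positive, got {self.fs}")
        names = list(self.channel_names)
        if len(names) != self.data.shape[0]:
            raise NeurofuseError(
                f"{len(names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(names)) != len(names):
            raise NeurofuseError("channel names must be unique")
        self.channel_names = names

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FeatureTable:
    """Subjects x features matrix with modality tags, group labels and age.

    Feature columns are named ``<modality>__<name>`` so one flat table can
    carry several omics blocks; :meth:`modality` slices one block out.
    """

    data: pd.DataFrame
    groups: pd.Series
    age: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index) or not self.data.index.equals(
            self.age.index
        ):
            raise NeurofuseError("data, groups and age must share the subject index")

    @property
    def modalities(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.data.columns:
            seen.setdefault(c.split(MODALITY_SEP, 1)[0], None)
        return list(seen)

    def modality(self, name: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c.split(MODALITY_SEP, 1)[0] == name]
        if not cols:
            raise NeurofuseError(f"no features tagged with modality {name!r}")
        return self.data[cols]

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "age", self.age)
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="subject")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        # keep_default_na: "NA" is the normal-aging group label, not a missing value
        df = pd.read_csv(path, sep="\t", index_col="subject",
                         keep_default_na=False, na_values=[""])
        groups = df.pop("group")
        age = df.pop("age").astype(float)
        return cls(data=df.astype(float), groups=groups, age=age)

    @classmethod
    def concat(cls, tables: list["FeatureTable"]) -> "FeatureTable":
        """Join several single-modality tables on the shared subject index."""
        base = tables[0]
        data = pd.concat([t.data for t in tables], axis=1)
        return cls(data=data, groups=base.groups, age=base.age)


@dataclass
class AbundanceTable:
    """Samples x taxa abundances with a taxonomy sidecar.

    ``kind`` distinguishes integer read counts from relative abundances
    (rows summing to one).  ``taxonomy`` maps each taxon column to
    (phylum, genus, species).
    """

    data: pd.DataFrame
    taxonomy: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise NeurofuseError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if (np.asarray(self.data) < 0).any():
            raise NeurofuseError("abundances must be non-negative")
        missing = set(self.data.columns) - set(self.taxonomy.index)
        if missing:
            raise NeurofuseError(f"taxa missing from taxonomy: {sorted(missing)[:5]}")
        if self.kind == "relative":
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise NeurofuseError("relative abundance rows must sum to 1")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="sample")
        side = path.with_suffix(path.suffix + ".taxonomy")
        self.taxonomy.to_csv(side, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "counts") -> "AbundanceTable":
        path = Path(path)
        data = pd.read_csv(path, sep="\t", index_col="sample")
        side = path.with_suffix(path.suffix + ".taxonomy")
        taxonomy = pd.read_csv(side, sep="\t", index_col="taxon")
        return cls(data=data, taxonomy=taxonomy, kind=kind)


def write_eeg_binary(rec: EEGRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Write an EEG record as flat 32-bit floats plus a JSON text sidecar."""
    prefix = Path(prefix)
    raw = prefix.with_suffix(".f32")
    sidecar = prefix.with_suffix(".json")
    rec.data.astype("<f4").tofile(raw)
    sidecar.write_text(
        json.dumps(
            {
                "n_channels": rec.n_channels,
                "n_samples": rec.n_samples,
                "fs": rec.fs,
                "channel_names": rec.channel_names,
                "subject_id": rec.subject_id,
                "group": rec.group,
                "dtype": "<f4",
                "order": "C (channels x samples)",
            },
            indent=1,
        )
    )
    return raw, sidecar


def read_eeg_binary(prefix: str | Path) -> EEGRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".f32"), dtype="<f4").reshape(
        meta["n_channels"], meta["n_samples"]
    )
    return EEGRecording(
        data=data.astype(float),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
    )
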