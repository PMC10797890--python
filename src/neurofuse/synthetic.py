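"""Synthetic cohorts and EEG with the statistical structure the pipeline assumes.

The cohort generator emulates the study conditions: two groups of 19 (normal
aging, NA) and 22 (neurocognitive disorders, NCD) subjects — the N = 41
classifier cohort — with group ages drawn from N(72.62, 3.64^2) and
N(80.31, 8.11^2) years, three feature modalities (microbiome 500, metabolome
300, EEG 400 features by default) of which a small sparse subset differs
between groups by a configured standardized mean difference (Cohen's d).
Microbiome features are compositional: effects are injected on the log scale
and rows are closed to sum to one, so the planted d is approximate after
closure.  The EEG generator produces a hidden semi-Markov sequence of K
topographic states (random orthogonal prototypes) with geometric dwell times,
a positive amplitude envelope and white noise at a configured SNR.

One global seed per generator; sub-streams are spawned from it so modalities
are independent but jointly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, EEGRecording, FeatureTable, MODALITY_SEP
from .errors import ConfigError

GROUP_NA = "NA"
GROUP_NCD = "NCD"

#: 64-electrode 10-20 montage (Biosemi layout, upper-case labels).
MONTAGE_64 = [
    "FP1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "IZ", "OZ", "POZ", "PZ", "CPZ",
    "FPZ", "FP2", "AF8", "AF4", "AFZ", "FZ", "F2", "F4", "F6", "F8", "FT8",
    "FC6", "FC4", "FC2", "FCZ", "CZ", "C2", "C4", "C6", "T8", "TP8", "CP6",
    "CP4", "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    discriminative_feature_ids: dict[str, list[str]] = field(default_factory=dict)
    group_labels: pd.Series | None = None
    state_label_sequence: np.ndarray | None = None


# ---------------------------------------------------------------------------
# cohort feature tables


@dataclass
class CohortConfig:
    n_group_a: int = 19  # NA
    n_group_b: int = 22  # NCD
    n_features_per_modality: dict[str, int] = field(
        default_factory=lambda: {"microbiome": 500, "metabolome": 300, "eeg": 400})
    n_discriminative: dict[str, int] = field(
        default_factory=lambda: {"microbiome": 10, "metabolome": 10, "eeg": 10})
    effect_size: float = 1.5
    age_means: tuple[float, float] = (72.62, 80.31)
    age_sds: tuple[float, float] = (3.64, 8.11)
    noise_model: str = "gaussian"
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a <= 0:
            raise ConfigError("n_group_a must be > 0")
        if self.n_group_b <= 0:
            raise ConfigError("n_group_b must be > 0")
        for mod, p in self.n_features_per_modality.items():
            if p <= 0:
                raise ConfigError(f"n_features_per_modality[{mod!r}] must be > 0")
        for mod, d in self.n_discriminative.items():
            if mod not in self.n_features_per_modality:
                raise ConfigError(f"n_discriminative names unknown modality {mod!r}")
            if d < 0 or d > self.n_features_per_modality[mod]:
                raise ConfigError(
                    f"n_discriminative[{mod!r}] must be in [0, n_features]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ConfigError("noise_model must be 'gaussian' or 'lognormal'")
        for name, sd in zip(("age_sds[0]", "age_sds[1]"), self.age_sds):
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0")


def gen_cohort_features(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate the multi-modality subjects x features table.

    Within each modality the first ``n_discriminative`` features carry a
    between-group standardized mean difference of ``effect_size`` (added to
    group B on the latent gaussian scale).  Microbiome features are
    exponentiated and closed to row sum one; other modalities follow
    ``noise_model``.
    """
    config.validate()
    n_a, n_b = config.n_group_a, config.n_group_b
    n = n_a + n_b
    subjects = [f"s{i:03d}" for i in range(n)]
    groups = pd.Series([GROUP_NA] * n_a + [GROUP_NCD] * n_b, index=subjects,
                       name="group")
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(len(config.n_features_per_modality) + 1)
    rng_age = np.random.default_rng(streams[0])
    age = np.concatenate([
        rng_age.normal(config.age_means[0], config.age_sds[0], n_a),
        rng_age.normal(config.age_means[1], config.age_sds[1], n_b),
    ])
    age_s = pd.Series(age, index=subjects, name="age")

    blocks = []
    truth_ids: dict[str, list[str]] = {}
    for stream, (mod, p) in zip(streams[1:], config.n_features_per_modality.items()):
        rng = np.random.default_rng(stream)
        latent = rng.standard_normal((n, p))
        n_disc = config.n_discriminative.get(mod, 0)
        latent[n_a:, :n_disc] += config.effect_size
        cols = [f"{mod}{MODALITY_SEP}f{j:04d}" for j in range(p)]
        truth_ids[mod] = cols[:n_disc]
        if mod == "microbiome":
            # compositional: log-scale effect then closure
            vals = np.exp(latent)
            vals /= vals.sum(axis=1, keepdims=True)
        elif config.noise_model == "lognormal":
            vals = np.exp(latent)
        else:
            vals = latent
        blocks.append(pd.DataFrame(vals, index=subjects, columns=cols))
    table = FeatureTable(data=pd.concat(blocks, axis=1), groups=groups, age=age_s)
    return table, GroundTruth(discriminative_feature_ids=truth_ids,
                              group_labels=groups)


# ---------------------------------------------------------------------------
# taxa count tables


def gen_taxa_counts(n_samples: int, n_taxa: int, dirichlet_concentration=1.0,
                    depth: int = 10000, seed: int = 0,
                    phyla: list[str] | None = None) -> AbundanceTable:
    """Multinomial read counts over Dirichlet-drawn per-sample proportions.

    ``dirichlet_concentration`` may be a scalar (symmetric) or a length-
    ``n_taxa`` vector.  Taxa are assigned round-robin to ``phyla`` (default
    the four dominant gut phyla) to give the taxonomy sidecar.
    """
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    if n_samples <= 0 or n_taxa <= 0:
        raise ConfigError("n_samples and n_taxa must be > 0")
    conc = np.broadcast_to(np.asarray(dirichlet_concentration, float), (n_taxa,)).copy()
    if (conc <= 0).any():
        raise ConfigError("dirichlet_concentration must be positive elementwise")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(conc, size=n_samples)
    counts = np.vstack([rng.multinomial(depth, p) for p in props])
    taxa = [f"taxon_{j:04d}" for j in range(n_taxa)]
    phyla = phyla or ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria"]
    taxonomy = pd.DataFrame(
        {
            "phylum": [phyla[j % len(phyla)] for j in range(n_taxa)],
            "genus": [f"genus_{j:04d}" for j in range(n_taxa)],
            "species": [f"species_{j:04d}" for j in range(n_taxa)],
        },
        index=pd.Index(taxa, name="taxon"),
    )
    data = pd.DataFrame(counts, columns=taxa,
                        index=[f"sample_{i:03d}" for i in range(n_samples)])
    return AbundanceTable(data=data, taxonomy=taxonomy, kind="counts")


# ---------------------------------------------------------------------------
# microstate EEG


@dataclass
class EEGSimConfig:
    n_channels: int = 64
    fs: float = 500.0
    duration: float = 300.0
    k_states: int = 4
    prototypes: np.ndarray | None = None  # (K, channels), zero-mean per map
    transition_matrix: np.ndarray | None = None  # row-stochastic, zero diagonal
    mean_dwell: float = 80.0  # ms
    snr: float = 4.0
    dwell: str = "geometric"  # "geometric" | "fixed"
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        if self.fs <= 0:
            raise ConfigError("fs must be > 0")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if self.k_states < 1:
            raise ConfigError("k_states must be >= 1")
        if self.k_states > self.n_channels - 1:
            raise ConfigError(
                "k_states must be <= n_channels - 1 (maps are average-referenced)")
        if self.mean_dwell <= 0:
            raise ConfigError("mean_dwell must be > 0")
        if self.snr <= 0:
            raise ConfigError("snr must be > 0")
        if self.dwell not in ("geometric", "fixed"):
            raise ConfigError("dwell must be 'geometric' or 'fixed'")
        if self.transition_matrix is not None:
            T = np.asarray(self.transition_matrix, float)
            if T.shape != (self.k_states, self.k_states):
                raise ConfigError("transition_matrix must be K x K")
            if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
                raise ConfigError("transition_matrix rows must sum to 1")
            if (T < 0).any():
                raise ConfigError("transition_matrix must be non-negative")
            off = T.copy()
            np.fill_diagonal(off, 0.0)
            if (off.sum(axis=1) == 0).any():
                raise ConfigError(
                    "transition_matrix has an absorbing state (no off-diagonal mass)")
        if self.prototypes is not None:
            P = np.asarray(self.prototypes, float)
            if P.shape != (self.k_states, self.n_channels):
                raise ConfigError("prototypes must be K x n_channels")
            Pd = P - P.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(Pd, axis=1)
            if (norms == 0).any():
                raise ConfigError("prototypes must be non-constant maps")
            C = np.abs((Pd / norms[:, None]) @ (Pd / norms[:, None]).T)
            np.fill_diagonal(C, 0.0)
            if (C > 1 - 1e-9).any():
                raise ConfigError("prototypes must be mutually non-collinear")


def random_prototypes(k: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """k mutually orthogonal zero-mean unit-norm topographies."""
    g = rng.standard_normal((n_channels, k + 1))
    g[:, 0] = 1.0  # force the mean direction into the basis, then drop it
    q, _ = np.linalg.qr(g)
    maps = q[:, 1 : k + 1].T  # orthogonal to the constant vector => zero-mean
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


def gen_microstate_eeg(config: EEGSimConfig) -> tuple[EEGRecording, GroundTruth]:
    """Semi-Markov sequence of K topographies + white noise at configured SNR.

    signal[:, t] = amplitude_t * prototype[state_t]; amplitudes are folded
    normals (|N(1, 0.25^2)|) so GFP has genuine local maxima; channel noise is
    iid gaussian scaled to give the requested state-signal-to-noise RMS ratio.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_seq, s_amp, s_noise, s_proto = ss.spawn(4)
    rng_seq = np.random.default_rng(s_seq)
    n = int(round(config.duration * config.fs))
    k = config.k_states

    if config.prototypes is None:
        protos = random_prototypes(k, config.n_channels, np.random.default_rng(s_proto))
    else:
        protos = np.asarray(config.prototypes, float)
        protos = protos - protos.mean(axis=1, keepdims=True)
        protos = protos / np.linalg.norm(protos, axis=1, keepdims=True)

    if config.transition_matrix is None:
        T = np.full((k, k), 1.0 / (k - 1) if k > 1 else 1.0)
        np.fill_diagonal(T, 0.0)
        if k == 1:
            T = np.ones((1, 1))
    else:
        T = np.asarray(config.transition_matrix, float)

    dwell_samples = config.mean_dwell / 1000.0 * config.fs
    states = np.empty(n, dtype=int)
    t = 0
    state = int(rng_seq.integers(k))
    while t < n:
        if config.dwell == "geometric":
            d = int(rng_seq.geometric(min(1.0, 1.0 / dwell_samples)))
        else:
            d = max(1, int(round(dwell_samples)))
        d = min(d, n - t)
        states[t : t + d] = state
        t += d
        if k > 1:
            row = T[state].copy()
            row[state] = 0.0  # dwell is explicit; transitions are between states
            row /= row.sum()
            state = int(rng_seq.choice(k, p=row))

    amp = np.abs(np.random.default_rng(s_amp).normal(1.0, 0.25, n))
    scale = 10.0  # uV
    sig = scale * amp * protos[states].T  # (channels, n)
    sig_rms = np.sqrt(np.mean(sig**2))
    noise = np.random.default_rng(s_noise).standard_normal((config.n_channels, n))
    noise *= sig_rms / config.snr / np.sqrt(np.mean(noise**2))
    data = sig + noise
    rec = EEGRecording(data=data, fs=config.fs,
                       channel_names=_channel_names(config.n_channels))
    truth = GroundTruth(state_label_sequence=states)
    truth.prototypes = protos  # type: ignore[attr-defined]
    return rec, truth


def _channel_names(n: int) -> list[str]:
    if n <= len(MONTAGE_64):
        return MONTAGE_64[:n]
    return MONTAGE_64 + [f"EXT{i}" for i in range(n - len(MONTAGE_64))]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "discriminative_feature_ids": truth.discriminative_feature_ids,
        "group_labels": (truth.group_labels.to_dict()
                         if truth.group_labels is not None else None),
        "state_label_sequence": (truth.state_label_sequence.tolist()
                                 if truth.state_label_sequence is not None else None),
    }
    Path(path).write_text(json.dumps(payload))
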