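"""Band-relative EEG power spectral density and group comparison.

Average-referenced, zero-phase band-pass filtered 2-s epochs; multitaper (or
Welch) PSD per channel; absolute and relative power in the six canonical
bands delta 1-4, theta 4-8, alpha1 8-11.5, alpha2 11.5-13, beta1 13-21 and
beta2 21-30 Hz (relative = band power / total power in 1-30 Hz); unweighted
region-of-interest averages; and a two-way (group x hemisphere) ANOVA with an
optional age covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import EEGRecording
from .errors import NeurofuseError


class BandDefinition(NamedTuple):
    name: str
    low_hz: float
    high_hz: float


#: The six canonical bands tiling 1-30 Hz.  Intervals are half-open
#: [low, high) so touching edges are never double-counted.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 11.5),
    BandDefinition("alpha2", 11.5, 13.0),
    BandDefinition("beta1", 13.0, 21.0),
    BandDefinition("beta2", 21.0, 30.0),
)

TOTAL_RANGE = (1.0, 30.0)

#: Region-of-interest electrode groups per hemisphere (odd digit = left,
#: even digit = right; midline Z/IZ electrodes belong to neither).
DEFAULT_ROI: dict[str, dict[str, list[str]]] = {
    "frontal": {
        "left": ["FP1", "AF7", "AF3", "F1", "F3", "F5"],
        "right": ["FP2", "AF8", "AF4", "F2", "F4", "F6"],
    },
    "central": {
        "left": ["FC5", "FC3", "FC1", "C1", "C3", "C5", "CP5", "CP3", "CP1"],
        "right": ["FC6", "FC4", "FC2", "C2", "C4", "C6", "CP6", "CP4", "CP2"],
    },
    "posterior": {
        "left": ["PO7", "PO3", "O1"],
        "right": ["PO8", "PO4", "O2"],
    },
    "temporal": {
        "left": ["F7", "FT7", "T7", "TP7", "P1", "P3", "P5", "P7", "P9"],
        "right": ["F8", "FT8", "T8", "TP8", "P2", "P4", "P6", "P8"],
    },
}


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs cut from one record."""

    data: np.ndarray  # (n_epochs, n_channels, n_times)
    fs: float
    channel_names: list[str]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class BandPowerTable:
    """Absolute (uV^2) and relative band power, channels x bands."""

    absolute: pd.DataFrame
    relative: pd.DataFrame
    method: str = "multitaper"


def average_reference(data: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the across-channel mean per sample."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess(rec: EEGRecording, low: float = 1.0, high: float = 30.0,
               epoch_len: float = 2.0) -> EpochSet:
    """Average-reference, zero-phase band-pass filter, cut into epochs.

    The filter is a 4th-order Butterworth applied forward-backward
    (zero phase); the trailing partial epoch is dropped.
    """
    if not low < high < rec.fs / 2:
        raise NeurofuseError("need low < high < Nyquist")
    n_per = int(round(epoch_len * rec.fs))
    if n_per < 8:
        raise NeurofuseError("epoch too short (< 8 samples)")
    if rec.n_samples < n_per:
        raise NeurofuseError("record shorter than one epoch")
    data = average_reference(rec.data)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    n_epochs = rec.n_samples // n_per
    epochs = data[:, : n_epochs * n_per].reshape(rec.n_channels, n_epochs, n_per)
    return EpochSet(data=np.swapaxes(epochs, 0, 1).copy(), fs=rec.fs,
                    channel_names=rec.channel_names)


def _psd(epochs: EpochSet, method: str):
    """Mean PSD over epochs; returns (freqs, psd[channels, freqs])."""
    n_times = epochs.data.shape[2]
    if method == "multitaper":
        from mne.time_frequency import psd_array_multitaper

        # time-half-bandwidth 4 per epoch -> bandwidth = 2*4/T Hz
        bandwidth = 2 * 4.0 / (n_times / epochs.fs)
        psd, freqs = psd_array_multitaper(
            epochs.data, sfreq=epochs.fs, fmin=0, fmax=epochs.fs / 2,
            bandwidth=bandwidth, normalization="full", verbose=False)
        return freqs, psd.mean(axis=0)
    if method == "welch":
        freqs, psd = signal.welch(epochs.data, fs=epochs.fs, window="hann",
                                  nperseg=n_times, axis=2)
        return freqs, psd.mean(axis=0)
    raise NeurofuseError(f"unknown PSD method {method!r}")


def band_power(epochs: EpochSet, bands=DEFAULT_BANDS, method: str = "multitaper",
               total_range: tuple[float, float] = TOTAL_RANGE) -> BandPowerTable:
    """Absolute and relative band power per channel.

    Band power integrates the epoch-averaged PSD over [low, high) by
    rectangle rule on the uniform frequency grid, so bands tiling the total
    range partition it exactly and relative powers sum to one.
    """
    if epochs.n_epochs < 1:
        raise NeurofuseError("need at least one epoch")
    lo_tot, hi_tot = total_range
    for b in bands:
        if b.low_hz < lo_tot or b.high_hz > hi_tot or b.low_hz >= b.high_hz:
            raise NeurofuseError(f"band {b.name} outside analyzed range {total_range}")
    freqs, psd = _psd(epochs, method)
    df = freqs[1] - freqs[0]
    absolute = {}
    for b in bands:
        mask = (freqs >= b.low_hz) & (freqs < b.high_hz)
        absolute[b.name] = psd[:, mask].sum(axis=1) * df
    total_mask = (freqs >= lo_tot) & (freqs < hi_tot)
    total = psd[:, total_mask].sum(axis=1) * df
    abs_df = pd.DataFrame(absolute, index=epochs.channel_names)
    rel_df = abs_df.div(total, axis=0)
    return BandPowerTable(absolute=abs_df, relative=rel_df, method=method)


def roi_summary(bp: BandPowerTable | pd.DataFrame,
                roi: dict[str, dict[str, list[str]]] | None = None,
                which: str = "relative") -> pd.DataFrame:
    """Unweighted mean over each region's electrodes, per hemisphere.

    Returns a table indexed by (region, hemisphere) with one column per band.
    """
    roi = roi or DEFAULT_ROI
    table = getattr(bp, which) if isinstance(bp, BandPowerTable) else bp
    rows = {}
    for region, hemis in roi.items():
        for hemi, electrodes in hemis.items():
            missing = [e for e in electrodes if e not in table.index]
            if missing:
                raise NeurofuseError(
                    f"electrode {missing[0]!r} of ROI {region}/{hemi} not in montage")
            rows[(region, hemi)] = table.loc[electrodes].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.names = ["region", "hemisphere"]
    return out


def group_band_comparison(values: pd.DataFrame, adjust_age: bool = True) -> dict:
    """Two-way ANOVA (group x hemisphere) on one band/ROI value per subject.

    ``values`` must have columns ``value``, ``group``, ``hemisphere`` and
    (if ``adjust_age``) ``age``.  Fits an OLS linear model with Type-II sums
    of squares; returns ``{"unadjusted": table, "age_adjusted": table}`` with
    F, df and p per term (age_adjusted only when requested).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"value", "group", "hemisphere"}
    if not required <= set(values.columns):
        raise NeurofuseError(f"need columns {sorted(required)}")
    counts = values.groupby(["group", "hemisphere"], observed=True).size()
    if (counts < 2).any():
        raise NeurofuseError("need >= 2 observations per group x hemisphere cell")

    def _fit(formula):
        model = smf.ols(formula, data=values).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise NeurofuseError("singular design matrix")
        tab = anova_lm(model, typ=2)
        tab = tab.rename(columns={"PR(>F)": "p", "df": "df", "F": "F"})
        return tab[["df", "F", "p"]]

    out = {"unadjusted": _fit("value ~ C(group) * C(hemisphere)")}
    if adjust_age:
        if "age" not in values.columns:
            raise NeurofuseError("age column required for age adjustment")
        out["age_adjusted"] = _fit("value ~ C(group) * C(hemisphere) + age")
    return out


def subject_roi_band_table(records: list[EEGRecording], band: str = "alpha1",
                           region: str = "temporal", ages=None,
                           method: str = "welch") -> pd.DataFrame:
    """Long-format table (subject, group, hemisphere, age, value) for one
    band and region across subjects — input for :func:`group_band_comparison`."""
    rows = []
    for i, rec in enumerate(records):
        bp = band_power(preprocess(rec), method=method)
        rois = roi_summary(bp)
        for hemi in ("left", "right"):
            rows.append({
                "subject": rec.subject_id or f"s{i:03d}",
                "group": rec.group,
                "hemisphere": hemi,
                "age": None if ages is None else ages[i],
                "value": rois.loc[(region, hemi), band],
            })
    return pd.DataFrame(rows)
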