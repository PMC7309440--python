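"""Quantitative EEG spectral features.

Welch power spectral density (Hann taper, 50% overlap), Simpson-rule band
powers (absolute and relative) in the five canonical bands — delta 0.5-4,
theta 4-8, alpha 8-12, beta 12-30, gamma 30-100 Hz — plus frontal alpha
asymmetry (F4 - F3) and per-site beta/alpha ratios, with optional
restriction to occipital (O1, Oz, O2) and/or frontal (F7, F3, Fz, F4, F8)
sites.  All powers are in uV^2 and densities in uV^2/Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.signal import welch

# ---------------------------------------------------------------------------
# Montage

#: 26-site montage (10-20 / 10-10 labels) spanning the five scalp regions.
MONTAGE_26: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4",
    "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CPz", "CP4",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Legacy 10-20 aliases (T3 is the older name for T7, etc.).
SITE_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

FRONTAL_SITES: tuple[str, ...] = ("F7", "F3", "Fz", "F4", "F8")
OCCIPITAL_SITES: tuple[str, ...] = ("O1", "Oz", "O2")

REGION_FILTERS: dict[str, tuple[str, ...]] = {
    "all": MONTAGE_26,
    "frontal": FRONTAL_SITES,
    "occipital": OCCIPITAL_SITES,
    "frontal+occipital": FRONTAL_SITES + OCCIPITAL_SITES,
}


def resolve_site(label: str) -> str:
    """Map a montage label (including legacy aliases) to its canonical name."""
    canonical = SITE_ALIASES.get(label, label)
    if canonical not in MONTAGE_26:
        raise KeyError(f"unresolvable site label {label!r}")
    return canonical


# ---------------------------------------------------------------------------
# Bands

@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name!r}: need 0 <= f_lo < f_hi")


BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 100.0),
}

#: Ratio features whose alpha denominator underflows get this sentinel.
RATIO_SENTINEL = 1e9
_ALPHA_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Containers

@dataclass
class EEGRecording:
    """Multichannel resting-state (eyes-closed) EEG segment.

    ``data`` is (n_sites, n_samples) in uV; rows follow ``site_labels``.
    """

    site_labels: Sequence[str]
    data: np.ndarray
    sampling_rate: float
    condition: str = "eyes-closed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.site_labels):
            raise ValueError("data must be (n_sites, n_samples) matching site_labels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.site_labels = [resolve_site(s) for s in self.site_labels]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    def channel(self, site: str) -> np.ndarray:
        return self.data[self.site_labels.index(resolve_site(site))]

    def to_csv(self, path: str | Path) -> None:
        """Write as the CSV matrix dialect: one column per site, a leading
        ``time_s`` column, sampling rate recoverable from the time step."""
        t = np.arange(self.data.shape[1]) / self.sampling_rate
        df = pd.DataFrame(self.data.T, columns=list(self.site_labels))
        df.insert(0, "time_s", t)
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EEGRecording":
        df = pd.read_csv(path)
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError(f"{path}: not an EEG matrix CSV (need time_s column, >=2 rows)")
        dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        sites = [c for c in df.columns if c != "time_s"]
        return cls(site_labels=sites, data=df[sites].to_numpy().T, sampling_rate=1.0 / dt)

    @classmethod
    def from_edf(cls, path: str | Path) -> "EEGRecording":
        """Read an EDF file (requires the optional mne dependency)."""
        import mne  # optional, pulled in by the "edf" extra

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne works in volts
        return cls(site_labels=list(raw.ch_names), data=data, sampling_rate=raw.info["sfreq"])


@dataclass(frozen=True)
class PowerSpectrum:
    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        d = np.asarray(self.density, float)
        if f.shape != d.shape:
            raise ValueError("frequencies and density must have equal length")
        if f.size >= 2 and not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "density", d)

    def total_power(self) -> float:
        return float(simpson(self.density, x=self.frequencies))


@dataclass(frozen=True)
class FeatureCombination:
    """One point in the feature search space.

    power_type: "absolute" or "relative"; bands: nonempty subset of the five
    canonical names; region_filter: one of "all", "frontal", "occipital",
    "frontal+occipital"; plus flags for the two derived feature families.
    """

    power_type: str = "absolute"
    bands: tuple[str, ...] = BAND_ORDER
    region_filter: str = "all"
    include_asymmetry: bool = False
    include_beta_alpha_ratio: bool = False

    def __post_init__(self) -> None:
        if self.power_type not in ("absolute", "relative"):
            raise ValueError(f"power_type {self.power_type!r}")
        if not self.bands:
            raise ValueError("bands must be nonempty")
        unknown = [b for b in self.bands if b not in CANONICAL_BANDS]
        if unknown:
            raise ValueError(f"unknown bands {unknown}")
        if self.region_filter not in REGION_FILTERS:
            raise ValueError(f"unknown region_filter {self.region_filter!r}")
        ordered = tuple(b for b in BAND_ORDER if b in self.bands)
        object.__setattr__(self, "bands", ordered)

    @property
    def sites(self) -> tuple[str, ...]:
        return REGION_FILTERS[self.region_filter]

    def label(self) -> str:
        parts = [self.power_type, "+".join(self.bands), self.region_filter]
        if self.include_asymmetry:
            parts.append("asym")
        if self.include_beta_alpha_ratio:
            parts.append("b/a")
        return " | ".join(parts)


# ---------------------------------------------------------------------------
# Spectral estimation

def welch_psd(
    signal: np.ndarray,
    sampling_rate: float,
    window_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
    oversample: int = 4,
) -> PowerSpectrum:
    """Welch PSD with a Hann taper and (by default) 50% overlap.

    The density is one-sided and normalised so its integral over frequency
    approximates the signal variance (Parseval).  The spectrum is evaluated
    on a grid ``oversample`` times finer than the native window resolution
    (zero-padded FFT) so that narrowband peaks are smooth on the quadrature
    grid used by :func:`band_power`; oversampling does not change the
    integral of the density.
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(window_seconds * sampling_rate))
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one window ({nperseg} samples)"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, dens = welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nperseg * max(1, int(oversample)),
        detrend="constant",
        scaling="density",
    )
    return PowerSpectrum(frequencies=freqs, density=dens)


def band_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Absolute band power: Simpson-rule integral of the density over the
    band, restricted to the bins available in the spectrum."""
    f, d = spectrum.frequencies, spectrum.density
    mask = (f >= band.f_lo) & (f <= band.f_hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}] Hz has no support on "
            f"the spectrum grid [{f[0]:g}, {f[-1]:g}] Hz"
        )
    return float(simpson(d[mask], x=f[mask]))


def relative_power(band_powers: Sequence[float]) -> np.ndarray:
    """Fractions of total power in each band (denominator = the sum over the
    five canonical bands, so the fractions sum to one)."""
    p = np.asarray(band_powers, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("total band power must be positive")
    return p / total


def band_ratio(powers: Mapping[str, float], numerator: str, denominator: str) -> float:
    """Generic per-site band-pair power ratio with the sentinel policy for a
    vanishing denominator."""
    den = powers[denominator]
    if den < _ALPHA_FLOOR:
        warnings.warn(
            f"{denominator} power below {_ALPHA_FLOOR:g}; ratio set to sentinel",
            RuntimeWarning,
            stacklevel=2,
        )
        return RATIO_SENTINEL
    return powers[numerator] / den


def alpha_asymmetry(alpha_by_site: Mapping[str, float]) -> float:
    """Frontal alpha asymmetry: alpha power at right frontal F4 minus the
    homologous left site F3 (same power type for both)."""
    try:
        return float(alpha_by_site["F4"]) - float(alpha_by_site["F3"])
    except KeyError as exc:
        raise KeyError(f"alpha power missing for site {exc.args[0]!r}") from exc


def beta_alpha_ratio(powers_at_site: Mapping[str, float]) -> float:
    """Beta/alpha power ratio at one site."""
    return band_ratio(powers_at_site, "beta", "alpha")


# ---------------------------------------------------------------------------
# Feature tables

def recording_band_powers(
    recording: EEGRecording,
    window_seconds: float = 4.0,
    bands: Mapping[str, BandDefinition] = CANONICAL_BANDS,
) -> pd.DataFrame:
    """Absolute band power per (site, band) for one recording.

    Returns a DataFrame indexed by canonical site with one column per band.
    """
    rows = {}
    for site, x in zip(recording.site_labels, recording.data):
        if np.allclose(x, 0):
            rows[site] = {name: 0.0 for name in bands}
            continue
        spec = welch_psd(x, recording.sampling_rate, window_seconds=window_seconds)
        rows[site] = {name: band_power(spec, b) for name, b in bands.items()}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(bands))


def cohort_band_powers(
    recordings: Mapping[str, EEGRecording], window_seconds: float = 4.0
) -> pd.DataFrame:
    """Per-subject absolute band powers; columns are a (site, band) MultiIndex."""
    frames = {}
    for sid, rec in recordings.items():
        bp = recording_band_powers(rec, window_seconds=window_seconds)
        frames[sid] = bp.stack()
    table = pd.DataFrame.from_dict(frames, orient="index")
    table.columns.names = ["site", "band"]
    return table


def feature_name(site: str, band: str, power_type: str) -> str:
    return f"{site} {band} {power_type}"


def features_from_band_powers(
    band_powers: pd.DataFrame, combination: FeatureCombination
) -> pd.DataFrame:
    """Assemble the feature table implied by a combination from a per-subject
    absolute (site, band) power table (as from :func:`cohort_band_powers`).

    Relative powers are renormalised over the five canonical bands per site.
    The asymmetry column is emitted only when alpha is among the selected
    bands; beta/alpha ratios only when both beta and alpha are selected.
    """
    sites = [s for s in combination.sites if s in band_powers.columns.get_level_values(0)]
    missing = set(combination.sites) - set(sites)
    if missing:
        raise KeyError(f"band-power table lacks sites {sorted(missing)}")

    if combination.power_type == "relative":
        values = {}
        for site in sites:
            abs_p = band_powers[site][list(BAND_ORDER)]
            values[site] = abs_p.div(abs_p.sum(axis=1), axis=0)
        powers = values
    else:
        powers = {site: band_powers[site] for site in sites}

    cols = {}
    for site in sites:
        for band in combination.bands:
            cols[feature_name(site, band, combination.power_type)] = powers[site][band]

    if combination.include_asymmetry and "alpha" in combination.bands:
        f3, f4 = band_powers["F3"], band_powers["F4"]
        if combination.power_type == "relative":
            f3 = f3[list(BAND_ORDER)].div(f3[list(BAND_ORDER)].sum(axis=1), axis=0)
            f4 = f4[list(BAND_ORDER)].div(f4[list(BAND_ORDER)].sum(axis=1), axis=0)
        cols[f"frontal alpha asymmetry {combination.power_type}"] = f4["alpha"] - f3["alpha"]

    if (
        combination.include_beta_alpha_ratio
        and "alpha" in combination.bands
        and "beta" in combination.bands
    ):
        for site in sites:
            alpha = powers[site]["alpha"].to_numpy(dtype=float)
            beta = powers[site]["beta"].to_numpy(dtype=float)
            ratio = np.where(alpha < _ALPHA_FLOOR, RATIO_SENTINEL, beta / np.maximum(alpha, _ALPHA_FLOOR))
            if np.any(alpha < _ALPHA_FLOOR):
                warnings.warn(
                    f"site {site}: alpha power underflow; ratio sentinel emitted",
                    RuntimeWarning,
                    stacklevel=2,
                )
            cols[f"{site} beta-alpha {combination.power_type} ratio"] = pd.Series(
                ratio, index=band_powers.index
            )

    out = pd.DataFrame(cols, index=band_powers.index)
    if out.isna().any().any():
        raise ValueError("feature table contains missing values")
    return out


def extract_features(
    recordings: Mapping[str, EEGRecording],
    combination: FeatureCombination,
    window_seconds: float = 4.0,
) -> pd.DataFrame:
    """Full path from raw recordings to the feature table of a combination."""
    return features_from_band_powers(
        cohort_band_powers(recordings, window_seconds=window_seconds), combination
    )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("subject_id").to_csv(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
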