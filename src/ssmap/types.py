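"""Core containers for spatio-spectral analysis of intracranial recordings.

The shared vocabulary of the package: raw monopolar recordings, bipolar
derivations, spectra, channels-by-frequency maps, cohort stacks, and the
result containers produced by the statistical machinery.  All containers are
thin dataclasses over numpy arrays / pandas frames; they validate shapes on
construction but otherwise stay out of the way.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

ECOG = "ecog_strip"
DBS = "dbs_lead"
DEVICES = (ECOG, DBS)

#: canonical analysis frequency grid: 1-Hz bins, 4..110 Hz inclusive (107 bins)
DEFAULT_FREQS = np.arange(4, 111, dtype=float)

#: named oscillatory bands (closed Hz ranges)
BANDS = {"alpha": (8.0, 11.0), "low_beta": (12.0, 20.0), "high_beta": (21.0, 35.0)}

#: beta range used for maximum-coherence pairing (closed)
PAIRING_BETA = (12.0, 35.0)


@dataclass
class ChannelInfo:
    """Metadata for one monopolar contact.

    ``cs_offset`` is the signed contact count relative to the central sulcus
    (negative = posterior, positive = anterior); it is meaningful for ECoG
    strips only and ``None`` for DBS leads.
    """

    name: str
    device: str
    contact_index: int  # 1-based along the lead/strip
    cs_offset: int | None = None

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}")
        if self.contact_index < 1:
            raise ValueError("contact_index is 1-based")


@dataclass
class RawRecording:
    """Multichannel monopolar time series (microvolts) plus montage metadata."""

    samples: np.ndarray  # (n_channels, n_samples)
    rate_hz: float
    channels: list[ChannelInfo]
    subject_id: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata does not match samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        for dev in DEVICES:
            idx = [c.contact_index for c in self.channels if c.device == dev]
            if len(idx) != len(set(idx)):
                raise ValueError(f"duplicate contact_index on {dev}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def device_channels(self, device: str) -> list[int]:
        """Indices of channels on ``device``, sorted by contact_index."""
        rows = [(c.contact_index, i) for i, c in enumerate(self.channels) if c.device == device]
        return [i for _, i in sorted(rows)]

    def copy(self) -> "RawRecording":
        return RawRecording(self.samples.copy(), self.rate_hz, list(self.channels),
                            self.subject_id, self.site)


@dataclass
class BipolarRecording:
    """Adjacent-contact difference signals derived from one device.

    ``pairs`` holds (anode contact_index, cathode contact_index, label) per
    derived channel; sample row i equals anode minus cathode of pair i.
    Channel order is ventral-to-rostral for DBS leads and posterior-to-anterior
    for ECoG strips.
    """

    samples: np.ndarray
    rate_hz: float
    pairs: list[tuple[int, int, str]]
    kind: str  # ecog_anatomical_3 | ecog_adjacent_7 | dbs_adjacent
    device: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] != len(self.pairs):
            raise ValueError("pairs do not match derived channels")
        labels = [p[2] for p in self.pairs]
        if len(labels) != len(set(labels)):
            raise ValueError("bipolar labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def labels(self) -> list[str]:
        return [p[2] for p in self.pairs]


@dataclass
class ArtifactMask:
    """Boolean per-(channel, sample) artifact flags plus an interpolation log."""

    mask: np.ndarray  # bool (n_channels, n_samples)
    spans: list[tuple[int, int, int]] = field(default_factory=list)  # (channel, start, end) inclusive

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for ch, s, e in self.spans:
            if not (0 <= s <= e < self.mask.shape[1]):
                raise ValueError("span outside recording bounds")

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


@dataclass
class Spectrum:
    """One power spectrum on the 1-Hz analysis grid.

    ``values`` are in arbitrary units.  After aperiodic adjustment values live
    in log10 units and may be negative; before adjustment they are nonnegative.
    """

    freqs: np.ndarray
    values: np.ndarray
    normalized: bool = False
    aperiodic_adjusted: bool = False
    n_windows: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs/values shape mismatch")
        if self.freqs.size >= 2 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if not self.aperiodic_adjusted and np.any(self.values < 0):
            raise ValueError("power must be nonnegative before aperiodic adjustment")


@dataclass
class AperiodicFit:
    """Parameters of the aperiodic (1/f-with-knee) model.

    The model, in semi-log space (log10 power vs linear frequency), is
    ``P(f) = b - log10(k + f**chi)`` with broadband offset ``b``, knee ``k``
    (Hz**chi units, >= 0) and exponent ``chi`` (> 0).
    """

    b: float
    k: float
    chi: float
    fit_range: tuple[float, float]
    residual_rms: float
    converged: bool = True
    knee_form: str = "k_plus_fchi"  # or "kchi_plus_fchi"

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        """Model log10-power on ``freqs``."""
        f = np.asarray(freqs, dtype=float)
        if self.knee_form == "kchi_plus_fchi":
            denom = self.k ** self.chi + f ** self.chi
        else:
            denom = self.k + f ** self.chi
        return self.b - np.log10(denom)


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence between one channel pair."""

    freqs: np.ndarray
    msc: np.ndarray
    pair: tuple[str, str]
    n_windows: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.msc = np.asarray(self.msc, dtype=float)
        if self.freqs.shape != self.msc.shape:
            raise ValueError("freqs/msc shape mismatch")
        if np.any((self.msc < -1e-9) | (self.msc > 1 + 1e-9)):
            raise ValueError("msc must lie in [0, 1]")
        self.msc = np.clip(self.msc, 0.0, 1.0)


MAP_KINDS = ("power", "coherence", "variance", "statistic")


@dataclass
class SpatioSpectralMap:
    """Channels-by-frequency matrix of a biomarker.

    The row (channel) axis is anatomically ordered: posterior-to-anterior for
    cortical maps, ventral-to-rostral for subcortical maps.
    """

    values: np.ndarray  # (n_channels, n_freqs)
    channels: list[str]
    freqs: np.ndarray
    kind: str = "power"
    spatial_order: str = "posterior_to_anterior"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape != (len(self.channels), self.freqs.size):
            raise ValueError("axis lengths do not match values")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.kind == "coherence" and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("coherence map values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CohortStack:
    """Aligned subjects x channels x frequencies array with subject IDs."""

    data: np.ndarray
    subject_ids: list[str]
    channels: list[str]
    freqs: np.ndarray
    kind: str = "power"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3-D (subjects x channels x freqs)")
        ns, nc, nf = self.data.shape
        if ns != len(self.subject_ids) or nc != len(self.channels) or nf != self.freqs.size:
            raise ValueError("stack axes do not match data")
        if len(set(self.subject_ids)) != ns:
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def mean_map(self) -> SpatioSpectralMap:
        """Group-average map across subjects."""
        return SpatioSpectralMap(self.data.mean(axis=0), list(self.channels),
                                 self.freqs, kind=self.kind)

    def subject_map(self, i: int) -> SpatioSpectralMap:
        return SpatioSpectralMap(self.data[i], list(self.channels), self.freqs, kind=self.kind)


@dataclass
class PixelStatMap:
    """Per-pixel permutation-Z statistics with FDR and blob-corrected masks.

    Pixels where the permutation null is degenerate (sigma_null == 0) carry
    NaN Z/p and are excluded from the multiple-comparison family.
    """

    z: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    sig_pre_blob: np.ndarray
    sig_post_blob: np.ndarray
    mu_null: np.ndarray | None = None
    sigma_null: np.ndarray | None = None
    n_perm: int = 0

    def __post_init__(self) -> None:
        shp = np.asarray(self.z).shape
        for name in ("p_raw", "p_fdr", "sig_pre_blob", "sig_post_blob"):
            if np.asarray(getattr(self, name)).shape != shp:
                raise ValueError(f"{name} shape mismatch")
        if np.any(self.sig_post_blob & ~self.sig_pre_blob):
            raise ValueError("post-blob mask must be a subset of the pre-blob mask")
        for p in (self.p_raw, self.p_fdr):
            ok = np.isnan(p) | ((p >= 0) & (p <= 1))
            if not np.all(ok):
                raise ValueError("p-values must lie in [0, 1]")


def band_bins(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    """Boolean mask of grid bins inside a closed band (named or (lo, hi))."""
    if isinstance(band, str):
        try:
            lo, hi = BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    else:
        lo, hi = band
    if lo > hi:
        raise ValueError("band lower edge exceeds upper edge")
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) contains no grid bins")
    return mask
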