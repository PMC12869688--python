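"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generation modes are provided.

Map mode (:func:`simulate_map_cohort`) draws subject spatio-spectral maps as

    subject map = canonical template + cluster signature
                  + latent-driven hotspot deviation + i.i.d. pixel noise

with clinical scores linearly coupled to the same latent severity factors,
so planted structure (hotspots, clusters, brain-behavior coupling) is known
exactly and every statistical stage can be checked against ground truth.

Time-series mode (:func:`simulate_timeseries_subject`) emits monopolar
voltage traces per contact: an aperiodic 1/f-with-knee background obtained
by spectral shaping of white noise, plus narrowband oscillations realized as
Gaussian-envelope band-limited noise with per-channel spatial profiles, plus
optional shared beta sources that couple cortical and subcortical bipolar
channels so their magnitude-squared coherence is controlled.  Monopolar
contacts are constructed so that adjacent-contact differencing recovers the
target bipolar structure, and a common-mode component (reference drift plus
60 Hz line) is added to every contact to exercise re-referencing and
filtering downstream.

All randomness flows through one RNG stream per subject derived from
(master seed, subject index), so cohorts are reproducible independently of
cohort size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (DBS, DEFAULT_FREQS, ECOG, ChannelInfo, CohortStack,
                    RawRecording, SpatioSpectralMap)

CLINICAL_COLUMNS = ["updrs_total", "brady_ipsi", "brady_contra", "rigid_ipsi",
                    "rigid_contra", "tremor_ipsi", "tremor_contra"]

#: baseline expected scores for an advanced-PD surgical cohort
_CLINICAL_BASE = np.array([35.0, 5.0, 6.0, 3.0, 4.0, 2.0, 3.0])

REGIONS = ("cortex", "gpi", "stn")


@dataclass
class PeakSpec:
    """One oscillatory peak: Gaussian bump in frequency with a spatial profile.

    ``bandwidth_hz`` is the Gaussian standard deviation.  ``profile`` weights
    the peak across bipolar channels (posterior-to-anterior / ventral-to-
    rostral order); ``None`` means uniform.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float
    profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.profile is not None:
            self.profile = np.asarray(self.profile, dtype=float)


@dataclass
class Hotspot:
    """A contiguous channel x frequency patch of elevated subject deviation.

    The per-subject deviation amplitude on the patch is ``sd`` times the
    subject's latent severity factor ``latent_index`` (plus an independent
    residual with relative weight ``residual_frac``), so hotspot deviations
    are both large and clinically coupled.
    """

    channel_lo: int
    channel_hi: int  # inclusive
    freq_lo: float
    freq_hi: float  # inclusive
    sd: float
    latent_index: int = 0
    residual_frac: float = 0.0

    def mask(self, n_channels: int, freqs: np.ndarray) -> np.ndarray:
        if not (0 <= self.channel_lo <= self.channel_hi < n_channels):
            raise ValueError("hotspot channel range outside map")
        m = np.zeros((n_channels, freqs.size), dtype=bool)
        fm = (freqs >= self.freq_lo) & (freqs <= self.freq_hi)
        m[self.channel_lo:self.channel_hi + 1, fm] = True
        return m


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the study conditions: 8-contact ECoG strip and 8-contact
    DBS lead (7 bipolar channels each), 1-Hz grid 4..110 Hz, an anterior
    20-23 Hz beta peak with a posterior 9-11 Hz alpha peak, and UPDRS-style
    integer clinical scores coupled to two latent severity factors.
    """

    n_subjects: int = 75
    disease: str = "pd_like"  # pd_like | et_like
    n_ecog_contacts: int = 8
    n_dbs_contacts: int = 8
    freqs: np.ndarray = field(default_factory=lambda: DEFAULT_FREQS.copy())
    peaks: list[PeakSpec] | None = None  # None -> region defaults at template time
    aperiodic: tuple[float, float, float] = (1.0, 10.0, 1.5)  # (b, k, chi)
    hotspots: list[Hotspot] = field(default_factory=list)
    clinical_coupling: np.ndarray | None = None  # (7 scores x q latents)
    n_latents: int = 2
    n_clusters: int = 1
    cluster_signature_sd: float = 0.3
    cluster_signatures: np.ndarray | None = None  # (n_clusters, n_ch, n_f)
    noise_sd: float = 0.15
    clinical_noise_sd: float = 2.0
    integer_scores: bool = True
    et_beta_attenuation: float = 0.25
    coupling_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    line_amp_uv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_ecog_contacts < 1 or self.n_dbs_contacts < 1:
            raise ValueError("counts must be >= 1")
        if self.n_clusters < 1 or self.n_latents < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0 or self.clinical_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.freqs.size >= 2 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.disease not in ("pd_like", "et_like"):
            raise ValueError(f"unknown disease {self.disease!r}")
        C = self.coupling_matrix()
        if C.shape[0] != len(CLINICAL_COLUMNS):
            raise ValueError("coupling matrix must have one row per clinical score "
                             f"({len(CLINICAL_COLUMNS)} = total + 6 sub-scores)")
        if C.shape[1] != self.n_latents:
            raise ValueError("coupling matrix columns must match n_latents")

    def coupling_matrix(self) -> np.ndarray:
        """Latent-to-score coupling (7 x q); default couples latent 0 to overall
        severity and latent 1 to a tremor-vs-bradykinesia contrast."""
        if self.clinical_coupling is not None:
            return np.asarray(self.clinical_coupling, dtype=float)
        C = np.zeros((len(CLINICAL_COLUMNS), self.n_latents))
        C[:, 0] = [8.0, 1.5, 2.0, 1.0, 1.5, 1.0, 1.0]
        if self.n_latents >= 2:
            C[:, 1] = [0.0, -1.0, -1.5, 0.0, 0.0, 1.5, 2.0]
        return C

    def subject_rng(self, subject_index: int) -> np.random.Generator:
        """Dedicated RNG stream for one subject."""
        return np.random.default_rng([int(self.seed) % (2 ** 31), 101, int(subject_index)])

    def cohort_rng(self, stream: int) -> np.random.Generator:
        """Cohort-level stream (cluster labels, clinical noise, ...)."""
        return np.random.default_rng([int(self.seed) % (2 ** 31), 202, int(stream)])


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle-style testing."""

    template: np.ndarray | None = None
    deviations: np.ndarray | None = None  # (n_subjects, n_ch, n_f)
    latents: np.ndarray | None = None  # (n_subjects, q)
    cluster_labels: np.ndarray | None = None  # 1-based
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    event_indices: np.ndarray | None = None


# ---------------------------------------------------------------------------
# canonical templates


def _ramp(n: int, lo: float, hi: float) -> np.ndarray:
    return np.linspace(lo, hi, n)


def default_peaks(region: str, n_channels: int) -> list[PeakSpec]:
    """Region-specific canonical peaks.

    cortex: a dominant beta peak (centered 21.5 Hz, i.e. within 20-23 Hz)
    increasing toward anterior channels, an alpha peak (9.5 Hz, within
    8-11 Hz) over posterior channels, and a small posterior 16-17 Hz beta
    peak.  gpi: high beta on all channels plus a ventral low-beta peak.
    stn: high beta weighted toward mid-to-ventral channels.
    """
    n = n_channels
    if region == "cortex":
        anterior = _ramp(n, 0.10, 1.0)
        posterior = _ramp(n, 1.0, 0.05)
        return [
            PeakSpec(21.5, 1.8, 1.0, anterior),
            PeakSpec(9.5, 1.2, 0.8, posterior),
            PeakSpec(16.5, 0.8, 0.25, posterior),
        ]
    if region == "gpi":
        ventral = _ramp(n, 1.0, 0.0)
        return [
            PeakSpec(27.0, 3.0, 1.0, None),
            PeakSpec(16.0, 1.5, 0.7, ventral),
        ]
    if region == "stn":
        mid_ventral = np.exp(-0.5 * ((np.arange(n) - (n - 1) / 3.0) / (n / 3.5)) ** 2)
        return [PeakSpec(27.0, 3.0, 1.0, mid_ventral)]
    raise ValueError(f"unknown region {region!r}; known: {REGIONS}")


def make_canonical_template(spec: CohortSpec, region: str = "cortex") -> SpatioSpectralMap:
    """Build the canonical (noise-free) spatio-spectral map for a region.

    Peaks are Gaussian bumps in frequency scaled by per-channel spatial
    profiles; the output is nonnegative on ``spec.freqs`` and lives on the
    aperiodic-adjusted (log10 a.u.) scale used throughout the analysis.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; known: {REGIONS}")
    n_contacts = spec.n_ecog_contacts if region == "cortex" else spec.n_dbs_contacts
    n_ch = n_contacts - 1  # bipolar channels
    if n_ch < 1:
        raise ValueError("need at least 2 contacts")
    peaks = spec.peaks if spec.peaks is not None else default_peaks(region, n_ch)
    freqs = spec.freqs
    vals = np.zeros((n_ch, freqs.size))
    for p in peaks:
        if not (freqs[0] <= p.center_hz <= freqs[-1]):
            raise ValueError(f"frequency grid does not cover peak center {p.center_hz} Hz")
        prof = np.ones(n_ch) if p.profile is None else np.asarray(p.profile, dtype=float)
        if prof.size != n_ch:
            raise ValueError("peak spatial profile length does not match channel count")
        amp = p.amplitude
        if spec.disease == "et_like" and 12.0 <= p.center_hz <= 35.0:
            amp *= spec.et_beta_attenuation
        bump = amp * np.exp(-0.5 * ((freqs - p.center_hz) / p.bandwidth_hz) ** 2)
        vals += prof[:, None] * bump[None, :]
    if region == "cortex":
        labels = [f"E{i + 1}-E{i}" for i in range(1, n_ch + 1)]
        order = "posterior_to_anterior"
    else:
        labels = [f"D{i}-D{i + 1}" for i in range(1, n_ch + 1)]
        order = "ventral_to_rostral"
    return SpatioSpectralMap(vals, labels, freqs, kind="power", spatial_order=order)


# ---------------------------------------------------------------------------
# map-level cohorts


def _cluster_signatures(spec: CohortSpec, n_ch: int, n_f: int) -> np.ndarray:
    if spec.cluster_signatures is not None:
        sig = np.asarray(spec.cluster_signatures, dtype=float)
        if sig.shape != (spec.n_clusters, n_ch, n_f):
            raise ValueError("cluster_signatures shape mismatch")
        return sig
    if spec.n_clusters == 1:
        return np.zeros((1, n_ch, n_f))
    # smooth random signatures, zero-mean across clusters so the template
    # stays the cohort mean
    rng = spec.cohort_rng(7)
    raw = rng.normal(size=(spec.n_clusters, n_ch, n_f))
    # smooth along frequency with a 7-bin Hann window
    win = np.hanning(9)[1:-1]
    win /= win.sum()
    for c in range(spec.n_clusters):
        for ch in range(n_ch):
            raw[c, ch] = np.convolve(raw[c, ch], win, mode="same")
    raw -= raw.mean(axis=0, keepdims=True)
    norm = np.sqrt((raw ** 2).mean(axis=(1, 2), keepdims=True))
    return spec.cluster_signature_sd * raw / np.maximum(norm, 1e-12)


def simulate_map_cohort(spec: CohortSpec, region: str = "cortex"
                        ) -> tuple[CohortStack, pd.DataFrame, GroundTruth]:
    """Draw a cohort of subject maps plus a coupled clinical table.

    Returns the stack (subjects x channels x freqs), a clinical table with
    age, years since diagnosis, the UPDRS III total and six sub-scores, and
    the :class:`GroundTruth` record of everything planted.
    """
    template = make_canonical_template(spec, region)
    n_ch, n_f = template.shape
    C = spec.coupling_matrix()
    if np.linalg.matrix_rank(C) < min(C.shape):
        warnings.warn("clinical coupling matrix is rank-deficient; "
                      "latent recovery from scores will be ambiguous")
    signatures = _cluster_signatures(spec, n_ch, n_f)
    label_rng = spec.cohort_rng(1)
    labels = 1 + label_rng.integers(0, spec.n_clusters, size=spec.n_subjects)

    hot_masks = [h.mask(n_ch, spec.freqs) for h in spec.hotspots]

    data = np.empty((spec.n_subjects, n_ch, n_f))
    deviations = np.empty_like(data)
    latents = np.empty((spec.n_subjects, spec.n_latents))
    for s in range(spec.n_subjects):
        rng = spec.subject_rng(s)
        z = rng.normal(size=spec.n_latents)
        latents[s] = z
        dev = signatures[labels[s] - 1].copy()
        for h, m in zip(spec.hotspots, hot_masks):
            amp = z[h.latent_index % spec.n_latents]
            if h.residual_frac > 0:
                amp = ((1 - h.residual_frac) * amp
                       + h.residual_frac * rng.normal())
            dev[m] += h.sd * amp
        noise = rng.normal(scale=spec.noise_sd, size=(n_ch, n_f)) if spec.noise_sd > 0 \
            else np.zeros((n_ch, n_f))
        deviations[s] = dev
        data[s] = template.values + dev + noise

    subject_ids = [f"S{s + 1:03d}" for s in range(spec.n_subjects)]
    clin = _clinical_table(spec, latents, subject_ids)
    stack = CohortStack(data, subject_ids, list(template.channels), spec.freqs, kind="power")
    gt = GroundTruth(template=template.values, deviations=deviations,
                     latents=latents, cluster_labels=labels,
                     coupled_pairs=list(spec.coupling_pairs))
    return stack, clin, gt


def _clinical_table(spec: CohortSpec, latents: np.ndarray,
                    subject_ids: list[str]) -> pd.DataFrame:
    C = spec.coupling_matrix()
    rng = spec.cohort_rng(2)
    n = len(subject_ids)
    scores = _CLINICAL_BASE[None, :] + latents @ C.T
    if spec.clinical_noise_sd > 0:
        scores = scores + rng.normal(scale=spec.clinical_noise_sd, size=scores.shape)
    scores = np.clip(scores, 0.0, None)
    if spec.integer_scores:
        scores = np.rint(scores)
    age = np.clip(np.rint(rng.normal(63.0, 8.0, size=n)), 35, 85)
    years_dx = np.clip(np.rint(rng.normal(8.0, 4.0, size=n)), 0, 30)
    df = pd.DataFrame({"subject_id": subject_ids, "age": age, "years_dx": years_dx})
    for j, col in enumerate(CLINICAL_COLUMNS):
        df[col] = scores[:, j]
    return df


# ---------------------------------------------------------------------------
# time-series mode


def _shaped_noise(rng: np.random.Generator, psd: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Gaussian time series whose one-sided PSD equals ``psd`` (len n//2+1)."""
    scale = np.sqrt(np.maximum(psd, 0.0) * fs * n / 2.0)
    re = rng.normal(size=psd.size)
    im = rng.normal(size=psd.size)
    coef = (re + 1j * im) / np.sqrt(2.0) * scale
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coef, n=n)


def _aperiodic_psd(freqs: np.ndarray, b: float, k: float, chi: float,
                   f_floor: float = 2.0) -> np.ndarray:
    """Linear-power aperiodic target 10**b / (k + f**chi).

    Below ``f_floor`` the curve is clamped to its value at ``f_floor`` (and
    DC is zeroed): a knee-free model diverges toward DC, which is
    unphysical and would leak through finite analysis windows into the
    4-110 Hz band.  The clamp sits a full half-bandwidth below the lowest
    analysis bin, so the emitted spectrum is exact everywhere it is
    measured.
    """
    f_eff = np.maximum(freqs, f_floor)
    psd = 10.0 ** b / (k + f_eff ** chi)
    return np.where(freqs > 0, psd, 0.0)


def _gaussian_peak_psd(freqs: np.ndarray, center: float, bw: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((freqs - center) / bw) ** 2)


def simulate_timeseries_subject(spec: CohortSpec, subject_index: int,
                                duration_s: float = 180.0, rate_hz: float = 2400.0
                                ) -> tuple[RawRecording, RawRecording, GroundTruth]:
    """Synthesize monopolar ECoG and DBS recordings for one subject.

    Each *bipolar* target channel is an aperiodic background (white noise
    spectrally shaped to ``10**b / (k + f**chi)``) plus Gaussian-envelope
    narrowband oscillations; ``spec.coupling_pairs`` entries
    (ecog_bipolar_idx, dbs_bipolar_idx, weight) inject a shared beta-band
    source into both members so their coherence rises with the weight.
    Monopolar contacts are reconstructed by cumulative summation so that
    adjacent differencing returns the bipolar targets exactly, and a common
    reference drift plus 60 Hz line is added to every contact.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz < 2 * float(spec.freqs[-1]):
        raise ValueError(f"rate {rate_hz} Hz is below twice the highest analysis "
                         f"frequency ({spec.freqs[-1]} Hz)")
    n = int(round(duration_s * rate_hz))
    fgrid = np.fft.rfftfreq(n, 1.0 / rate_hz)
    rng = spec.subject_rng(subject_index)
    b, k, chi = spec.aperiodic

    shared: dict[int, np.ndarray] = {}
    for pi, (_, _, w) in enumerate(spec.coupling_pairs):
        if w != 0:
            psd = _gaussian_peak_psd(fgrid, 21.0, 2.0, 1.0)
            shared[pi] = _shaped_noise(rng, psd, n, rate_hz)

    def bipolar_bank(region: str, n_contacts: int) -> np.ndarray:
        n_bip = n_contacts - 1
        peaks = spec.peaks if spec.peaks is not None else default_peaks(region, n_bip)
        out = np.empty((n_bip, n))
        for ch in range(n_bip):
            psd = _aperiodic_psd(fgrid, b, k, chi)
            for p in peaks:
                prof = np.ones(n_bip) if p.profile is None else p.profile
                amp = p.amplitude
                if spec.disease == "et_like" and 12.0 <= p.center_hz <= 35.0:
                    amp *= spec.et_beta_attenuation
                psd = psd + _gaussian_peak_psd(fgrid, p.center_hz, p.bandwidth_hz,
                                               amp * prof[ch])
            out[ch] = _shaped_noise(rng, psd, n, rate_hz)
        return out

    ecog_bip = bipolar_bank("cortex", spec.n_ecog_contacts)
    region = "gpi"
    dbs_bip = bipolar_bank(region, spec.n_dbs_contacts)

    for pi, (ei, di, w) in enumerate(spec.coupling_pairs):
        if w == 0:
            continue
        src = shared[pi]
        ecog_bip[ei] = ecog_bip[ei] + w * src
        dbs_bip[di] = dbs_bip[di] + w * src

    common = _shaped_noise(rng, _aperiodic_psd(fgrid, b, max(k, 1.0), chi), n, rate_hz)
    t = np.arange(n) / rate_hz
    line = spec.line_amp_uv * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
    common = common + line

    def monopolarize(bip: np.ndarray, n_contacts: int) -> np.ndarray:
        # contact_i - contact_{i+1} = bip_i  (DBS convention); build from the
        # last contact backwards, then add the common-mode to every contact
        mono = np.empty((n_contacts, n))
        mono[-1] = 0.0
        for i in range(n_contacts - 2, -1, -1):
            mono[i] = mono[i + 1] + bip[i]
        return mono + common[None, :]

    dbs_mono = monopolarize(dbs_bip, spec.n_dbs_contacts)
    # ECoG bipolar convention is anterior minus posterior: contact_{i+1} - contact_i
    ecog_mono = np.empty((spec.n_ecog_contacts, n))
    ecog_mono[0] = 0.0
    for i in range(1, spec.n_ecog_contacts):
        ecog_mono[i] = ecog_mono[i - 1] + ecog_bip[i - 1]
    ecog_mono = ecog_mono + common[None, :]

    half = spec.n_ecog_contacts // 2
    ecog_channels = [
        ChannelInfo(f"E{i + 1}", ECOG, i + 1,
                    cs_offset=(i + 1 - half) if i + 1 > half else (i + 1 - half - 1))
        for i in range(spec.n_ecog_contacts)
    ]
    dbs_channels = [ChannelInfo(f"D{i + 1}", DBS, i + 1) for i in range(spec.n_dbs_contacts)]
    sid = f"S{subject_index + 1:03d}"
    ecog = RawRecording(ecog_mono, rate_hz, ecog_channels, subject_id=sid, site="synthetic")
    dbs = RawRecording(dbs_mono, rate_hz, dbs_channels, subject_id=sid, site="synthetic")
    gt = GroundTruth(coupled_pairs=list(spec.coupling_pairs))
    return ecog, dbs, gt


def simulate_segment_replicates(spec: CohortSpec, n_segments: int, region: str = "cortex",
                                segment_noise_sd: float | None = None) -> np.ndarray:
    """Segment-level map replicates: (subjects, segments, channels, freqs).

    Each segment map is the canonical template plus i.i.d. pixel noise; used
    for per-subject consistency testing where 1-s windows serve as
    within-subject replicates.  With the default arguments all subjects are
    exchangeable draws from the population model (no subject effect).
    """
    template = make_canonical_template(spec, region)
    n_ch, n_f = template.shape
    sd = spec.noise_sd if segment_noise_sd is None else segment_noise_sd
    out = np.empty((spec.n_subjects, n_segments, n_ch, n_f))
    for s in range(spec.n_subjects):
        rng = spec.subject_rng(s)
        out[s] = template.values + rng.normal(scale=sd, size=(n_segments, n_ch, n_f))
    return out


# ---------------------------------------------------------------------------
# artifact injection


def inject_artifacts(rec: RawRecording, n_events: int, amplitude_sd: float,
                     seed: int) -> tuple[RawRecording, np.ndarray]:
    """Insert rapid-voltage-change transients at random sample positions.

    Each event is a two-sided spike (3 samples up, 3 samples down) of height
    ``amplitude_sd`` times the per-channel SD, applied to every channel (as a
    movement artifact would be).  Returns the modified copy and the sorted
    event sample indices; the rest of the signal is untouched.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_events == 0:
        return rec.copy(), np.array([], dtype=int)
    if amplitude_sd <= 0:
        raise ValueError("amplitude_sd must be > 0 when events are requested")
    rng = np.random.default_rng(seed)
    out = rec.copy()
    n = rec.n_samples
    margin = max(10, int(0.01 * rec.rate_hz))
    # keep events well separated so planted regions are disjoint
    min_gap = max(4 * margin, int(0.05 * rec.rate_hz))
    idx: list[int] = []
    tries = 0
    while len(idx) < n_events and tries < 10000:
        cand = int(rng.integers(margin, n - margin))
        if all(abs(cand - j) >= min_gap for j in idx):
            idx.append(cand)
        tries += 1
    if len(idx) < n_events:
        raise ValueError("recording too short to place the requested events")
    idx_arr = np.array(sorted(idx), dtype=int)
    shape = np.array([0.3, 0.8, 1.0, -1.0, -0.8, -0.3])
    sd = out.samples.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    for i in idx_arr:
        seg = slice(i, i + shape.size)
        out.samples[:, seg] += amplitude_sd * sd * shape[None, :out.samples[:, seg].shape[1]]
    return out, idx_arr
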