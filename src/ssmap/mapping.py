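"""Assembly of spatio-spectral maps, cohort stacks and variance maps.

A map is a channels x frequency matrix with an anatomical row order; a
cohort stack aligns subject maps along a leading axis.  Maximum-coherence
pairing reduces the full primary x partner x frequency coherence array to
one representative partner (the one with the highest mean 12-35 Hz
coherence) per primary channel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CohortStack, PAIRING_BETA, SpatioSpectralMap, Spectrum


def assemble_power_map(spectra: list[Spectrum], channels: list[str],
                       spatial_order: str = "posterior_to_anterior",
                       kind: str = "power") -> SpatioSpectralMap:
    """Stack per-channel spectra (given in spatial order) into one map.

    All spectra must share the frequency grid and processing flags; mixing
    normalized with unnormalized (or adjusted with unadjusted) input is an
    error.
    """
    if not spectra:
        raise ValueError("no spectra given")
    if len(spectra) != len(channels):
        raise ValueError("one channel label per spectrum required")
    f0 = spectra[0].freqs
    flags = (spectra[0].normalized, spectra[0].aperiodic_adjusted)
    for s in spectra[1:]:
        if not np.array_equal(s.freqs, f0):
            raise ValueError("spectra do not share a frequency grid")
        if (s.normalized, s.aperiodic_adjusted) != flags:
            raise ValueError("spectra carry mixed processing flags")
    vals = np.stack([s.values for s in spectra])
    return SpatioSpectralMap(vals, list(channels), f0, kind=kind, spatial_order=spatial_order)


@dataclass
class PairingResult:
    """Chosen partner per primary channel under maximum-coherence pairing."""

    partner_index: np.ndarray  # (n_primary,)
    beta_coherence: np.ndarray  # mean msc of the chosen pair in the beta band
    beta_band: tuple[float, float] = PAIRING_BETA


def max_coherence_pairing(coh: np.ndarray, freqs: np.ndarray,
                          channels: list[str] | None = None,
                          beta: tuple[float, float] = PAIRING_BETA,
                          spatial_order: str = "posterior_to_anterior"
                          ) -> tuple[PairingResult, SpatioSpectralMap]:
    """Select, per primary channel, the partner with maximal beta coherence.

    ``coh`` is the complete (n_primary, n_partner, n_freqs) msc array.  The
    mean msc over the closed beta band (both endpoint bins included) is
    maximized over partners; ties break toward the lowest partner index
    (most ventral / most posterior).  The returned map's row i is the full
    coherence spectrum of primary channel i with its chosen partner.  The
    search is direction-symmetric: pass the transposed array to pair from
    the other side.
    """
    coh = np.asarray(coh, dtype=float)
    if coh.ndim != 3:
        raise ValueError("coherence array must be 3-D (primary x partner x freq)")
    freqs = np.asarray(freqs, dtype=float)
    if coh.shape[2] != freqs.size:
        raise ValueError("frequency axis mismatch")
    if not ((freqs[0] <= beta[0]) and (beta[1] <= freqs[-1])):
        raise ValueError("beta band outside frequency grid")
    band = (freqs >= beta[0]) & (freqs <= beta[1])
    means = np.nanmean(coh[:, :, band], axis=2)  # (n_primary, n_partner)
    if np.isnan(means).all(axis=1).any():
        raise ValueError("all-NaN coherence row")
    partner = np.nanargmax(means, axis=1)  # argmax takes first (lowest) on ties
    rows = coh[np.arange(coh.shape[0]), partner, :]
    labels = channels if channels is not None else [f"ch{i}" for i in range(coh.shape[0])]
    chosen = means[np.arange(coh.shape[0]), partner]
    result = PairingResult(partner_index=partner, beta_coherence=chosen, beta_band=beta)
    map_ = SpatioSpectralMap(np.nan_to_num(rows, nan=0.0), list(labels), freqs,
                             kind="coherence", spatial_order=spatial_order)
    return result, map_


def stack_cohort(maps: list[SpatioSpectralMap], subject_ids: list[str]) -> CohortStack:
    """Stack per-subject maps with identical axes into a cohort array."""
    if not maps:
        raise ValueError("no maps given")
    if len(maps) != len(subject_ids):
        raise ValueError("one subject id per map required")
    ref = maps[0]
    for m, sid in zip(maps, subject_ids):
        if m.channels != ref.channels or not np.array_equal(m.freqs, ref.freqs):
            raise ValueError(f"subject {sid}: map axes do not match the cohort axes")
    data = np.stack([m.values for m in maps])
    return CohortStack(data, list(subject_ids), list(ref.channels), ref.freqs, kind=ref.kind)


def variance_map(stack: CohortStack) -> SpatioSpectralMap:
    """Per-pixel unbiased (n-1) sample variance across subjects."""
    if stack.n_subjects < 2:
        raise ValueError("variance requires >= 2 subjects")
    v = stack.data.var(axis=0, ddof=1)
    return SpatioSpectralMap(v, list(stack.channels), stack.freqs, kind="variance")
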