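"""Complement-cluster prediction and extraction from centroided MS2 spectra.

After CID fragmentation of a TMTpro-labeled precursor, the reporter region
departs (by default as a singly charged fragment together with the carbonyl
CO), leaving the balancer-peptide conjugate — the complementary ion — whose
m/z encodes both the peptide and the quantification channel.  The cluster of
complementary ions of one peptide spans the nine channel offsets on an
approximately 1.00335/z_c-spaced grid, extended by trailing peptide-isotope
peaks so that the deconvolution system is overdetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chem

log = logging.getLogger(__name__)

#: spacing of adjacent nominal cluster positions for a singly charged ion (Da)
GRID_SPACING = 13.0033548378 - 12.0

#: precursor eligibility windows (m/z, inclusive) per charge state
ELIGIBILITY_WINDOWS = {2: (500.0, 1074.0), 3: (350.0, 1381.0)}

#: default number of trailing isotope peaks beyond the last channel
DEFAULT_EXTRA_ISOTOPES = 2

DEFAULT_TOL_PPM = 10.0


def precursor_eligible(z: int, mz: float) -> bool:
    """Whether a precursor may trigger a quantification scan.

    Only 2+ ions at 500-1074 Th and 3+ ions at 350-1381 Th are analyzed, so
    that the full complement cluster stays inside a normal-range scan.
    """
    if z < 1 or mz <= 0:
        raise ValueError("require z >= 1 and mz > 0")
    window = ELIGIBILITY_WINDOWS.get(z)
    return window is not None and window[0] <= mz <= window[1]


@dataclass(frozen=True)
class LossModel:
    """How the reporter region departs during fragmentation.

    ``charged`` — reporter leaves as a singly charged fragment (with CO), the
    complement retains z-1 charges.  ``neutral`` — the whole reporter region
    leaves uncharged and the complement keeps the precursor charge.
    ``loss_mass`` overrides the departing mass (defaults to the channel-0
    reporter cation + CO for ``charged``, the same minus a proton for
    ``neutral``).
    """

    kind: str = "charged"
    loss_mass: float | None = None

    def __post_init__(self):
        if self.kind not in ("charged", "neutral"):
            raise ValueError("loss model kind must be 'charged' or 'neutral'")

    def complement_charge(self, z: int) -> int:
        return z - 1 if self.kind == "charged" else z

    def departing_mass(self, channel_zero_loss: float) -> float:
        if self.loss_mass is not None:
            return self.loss_mass
        if self.kind == "charged":
            return channel_zero_loss
        return channel_zero_loss - chem.PROTON_MASS


@dataclass(frozen=True)
class PrecursorIon:
    sequence: str
    charge: int
    mz: float
    n_variable_ox: int = 0

    def __post_init__(self):
        if self.charge < 1 or self.mz <= 0:
            raise ValueError("invalid precursor charge or m/z")

    @property
    def n_labels(self) -> int:
        return chem.label_count(self.sequence)


@dataclass(frozen=True)
class ClusterTemplate:
    """Expected complement-cluster peak positions for one precursor."""

    complement_charge: int
    base_mz: float
    peak_mzs: np.ndarray          # one per grid row (channels + extra isotopes)
    channel_rows: np.ndarray      # grid row of each channel

    def __post_init__(self):
        p = np.asarray(self.peak_mzs, dtype=float)
        if (np.diff(p) <= 0).any():
            raise ValueError("template peaks must be strictly increasing")
        object.__setattr__(self, "peak_mzs", p)
        object.__setattr__(self, "channel_rows",
                           np.asarray(self.channel_rows, dtype=int))

    @property
    def n_rows(self) -> int:
        return len(self.peak_mzs)


@dataclass
class ComplementCluster:
    """Observed intensities B on a template grid, with per-peak FT noise."""

    intensities: np.ndarray
    noise: np.ndarray
    matched: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.intensities, dtype=float)
        n = np.asarray(self.noise, dtype=float)
        m = np.asarray(self.matched, dtype=bool)
        if not (len(b) == len(n) == len(m)):
            raise ValueError("intensity, noise and mask lengths must agree")
        if (b < 0).any():
            raise ValueError("intensities must be non-negative")
        if (n[m] <= 0).any():
            raise ValueError("matched peaks must have positive noise")
        self.intensities, self.noise, self.matched = b, n, m

    @property
    def total_signal_to_noise(self) -> float:
        m = self.matched
        return float((self.intensities[m] / self.noise[m]).sum())


def complement_grid(
    precursor: PrecursorIon,
    channels: chem.ChannelModel,
    tags: list[chem.TagSpec],
    loss_model: LossModel | None = None,
    extra_isotopes: int = DEFAULT_EXTRA_ISOTOPES,
) -> ClusterTemplate:
    """Predict the complement-cluster m/z grid for a precursor.

    The base (lowest-channel) position follows from the precursor m/z and the
    theoretical fragmentation loss; subsequent rows are spaced by
    ``GRID_SPACING / z_c``.  The template is channel-independent — channels
    index positions within it.
    """
    loss_model = loss_model or LossModel()
    z = precursor.charge
    z_c = loss_model.complement_charge(z)
    if z_c < 1:
        raise ValueError(f"complement charge {z_c} < 1 for z={z}")
    loss = loss_model.departing_mass(chem.channel_loss_mass(channels, tags, 0))
    base = (z * precursor.mz - loss) / z_c
    n_rows = channels.max_offset + 1 + extra_isotopes
    rows = np.arange(n_rows)
    return ClusterTemplate(
        complement_charge=z_c,
        base_mz=base,
        peak_mzs=base + rows * GRID_SPACING / z_c,
        channel_rows=channels.nominal_offsets.copy(),
    )


def extract_cluster(
    spectrum_mz: np.ndarray,
    spectrum_intensity: np.ndarray,
    template: ClusterTemplate,
    tol_ppm: float = DEFAULT_TOL_PPM,
    spectrum_noise: np.ndarray | None = None,
    noise_floor: float = 1.0,
) -> ComplementCluster:
    """Match template positions against a centroided peak list.

    For each expected position the most intense peak within ±tol_ppm is
    taken; when two expected positions claim the same spectrum peak the
    closer one wins and the other is left unmatched.  Unmatched positions
    get zero intensity and the spectrum noise floor.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mz = np.asarray(spectrum_mz, dtype=float)
    if (np.diff(mz) < 0).any():
        raise ValueError("spectrum must be sorted by m/z")
    inten = np.asarray(spectrum_intensity, dtype=float)
    noise = (np.asarray(spectrum_noise, dtype=float)
             if spectrum_noise is not None else np.full_like(inten, noise_floor))

    n = template.n_rows
    chosen = np.full(n, -1)
    for i, pos in enumerate(template.peak_mzs):
        tol = pos * tol_ppm * 1e-6
        lo, hi = np.searchsorted(mz, (pos - tol, pos + tol))
        if hi > lo:
            chosen[i] = lo + int(np.argmax(inten[lo:hi]))
    # resolve double assignments: closer expected position wins
    for peak_idx in set(chosen[chosen >= 0]):
        claimers = np.flatnonzero(chosen == peak_idx)
        if len(claimers) > 1:
            dist = np.abs(template.peak_mzs[claimers] - mz[peak_idx])
            losers = claimers[claimers != claimers[np.argmin(dist)]]
            chosen[losers] = -1
            log.debug("template rows %s lost peak-match conflict", losers.tolist())

    b = np.zeros(n)
    nvec = np.full(n, max(noise_floor, 1e-12))
    mask = chosen >= 0
    b[mask] = inten[chosen[mask]]
    nvec[mask] = np.maximum(noise[chosen[mask]], 1e-12)
    return ComplementCluster(b, nvec, mask)
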