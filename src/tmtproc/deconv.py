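"""Impurity design matrix and least-squares channel deconvolution.

Observed complement-cluster intensities B mix the true channel abundances x
through two linear effects: the isotopic impurities of each tag's complement
region (signal appearing at +/-1 and +/-2 nominal offsets) and the peptide's
own isotope envelope (trailing +1, +2, ... peaks that overlap the next
channels' positions).  Both are encoded in a design matrix A, and the
overdetermined system A x = B is solved by orthogonal (QR) decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as _sla
from scipy import optimize as _sopt

from . import chem, complement

log = logging.getLogger(__name__)

#: total S/N required to call a 9-plex peptide quantified
QUANT_SN_THRESHOLD = 90.0
#: per-labeled-channel S/N requirement for smaller plexes
QUANT_SN_PER_CHANNEL = 10.0


@dataclass(frozen=True)
class ImpurityMatrix:
    """Design matrix A: rows = observed cluster positions, columns = channels."""

    values: np.ndarray
    row_labels: tuple
    column_labels: tuple

    def __post_init__(self):
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2:
            raise ValueError("A must be 2-D")
        if (a < -1e-12).any():
            raise ValueError("A entries must be non-negative")
        if a.shape[0] < a.shape[1]:
            raise ValueError("system must be overdetermined (rows >= columns)")
        if (a.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("each column may carry at most unit signal")
        object.__setattr__(self, "values", a)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ChannelAbundances:
    """Solved channel abundance vector with fit diagnostics."""

    values: np.ndarray
    channel_names: tuple
    residual_norm: float
    total_signal_to_noise: float = float("nan")
    quantified: bool = False
    raw_values: np.ndarray | None = None  # pre-clipping least-squares solution

    def ratio(self, num: int, den: int) -> float:
        return float(self.values[num] / self.values[den])


def build_design_matrix(
    envelope: chem.IsotopeDistribution,
    tags: list[chem.TagSpec],
    channels: chem.ChannelModel,
    n_rows: int | None = None,
) -> ImpurityMatrix:
    """Convolve per-channel tag impurities with the peptide isotope envelope.

    Column c places ``conv(channel-c impurity vector, envelope)`` at channel
    c's nominal offset; mass falling outside the observed rows (including
    -1/-2 impurities below the grid) is simply lost, so columns sum to <= 1.
    """
    offsets = channels.nominal_offsets
    min_rows = channels.max_offset + 1
    if n_rows is None:
        n_rows = min_rows + complement.DEFAULT_EXTRA_ISOTOPES
    if n_rows < min_rows:
        raise ValueError(f"n_rows must be >= {min_rows} to cover all channels")
    env = envelope.fractions
    a = np.zeros((n_rows, channels.n_channels))
    for c in range(channels.n_channels):
        imp = chem.channel_impurity_vector(channels, tags, c)
        mixed = np.convolve(imp, env)  # offsets -2 .. +2+len(env)-1
        for k, frac in enumerate(mixed):
            row = offsets[c] + k - 2
            if 0 <= row < n_rows:
                a[row, c] += frac
    return ImpurityMatrix(
        a,
        row_labels=tuple(f"p{r}" for r in range(n_rows)),
        column_labels=tuple(ch.name for ch in channels.channels),
    )


def _collinear_pairs(a: np.ndarray, labels) -> list[tuple]:
    g = a.T @ a
    norms = np.sqrt(np.diag(g))
    bad = []
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = g / np.outer(norms, norms)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if not np.isfinite(corr[i, j]) or corr[i, j] > 1 - 1e-10:
                bad.append((labels[i], labels[j]))
    return bad


def solve_channels(
    a: ImpurityMatrix,
    b: complement.ComplementCluster | np.ndarray,
    nonnegative: bool = False,
    clip_negative: bool = True,
) -> ChannelAbundances:
    """Least-squares solution of A x = B via orthogonal decomposition.

    Negative components are clipped to zero after the solve (abundances are
    physical); set ``nonnegative`` for a full non-negative least squares fit
    instead.  Rank deficiency is rejected with a diagnostic naming the
    collinear channels.
    """
    if isinstance(b, complement.ComplementCluster):
        bvec = b.intensities
        total_sn = b.total_signal_to_noise
    else:
        bvec = np.asarray(b, dtype=float)
        total_sn = float("nan")
    if a.shape[0] != len(bvec):
        raise ValueError("rows(A) must equal length(B)")
    if np.linalg.matrix_rank(a.values) < a.shape[1]:
        pairs = _collinear_pairs(a.values, a.column_labels)
        raise ValueError(f"design matrix is rank deficient; collinear channels: {pairs}")
    if nonnegative:
        x, rnorm = _sopt.nnls(a.values, bvec)
        raw = x.copy()
    else:
        # lapack 'gelsy' solves via complete orthogonal (QR) factorization
        raw, _, _, _ = _sla.lstsq(a.values, bvec, lapack_driver="gelsy")
        rnorm = float(np.linalg.norm(a.values @ raw - bvec))
        x = np.clip(raw, 0.0, None) if clip_negative else raw.copy()
    return ChannelAbundances(
        values=x,
        channel_names=a.column_labels,
        residual_norm=float(rnorm),
        total_signal_to_noise=total_sn,
        raw_values=raw,
    )


def passes_quant_filter(x: ChannelAbundances, n_labeled_channels: int = 9) -> bool:
    """Total-S/N gate for calling a peptide quantified.

    The threshold is 90 for a full 9-plex and 10x the number of labeled
    channels for smaller plexes.
    """
    if n_labeled_channels < 1:
        raise ValueError("n_labeled_channels must be >= 1")
    threshold = (QUANT_SN_THRESHOLD if n_labeled_channels == 9
                 else QUANT_SN_PER_CHANNEL * n_labeled_channels)
    return bool(x.total_signal_to_noise >= threshold)


# ---------------------------------------------------------------------------
# per-run quantification driver
# ---------------------------------------------------------------------------

def quantify_psm(
    spectrum,
    psm,
    tags: list[chem.TagSpec],
    channels: chem.ChannelModel,
    loss_model: complement.LossModel | None = None,
    tol_ppm: float = complement.DEFAULT_TOL_PPM,
    n_labeled_channels: int = 9,
    nonnegative: bool = False,
) -> ChannelAbundances | None:
    """Full extract-and-deconvolve pipeline for one PSM; None if ineligible."""
    if not complement.precursor_eligible(psm.charge, psm.precursor_mz):
        return None
    prec = complement.PrecursorIon(psm.peptide, psm.charge, psm.precursor_mz,
                                   n_variable_ox=psm.n_variable_ox)
    template = complement.complement_grid(prec, channels, tags, loss_model)
    comp = chem.composition_of_peptide(prec.sequence, prec.n_variable_ox)
    envelope = chem.envelope_for_quantification(comp)
    cluster = complement.extract_cluster(
        spectrum.mz, spectrum.intensity, template, tol_ppm=tol_ppm,
        spectrum_noise=spectrum.noise,
    )
    a = build_design_matrix(envelope, tags, channels, n_rows=template.n_rows)
    result = solve_channels(a, cluster, nonnegative=nonnegative)
    result.quantified = passes_quant_filter(result, n_labeled_channels)
    return result


def quantify_run(
    spectra_by_scan: dict,
    psms,
    tags: list[chem.TagSpec],
    channels: chem.ChannelModel,
    loss_model: complement.LossModel | None = None,
    tol_ppm: float = complement.DEFAULT_TOL_PPM,
    n_labeled_channels: int = 9,
    nonnegative: bool = False,
) -> pd.DataFrame:
    """Quantify every eligible PSM of a run into a peptide x channel table."""
    rows = []
    for psm in psms:
        spectrum = spectra_by_scan.get(psm.scan_id)
        if spectrum is None:
            log.warning("scan %s not found in spectrum file; PSM skipped", psm.scan_id)
            continue
        result = quantify_psm(
            spectrum, psm, tags, channels, loss_model=loss_model,
            tol_ppm=tol_ppm, n_labeled_channels=n_labeled_channels,
            nonnegative=nonnegative,
        )
        if result is None:
            log.info("PSM %s ineligible (z=%d, m/z=%.3f)", psm.scan_id,
                     psm.charge, psm.precursor_mz)
            continue
        row = {"psm_id": psm.scan_id, "peptide": psm.peptide, "protein": psm.protein}
        row.update(dict(zip(result.channel_names, result.values)))
        row.update(
            total_sn=result.total_signal_to_noise,
            residual=result.residual_norm,
            quantified=result.quantified,
        )
        rows.append(row)
    columns = (["psm_id", "peptide", "protein"]
               + [c.name for c in channels.channels]
               + ["total_sn", "residual", "quantified"])
    return pd.DataFrame(rows, columns=columns)
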