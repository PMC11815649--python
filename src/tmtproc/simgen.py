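"""Synthetic two-proteome interference samples with known channel truth.

Emulates the HeLa/yeast interference design: one proteome labeled at
graded design ratios across the nine complement channels, a second labeled
1:1, mixed at a configurable weight.  Each simulated MS2 scan carries the
target peptide's complement cluster (channel intensities distorted by the
tag impurity table and the peptide isotope envelope, with Poisson ion
statistics), reporter-region peaks of every coisolated species, and — with
configurable probability — an interfering peptide's complement cluster.
Peaks closer than the resolution-dependent width coalesce into one
centroid, as in an FT analyzer.

The acquisition-noise model (Poisson counts per peak plus an FT noise
floor) is a stand-in: the study this emulates does not describe its noise
process.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import chem, complement, deconv
from .msio import PSMRecord, Spectrum

log = logging.getLogger(__name__)

#: default design ratios (yeast-like graded, human-like flat)
YEAST_DESIGN_RATIOS = (0.0, 1.0, 5.0, 10.0, 1.0, 10.0, 5.0, 1.0, 0.0)
HUMAN_DESIGN_RATIOS = (1.0,) * 9

_RESIDUES = "ACDEFGHILMNPQSTVWY"  # internal residues; terminus drawn from K/R


def rts_accept(xcorr: float, delta_cn: float, ppm_dev: float,
               on_target_list: bool = True) -> bool:
    """Real-time-search acceptance emulation.

    A match triggers quantification iff its cross-correlation exceeds 1.4
    (strictly), its delta cross-correlation is at least 0.2, its absolute
    precursor deviation is at most 10 ppm, and its protein is on the target
    list (exclusion-tag emulation of the semitargeted mode).
    """
    if not (np.isfinite(xcorr) and np.isfinite(delta_cn) and np.isfinite(ppm_dev)):
        raise ValueError("scores must be finite")
    return bool(xcorr > 1.4 and delta_cn >= 0.2 and abs(ppm_dev) <= 10.0
                and on_target_list)


def peak_fwhm(mz: float, resolution_at_200: float) -> float:
    """Orbitrap FT peak width: resolution falls off as 1/sqrt(m/z)."""
    return mz ** 1.5 / (resolution_at_200 * np.sqrt(200.0))


@dataclass
class SimConfig:
    """Study conditions of the simulated interference experiment."""

    yeast_ratios: tuple = YEAST_DESIGN_RATIOS
    human_ratios: tuple = HUMAN_DESIGN_RATIOS
    mixing_weight: float = 10.0          # parts human per part yeast
    n_yeast_peptides: int = 100
    n_human_peptides: int = 100
    coisolation_prob: float = 0.5
    interferent_fraction: float = 0.5    # interferent ions relative to target
    interferent_ratios: tuple = HUMAN_DESIGN_RATIOS
    ion_scale: float = 5000.0            # expected ions per complement cluster
    reporter_yield: float = 1.0          # reporter ions relative to ion_scale
    ft_noise_floor: float = 5.0          # ion-units noise floor per peak
    poisson: bool = True
    resolution: float = 60000.0          # Orbitrap resolution at m/z 200
    loss_model: str = "charged"
    isolation_half_width: float = 0.25   # Th
    charge_probs: tuple = (0.6, 0.4)     # P(z=2), P(z=3)
    impurities: str = "default"          # "default", "identity" or a TSV path
    seed: int = 0

    def __post_init__(self):
        if min(self.yeast_ratios + self.human_ratios + self.interferent_ratios) < 0:
            raise ValueError("design ratios must be non-negative")
        if self.mixing_weight <= 0:
            raise ValueError("mixing weight must be > 0")
        if not 0 <= self.coisolation_prob <= 1:
            raise ValueError("coisolation probability must be in [0, 1]")


@dataclass
class LedgerRow:
    psm_id: int
    peptide: str
    proteome: str
    protein: str
    channel_truth: tuple
    interferent_present: bool
    interferent_fraction: float
    interferent_reporter_per_channel: float
    empty: bool
    noiseless_peaks: str  # JSON [m/z, intensity] pairs


@dataclass
class TruthLedger:
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.rows])
        if len(df):
            df["channel_truth"] = df["channel_truth"].map(
                lambda v: ";".join(f"{x:.8g}" for x in v))
        return df


@dataclass
class SimSample:
    spectra: list
    psms: list
    ledger: TruthLedger
    config: SimConfig
    channels: chem.ChannelModel
    tags: list


def _random_tryptic_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    body = "".join(rng.choice(list(_RESIDUES), size=length - 1))
    return body + rng.choice(["K", "R"])


def _eligible_peptide(rng):
    """Draw (sequence, z, composition, mz) until the precursor is eligible."""
    for _ in range(200):
        seq = _random_tryptic_peptide(rng)
        z = 2 if rng.random() < 0.6 else 3
        comp = chem.composition_of_peptide(seq)
        mass = chem.monoisotopic_mass(comp)
        mz = (mass + z * chem.PROTON_MASS) / z
        if complement.precursor_eligible(z, mz):
            return seq, z, comp, mz
    raise RuntimeError("could not draw an eligible precursor")


def _cluster_peaks(mz_precursor, z, comp, truth, tags, channels, loss_model):
    """Noiseless complement-cluster peak table (all envelope rows) for one species."""
    env = chem.envelope_for_quantification(comp)
    z_c = loss_model.complement_charge(z)
    loss = loss_model.departing_mass(chem.channel_loss_mass(channels, tags, 0))
    base = (z * mz_precursor - loss) / z_c
    n_rows = channels.max_offset + len(env) + 3
    a = deconv.build_design_matrix(env, tags, channels, n_rows=n_rows)
    intensities = a.values @ np.asarray(truth, dtype=float)
    positions = base + np.arange(n_rows) * complement.GRID_SPACING / z_c
    keep = intensities > 0
    return positions[keep], intensities[keep]


def _reporter_peaks(truth, tags, channels):
    """Reporter-region peaks (with reporter impurities) for one labeled species."""
    mzs, intens = [], []
    by_name = {t.name: t for t in tags}
    for ch, x in zip(channels.channels, truth):
        if x <= 0:
            continue
        share = x / len(ch.members)
        for name in ch.members:
            tag = by_name[name]
            for off, frac in zip(range(-2, 3), tag.reporter_impurities):
                if frac > 0:
                    mzs.append(tag.reporter_ion_mz + off * complement.GRID_SPACING)
                    intens.append(share * frac)
    return np.array(mzs), np.array(intens)


def coalesce_peaks(mz: np.ndarray, intensity: np.ndarray,
                   resolution_at_200: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks closer than the FT peak width into intensity-weighted centroids."""
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [mz[0]], [intensity[0]]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - out_mz[-1] < peak_fwhm(m, resolution_at_200):
            tot = out_int[-1] + i
            out_mz[-1] = (out_mz[-1] * out_int[-1] + m * i) / tot
            out_int[-1] = tot
        else:
            out_mz.append(m)
            out_int.append(i)
    return np.array(out_mz), np.array(out_int)


def simulate_interference_sample(config: SimConfig) -> SimSample:
    """Generate mzML-ready spectra, a PSM table and a truth ledger."""
    rng = np.random.default_rng(config.seed)
    if config.impurities == "default":
        tags = chem.default_tags()
    elif config.impurities == "identity":
        tags = chem.identity_tags()
    else:
        tags = chem.default_tags(chem.load_impurity_table(config.impurities))
    channels = chem.build_channel_model(tags)
    loss_model = complement.LossModel(kind=config.loss_model)

    spectra, psms = [], []
    ledger = TruthLedger()
    plan = ([("yeast", np.asarray(config.yeast_ratios, float))] * config.n_yeast_peptides
            + [("human", np.asarray(config.human_ratios, float) * config.mixing_weight)]
            * config.n_human_peptides)
    for scan_id, (proteome, ratios) in enumerate(plan):
        seq, z, comp, mz = _eligible_peptide(rng)
        protein = f"{proteome.upper()}_P{scan_id // 3:04d}"

        # scale channel truth so the expected cluster carries ion_scale ions
        rel = ratios / ratios.sum() if ratios.sum() > 0 else ratios
        pos_t, expected_t = _cluster_peaks(mz, z, comp, rel, tags, channels, loss_model)
        scale = config.ion_scale / expected_t.sum() if expected_t.sum() > 0 else 0.0
        truth = rel * scale
        expected_t = expected_t * scale

        all_mz = [pos_t]
        all_int = [expected_t]
        rep_mz, rep_int = _reporter_peaks(
            truth * config.reporter_yield, tags, channels)
        all_mz.append(rep_mz)
        all_int.append(rep_int)

        interfered = rng.random() < config.coisolation_prob
        interferent_reporter = 0.0
        if interfered and config.interferent_fraction > 0 and config.ion_scale > 0:
            iseq, iz, icomp, _ = _eligible_peptide(rng)
            imz = mz + rng.uniform(-config.isolation_half_width,
                                   config.isolation_half_width)
            irel = np.asarray(config.interferent_ratios, float)
            irel = irel / irel.sum()
            ipos, iexp = _cluster_peaks(imz, z, icomp, irel, tags, channels, loss_model)
            iscale = config.interferent_fraction * config.ion_scale / iexp.sum()
            itruth = irel * iscale
            all_mz.append(ipos)
            all_int.append(iexp * iscale)
            irep_mz, irep_int = _reporter_peaks(
                itruth * config.reporter_yield, tags, channels)
            all_mz.append(irep_mz)
            all_int.append(irep_int)
            interferent_reporter = float(itruth.mean() * config.reporter_yield)

        mz_all = np.concatenate(all_mz)
        int_all = np.concatenate(all_int)
        mz_all, int_all = coalesce_peaks(mz_all, int_all, config.resolution)

        noiseless = json.dumps([[round(m, 6), round(i, 4)]
                                for m, i in zip(mz_all, int_all)])
        if config.poisson:
            int_obs = rng.poisson(int_all).astype(float)
        else:
            int_obs = int_all.copy()
        keep = int_obs > 0
        mz_obs, int_obs = mz_all[keep], int_obs[keep]
        noise = np.sqrt(int_obs + config.ft_noise_floor ** 2)

        spectra.append(Spectrum(
            scan_id=scan_id, ms_level=2, mz=mz_obs, intensity=int_obs,
            noise=noise, precursor_mz=mz, precursor_charge=z,
        ))
        psms.append(PSMRecord(
            scan_id=scan_id, peptide=seq, mods="ox:0", charge=z,
            precursor_mz=mz, protein=protein,
            xcorr=float(rng.uniform(1.5, 4.5)),
            delta_cn=float(rng.uniform(0.2, 0.6)),
            ppm_dev=float(rng.normal(0.0, 2.0)),
            extra={"proteome": proteome},
        ))
        ledger.rows.append(LedgerRow(
            psm_id=scan_id, peptide=seq, proteome=proteome, protein=protein,
            channel_truth=tuple(truth),
            interferent_present=bool(interfered and config.ion_scale > 0
                                     and config.interferent_fraction > 0),
            interferent_fraction=config.interferent_fraction,
            interferent_reporter_per_channel=interferent_reporter,
            empty=bool(len(mz_obs) == 0),
            noiseless_peaks=noiseless,
        ))
    return SimSample(spectra, psms, ledger, config, channels, tags)


def quantify_reporters(spectrum, channels: chem.ChannelModel,
                       tags: list, tol_ppm: float = 10.0) -> np.ndarray:
    """Per-channel reporter intensities, summed over all coisolated species.

    Reporter ions of coisolated peptides are indistinguishable, so the
    returned vector includes interference by construction.
    """
    by_name = {t.name: t for t in tags}
    mz = np.asarray(spectrum.mz, float)
    inten = np.asarray(spectrum.intensity, float)
    out = np.zeros(channels.n_channels)
    for i, ch in enumerate(channels.channels):
        for name in ch.members:
            pos = by_name[name].reporter_ion_mz
            tol = pos * tol_ppm * 1e-6
            lo, hi = np.searchsorted(mz, (pos - tol, pos + tol))
            if hi > lo:
                out[i] += inten[lo + int(np.argmax(inten[lo:hi]))]
    return out


# ---------------------------------------------------------------------------
# time-course generator
# ---------------------------------------------------------------------------

def _archetype_profile(name: str, n_stages: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_stages)
    profiles = {
        "constant": np.ones(n_stages),
        "increasing": 2.0 ** np.linspace(-1.5, 1.5, n_stages),
        "decreasing": 2.0 ** np.linspace(1.5, -1.5, n_stages),
        "peaked": 1.0 + 3.0 * np.exp(-((t - 0.5) ** 2) / (2 * 0.12 ** 2)),
    }
    if name not in profiles:
        raise ValueError(f"unknown archetype {name!r}")
    return profiles[name]


def simulate_timecourse(
    n_proteins: int = 240,
    n_stages: int = 9,
    cluster_archetypes: tuple = ("constant", "increasing", "decreasing", "peaked"),
    anchor_fraction: float = 0.1,
    noise_sd: float = 0.1,
    mean_peptides_per_protein: float = 3.0,
    seed: int = 0,
):
    """Peptide x stage abundances drawn from archetype trajectories.

    Proteins cycle through the archetypes; a fraction of the constant class
    is flagged as anchors (mitochondrial stand-ins).  Peptides inherit their
    protein's trajectory with multiplicative lognormal noise per stage.
    Returns ``(QuantMatrix, protein truth DataFrame)``.
    """
    from .timecourse import QuantMatrix

    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    if "constant" not in cluster_archetypes:
        raise ValueError("archetypes must include a constant (anchor) class")
    rng = np.random.default_rng(seed)
    stages = [f"s{j + 1}" for j in range(n_stages)]
    n_anchor = int(round(anchor_fraction * n_proteins))

    prot_rows, pep_rows, pep_index = [], [], []
    for i in range(n_proteins):
        if i < n_anchor:
            arch, is_anchor = "constant", True
        else:
            arch = cluster_archetypes[(i - n_anchor) % len(cluster_archetypes)]
            is_anchor = False
        protein = f"PROT{i:04d}"
        base = float(rng.lognormal(np.log(100.0), 0.8))
        profile = _archetype_profile(arch, n_stages) * base
        prot_rows.append({"protein": protein, "archetype": arch,
                          "is_anchor": is_anchor})
        n_pep = 1 + int(rng.poisson(max(mean_peptides_per_protein - 1, 0)))
        for p in range(n_pep):
            pep_scale = float(rng.lognormal(0.0, 0.5))
            noise = (rng.lognormal(0.0, noise_sd, size=n_stages)
                     if noise_sd > 0 else np.ones(n_stages))
            pep_rows.append(profile * pep_scale * noise)
            pep_index.append({"peptide": f"{protein}_pep{p}", "protein": protein,
                              "is_anchor": is_anchor})
    values = pd.DataFrame(pep_rows, columns=stages,
                          index=[r["peptide"] for r in pep_index])
    meta = pd.DataFrame(pep_index).set_index("peptide")
    truth = pd.DataFrame(prot_rows).set_index("protein")
    return QuantMatrix(values, meta), truth
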