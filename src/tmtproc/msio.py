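"""Readers/writers, configuration, logging and the command-line interface.

Spectra travel as mzML (centroided MS2 scans with precursor metadata and an
optional per-peak noise array); peptide-spectrum matches and quantification
results travel as documented TSV tables.  All writes are atomic (temp file +
rename), so re-running a command with the same seed and configuration
reproduces outputs byte for byte.
"""

from __future__ import annotations

import base64
import logging
import os
import sys
import tempfile
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml
from lxml import etree

log = logging.getLogger(__name__)

_MZML_NS = "http://psi.hupo.org/ms/mzml"

PSM_REQUIRED_COLUMNS = ["scan_id", "peptide", "mods", "charge", "precursor_mz",
                        "protein", "xcorr", "delta_cn", "ppm_dev"]


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One centroided scan: peak arrays plus precursor metadata."""

    scan_id: int
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray | None = None
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    native_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.noise is not None:
            self.noise = np.asarray(self.noise, dtype=float)
        if not self.native_id:
            self.native_id = f"scan={self.scan_id + 1}"


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from the search results table."""

    scan_id: int
    peptide: str
    mods: str
    charge: int
    precursor_mz: float
    protein: str
    xcorr: float = 0.0
    delta_cn: float = 0.0
    ppm_dev: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"PSM {self.scan_id}: charge must be >= 1")

    @property
    def n_variable_ox(self) -> int:
        for part in self.mods.split(";"):
            if part.startswith("ox:"):
                return int(part[3:])
        return 0


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------

def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_dataframe(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format=float_format))


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _b64(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode()


def _cv(parent, accession: str, name: str, value: str = "") -> None:
    etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                     accession=accession, name=name, value=value)


def _binary_array(parent, accession: str, name: str, data: np.ndarray,
                  nonstandard: str | None = None) -> None:
    enc = _b64(data)
    arr = etree.SubElement(parent, f"{{{_MZML_NS}}}binaryDataArray",
                           encodedLength=str(len(enc)))
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    if nonstandard is None:
        _cv(arr, accession, name)
    else:
        _cv(arr, "MS:1000786", "non-standard data array", nonstandard)
    etree.SubElement(arr, f"{{{_MZML_NS}}}binary").text = enc


def write_spectra(spectra, path) -> None:
    """Write centroided spectra to a (plain, non-indexed) mzML file."""
    E = lambda tag, **kw: etree.Element(f"{{{_MZML_NS}}}{tag}", **kw)  # noqa: E731
    root = E("mzML", version="1.1.0")
    cvlist = etree.SubElement(root, f"{{{_MZML_NS}}}cvList", count="1")
    etree.SubElement(cvlist, f"{{{_MZML_NS}}}cv", id="MS",
                     fullName="PSI-MS ontology",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    run = etree.SubElement(root, f"{{{_MZML_NS}}}run", id="run1")
    spectra = list(spectra)
    slist = etree.SubElement(run, f"{{{_MZML_NS}}}spectrumList", count=str(len(spectra)))
    for i, s in enumerate(spectra):
        spec = etree.SubElement(slist, f"{{{_MZML_NS}}}spectrum", index=str(i),
                                id=s.native_id, defaultArrayLength=str(len(s.mz)))
        _cv(spec, "MS:1000511", "ms level", str(s.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        if s.ms_level >= 2 and s.precursor_mz is not None:
            plist = etree.SubElement(spec, f"{{{_MZML_NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{_MZML_NS}}}precursor")
            silist = etree.SubElement(prec, f"{{{_MZML_NS}}}selectedIonList", count="1")
            si = etree.SubElement(silist, f"{{{_MZML_NS}}}selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)))
            if s.precursor_charge is not None:
                _cv(si, "MS:1000041", "charge state", str(s.precursor_charge))
        n_arrays = 2 + (s.noise is not None)
        alist = etree.SubElement(spec, f"{{{_MZML_NS}}}binaryDataArrayList",
                                 count=str(n_arrays))
        _binary_array(alist, "MS:1000514", "m/z array", s.mz)
        _binary_array(alist, "MS:1000515", "intensity array", s.intensity)
        if s.noise is not None:
            _binary_array(alist, "", "", s.noise, nonstandard="noise array")
    text = etree.tostring(root, xml_declaration=True, encoding="utf-8",
                          pretty_print=True).decode()
    atomic_write_text(path, text)


def _q(tag: str) -> str:
    return f"{{{_MZML_NS}}}{tag}"


def _decode_arrays(spectrum_el):
    arrays = {}
    for arr in spectrum_el.iter(_q("binaryDataArray")):
        names = {cv.get("accession"): cv.get("name") for cv in arr.iter(_q("cvParam"))}
        values = {cv.get("accession"): cv.get("value") for cv in arr.iter(_q("cvParam"))}
        if "MS:1000523" not in names:
            raise ValueError("only 64-bit float arrays are supported")
        if "MS:1000574" in names:
            raise ValueError("compressed binary arrays are not supported")
        key = None
        if "MS:1000514" in names:
            key = "mz"
        elif "MS:1000515" in names:
            key = "intensity"
        elif "MS:1000786" in names:
            key = values.get("MS:1000786") or "non-standard"
        if key is None:
            continue
        binary = arr.findtext(_q("binary")) or ""
        arrays[key] = np.frombuffer(base64.b64decode(binary), dtype="<f8")
    return arrays


def read_spectra(path):
    """Stream centroided scans from an mzML file (bounded memory).

    Profile-mode spectra are rejected; MS2 scans without precursor metadata
    are skipped with a warning.
    """
    n_seen = 0
    for _, el in etree.iterparse(str(path), events=("end",), tag=_q("spectrum")):
        n_seen += 1
        params = {cv.get("accession"): cv.get("value")
                  for cv in el.iterchildren(_q("cvParam"))}
        if "MS:1000128" in params:
            raise ValueError(f"profile-mode spectrum {el.get('id')}: centroid data required")
        ms_level = int(params.get("MS:1000511", "1"))
        prec_mz = prec_z = None
        for si in el.iter(_q("selectedIon")):
            sip = {cv.get("accession"): cv.get("value") for cv in si.iter(_q("cvParam"))}
            if "MS:1000744" in sip:
                prec_mz = float(sip["MS:1000744"])
            if "MS:1000041" in sip:
                prec_z = int(sip["MS:1000041"])
        arrays = _decode_arrays(el)
        index = int(el.get("index", n_seen - 1))
        native_id = el.get("id", f"scan={index + 1}")
        if native_id.startswith("scan="):  # native ids win over file position
            index = int(native_id.split("=", 1)[1]) - 1
        el.clear()
        if ms_level >= 2 and (prec_mz is None or prec_z is None):
            log.warning("scan %s lacks precursor metadata; skipped", native_id)
            continue
        yield Spectrum(
            scan_id=index, ms_level=ms_level,
            mz=arrays.get("mz", np.empty(0)),
            intensity=arrays.get("intensity", np.empty(0)),
            noise=arrays.get("noise array"),
            precursor_mz=prec_mz, precursor_charge=prec_z,
            native_id=native_id,
        )
    if n_seen == 0:
        log.warning("no spectra found in %s", path)


def spectra_by_scan(path) -> dict:
    """All quantifiable (MS2) scans of a file keyed by scan id."""
    return {s.scan_id: s for s in read_spectra(path) if s.ms_level == 2}


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def read_psm_table(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required column(s): {missing}")
    extra_cols = [c for c in df.columns if c not in PSM_REQUIRED_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(PSMRecord(
            scan_id=int(d["scan_id"]), peptide=str(d["peptide"]),
            mods=str(d["mods"]) if not pd.isna(d["mods"]) else "",
            charge=int(d["charge"]), precursor_mz=float(d["precursor_mz"]),
            protein=str(d["protein"]), xcorr=float(d["xcorr"]),
            delta_cn=float(d["delta_cn"]), ppm_dev=float(d["ppm_dev"]),
            extra={c: d[c] for c in extra_cols},
        ))
    return records


def write_psm_table(psms, path) -> None:
    rows = []
    for p in psms:
        row = {c: getattr(p, c) for c in PSM_REQUIRED_COLUMNS}
        row.update(p.extra)
        rows.append(row)
    write_dataframe(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# configuration / logging
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a TOML or YAML configuration file."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level):
    """TMTproC complementary-ion quantification toolkit."""
    setup_logging(log_level)


@main.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="TOML/YAML file overriding simulation parameters.")
@click.option("--out-dir", type=click.Path(), default="sim_out", show_default=True)
@click.option("--n-peptides", type=int, default=None, help="peptides per proteome override")
@click.option("--resolution", type=float, default=None, help="Orbitrap resolution override")
@click.option("--loss-model", type=click.Choice(["charged", "neutral"]), default=None)
def simulate(seed, config_path, out_dir, n_peptides, resolution, loss_model):
    """Write a synthetic interference sample: mzML + PSM table + truth ledger."""
    from . import simgen

    overrides = load_config(config_path) if config_path else {}
    if n_peptides is not None:
        overrides["n_yeast_peptides"] = n_peptides
        overrides["n_human_peptides"] = n_peptides
    if resolution is not None:
        overrides["resolution"] = resolution
    if loss_model is not None:
        overrides["loss_model"] = loss_model
    config = simgen.SimConfig(seed=seed, **overrides)
    sample = simgen.simulate_interference_sample(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra(sample.spectra, out / "sample.mzML")
    write_psm_table(sample.psms, out / "psms.tsv")
    write_dataframe(sample.ledger.to_frame(), out / "truth_ledger.tsv")
    click.echo(f"wrote {len(sample.spectra)} scans to {out}")


@main.command()
@click.option("--mzml", "mzml_path", type=click.Path(exists=True), required=True)
@click.option("--psms", "psm_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), default="quant.tsv", show_default=True)
@click.option("--tol-ppm", type=float, default=10.0, show_default=True)
@click.option("--loss-model", type=click.Choice(["charged", "neutral"]), default="charged",
              show_default=True)
@click.option("--impurities", type=click.Path(exists=True), default=None,
              help="alternative tag impurity TSV")
@click.option("--nonnegative", is_flag=True, help="use full non-negative least squares")
def quantify(mzml_path, psm_path, out_path, tol_ppm, loss_model, impurities, nonnegative):
    """Quantify complement clusters: mzML + PSM table -> peptide x channel TSV."""
    from . import chem, complement, deconv

    table = chem.load_impurity_table(impurities) if impurities else None
    tags = chem.default_tags(table)
    channels = chem.build_channel_model(tags)
    quant = deconv.quantify_run(
        spectra_by_scan(mzml_path), read_psm_table(psm_path), tags, channels,
        loss_model=complement.LossModel(kind=loss_model), tol_ppm=tol_ppm,
        nonnegative=nonnegative,
    )
    write_dataframe(quant, out_path)
    click.echo(f"quantified {len(quant)} PSMs -> {out_path}")


@main.command()
@click.option("--quant", "quant_path", type=click.Path(exists=True), required=True,
              help="peptide x stage TSV (peptide, protein, is_anchor, stage columns)")
@click.option("--out-dir", type=click.Path(), default="timecourse_out", show_default=True)
@click.option("--k", type=int, default=6, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
def timecourse(quant_path, out_dir, k, seed):
    """Normalize, roll up to proteins and cluster a developmental time course."""
    import json

    from . import timecourse as tc

    qm = tc.QuantMatrix.from_frame(pd.read_csv(quant_path, sep="\t"))
    normalized = tc.normalize_to_anchor(qm)
    proteins = tc.rollup_proteins(normalized)
    labels, centroids = tc.hkmeans_cluster(proteins.values.to_numpy(), k=k, seed=seed)
    summary = tc.fold_change_summary(proteins.values.to_numpy())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prot_out = proteins.values.copy()
    prot_out.insert(0, "protein", proteins.values.index)
    prot_out["cluster"] = labels
    write_dataframe(prot_out, out / "protein_clusters.tsv")
    atomic_write_text(out / "summary.json", json.dumps({
        "n_proteins": int(len(proteins.values)),
        "k": int(k),
        "median_log2_first_last": float(np.median(summary.log2_first_last)),
        "fraction_decreasing": summary.fraction_decreasing,
        "fraction_increasing": summary.fraction_increasing,
    }, indent=2) + "\n")
    click.echo(f"clustered {len(proteins.values)} proteins into {k} clusters -> {out}")


if __name__ == "__main__":
    main()
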