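"""Elemental compositions, isotope envelopes and TMTpro tag chemistry.

The TMTpro label (+304.2071 Da, C15H25N3O3 with nine heavy substitutions)
consists of a reporter region (C8N1), a carbonyl linking carbon, and a
balancer region (C6N2, plus the carbonyl) that stays attached to the peptide
when the reporter is cleaved.  The eighteen commercial tags place their
7x13C+2x15N (or 8x13C+1x15N) substitutions differently between the two
regions.  Because a 13C-for-15N swap shifts the mass by only 6.32 mDa, tags
whose balancers differ by such swaps produce complementary ions that are
unresolvable at practical Orbitrap transients; grouping the eighteen
balancer masses at a 0.02 Da threshold collapses them onto a 1 Da-spaced
grid of nine distinguishable complement channels.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

# ---------------------------------------------------------------------------
# constants
# ---------------------------------------------------------------------------

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990
CO_MASS = _pmass.calculate_mass(formula="CO")          # 27.9949146
CO13_MASS = CO_MASS + (13.0033548378 - 12.0)           # carbonyl with 13C

#: printed modification masses
TMTPRO_MASS = 304.2071
NEM_MASS = 125.047679
MET_OX_MASS = 15.99492

#: reporter ion of the lightest tag (C8H16N+)
REPORTER_BASE_MZ = 126.127726

_C13 = 13.0033548378 - 12.0
_N15 = 15.0001088982 - 14.0030740052

# elements whose natural isotope variability is modelled (nominal offsets)
_ISOTOPE_PATTERNS = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0001],
}

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# compositions
# ---------------------------------------------------------------------------

class ElementalComposition(_pmass.Composition):
    """Element/isotope counts (``C``, ``H``, ... plus fixed ``C[13]``/``N[15]``).

    Thin subclass of :class:`pyteomics.mass.Composition`; addition and
    subtraction are element-wise and mass is a pure function of the counts.
    """

    def validate(self) -> "ElementalComposition":
        for k, v in self.items():
            if v < 0:
                raise ValueError(f"negative count for {k}: {v}")
        return self


def composition(formula: str = "", **counts: int) -> ElementalComposition:
    if formula:
        return ElementalComposition(formula=formula)
    return ElementalComposition(**counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da (heavy substitutions use their own isotope mass)."""
    return float(_pmass.calculate_mass(composition=comp))


# generic TMTpro label composition used for peptide-level mass/envelope work;
# individual tags redistribute the same heavy atoms between their regions.
TMTPRO_TAG_COMPOSITION = composition(
    **{"C": 8, "C[13]": 7, "H": 25, "N": 1, "N[15]": 2, "O": 3}
)
NEM_COMPOSITION = composition(formula="C6H7NO2")
MET_OX_COMPOSITION = composition(formula="O")


def composition_of_peptide(
    sequence: str,
    n_variable_ox: int = 0,
    tag: ElementalComposition | None = None,
    nem_on_cys: bool = True,
) -> ElementalComposition:
    """Elemental composition of a fully labeled tryptic peptide.

    One TMTpro tag per N terminus and per lysine, NEM on every cysteine,
    and up to two variable methionine oxidations.
    """
    bad = set(sequence) - _VALID_RESIDUES
    if bad or not sequence:
        raise ValueError(f"unknown residue letter(s): {sorted(bad) or sequence!r}")
    if n_variable_ox > 2:
        raise ValueError("at most 2 variable modifications are allowed")
    if n_variable_ox > sequence.count("M"):
        raise ValueError("more oxidations requested than methionines present")
    if tag is None:
        tag = TMTPRO_TAG_COMPOSITION
    comp = ElementalComposition()
    for aa in sequence:
        comp += _pmass.std_aa_comp[aa]
    comp += composition(formula="H2O")
    n_tags = 1 + sequence.count("K")
    for _ in range(n_tags):
        comp += tag
    if nem_on_cys:
        for _ in range(sequence.count("C")):
            comp += NEM_COMPOSITION
    for _ in range(n_variable_ox):
        comp += MET_OX_COMPOSITION
    return ElementalComposition(comp).validate()


def label_count(sequence: str) -> int:
    """Number of TMTpro labels on a peptide (N terminus + lysines)."""
    return 1 + sequence.count("K")


# ---------------------------------------------------------------------------
# isotope envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated (unit-mass binned) isotope distribution.

    ``fractions[j]`` is the probability of a +j nominal-mass isotopologue;
    offset 0 is the monoisotopic peak.  Retained fractions sum to <= 1.
    """

    fractions: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or len(f) < 1:
            raise ValueError("fractions must be a non-empty 1-D array")
        if (f < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        object.__setattr__(self, "fractions", np.clip(f, 0.0, None))

    def __len__(self) -> int:
        return len(self.fractions)

    @property
    def retained_mass(self) -> float:
        return float(self.fractions.sum())

    def renormalized(self) -> "IsotopeDistribution":
        return IsotopeDistribution(self.fractions / self.fractions.sum())


def _element_pattern_power(pattern: np.ndarray, n: int, n_offsets: int) -> np.ndarray:
    """Distribution of the summed nominal-mass offset of ``n`` atoms."""
    result = np.zeros(n_offsets)
    result[0] = 1.0
    base = np.asarray(pattern, dtype=float)[:n_offsets]
    while n:  # exponentiation by squaring on truncated polynomials
        if n & 1:
            result = np.convolve(result, base)[:n_offsets]
        base = np.convolve(base, base)[:n_offsets]
        n >>= 1
    return result


def isotope_envelope(comp: ElementalComposition, n_offsets: int = 6) -> IsotopeDistribution:
    """Aggregated isotope envelope of a composition, truncated at ``n_offsets``.

    Convolves per-element multinomial offset distributions; fixed heavy
    substitutions (``C[13]``, ``N[15]``) contribute no further variability.
    """
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    env = np.zeros(n_offsets)
    env[0] = 1.0
    for elem, n in comp.items():
        if elem in ("C[13]", "N[15]") or n == 0:
            continue
        if elem not in _ISOTOPE_PATTERNS:
            raise ValueError(f"no isotope pattern for element {elem!r}")
        env = np.convolve(env, _element_pattern_power(_ISOTOPE_PATTERNS[elem], n, n_offsets))[
            :n_offsets
        ]
    return IsotopeDistribution(env)


def envelope_for_quantification(
    comp: ElementalComposition, min_retained: float = 0.999, max_offsets: int = 12
) -> IsotopeDistribution:
    """Envelope truncated at the first length retaining ``min_retained`` mass.

    The retained envelope is renormalized to unit mass so that the design
    matrix conserves each channel's signal; if even ``max_offsets`` offsets
    do not retain enough mass the longest envelope is used.
    """
    for n in range(3, max_offsets + 1):
        env = isotope_envelope(comp, n)
        if env.retained_mass >= min_retained:
            return env.renormalized()
    return isotope_envelope(comp, max_offsets).renormalized()


# ---------------------------------------------------------------------------
# TMTpro tags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagSpec:
    """One TMTpro label: region compositions and complement-region impurities."""

    name: str
    reporter_composition: ElementalComposition   # reporter ion (cation, incl. charge H)
    balancer_composition: ElementalComposition   # carbonyl + complement region
    complement_impurities: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    )  # fractions at offsets -2..+2
    reporter_impurities: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    )
    carbonyl_13c: bool = False  # whether the departing carbonyl C is 13C

    def __post_init__(self):
        for attr in ("complement_impurities", "reporter_impurities"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (5,) or (v < 0).any():
                raise ValueError(f"{attr} must be 5 non-negative fractions (-2..+2)")
            if abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{attr} must sum to 1")
            object.__setattr__(self, attr, v)

    @property
    def reporter_ion_mz(self) -> float:
        return monoisotopic_mass(self.reporter_composition) - ELECTRON_MASS

    @property
    def complement_composition(self) -> ElementalComposition:
        comp = ElementalComposition(self.balancer_composition)
        if self.carbonyl_13c:
            comp["C[13]"] -= 1
        else:
            comp["C"] -= 1
        comp["O"] -= 1
        return ElementalComposition({k: v for k, v in comp.items() if v}).validate()

    @property
    def total_mass(self) -> float:
        """Mass of the intact label as a peptide modification."""
        # reporter ion carries one H abstracted from elsewhere plus the charge
        return (
            monoisotopic_mass(self.reporter_composition)
            - _pmass.nist_mass["H"][0][0]
            + monoisotopic_mass(self.balancer_composition)
        )

    @property
    def complement_mass_offset(self) -> float:
        """Exact complement-region mass above the all-light complement (Da)."""
        comp = self.complement_composition
        return comp.get("C[13]", 0) * _C13 + comp.get("N[15]", 0) * _N15

    @property
    def loss_mass_charged(self) -> float:
        """Mass departing as reporter cation + neutral CO (charged-reporter loss)."""
        co = CO13_MASS if self.carbonyl_13c else CO_MASS
        return self.reporter_ion_mz + co


def _build_tag(name: str, rep13: int, rep15: int, co13: int, comp13: int, comp15: int,
               comp_imp: np.ndarray, rep_imp: np.ndarray) -> TagSpec:
    rep = composition(**{"C": 8 - rep13, "H": 16, "N": 1 - rep15})
    if rep13:
        rep += composition(**{"C[13]": rep13})
    if rep15:
        rep += composition(**{"N[15]": rep15})
    # balancer = carbonyl CO + complement region C6H10N2O2, heavies applied
    bal = composition(**{"C": (1 - co13) + (6 - comp13), "H": 10,
                         "N": 2 - comp15, "O": 3})
    nheavy_c = co13 + comp13
    if nheavy_c:
        bal += composition(**{"C[13]": nheavy_c})
    if comp15:
        bal += composition(**{"N[15]": comp15})
    return TagSpec(name, ElementalComposition(rep).validate(),
                   ElementalComposition(bal).validate(), comp_imp, rep_imp,
                   carbonyl_13c=bool(co13))


# heavy-substitution layout of the 18 tags:
# (reporter 13C, reporter 15N, carbonyl 13C, complement 13C, complement 15N)
_TAG_LAYOUT: dict[str, tuple[int, int, int, int, int]] = {
    "126":  (0, 0, 1, 6, 2),
    "127N": (0, 1, 1, 6, 1),
    "127C": (1, 0, 1, 5, 2),
    "128N": (1, 1, 1, 5, 1),
    "128C": (2, 0, 1, 4, 2),
    "129N": (2, 1, 1, 4, 1),
    "129C": (3, 0, 1, 3, 2),
    "130N": (3, 1, 1, 3, 1),
    "130C": (4, 0, 1, 2, 2),
    "131N": (4, 1, 1, 2, 1),
    "131C": (5, 0, 1, 1, 2),
    "132N": (5, 1, 1, 1, 1),
    "132C": (6, 0, 1, 0, 2),
    "133N": (6, 1, 1, 1, 0),
    "133C": (7, 0, 1, 0, 1),
    "134N": (7, 1, 1, 0, 0),
    "134C": (8, 0, 0, 0, 1),
    "135N": (8, 1, 0, 0, 0),
}

TAG_NAMES = list(_TAG_LAYOUT)


def load_impurity_table(path=None) -> pd.DataFrame:
    """Load a tag impurity table (columns tag_name, region, offset, fraction)."""
    if path is None:
        text = (
            importlib.resources.files("tmtproc")
            .joinpath("data/impurities_default.tsv")
            .read_text()
        )
        src = io.StringIO(text)
    else:
        src = path
    df = pd.read_csv(src, sep="\t", comment="#")
    required = {"tag_name", "region", "offset", "fraction"}
    if missing := required - set(df.columns):
        raise ValueError(f"impurity table missing column(s): {sorted(missing)}")
    return df


def _impurity_vector(df: pd.DataFrame, tag: str, region: str) -> np.ndarray:
    sub = df[(df.tag_name == tag) & (df.region == region)]
    vec = np.zeros(5)
    for _, row in sub.iterrows():
        off = int(row.offset)
        if not -2 <= off <= 2:
            raise ValueError(f"impurity offset out of range: {off}")
        vec[off + 2] = row.fraction
    if vec.sum() == 0:
        vec[2] = 1.0
    return vec / vec.sum()


def default_tags(impurity_table: pd.DataFrame | None = None) -> list[TagSpec]:
    """The 18 TMTpro tags with impurity vectors from a table (default bundled)."""
    if impurity_table is None:
        impurity_table = load_impurity_table()
    tags = []
    for name, layout in _TAG_LAYOUT.items():
        tags.append(
            _build_tag(
                name, *layout,
                comp_imp=_impurity_vector(impurity_table, name, "complement"),
                rep_imp=_impurity_vector(impurity_table, name, "reporter"),
            )
        )
    return tags


def identity_tags() -> list[TagSpec]:
    """The 18 tags with impurity-free (identity) impurity vectors."""
    ident = pd.DataFrame(
        [(n, r, 0, 1.0) for n in TAG_NAMES for r in ("reporter", "complement")],
        columns=["tag_name", "region", "offset", "fraction"],
    )
    return default_tags(ident)


# ---------------------------------------------------------------------------
# channel model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    index: int
    name: str
    nominal_offset: int
    exact_offset: float
    members: tuple[str, ...]


@dataclass(frozen=True)
class ChannelModel:
    """Complement channels obtained by merging unresolvable tag balancers."""

    channels: tuple[Channel, ...]
    tag_to_channel: dict

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def nominal_offsets(self) -> np.ndarray:
        return np.array([c.nominal_offset for c in self.channels])

    @property
    def max_offset(self) -> int:
        return int(self.nominal_offsets.max())

    def channel_of(self, tag_name: str) -> Channel:
        return self.channels[self.tag_to_channel[tag_name]]


def build_channel_model(tags: list[TagSpec], resolvable_dm: float = 0.02) -> ChannelModel:
    """Merge tags whose complement exact masses differ by less than ``resolvable_dm``.

    Channels are ordered by increasing complement mass and labeled c1..cN.
    A threshold so coarse that tags of distinct nominal complement mass would
    merge is rejected, since it would break the 1 Da cluster-grid assumption.
    """
    if not tags:
        raise ValueError("tags must be non-empty")
    if resolvable_dm <= 0:
        raise ValueError("resolvable_dm must be > 0")
    order = sorted(tags, key=lambda t: (t.complement_mass_offset, t.name))
    groups: list[list[TagSpec]] = [[order[0]]]
    for tag in order[1:]:
        if tag.complement_mass_offset - groups[-1][0].complement_mass_offset < resolvable_dm:
            groups[-1].append(tag)
        else:
            groups.append([tag])
    channels = []
    tag_to_channel = {}
    for i, grp in enumerate(groups):
        nominal = {round(t.complement_mass_offset) for t in grp}
        if len(nominal) > 1:
            raise ValueError(
                "resolvable_dm merges channels with distinct nominal mass: "
                f"{sorted(t.name for t in grp)}"
            )
        channels.append(
            Channel(
                index=i,
                name=f"c{i + 1}",
                nominal_offset=nominal.pop(),
                exact_offset=float(np.mean([t.complement_mass_offset for t in grp])),
                members=tuple(t.name for t in grp),
            )
        )
        for t in grp:
            tag_to_channel[t.name] = i
    return ChannelModel(tuple(channels), tag_to_channel)


def channel_impurity_vector(model: ChannelModel, tags: list[TagSpec], index: int) -> np.ndarray:
    """Complement impurity vector of a channel: mean over its member tags."""
    by_name = {t.name: t for t in tags}
    members = model.channels[index].members
    return np.mean([by_name[m].complement_impurities for m in members], axis=0)


def channel_loss_mass(model: ChannelModel, tags: list[TagSpec], index: int = 0) -> float:
    """Mass lost (reporter cation + CO) when a member tag of a channel fragments."""
    by_name = {t.name: t for t in tags}
    losses = [by_name[name].loss_mass_charged for name in model.channels[index].members]
    return float(np.mean(losses))
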