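"""(Poly)phosphate anion database and exact-mass arithmetic.

Condensed phosphates — linear chains H(n+2)PnO(3n+1) and cyclic (meta)
rings HnPnO(3n) — are detected in negative-mode HRMS as the singly
deprotonated anions [M−H]⁻.  This module
holds the monoisotopic mass constants, the elemental-composition type, the
curated anion database (name, neutral formula, expected retention time,
precursor and diagnostic fragment m/z), and the stoichiometric conversion to
P₂O₅ equivalents used by regulation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "P2O5_MASS",
    "LONG_CHAIN_NAMES",
    "SHORT_CHAIN_ADDITIVES",
    "ElementalComposition",
    "PhosphateSpecies",
    "monoisotopic_mass",
    "mz_deprotonated",
    "p2o5_equivalent",
    "species_mass_from_p2o5",
    "default_database",
    "database_to_table",
    "database_from_table",
]

# Monoisotopic masses in Da (CODATA/AME-derived standard values).  Isotope
# labels are first-class symbols so the ¹⁵N internal standard needs no
# special-casing downstream.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "N": 14.0030740052,
    "15N": 15.0001088984,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Mass removed when forming the [M−H]⁻ anion (proton, not H atom).
PROTON_MASS: float = 1.00727646688

#: Monoisotopic mass of P₂O₅ (phosphorus pentoxide), the reporting unit of
#: the spectrophotometric reference method and of EU maximum levels.
P2O5_MASS: float = 2 * MONOISOTOPIC_MASS["P"] + 5 * MONOISOTOPIC_MASS["O"]

#: The six species whose joint HRMS detection constitutes the long-chain
#: "confirmation fingerprint" for polyphosphate (E452) treatment.
LONG_CHAIN_NAMES: tuple[str, ...] = (
    "tetraphosphate",
    "tetrametaphosphate",
    "pentaphosphate",
    "pentametaphosphate",
    "hexaphosphate",
    "hexametaphosphate",
)

#: Short-chain species quantifiable against commercial standards and used
#: directly as additives (E450 pyro-, E451 tri-, trimeta-).
SHORT_CHAIN_ADDITIVES: tuple[str, ...] = (
    "pyrophosphate",
    "triphosphate",
    "trimetaphosphate",
)

_FORMULA_TOKEN = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


class ElementalComposition:
    """A neutral-molecule elemental composition.

    Symbols are element symbols or bracketed isotope labels (``[15N]``);
    internally isotopes are stored bare (``15N``).  All counts must be
    positive integers and every symbol must have a known monoisotopic mass.
    """

    __slots__ = ("entries",)

    def __init__(self, entries: Mapping[str, int]):
        clean: dict[str, int] = {}
        for sym, n in entries.items():
            sym = sym.strip("[]")
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element or isotope symbol: {sym!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
                raise ValueError(f"count for {sym} must be a positive integer, got {n!r}")
            clean[sym] = clean.get(sym, 0) + n
        self.entries = clean

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``H4P2O7`` or ``H[15N]O3``."""
        formula = formula.strip()
        if not formula:
            raise ValueError("empty formula")
        pos = 0
        entries: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            sym = m.group(1).strip("[]")
            n = int(m.group(2) or 1)
            entries[sym] = entries.get(sym, 0) + n
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(entries)

    def formula(self) -> str:
        """Render back to a formula string, isotopes bracketed."""
        parts = []
        for sym, n in self.entries.items():
            tok = f"[{sym}]" if sym[0].isdigit() else sym
            parts.append(f"{tok}{n if n > 1 else ''}")
        return "".join(parts)

    def count(self, symbol: str) -> int:
        return self.entries.get(symbol, 0)

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalComposition) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"ElementalComposition({self.entries!r})"


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic mass of a neutral composition, in Da."""
    if not composition.entries:
        raise ValueError("empty composition has no mass")
    return sum(MONOISOTOPIC_MASS[s] * n for s, n in composition.entries.items())


def mz_deprotonated(composition: ElementalComposition) -> float:
    """m/z (Th) of the singly deprotonated anion [M−H]⁻.

    Exact value; round only for display (the database prints 4 decimals).
    """
    if composition.count("H") < 1:
        raise ValueError("composition has no hydrogen to deprotonate")
    return monoisotopic_mass(composition) - PROTON_MASS


@dataclass(frozen=True)
class PhosphateSpecies:
    """One anion of the target database.

    ``precursor_mz`` and ``fragment_mzs`` are the curated (printed) values;
    the computed [M−H]⁻ mass is available as :meth:`computed_precursor_mz`
    and is authoritative for matching.  ``quantifiable`` is true only where
    a commercial reference standard exists (ortho-, pyro-, tri-, trimeta-).
    """

    name: str
    composition: ElementalComposition
    expected_rt: float  # minutes
    precursor_mz: float  # Th, [M−H]⁻ as printed
    fragment_mzs: tuple[float, ...]  # Th, DIA confirmation ions as printed
    chain_class: str  # ortho | short_linear | short_cyclic | long_linear | long_cyclic | internal_standard
    quantifiable: bool = False
    unverified_fragments: tuple[float, ...] = field(default_factory=tuple)

    _CLASSES = frozenset(
        {"ortho", "short_linear", "short_cyclic", "long_linear", "long_cyclic", "internal_standard"}
    )

    def __post_init__(self):
        if self.chain_class not in self._CLASSES:
            raise ValueError(f"unknown chain class {self.chain_class!r}")
        computed = mz_deprotonated(self.composition)
        if abs(computed - self.precursor_mz) > 0.001:
            raise ValueError(
                f"{self.name}: precursor {self.precursor_mz} differs from computed "
                f"{computed:.4f} by more than 0.001 Th"
            )
        if self.chain_class.startswith("long") and self.n_phosphorus < 4:
            raise ValueError(f"{self.name}: long-chain species must have ≥ 4 P")

    @property
    def n_phosphorus(self) -> int:
        return self.composition.count("P")

    @property
    def is_long_chain(self) -> bool:
        return self.chain_class in ("long_linear", "long_cyclic")

    def computed_precursor_mz(self) -> float:
        return mz_deprotonated(self.composition)


def p2o5_equivalent(amount_ug: float, species: PhosphateSpecies) -> float:
    """Convert µg of a species (free-acid basis) to µg P₂O₅ equivalents.

    Each phosphorus atom contributes half a P₂O₅ unit:
    ``amount × n_P × M(P₂O₅)/2 / M(species)``.
    """
    n_p = species.n_phosphorus
    if n_p < 1:
        raise ValueError(f"{species.name} contains no phosphorus; no P₂O₅ equivalent")
    return amount_ug * n_p * (P2O5_MASS / 2.0) / monoisotopic_mass(species.composition)


def species_mass_from_p2o5(amount_p2o5_ug: float, species: PhosphateSpecies) -> float:
    """Inverse of :func:`p2o5_equivalent`: µg P₂O₅ → µg of species."""
    n_p = species.n_phosphorus
    if n_p < 1:
        raise ValueError(f"{species.name} contains no phosphorus; no P₂O₅ equivalent")
    return amount_p2o5_ug * monoisotopic_mass(species.composition) / (n_p * P2O5_MASS / 2.0)


# name, formula, RT (min), printed precursor, printed fragments, chain class,
# quantifiable, fragments whose elemental assignment could not be verified
# against any plausible composition (retained as printed, flagged).
_DB_ROWS = [
    ("orthophosphate", "H3PO4", 5.9, 96.9696, (78.9590,), "ortho", True, ()),
    ("pyrophosphate", "H4P2O7", 9.0, 176.9359, (78.9561, 96.9697), "short_linear", True, (78.9561,)),
    ("triphosphate", "H5P3O10", 11.8, 256.9023, (96.9697, 176.9685), "short_linear", True, (176.9685,)),
    ("trimetaphosphate", "H3P3O9", 13.5, 238.8917, (118.9422, 158.9253), "short_cyclic", True, (118.9422, 158.9253)),
    ("tetraphosphate", "H6P4O13", 15.6, 336.8686, (78.9591, 256.9025), "long_linear", False, ()),
    ("tetrametaphosphate", "H4P4O12", 16.8, 318.8580, (158.9254, 256.9025), "long_cyclic", False, (158.9254,)),
    ("pentaphosphate", "H7P5O16", 17.9, 416.8349, (256.9025, 336.8689), "long_linear", False, ()),
    ("pentametaphosphate", "H5P5O15", 18.9, 398.8244, (198.9086, 318.8582), "long_cyclic", False, (198.9086,)),
    ("hexametaphosphate", "H6P6O18", 18.7, 478.7907, (238.8919, 318.8582), "long_cyclic", False, ()),
    ("hexaphosphate", "H8P6O19", 21.7, 496.8013, (247.8970, 336.8689), "long_linear", False, (247.8970,)),
    ("internal standard", "H[15N]O3", 7.0, 62.9854, (), "internal_standard", False, ()),
]


def default_database() -> list[PhosphateSpecies]:
    """The curated 11-anion target database (ten phosphates + ¹⁵N-nitrate IS)."""
    return [
        PhosphateSpecies(
            name=name,
            composition=ElementalComposition.parse(formula),
            expected_rt=rt,
            precursor_mz=prec,
            fragment_mzs=frags,
            chain_class=cls,
            quantifiable=quant,
            unverified_fragments=unver,
        )
        for name, formula, rt, prec, frags, cls, quant, unver in _DB_ROWS
    ]


def database_to_table(species: Iterable[PhosphateSpecies]) -> pd.DataFrame:
    """Serialise a species list to a flat table (fragments ';'-joined)."""
    rows = []
    for sp in species:
        rows.append(
            {
                "name": sp.name,
                "formula": sp.composition.formula(),
                "rt_min": sp.expected_rt,
                "precursor_mz": sp.precursor_mz,
                "fragment_mzs": ";".join(f"{f:.4f}" for f in sp.fragment_mzs),
                "chain_class": sp.chain_class,
                "quantifiable": sp.quantifiable,
            }
        )
    return pd.DataFrame(rows)


def database_from_table(table: pd.DataFrame) -> list[PhosphateSpecies]:
    """Inverse of :func:`database_to_table`."""
    out = []
    for _, r in table.iterrows():
        frags = tuple(float(x) for x in str(r["fragment_mzs"]).split(";") if x.strip())
        out.append(
            PhosphateSpecies(
                name=str(r["name"]),
                composition=ElementalComposition.parse(str(r["formula"])),
                expected_rt=float(r["rt_min"]),
                precursor_mz=float(r["precursor_mz"]),
                fragment_mzs=frags,
                chain_class=str(r["chain_class"]),
                quantifiable=bool(r["quantifiable"]),
            )
        )
    return out


def get_species(name: str, database: Iterable[PhosphateSpecies] | None = None) -> PhosphateSpecies:
    """Look a species up by exact name or unique prefix (e.g. ``'pyro'``)."""
    db = list(database) if database is not None else default_database()
    for sp in db:
        if sp.name == name:
            return sp
    hits = [sp for sp in db if sp.name.startswith(name)]
    if len(hits) == 1:
        return hits[0]
    raise KeyError(f"species {name!r} not found" + (" (ambiguous)" if hits else ""))
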