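"""Elemental-formula arithmetic, adduct m/z computation and biotransformation
enumeration.

Exact masses are the backbone of xenobiotic screening: a parent compound and a
set of formula-level reaction deltas (oxidation +O, demethylation -CH2, ...)
define a list of theoretical products whose ion m/z can be matched against an
observed feature table within a ppm tolerance.

All masses are monoisotopic (most abundant isotope per element, CODATA/IUPAC
values).  Ion m/z always includes the electron-mass correction: the 3-decimal
agreement with published adduct tables holds either way, but 4-decimal
fragment work does not.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Monoisotopic atomic masses in Da (CODATA/IUPAC 2021).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645...

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a formula contains an element without a tabulated mass."""


class UnsupportedAdductError(ValueError):
    """Raised when an adduct label is not in the ion table."""


@dataclass(frozen=True)
class ElementalFormula:
    """A neutral molecular formula as an element -> count map.

    Counts are non-negative integers; a valid formula has at least one atom.
    Instances are immutable and hashable, so they can key dictionaries during
    biotransformation deduplication.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | str):
        if isinstance(counts, str):
            counts = _parse_formula(counts)
        clean = {}
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise UnknownElementError(
                    f"unknown element symbol {el!r}; known: "
                    f"{sorted(MONOISOTOPIC_MASS)}"
                )
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", tuple(sorted(clean.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        d = self.as_dict()
        parts = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            n = d.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __add__(self, other: "ElementalFormula | Mapping[str, int]"):
        return self.shift(add=_as_counts(other))

    def shift(
        self,
        add: Mapping[str, int] | None = None,
        remove: Mapping[str, int] | None = None,
    ) -> "ElementalFormula | None":
        """Apply a formula delta; returns None if any count would go negative."""
        d = self.as_dict()
        for el, n in (add or {}).items():
            d[el] = d.get(el, 0) + n
        for el, n in (remove or {}).items():
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                return None
        if not any(v > 0 for v in d.values()):
            return None
        return ElementalFormula(d)


def _parse_formula(text: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        el = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def _as_counts(x) -> dict[str, int]:
    if isinstance(x, ElementalFormula):
        return x.as_dict()
    return dict(x)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass of a neutral formula in Da."""
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts)


@dataclass(frozen=True)
class IonSpecies:
    """An adduct ion: formula delta relative to the neutral molecule M plus a
    unit charge.  m/z is computed with the electron-mass correction."""

    label: str
    add: tuple[tuple[str, int], ...]
    remove: tuple[tuple[str, int], ...]
    charge: int  # +1 or -1

    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.add) - sum(
            MONOISOTOPIC_MASS[el] * n for el, n in self.remove
        )


def _ion(label, add, remove, charge) -> IonSpecies:
    return IonSpecies(
        label=label,
        add=tuple(sorted(_parse_formula(add).items())) if add else (),
        remove=tuple(sorted(_parse_formula(remove).items())) if remove else (),
        charge=charge,
    )


#: The ten ion species considered during peak picking, as data not code.
ADDUCTS: dict[str, IonSpecies] = {
    ion.label: ion
    for ion in [
        _ion("[M+H]+", "H", "", +1),
        _ion("[M+NH4]+", "NH4", "", +1),
        _ion("[M+Na]+", "Na", "", +1),
        _ion("[M+K]+", "K", "", +1),
        _ion("[M+MeCN+H]+", "C2H4N", "", +1),
        _ion("[M+Cl]-", "Cl", "", -1),
        _ion("[M+MeOH+H]+", "CH5O", "", +1),
        _ion("[M+H-H2O]+", "", "HO", +1),
        _ion("[M+H-NH3]+", "", "NH2", +1),
        _ion("[M-H]-", "", "H", -1),
    ]
}

_LABEL_ALIASES = {
    "[M−H]−": "[M-H]-",
    "[M+Cl]−": "[M+Cl]-",
    "[M+H]⁺": "[M+H]+",
}


def get_ion(ion: str | IonSpecies) -> IonSpecies:
    if isinstance(ion, IonSpecies):
        return ion
    label = _LABEL_ALIASES.get(ion, ion)
    try:
        return ADDUCTS[label]
    except KeyError:
        raise UnsupportedAdductError(
            f"unsupported adduct {ion!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def ion_mz(formula: ElementalFormula | str, ion: str | IonSpecies) -> float:
    """m/z of an adduct ion of the neutral molecule with the given formula.

    m/z = (M + adduct delta − charge × m_e) / |charge|.
    """
    spec = get_ion(ion)
    m = monoisotopic_mass(formula)
    return (m + spec.delta_mass() - spec.charge * ELECTRON_MASS) / abs(spec.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation, 1e6 × (obs − theo) / theo."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class Transformation:
    """A formula-level biotransformation delta (atoms added / removed)."""

    name: str
    add: tuple[tuple[str, int], ...] = ()
    remove: tuple[tuple[str, int], ...] = ()

    @classmethod
    def make(cls, name: str, add: str = "", remove: str = "") -> "Transformation":
        return cls(
            name=name,
            add=tuple(sorted(_parse_formula(add).items())) if add else (),
            remove=tuple(sorted(_parse_formula(remove).items())) if remove else (),
        )

    def apply(self, formula: ElementalFormula) -> ElementalFormula | None:
        return formula.shift(add=dict(self.add), remove=dict(self.remove))

    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.add) - sum(
            MONOISOTOPIC_MASS[el] * n for el, n in self.remove
        )


#: Default reaction classes for xenobiotic screening.  Deamination of the
#: pyrrolidine ring to keto/hydroxy acids is represented by two composite
#: deltas (-NH+O and -N+H+O) since formula algebra cannot open rings.
DEFAULT_TRANSFORMATIONS: list[Transformation] = [
    Transformation.make("demethylation", remove="CH2"),
    Transformation.make("desaturation", remove="H2"),
    Transformation.make("oxidation", add="O"),
    Transformation.make("di-oxidation", add="O2"),
    Transformation.make("reduction", add="H2"),
    Transformation.make("hydration", add="H2O"),
    Transformation.make("deamination to keto acid", add="O", remove="NH"),
    Transformation.make("deamination to hydroxy acid", add="HO", remove="N"),
    Transformation.make("glycine conjugation", add="C2H3NO"),
    Transformation.make("acetylation", add="C2H2O"),
]


@dataclass(frozen=True)
class BiotransformationCandidate:
    """A theoretical product: parent, ordered reaction chain, product formula,
    and the expected m/z for every configured ion species."""

    parent: ElementalFormula
    chain: tuple[str, ...]
    product: ElementalFormula
    expected_mz: tuple[tuple[str, float], ...]
    depth: int

    def mz(self, ion_label: str) -> float:
        return dict(self.expected_mz)[ion_label]


def enumerate_biotransformations(
    parent: ElementalFormula | str,
    transformations: Sequence[Transformation] = tuple(DEFAULT_TRANSFORMATIONS),
    max_depth: int = 2,
    ions: Iterable[str | IonSpecies] = ("[M+H]+",),
) -> list[BiotransformationCandidate]:
    """All distinct product formulas reachable by <= max_depth reactions.

    Products are deduplicated by formula, keeping the shortest chain found
    first (breadth-first).  Positional isomers share a formula and are
    distinguished downstream by retention time, never here.  Deltas that would
    drive an atom count negative are skipped and logged at debug level.
    The depth-0 parent is included as a candidate.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if isinstance(parent, str):
        parent = ElementalFormula(parent)
    ion_specs = [get_ion(i) for i in ions]

    def expected(f: ElementalFormula):
        return tuple((s.label, ion_mz(f, s)) for s in ion_specs)

    seen: dict[ElementalFormula, BiotransformationCandidate] = {}
    seen[parent] = BiotransformationCandidate(parent, (), parent, expected(parent), 0)
    frontier = [(parent, ())]
    for depth in range(1, max_depth + 1):
        nxt = []
        for formula, chain in frontier:
            for t in transformations:
                prod = t.apply(formula)
                if prod is None:
                    log.debug(
                        "skip %s on %s: negative atom count", t.name, formula
                    )
                    continue
                if prod in seen:
                    continue
                cand = BiotransformationCandidate(
                    parent, chain + (t.name,), prod, expected(prod), depth
                )
                seen[prod] = cand
                nxt.append((prod, chain + (t.name,)))
        frontier = nxt
    return list(seen.values())


@dataclass(frozen=True)
class ExpectedMatch:
    """A (candidate, ion, feature) pair within the ppm tolerance."""

    candidate: BiotransformationCandidate
    ion_label: str
    feature_id: str
    observed_mz: float
    ppm: float


def match_expected(
    candidates: Sequence[BiotransformationCandidate],
    feature_mz: Mapping[str, float],
    tol_ppm: float = 5.0,
) -> list[ExpectedMatch]:
    """Match theoretical product m/z against observed feature m/z.

    ``feature_mz`` maps feature id -> observed m/z (use
    ``FeatureTable.feature_meta["mz"]``).  One candidate may match several
    features (isomers); all pairs within tolerance are returned.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out: list[ExpectedMatch] = []
    for cand in candidates:
        for label, theo in cand.expected_mz:
            for fid, obs in feature_mz.items():
                err = ppm_error(obs, theo)
                if abs(err) <= tol_ppm:
                    out.append(ExpectedMatch(cand, label, str(fid), obs, err))
    return out


def candidates_to_records(
    candidates: Sequence[BiotransformationCandidate],
) -> list[dict]:
    """Flatten candidates for CSV export (one row per candidate x ion)."""
    rows = []
    for c in candidates:
        for label, mz in c.expected_mz:
            rows.append(
                {
                    "parent": str(c.parent),
                    "chain": " > ".join(c.chain) if c.chain else "(parent)",
                    "product_formula": str(c.product),
                    "ion": label,
                    "expected_mz": mz,
                    "depth": c.depth,
                }
            )
    return rows
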