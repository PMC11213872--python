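"""Library matching and MSI-style identification-confidence levels.

Evidence types accumulate independently per candidate: accurate m/z (ppm
tolerance against the entry's ion m/z), retention time (absolute tolerance in
minutes) and MS2 spectral similarity (modified cosine >= cutoff, 85 by
default).  Levels follow the Metabolomics Standards Initiative convention:

* level 1 — matched to an authentic in-house standard on >= 2 independent
  orthogonal properties (m/z + RT, or m/z + MS2);
* level 2 — putative: MS2 match against a (public) spectral library only;
* level 3 — class-level: an externally supplied class label only;
* level 4 — unknown.

An isotope-pattern check (M+1/M ratio vs the theoretical carbon count) counts
as supporting, not orthogonal, evidence.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import ElementalFormula, ion_mz, ppm_error
from .msms import Ms2Spectrum, spectral_similarity

log = logging.getLogger(__name__)

#: natural abundance of 13C relative to 12C
_C13_ABUNDANCE = 0.0107


@dataclass
class LibraryEntry:
    """One compound in a spectral/standard library."""

    name: str
    formula: ElementalFormula
    ion: str = "[M+H]+"
    rt: float | None = None
    spectrum: Ms2Spectrum | None = None
    source: str = "in_house"  # "in_house" (authentic standard) or "public"
    class_label: str | None = None

    def __post_init__(self):
        if isinstance(self.formula, str):
            self.formula = ElementalFormula(self.formula)
        if self.rt is not None and self.rt < 0:
            raise ValueError(f"negative retention time for {self.name}")

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, self.ion)


@dataclass
class Annotation:
    """A feature's match against a library entry, with evidence and level."""

    feature_id: str
    entry: LibraryEntry | None
    evidence: frozenset[str] = frozenset()
    similarity: float | None = None
    level: int = 4
    supporting: frozenset[str] = frozenset()
    status: str = "ok"

    @property
    def name(self) -> str:
        return self.entry.name if self.entry else "unknown"


def _isotope_supported(m1_ratio: float | None, formula: ElementalFormula,
                       rel_tol: float = 0.20) -> bool:
    """Two-isotopologue check: observed M+1/M vs carbon-count prediction."""
    if m1_ratio is None:
        return False
    expected = formula.count("C") * _C13_ABUNDANCE
    if expected <= 0:
        return False
    return abs(m1_ratio - expected) <= rel_tol * expected


def match_library(
    feature_id: str,
    feature_mz: float,
    library: list[LibraryEntry],
    feature_rt: float | None = None,
    feature_spectrum: Ms2Spectrum | None = None,
    m1_ratio: float | None = None,
    mz_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.2,
    ms2_cutoff: float = 85.0,
) -> list[Annotation]:
    """All library entries matching the feature's m/z, ranked by evidence
    count then spectral similarity.

    Entries failing the m/z gate are never returned; RT and MS2 evidence are
    evaluated independently on top of it.
    """
    if not library:
        raise ValueError("library must be non-empty")
    out: list[Annotation] = []
    for entry in library:
        if abs(ppm_error(feature_mz, entry.mz)) > mz_tol_ppm:
            continue
        evidence = {"mz"}
        sim = None
        if (feature_rt is not None and entry.rt is not None
                and abs(feature_rt - entry.rt) <= rt_tol_min):
            evidence.add("rt")
        if feature_spectrum is not None and entry.spectrum is not None:
            sim, _ = spectral_similarity(feature_spectrum, entry.spectrum)
            if sim >= ms2_cutoff:
                evidence.add("ms2")
        supporting = set()
        if _isotope_supported(m1_ratio, entry.formula):
            supporting.add("isotope")
        out.append(
            Annotation(
                feature_id=str(feature_id), entry=entry,
                evidence=frozenset(evidence), similarity=sim,
                supporting=frozenset(supporting),
            )
        )
    out.sort(key=lambda a: (-len(a.evidence), -(a.similarity or 0.0),
                            a.entry.name))
    return out


def assign_level(
    candidates: list[Annotation],
    feature_id: str = "",
    class_label: str | None = None,
) -> Annotation:
    """Pick the best candidate and assign the MSI confidence level.

    With no candidates: level 3 if an external class label is supplied, else
    level 4.  Deterministic and independent of candidate order (candidates are
    re-ranked internally).
    """
    if candidates:
        ranked = sorted(
            candidates,
            key=lambda a: (-len(a.evidence), -(a.similarity or 0.0),
                           a.entry.name),
        )
        best = ranked[0]
        orthogonal = best.evidence & {"mz", "rt", "ms2"}
        if best.entry.source == "in_house" and len(orthogonal) >= 2:
            level = 1
        elif "ms2" in best.evidence:
            level = 2
        elif class_label is not None:
            level = 3
        else:
            level = 4
        return Annotation(
            feature_id=best.feature_id, entry=best.entry,
            evidence=best.evidence, similarity=best.similarity, level=level,
            supporting=best.supporting,
        )
    fid = feature_id
    if class_label is not None:
        return Annotation(feature_id=fid, entry=None,
                          evidence=frozenset({"class_only"}), level=3)
    return Annotation(feature_id=fid, entry=None, level=4)


def verify_against_standard(
    annotation: Annotation,
    feature_spectrum: Ms2Spectrum | None,
    standard_spectrum: Ms2Spectrum | None,
    ms2_cutoff: float = 85.0,
) -> Annotation:
    """Confirm or refute an MS2-based annotation against an authentic
    standard's spectrum.

    A similarity below the cutoff refutes the identity: the annotation is
    demoted to class level (3) when a class label survives, else to 4, and
    flagged.  Missing spectra yield status ``"unverifiable"``.
    """
    if feature_spectrum is None or standard_spectrum is None:
        return Annotation(
            feature_id=annotation.feature_id, entry=annotation.entry,
            evidence=annotation.evidence, similarity=annotation.similarity,
            level=annotation.level, supporting=annotation.supporting,
            status="unverifiable",
        )
    sim, _ = spectral_similarity(feature_spectrum, standard_spectrum)
    if sim >= ms2_cutoff:
        status = "confirmed"
        level = annotation.level
        entry = annotation.entry
    else:
        status = "refuted"
        level = 3 if (annotation.entry and annotation.entry.class_label) else 4
        entry = None
        log.info("annotation %s refuted against standard (similarity %.1f)",
                 annotation.name, sim)
    return Annotation(
        feature_id=annotation.feature_id, entry=entry,
        evidence=annotation.evidence, similarity=sim, level=level,
        supporting=annotation.supporting, status=status,
    )


def annotations_frame(annotations: list[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_id": a.feature_id,
                "name": a.name,
                "formula": str(a.entry.formula) if a.entry else "",
                "level": a.level,
                "evidence": "+".join(sorted(a.evidence)),
                "similarity": a.similarity,
                "status": a.status,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demo library (synthetic)
# ---------------------------------------------------------------------------

_DEMO_COMPOUNDS: list[tuple[str, str, str, float]] = [
    # name, neutral formula, preferred ion, retention time (min)
    ("nicotine", "C10H14N2", "[M+H]+", 14.2),
    ("nornicotine", "C9H12N2", "[M+H]+", 14.8),
    ("cotinine", "C10H12N2O", "[M+H]+", 9.1),
    ("nicotine N-oxide", "C10H14N2O", "[M+H]+", 12.4),
    ("hydroxycotinine", "C10H12N2O2", "[M+H]+", 8.3),
    ("norcotinine", "C9H10N2O", "[M+H]+", 9.6),
    ("methylthioadenosine", "C11H15N5O3S", "[M+H]+", 6.55),
    ("L-glutamate", "C5H9NO4", "[M-H]-", 15.34),
    ("cytosine", "C4H5N3O", "[M+H]+", 10.35),
    ("uric acid", "C5H4N4O3", "[M-H]-", 13.76),
    ("maleamic acid", "C4H5NO3", "[M-H]-", 15.55),
    ("S-glutathionyl-L-cysteine", "C13H22N4O8S2", "[M+H]+", 17.29),
    ("N-acetylneuraminic acid", "C11H19NO9", "[M+H]+", 16.89),
    ("methylindole", "C9H9N", "[M+H]+", 4.79),
    ("ureidoisobutyric acid", "C5H10N2O2", "[M+H]+", 11.44),
    ("deoxycytidine", "C9H13N3O4", "[M+H]+", 10.34),
    ("proline", "C5H9NO2", "[M+H]+", 12.9),
    ("citrulline", "C6H13N3O3", "[M+H]+", 16.1),
    ("arginine", "C6H14N4O2", "[M+H]+", 18.4),
    ("ornithine", "C5H12N2O2", "[M+H]+", 18.9),
    ("spermidine", "C7H19N3", "[M+H]+", 20.2),
    ("S-adenosylmethionine", "C15H22N6O5S", "[M+H]+", 19.5),
    ("glutathione", "C10H17N3O6S", "[M+H]+", 16.8),
    ("cystine", "C6H12N2O4S2", "[M+H]+", 17.6),
    ("glutamine", "C5H10N2O3", "[M+H]+", 14.9),
    ("alanine", "C3H7NO2", "[M+H]+", 13.8),
    ("serine", "C3H7NO3", "[M+H]+", 15.2),
    ("threonine", "C4H9NO3", "[M+H]+", 14.4),
    ("valine", "C5H11NO2", "[M+H]+", 12.6),
    ("leucine", "C6H13NO2", "[M+H]+", 11.2),
    ("phenylalanine", "C9H11NO2", "[M+H]+", 10.1),
    ("tyrosine", "C9H11NO3", "[M+H]+", 11.8),
    ("tryptophan", "C11H12N2O2", "[M+H]+", 9.8),
    ("methionine", "C5H11NO2S", "[M+H]+", 12.2),
    ("histidine", "C6H9N3O2", "[M+H]+", 17.3),
    ("lysine", "C6H14N2O2", "[M+H]+", 18.7),
    ("creatinine", "C4H7N3O", "[M+H]+", 10.9),
    ("hypoxanthine", "C5H4N4O", "[M+H]+", 9.4),
    ("xanthine", "C5H4N4O2", "[M-H]-", 11.1),
    ("choline", "C5H13NO", "[M+H]+", 16.4),
]


def synthetic_reference_spectrum(entry_name: str, formula: ElementalFormula,
                                 ion: str, n_peaks: int = 8) -> Ms2Spectrum:
    """A synthetic stand-in reference spectrum, deterministic per compound.

    Fragment masses are drawn reproducibly from a hash of the compound name;
    these are NOT measured spectra and exist only so that matching and level
    assignment can be exercised without a licensed spectral library.
    """
    precursor = ion_mz(formula, ion)
    # zlib.crc32 is stable across sessions (str hash randomization is not)
    rng = np.random.default_rng(zlib.crc32(entry_name.encode()) % (2**31))
    frags = np.sort(rng.uniform(50.0, max(60.0, precursor - 1.5), n_peaks))
    inten = rng.uniform(5.0, 100.0, n_peaks)
    inten[rng.integers(0, n_peaks)] = 100.0
    return Ms2Spectrum(entry_name, precursor,
                       np.column_stack([frags, inten]), polarity="pos")


def demo_library(with_spectra: bool = True) -> list[LibraryEntry]:
    """A ~40-entry synthetic demo library (parent-alkaloid series plus common
    polar metabolites), standing in for a proprietary in-house library."""
    entries = []
    for name, formula, ion, rt in _DEMO_COMPOUNDS:
        f = ElementalFormula(formula)
        spectrum = (synthetic_reference_spectrum(name, f, ion)
                    if with_spectra else None)
        entries.append(LibraryEntry(name=name, formula=f, ion=ion, rt=rt,
                                    spectrum=spectrum))
    return entries


def library_to_csv(entries: list[LibraryEntry], path) -> None:
    pd.DataFrame(
        [
            {"name": e.name, "formula": str(e.formula), "ion": e.ion,
             "rt": e.rt, "source": e.source, "class": e.class_label or ""}
            for e in entries
        ]
    ).to_csv(path, index=False)


def library_from_csv(path, spectra: dict[str, Ms2Spectrum] | None = None
                     ) -> list[LibraryEntry]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            LibraryEntry(
                name=row["name"], formula=ElementalFormula(row["formula"]),
                ion=row.get("ion", "[M+H]+"),
                rt=None if pd.isna(row.get("rt")) else float(row["rt"]),
                source=row.get("source", "in_house"),
                class_label=row.get("class") or None,
                spectrum=(spectra or {}).get(row["name"]),
            )
        )
    return out
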