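"""MS2 spectrum handling, modified-cosine similarity and molecular networking.

Spectra are exchanged as MGF or NIST-style ``.msp`` text (both line-oriented;
the readers skip malformed records with a line-number warning and round-trip
losslessly with the writers).

The similarity score is a modified cosine scaled to 0-100: fragments are
matched one-to-one within a fragment tolerance, either directly or shifted by
the precursor mass difference, greedily in descending intensity-product order.
A network edge requires score >= 50, >= 3 matched fragments and >= 70%
coverage (fraction of total fragment intensity of the less intense spectrum
explained by matches) at the defaults; nodes without a qualifying edge remain
singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .chem import (
    BiotransformationCandidate,
    Transformation,
    ppm_error,
)

log = logging.getLogger(__name__)


@dataclass
class Ms2Spectrum:
    """A fragment spectrum: precursor m/z plus (m/z, relative intensity)
    peaks, kept sorted by m/z.  Intensities are on a 0-100 relative scale."""

    identifier: str
    precursor_mz: float
    peaks: np.ndarray  # (n, 2): m/z, intensity
    rt: float | None = None
    polarity: str = "pos"
    collision_energy: str | None = None

    def __post_init__(self):
        pk = np.asarray(self.peaks, float).reshape(-1, 2)
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive: {self.identifier}")
        if (pk[:, 1] < 0).any():
            raise ValueError(f"negative intensity in {self.identifier}")
        # isotope guard: fragments cannot exceed precursor + 1.5
        if len(pk) and pk[:, 0].max() >= self.precursor_mz + 1.5:
            raise ValueError(
                f"fragment above precursor+1.5 in {self.identifier}"
            )
        self.peaks = pk[np.argsort(pk[:, 0])]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def normalized(self) -> "Ms2Spectrum":
        """Scale the base peak to 100."""
        if not len(self.peaks) or self.peaks[:, 1].max() == 0:
            return self
        pk = self.peaks.copy()
        pk[:, 1] = 100.0 * pk[:, 1] / pk[:, 1].max()
        return Ms2Spectrum(self.identifier, self.precursor_mz, pk, self.rt,
                           self.polarity, self.collision_energy)


# ---------------------------------------------------------------------------
# I/O: MGF and NIST-style .msp
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    spectra, errors = [], 0
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    in_block = False
    start_line = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.upper() == "BEGIN IONS":
            in_block, fields, peaks, start_line = True, {}, [], lineno
        elif line.upper() == "END IONS":
            spec = _assemble(fields, peaks, start_line, fmt="mgf")
            if spec is not None:
                spectra.append(spec)
            else:
                errors += 1
            in_block = False
        elif in_block:
            if "=" in line:
                key, _, val = line.partition("=")
                fields[key.strip().upper()] = val.strip()
            else:
                try:
                    mz, inten = line.split()[:2]
                    peaks.append((float(mz), float(inten)))
                except ValueError:
                    log.warning("%s:%d malformed peak line skipped", path, lineno)
    if errors:
        log.warning("%s: %d malformed record(s) skipped", path, errors)
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    lines = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.identifier}")
        lines.append(f"PEPMASS={s.precursor_mz:.5f}")
        if s.rt is not None:
            lines.append(f"RTINSECONDS={s.rt * 60.0:.2f}")
        lines.append("CHARGE=1+" if s.polarity == "pos" else "CHARGE=1-")
        if s.collision_energy:
            lines.append(f"COLLISION_ENERGY={s.collision_energy}")
        for mz, inten in s.peaks:
            lines.append(f"{mz:.5f} {inten:.4f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_msp(path: str | Path) -> list[Ms2Spectrum]:
    spectra, errors = [], 0
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_expected = 0
    start_line = 1

    def flush():
        nonlocal errors
        if not fields and not peaks:
            return
        spec = _assemble(fields, peaks, start_line, fmt="msp")
        if spec is not None:
            spectra.append(spec)
        else:
            errors += 1

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if ":" in line and not line[0].isdigit():
            key, _, val = line.partition(":")
            key = key.strip().upper()
            if key == "NAME" and fields:
                flush()
                fields, peaks = {}, []
                start_line = lineno
            fields[key] = val.strip()
            if key == "NUM PEAKS":
                n_expected = int(val)
        else:
            try:
                mz, inten = line.replace(";", " ").split()[:2]
                peaks.append((float(mz), float(inten)))
            except ValueError:
                log.warning("%s:%d malformed peak line skipped", path, lineno)
    flush()
    if errors:
        log.warning("%s: %d malformed record(s) skipped", path, errors)
    return spectra


def write_msp(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    lines = []
    for s in spectra:
        lines.append(f"Name: {s.identifier}")
        lines.append(f"PrecursorMZ: {s.precursor_mz:.5f}")
        if s.rt is not None:
            lines.append(f"RT: {s.rt:.3f}")
        lines.append(f"Ion_mode: {'P' if s.polarity == 'pos' else 'N'}")
        if s.collision_energy:
            lines.append(f"Collision_energy: {s.collision_energy}")
        lines.append(f"Num Peaks: {s.n_peaks}")
        for mz, inten in s.peaks:
            lines.append(f"{mz:.5f} {inten:.4f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _assemble(fields, peaks, lineno, fmt) -> Ms2Spectrum | None:
    try:
        if fmt == "mgf":
            precursor = float(fields["PEPMASS"].split()[0])
            name = fields.get("TITLE", f"spectrum_{lineno}")
            rt = (float(fields["RTINSECONDS"]) / 60.0
                  if "RTINSECONDS" in fields else None)
            polarity = "neg" if fields.get("CHARGE", "1+").endswith("-") else "pos"
            ce = fields.get("COLLISION_ENERGY")
        else:
            precursor = float(fields["PRECURSORMZ"])
            name = fields.get("NAME", f"spectrum_{lineno}")
            rt = float(fields["RT"]) if "RT" in fields else None
            polarity = "neg" if fields.get("ION_MODE", "P").upper().startswith("N") else "pos"
            ce = fields.get("COLLISION_ENERGY")
        return Ms2Spectrum(name, precursor, np.array(peaks, float).reshape(-1, 2),
                           rt, polarity, ce)
    except (KeyError, ValueError) as exc:
        log.warning("record starting at line %d rejected: %s", lineno, exc)
        return None


def read_spectra(path: str | Path, fmt: str | None = None) -> list[Ms2Spectrum]:
    """Read spectra from MGF or .msp, inferring the format from the suffix."""
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "mgf":
        return read_mgf(path)
    if fmt == "msp":
        return read_msp(path)
    raise ValueError(f"unknown spectrum format {fmt!r} (use 'mgf' or 'msp')")


def write_spectra(spectra, path: str | Path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "mgf":
        write_mgf(spectra, path)
    elif fmt == "msp":
        write_msp(spectra, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r} (use 'mgf' or 'msp')")


# ---------------------------------------------------------------------------
# Similarity and networking
# ---------------------------------------------------------------------------

def spectral_similarity(
    a: Ms2Spectrum,
    b: Ms2Spectrum,
    frag_tol: float = 0.0025,
) -> tuple[float, int]:
    """Modified-cosine similarity scaled to 0-100 plus matched-fragment count.

    Candidate fragment pairs match either directly (|Δm/z| <= frag_tol) or
    after shifting by the precursor mass difference.  Pairs are accepted
    greedily in descending intensity-product order, each fragment used at most
    once (first-come tie-breaking at equal products).  The score is the cosine
    of the matched intensity vectors; identical spectra score 100, disjoint
    spectra 0.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        log.warning("empty spectrum in similarity: %s vs %s",
                    a.identifier, b.identifier)
        return 0.0, 0
    shift = a.precursor_mz - b.precursor_mz
    mza, ia = a.peaks[:, 0], a.peaks[:, 1]
    mzb, ib = b.peaks[:, 0], b.peaks[:, 1]

    cand: list[tuple[float, int, int]] = []
    for i in range(len(mza)):
        for j in range(len(mzb)):
            d = mza[i] - mzb[j]
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                cand.append((ia[i] * ib[j], i, j))
    if not cand:
        return 0.0, 0
    cand.sort(key=lambda t: -t[0])  # stable: first-come at ties

    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    matched = 0
    matched_a: list[int] = []
    matched_b: list[int] = []
    for prod, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += prod
        matched += 1
        matched_a.append(i)
        matched_b.append(j)
    norm = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    score = 100.0 * dot / norm if norm > 0 else 0.0
    return min(score, 100.0), matched


def match_coverage(a: Ms2Spectrum, b: Ms2Spectrum,
                   frag_tol: float = 0.0025) -> float:
    """Percent of total fragment intensity of the less intense spectrum
    explained by matched peaks (the 'MSn coverage' interpretation)."""
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0
    shift = a.precursor_mz - b.precursor_mz
    mza, ia = a.peaks[:, 0], a.peaks[:, 1]
    mzb, ib = b.peaks[:, 0], b.peaks[:, 1]
    cand = []
    for i in range(len(mza)):
        for j in range(len(mzb)):
            d = mza[i] - mzb[j]
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                cand.append((ia[i] * ib[j], i, j))
    cand.sort(key=lambda t: -t[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
    tot_a, tot_b = ia.sum(), ib.sum()
    if tot_a <= tot_b:
        smaller_total, smaller_matched = tot_a, ia[sorted(used_a)].sum()
    else:
        smaller_total, smaller_matched = tot_b, ib[sorted(used_b)].sum()
    return 100.0 * smaller_matched / smaller_total if smaller_total > 0 else 0.0


def build_network(
    spectra: Sequence[Ms2Spectrum],
    min_score: float = 50.0,
    min_fragments: int = 3,
    min_coverage: float = 70.0,
    frag_tol: float = 0.0025,
) -> nx.Graph:
    """Molecular network: nodes are spectra, edges pass all three thresholds.

    Edge attributes: ``score``, ``matched``, ``coverage`` and the precursor
    ``mass_shift`` (node b minus node a in file order).  Spectra without any
    qualifying edge are retained as singleton nodes, and the edge set does not
    depend on input order.
    """
    if not spectra:
        raise ValueError("spectra list must be non-empty")
    g = nx.Graph()
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.identifier))
    for s in ordered:
        attrs = {"precursor_mz": s.precursor_mz, "polarity": s.polarity}
        if s.rt is not None:  # None breaks GraphML serialization
            attrs["rt"] = s.rt
        g.add_node(s.identifier, **attrs)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            score, matched = spectral_similarity(a, b, frag_tol)
            if score < min_score or matched < min_fragments:
                continue
            cov = match_coverage(a, b, frag_tol)
            if cov < min_coverage:
                continue
            g.add_edge(
                a.identifier, b.identifier,
                score=round(score, 4), matched=matched,
                coverage=round(cov, 4),
                mass_shift=round(b.precursor_mz - a.precursor_mz, 5),
            )
    return g


def connected_components(g: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(g)]


def annotate_network_with_candidates(
    g: nx.Graph,
    candidates: Sequence[BiotransformationCandidate],
    transformations: Sequence[Transformation] = (),
    ppm_tol: float = 5.0,
    shift_tol_da: float = 0.005,
) -> nx.Graph:
    """Label nodes matching a theoretical product within ``ppm_tol`` and edges
    whose precursor mass shift matches a transformation delta.

    Returns the same graph with ``candidate_formula``/``candidate_chain`` node
    attributes and ``transformation`` edge attributes added; with no
    candidates the network is returned unchanged.
    """
    for node, data in g.nodes(data=True):
        mz = data.get("precursor_mz")
        if mz is None:
            continue
        best = None
        for cand in candidates:
            for label, theo in cand.expected_mz:
                err = abs(ppm_error(mz, theo))
                if err <= ppm_tol and (best is None or err < best[0]):
                    best = (err, cand, label)
        if best is not None:
            _, cand, label = best
            data["candidate_formula"] = str(cand.product)
            data["candidate_chain"] = " > ".join(cand.chain) or "(parent)"
            data["candidate_ion"] = label
    for u, v, data in g.edges(data=True):
        shift = abs(data.get("mass_shift", 0.0))
        for t in transformations:
            if abs(shift - abs(t.delta_mass())) <= shift_tol_da:
                data["transformation"] = t.name
                break
    return g


def network_to_edgelist(g: nx.Graph) -> "list[dict]":
    rows = []
    for u, v, data in g.edges(data=True):
        rows.append({"source": u, "target": v, **data})
    return rows
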