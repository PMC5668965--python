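"""Metabolite signature library and pathway annotations.

The bundled library covers the 47 resonance assignments of a 500-MHz CPMG
serum spectrum: 45 quantifiable metabolites plus two excluded-region markers
(residual water, HOD, at 4.76 ppm and urea at 5.80 ppm).  Each signature
carries its chemical shifts with multiplicity codes, a biochemical category
used for reporting, and optional pathway memberships used by the
over-representation stage.  The bundled pathway map is a small curated
annotation keyed to library abbreviations (KEGG-style pathway names); it is
a synthetic stand-in for a full compound database and is documented as such.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MetabolitePeak",
    "MetaboliteSignature",
    "PathwayMap",
    "LibraryParseError",
    "LibraryValidationError",
    "load_library",
    "load_pathway_map",
    "peaks_in_window",
    "by_abbreviation",
]

MULTIPLICITY_CODES = ("s", "d", "t", "q", "dd", "ddb", "m", "br")

CATEGORIES = (
    "glycolysis_glutaminolysis",
    "carboxylic_acid",
    "alcohol",
    "lipid",
    "ketone_body",
    "choline_derivative",
    "nonessential_amino_acid",
    "essential_amino_acid",
    "other",
    "region_marker",
)


class LibraryParseError(ValueError):
    """A library row could not be parsed (malformed shift/multiplicity)."""


class LibraryValidationError(ValueError):
    """The parsed library violates a structural invariant."""


@dataclass(frozen=True)
class MetabolitePeak:
    """One resonance: chemical shift centre, multiplicity code, weight.

    ``weight`` is the fraction of the metabolite's total signal carried by
    this resonance (all weights of a signature sum to one).
    """

    shift_ppm: float
    multiplicity: str
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift_ppm <= 10.0:
            raise LibraryValidationError(
                f"shift {self.shift_ppm} ppm outside [0, 10]"
            )
        if self.multiplicity not in MULTIPLICITY_CODES:
            raise LibraryValidationError(
                f"unknown multiplicity code {self.multiplicity!r}"
            )
        if not self.weight > 0:
            raise LibraryValidationError("peak weight must be > 0")


@dataclass(frozen=True)
class MetaboliteSignature:
    """A metabolite's identity, resonances and annotations."""

    abbreviation: str
    name: str
    peaks: tuple[MetabolitePeak, ...]
    category: str = "other"
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise LibraryValidationError(
                f"{self.abbreviation}: signature has no peaks"
            )
        if self.category not in CATEGORIES:
            raise LibraryValidationError(
                f"{self.abbreviation}: unknown category {self.category!r}"
            )
        total = sum(p.weight for p in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise LibraryValidationError(
                f"{self.abbreviation}: peak weights sum to {total}, not 1"
            )

    @property
    def is_marker(self) -> bool:
        """True for excluded-region markers (water, urea), never assigned."""
        return self.category == "region_marker"


_PEAK_RE = re.compile(
    r"^\s*(?P<shift>\d+(?:\.\d+)?)\((?P<mult>[a-z]+)\)(?:@(?P<w>\d*\.?\d+))?\s*$"
)


def _parse_peaks(text: str, row_label: str) -> tuple[MetabolitePeak, ...]:
    """Parse ``"1.33(d);4.11(q)"`` (optionally ``...@0.7`` explicit weights)."""
    parts = [p for p in text.split(";") if p.strip()]
    if not parts:
        raise LibraryParseError(f"{row_label}: empty peak list")
    raw: list[tuple[float, str, float | None]] = []
    for part in parts:
        m = _PEAK_RE.match(part)
        if m is None:
            raise LibraryParseError(
                f"{row_label}: malformed shift entry {part.strip()!r}"
            )
        mult = m.group("mult")
        if mult not in MULTIPLICITY_CODES:
            raise LibraryParseError(
                f"{row_label}: unknown multiplicity in {part.strip()!r}"
            )
        w = m.group("w")
        raw.append((float(m.group("shift")), mult, float(w) if w else None))
    explicit = [w for (_, _, w) in raw if w is not None]
    if explicit and len(explicit) != len(raw):
        raise LibraryParseError(
            f"{row_label}: mix of explicit and implicit peak weights"
        )
    if explicit:
        total = sum(explicit)
        if total <= 0:
            raise LibraryParseError(f"{row_label}: non-positive weight total")
        weights = [w / total for w in explicit]
    else:
        weights = [1.0 / len(raw)] * len(raw)
    return tuple(
        MetabolitePeak(shift, mult, w)
        for (shift, mult, _), w in zip(raw, weights)
    )


def _bundled(name: str):
    return resources.files("nmrmetab.data").joinpath(name)


@dataclass(frozen=True)
class PathwayMap:
    """pathway id -> (name, member abbreviations); universe = all annotated."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (pname, members) in self.pathways.items():
            if not members:
                raise LibraryValidationError(f"pathway {pid} has no members")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.pathways.values():
            out |= members
        return frozenset(out)

    def __iter__(self):
        return iter(self.pathways.items())

    def __len__(self) -> int:
        return len(self.pathways)


def load_pathway_map(source: str | Path | None = None) -> PathwayMap:
    """Load a pathway annotation CSV (``pathway_id,pathway_name,members``).

    ``members`` is a semicolon-separated list of library abbreviations.
    With ``source=None`` the bundled curated map is returned.
    """
    ref = _bundled("pathways.csv") if source is None else Path(source)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with ref.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["pathway_id"].strip()
            if pid in pathways:
                raise LibraryValidationError(f"duplicate pathway id {pid}")
            members = frozenset(
                m.strip() for m in row["members"].split(";") if m.strip()
            )
            pathways[pid] = (row["pathway_name"].strip(), members)
    return PathwayMap(pathways)


def load_library(
    source: str | Path | None = None,
    pathway_map: PathwayMap | None = None,
) -> list[MetaboliteSignature]:
    """Load a metabolite signature library from a CSV table.

    Expected columns: ``abbreviation,name,peaks,category`` with an optional
    ``pathways`` column (semicolon-separated pathway ids).  ``peaks`` is a
    semicolon-separated list of ``shift(multiplicity)`` entries; peak weights
    default to equal shares and may be overridden as ``shift(mult)@weight``.

    With ``source=None`` the bundled 47-signature serum library is returned,
    with pathway memberships joined in from the bundled pathway map (or from
    ``pathway_map`` when given).  An empty table yields an empty library.
    """
    ref = _bundled("metabolite_library.csv") if source is None else Path(source)
    if pathway_map is None and source is None:
        pathway_map = load_pathway_map()
    membership: dict[str, set[str]] = {}
    if pathway_map is not None:
        for pid, (_, members) in pathway_map:
            for abbr in members:
                membership.setdefault(abbr, set()).add(pid)

    signatures: list[MetaboliteSignature] = []
    seen: set[str] = set()
    with ref.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            abbr = row["abbreviation"].strip()
            if abbr in seen:
                raise LibraryValidationError(f"duplicate abbreviation {abbr!r}")
            seen.add(abbr)
            peaks = _parse_peaks(row["peaks"], f"row {abbr!r}")
            category = (row.get("category") or "other").strip() or "other"
            ids: set[str] = set(membership.get(abbr, set()))
            extra = (row.get("pathways") or "").strip()
            if extra:
                ids |= {p.strip() for p in extra.split(";") if p.strip()}
            signatures.append(
                MetaboliteSignature(
                    abbreviation=abbr,
                    name=row["name"].strip(),
                    peaks=peaks,
                    category=category,
                    pathway_ids=frozenset(ids),
                )
            )
    return signatures


def by_abbreviation(
    library: Iterable[MetaboliteSignature],
) -> dict[str, MetaboliteSignature]:
    return {sig.abbreviation: sig for sig in library}


def peaks_in_window(
    library: Sequence[MetaboliteSignature],
    lo_ppm: float,
    hi_ppm: float,
    include_markers: bool = False,
) -> list[tuple[str, MetabolitePeak]]:
    """All peaks with ``lo_ppm <= shift < hi_ppm``, sorted by shift.

    Half-open on the right so adjacent windows partition the axis without
    double counting.  Region markers (water/urea) are skipped unless
    ``include_markers`` is set.
    """
    if not lo_ppm < hi_ppm:
        raise ValueError(f"inverted window [{lo_ppm}, {hi_ppm})")
    hits = [
        (sig.abbreviation, peak)
        for sig in library
        if include_markers or not sig.is_marker
        for peak in sig.peaks
        if lo_ppm <= peak.shift_ppm < hi_ppm
    ]
    hits.sort(key=lambda ap: (ap[1].shift_ppm, ap[0]))
    return hits
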