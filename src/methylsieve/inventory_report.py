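"""Site-level inventory: stoichiometry, motif windows, summary counts, and
the packaged curated inventory fixture."""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "InventoryRecord",
    "MotifWindow",
    "CHLOROPLAST_LOCATIONS",
    "stoichiometry",
    "sequence_window",
    "load_packaged_inventory",
    "count_summary",
    "FixtureIntegrityError",
]

CHLOROPLAST_LOCATIONS = frozenset({"stroma", "thylakoid", "envelope"})

_FIXTURE_NAME = "curated_inventory.tsv"
_FIXTURE_SHA256 = "61c90238d5b5ced4b7dff208c84255a6b0300455d0fcd6980298bae9be7daed1"


class FixtureIntegrityError(RuntimeError):
    """The packaged inventory fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class InventoryRecord:
    """One curated methylation site (one table row).

    ``degrees`` is the set of observed methyl degrees; ``flags`` may contain
    ``confirmed_trimethyl`` or ``ambiguous_trimethyl_acetyl``;
    ``alt_positions`` holds alternative localizations ("K140 or K147" style
    sites), which still count as a single site. ``positioning_3d`` is an
    inert annotation.
    """

    accession: str
    symbol: str
    description: str
    category: str
    location: str
    position: int
    residue: str
    degrees: frozenset[int]
    flags: frozenset[str] = frozenset()
    alt_positions: tuple[int, ...] = ()
    sc_methyl: int | None = None
    sc_total: int | None = None
    positioning_3d: str = ""

    def __post_init__(self):
        if self.residue not in ("K", "R"):
            raise ValueError(f"residue must be K or R, got {self.residue!r}")
        if self.residue == "R" and 3 in self.degrees:
            raise ValueError("Arg cannot carry trimethylation")
        if (
            self.sc_methyl is not None
            and self.sc_total is not None
            and self.sc_methyl > self.sc_total
        ):
            raise ValueError("sc_methyl cannot exceed sc_total")

    @property
    def is_chloroplastic(self) -> bool:
        return self.location in CHLOROPLAST_LOCATIONS

    @property
    def stoichiometry_estimate(self) -> float | None:
        if self.sc_methyl is None or self.sc_total is None or self.sc_total == 0:
            return None
        return stoichiometry(self.sc_methyl, self.sc_total)


@dataclass(frozen=True)
class MotifWindow:
    """A 13-residue window centered on a methylation site, '-' padded."""

    window: str
    residue: str
    degrees: frozenset[int] = frozenset()

    def __post_init__(self):
        if len(self.window) != 13:
            raise ValueError(f"window must be 13 residues, got {len(self.window)}")
        if self.window[6] not in ("K", "R"):
            raise ValueError(f"window center must be K or R, got {self.window[6]!r}")


def stoichiometry(sc_methyl: int, sc_total: int) -> float | None:
    """Spectral-count stoichiometry proxy: methylated / total covering PSMs.

    Returns ``None`` (missing) when ``sc_total`` is zero.
    """
    if sc_methyl > sc_total:
        raise ValueError(
            f"sc_methyl ({sc_methyl}) cannot exceed sc_total ({sc_total})"
        )
    if sc_total == 0:
        return None
    return sc_methyl / sc_total


def sequence_window(
    sequence: str, position: int, degrees: Iterable[int] = (), flank: int = 6
) -> MotifWindow:
    """Extract the site +/- ``flank`` residue window, padding ends with '-'."""
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    center = sequence[position - 1]
    if center not in ("K", "R"):
        raise ValueError(f"window center must be K or R, got {center!r}")
    left = sequence[max(0, position - 1 - flank) : position - 1]
    right = sequence[position : position + flank]
    window = left.rjust(flank, "-") + center + right.ljust(flank, "-")
    return MotifWindow(window=window, residue=center, degrees=frozenset(degrees))


def _parse_degrees(text: str) -> frozenset[int]:
    # "me1/2/3" -> {1, 2, 3}
    if not text.startswith("me"):
        raise ValueError(f"malformed degrees field {text!r}")
    return frozenset(int(tok) for tok in text[2:].split("/"))


_FLAG_CODES = {"c": "confirmed_trimethyl", "a": "ambiguous_trimethyl_acetyl"}


def _records_from_rows(rows: Iterable[dict[str, str]]) -> list[InventoryRecord]:
    records = []
    for row in rows:
        records.append(
            InventoryRecord(
                accession=row["accession"],
                symbol=row["symbol"],
                description=row["description"],
                category=row["category"],
                location=row["location"],
                position=int(row["position"]),
                residue=row["residue"],
                degrees=_parse_degrees(row["degrees"]),
                flags=frozenset(
                    _FLAG_CODES[f] for f in row["flags"] if f in _FLAG_CODES
                ),
                alt_positions=tuple(
                    int(p) for p in row["alt_positions"].split(";") if p
                ),
                sc_methyl=int(row["sc_methyl"]) if row["sc_methyl"] else None,
                sc_total=int(row["sc_total"]) if row["sc_total"] else None,
                positioning_3d=row.get("positioning_3d", ""),
            )
        )
    return records


def load_packaged_inventory() -> list[InventoryRecord]:
    """The curated site inventory shipped with the package.

    Verifies the fixture checksum before parsing and raises
    :class:`FixtureIntegrityError` on mismatch.
    """
    data = (
        resources.files("methylsieve").joinpath("data", _FIXTURE_NAME).read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"inventory fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    reader = csv.DictReader(data.decode().splitlines(), delimiter="\t")
    return _records_from_rows(reader)


def count_summary(
    records: Sequence[InventoryRecord],
    locations: Iterable[str] | None = None,
    residue: str | None = None,
) -> dict:
    """Deterministic site/protein counts over (optionally filtered) records.

    A localization-ambiguous site and a multi-degree site each count once.
    ``locations`` filters by curated location (e.g. the chloroplast
    sub-compartments); ``residue`` filters by K or R.
    """
    selected = list(records)
    if locations is not None:
        locations = set(locations)
        selected = [r for r in selected if r.location in locations]
    if residue is not None:
        selected = [r for r in selected if r.residue == residue]

    sites = {(r.accession, r.position, r.residue) for r in selected}
    proteins = {r.accession for r in selected}

    sites_by_residue: dict[str, int] = {"K": 0, "R": 0}
    sites_by_location: dict[str, int] = {}
    sites_per_protein: dict[str, list[InventoryRecord]] = {}
    for r in selected:
        sites_by_residue[r.residue] += 1
        sites_by_location[r.location] = sites_by_location.get(r.location, 0) + 1
        sites_per_protein.setdefault(r.accession, []).append(r)

    single_site = {
        acc: recs[0] for acc, recs in sites_per_protein.items() if len(recs) == 1
    }
    single_by_residue = {"K": 0, "R": 0}
    for rec in single_site.values():
        single_by_residue[rec.residue] += 1

    return {
        "n_sites": len(sites),
        "n_proteins": len(proteins),
        "sites_by_residue": sites_by_residue,
        "sites_by_location": dict(sorted(sites_by_location.items())),
        "single_site_proteins_by_residue": single_by_residue,
    }
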