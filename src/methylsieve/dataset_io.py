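"""Readers/writers for PSM tables and MGF peak lists, plus the pre-pipeline
parsing filters (score cutoff, rank, homology) applied before methyl filtering."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .masschem import (
    ModifiedPeptide,
    mz_to_neutral_mass,
    peptide_mass,
    ppm_error,
)

__all__ = [
    "PSM",
    "Spectrum",
    "ParseConfig",
    "SchemaError",
    "RowError",
    "MgfError",
    "PSM_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "read_mgf",
    "write_mgf",
    "parse_filter",
    "compile_runs",
]

PSM_COLUMNS = (
    "spectrum_id",
    "run_id",
    "peptide",
    "mods",
    "charge",
    "obs_mz",
    "score",
    "rank",
    "homology_pass",
    "accessions",
    "is_decoy",
)


class SchemaError(ValueError):
    """A required column is missing from a PSM table."""


class RowError(ValueError):
    """A malformed row in a PSM table; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MgfError(ValueError):
    """A malformed MGF file; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class PSM:
    """One spectrum-to-peptide match with score and decoy status.

    ``is_decoy`` follows the standard target-decoy convention: true iff every
    matched accession is a decoy.
    """

    spectrum_id: str
    run_id: str
    peptide: ModifiedPeptide
    observed_precursor_mz: float
    charge: int
    score: float
    rank: int = 1
    homology_pass: bool = True
    protein_accessions: tuple[str, ...] = ()
    is_decoy: bool = False

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")

    @property
    def observed_neutral_mass(self) -> float:
        return mz_to_neutral_mass(self.observed_precursor_mz, self.charge)

    @property
    def precursor_ppm_error(self) -> float:
        """Observed-vs-theoretical precursor error under this PSM's own hypothesis."""
        return ppm_error(self.observed_neutral_mass, peptide_mass(self.peptide))

    def is_methyl(self) -> bool:
        return bool(self.peptide.methyl_sites())


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS peak list; peaks are kept sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for _, intensity in peaks:
            if intensity < 0:
                raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class ParseConfig:
    """Pre-pipeline report filters (peptide score cutoff, rank-1, homology)."""

    peptide_score_cutoff: float = 20.0
    require_rank1: bool = True
    require_homology: bool = True
    protein_pvalue: float = 0.05


def _serialize_mods(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{name}@{pos}" for pos, name in sorted(mods))


def _parse_mods(text: str, line: int) -> tuple[tuple[int, str], ...]:
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        if "@" not in token:
            raise RowError(line, f"malformed mod token {token!r} (expected name@position)")
        name, _, pos = token.rpartition("@")
        try:
            out.append((int(pos), name))
        except ValueError:
            raise RowError(line, f"non-integer mod position in {token!r}") from None
    return tuple(out)


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for p in psms:
            writer.writerow(
                [
                    p.spectrum_id,
                    p.run_id,
                    p.peptide.sequence,
                    _serialize_mods(p.peptide.mods),
                    p.charge,
                    repr(p.observed_precursor_mz),
                    repr(p.score),
                    p.rank,
                    str(p.homology_pass).lower(),
                    ";".join(p.protein_accessions),
                    str(p.is_decoy).lower(),
                ]
            )


def _parse_bool(text: str, line: int, column: str) -> bool:
    if text.lower() in ("true", "1"):
        return True
    if text.lower() in ("false", "0"):
        return False
    raise RowError(line, f"invalid boolean {text!r} in column {column}")


def read_psm_table(path: str | Path) -> list[PSM]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: missing header") from None
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in PSM_COLUMNS}
        psms = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                peptide = ModifiedPeptide(
                    sequence=row[idx["peptide"]],
                    mods=_parse_mods(row[idx["mods"]], lineno),
                    charge=int(row[idx["charge"]]),
                )
                psm = PSM(
                    spectrum_id=row[idx["spectrum_id"]],
                    run_id=row[idx["run_id"]],
                    peptide=peptide,
                    observed_precursor_mz=float(row[idx["obs_mz"]]),
                    charge=int(row[idx["charge"]]),
                    score=float(row[idx["score"]]),
                    rank=int(row[idx["rank"]]),
                    homology_pass=_parse_bool(
                        row[idx["homology_pass"]], lineno, "homology_pass"
                    ),
                    protein_accessions=tuple(
                        a for a in row[idx["accessions"]].split(";") if a
                    ),
                    is_decoy=_parse_bool(row[idx["is_decoy"]], lineno, "is_decoy"),
                )
            except RowError:
                raise
            except (ValueError, KeyError) as exc:
                raise RowError(lineno, str(exc)) from exc
            psms.append(psm)
    return psms


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.spectrum_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={spec.charge}+\n")
            for mz, intensity in spec.peaks:
                fh.write(f"{mz:.5f} {intensity:.2f}\n")
            fh.write("END IONS\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    title = pepmass = charge = None
    peaks: list[tuple[float, float]] = []
    in_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfError(lineno, "nested BEGIN IONS")
                in_block = True
                title = pepmass = charge = None
                peaks = []
            elif line == "END IONS":
                if not in_block:
                    raise MgfError(lineno, "END IONS without BEGIN IONS")
                if title is None or pepmass is None or charge is None:
                    raise MgfError(lineno, "spectrum missing TITLE/PEPMASS/CHARGE")
                spectra.append(Spectrum(title, pepmass, charge, tuple(peaks)))
                in_block = False
            elif not in_block:
                raise MgfError(lineno, f"unexpected content outside spectrum: {line!r}")
            elif "=" in line:
                key, _, value = line.partition("=")
                if key == "TITLE":
                    title = value
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    try:
                        charge = int(value.rstrip("+"))
                    except ValueError:
                        raise MgfError(lineno, f"invalid CHARGE {value!r}") from None
                # other headers ignored
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise MgfError(lineno, f"malformed peak line {line!r}")
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise MgfError(lineno, f"malformed peak line {line!r}") from None
    if in_block:
        raise MgfError(lineno, "unterminated spectrum (missing END IONS)")
    return spectra


def parse_filter(psms: Sequence[PSM], cfg: ParseConfig | None = None) -> list[PSM]:
    """Retain PSMs passing the report filters; order and duplicates preserved.

    The score cutoff is inclusive (score >= cutoff kept). Duplicate peptide
    sequences from different spectra are all conserved.
    """
    cfg = cfg or ParseConfig()
    out = []
    for p in psms:
        if p.score < cfg.peptide_score_cutoff:
            continue
        if cfg.require_rank1 and p.rank != 1:
            continue
        if cfg.require_homology and not p.homology_pass:
            continue
        out.append(p)
    return out


def compile_runs(
    per_run_psms: Sequence[Sequence[PSM]],
) -> tuple[list[PSM], dict[str, dict]]:
    """Pool PSMs across runs and build non-redundant protein groups.

    Proteins matched by exactly the same set of peptide sequences are merged
    into one group whose representative is the lexicographically smallest
    accession. Raises on duplicate (run_id, spectrum_id, rank) triples.
    """
    pooled: list[PSM] = []
    seen: set[tuple[str, str, int]] = set()
    for run in per_run_psms:
        for p in run:
            key = (p.run_id, p.spectrum_id, p.rank)
            if key in seen:
                raise ValueError(f"duplicate PSM identity {key}")
            seen.add(key)
            pooled.append(p)

    peptides_by_protein: dict[str, set[str]] = {}
    for p in pooled:
        for acc in p.protein_accessions:
            peptides_by_protein.setdefault(acc, set()).add(p.peptide.sequence)

    by_peptide_set: dict[frozenset[str], list[str]] = {}
    for acc, peps in peptides_by_protein.items():
        by_peptide_set.setdefault(frozenset(peps), []).append(acc)

    groups: dict[str, dict] = {}
    for peps, accs in by_peptide_set.items():
        rep = min(accs)
        groups[rep] = {
            "accessions": sorted(accs),
            "peptides": sorted(peps),
        }
    return pooled, groups
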