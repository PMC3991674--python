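"""Six-step methylation-site candidate filter with target-decoy FDR.

Steps: (1) seed selection at a high score threshold, (2) spectral-quality
assessment of seeds, (3) corroboration by lower-scoring PSMs mapping to the
same site, (4) minimum-spectra requirement, (5) removal of sites explained
entirely by exact isobaric substitutions, (6) trimethyl-vs-acetyl
adjudication. Site coordinates are 1-based on full-length precursor
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .dataset_io import PSM, ParseConfig, Spectrum, parse_filter
from .digestion_decoy import ProteinEntry
from .isobar import (
    CalibrationDistribution,
    TrimethylAcetylEvidence,
    find_isobaric_substitutions,
    resolve_trimethyl_acetyl,
)
from .masschem import fragment_ions

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "MethylSiteCandidate",
    "FdrEstimate",
    "QualityResult",
    "PipelineResult",
    "estimate_fdr",
    "assess_spectrum_quality",
    "seed_and_corroborate",
    "apply_min_spectra",
    "apply_ambiguity_filters",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    seed_score: float = 50.0
    support_score_floor: float = 20.0
    min_spectra_per_site: int = 2
    calibration_score_floor: float = 40.0
    calibration_min_n: int = 20
    k_spread: float = 3.0
    min_matched_fraction: float = 0.3
    min_site_determining_ions: int = 1
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.8

    def __post_init__(self):
        if self.seed_score < self.support_score_floor:
            raise ValueError("seed_score must be >= support_score_floor")
        if self.min_spectra_per_site < 1:
            raise ValueError("min_spectra_per_site must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class MethylSiteCandidate:
    """A (protein, position, residue) methylation site with its support."""

    accession: str
    position: int
    residue: str
    degrees_observed: set[int] = field(default_factory=set)
    seed_psms: list[PSM] = field(default_factory=list)
    support_psms: list[PSM] = field(default_factory=list)  # includes seeds
    localization_ambiguous: bool = False
    alt_positions: tuple[int, ...] = ()
    ambiguity_flags: set[str] = field(default_factory=set)
    is_decoy: bool = False
    sc_methyl: int = 0
    sc_total: int = 0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.residue)

    @property
    def n_spectra(self) -> int:
        return len({p.spectrum_id for p in self.support_psms})


@dataclass(frozen=True)
class FdrEstimate:
    """Target-decoy FDR: 2 * n_rev / (n_rev + n_real), capped at 1."""

    n_rev: int
    n_real: int
    score_threshold: float

    @property
    def fdr(self) -> float:
        return min(1.0, 2.0 * self.n_rev / (self.n_rev + self.n_real))


@dataclass(frozen=True)
class QualityResult:
    passed: bool
    matched_fraction: float
    n_site_determining: int
    n_theoretical: int


@dataclass
class PipelineResult:
    sites: list[MethylSiteCandidate]
    fdr_initial: FdrEstimate | None
    fdr_final: FdrEstimate | None
    audit: dict


def estimate_fdr(psms: Sequence[PSM], score_threshold: float) -> FdrEstimate:
    """Count methyl-PSMs at/above ``score_threshold`` by decoy status."""
    n_rev = n_real = 0
    for p in psms:
        if not p.is_methyl() or p.score < score_threshold:
            continue
        if p.is_decoy:
            n_rev += 1
        else:
            n_real += 1
    if n_rev + n_real == 0:
        raise ValueError(
            f"no methyl-PSMs at score >= {score_threshold}: FDR undefined"
        )
    return FdrEstimate(n_rev=n_rev, n_real=n_real, score_threshold=score_threshold)


def assess_spectrum_quality(
    spec: Spectrum, psm: PSM, cfg: PipelineConfig | None = None
) -> QualityResult:
    """Matched b/y-fragment fraction and site-determining ion count.

    Site-determining ions are matched singly-charged b/y fragments covering a
    methylated position (their mass shifts with the modification, localizing
    it). Pass requires both thresholds.
    """
    cfg = cfg or PipelineConfig()
    if spec.spectrum_id != psm.spectrum_id:
        raise ValueError(
            f"spectrum/PSM id mismatch: {spec.spectrum_id!r} vs {psm.spectrum_id!r}"
        )
    theoretical = fragment_ions(psm.peptide, ("b", "y"), charge=1)
    n = len(psm.peptide.sequence)
    site_positions = [pos for pos, _ in psm.peptide.methyl_sites() if pos > 0]
    peak_mzs = [mz for mz, _ in spec.peaks]

    def matched(target: float) -> bool:
        return any(abs(mz - target) <= cfg.fragment_tol_da for mz in peak_mzs)

    n_matched = 0
    n_site = 0
    for label, mz in theoretical:
        if not matched(mz):
            continue
        n_matched += 1
        idx = int(label.rstrip("+")[1:])
        covers = any(
            (label.startswith("b") and idx >= site)
            or (label.startswith("y") and idx >= n - site + 1)
            for site in site_positions
        )
        if covers:
            n_site += 1
    fraction = n_matched / len(theoretical) if theoretical else 0.0
    passed = (
        fraction >= cfg.min_matched_fraction
        and n_site >= cfg.min_site_determining_ions
    )
    return QualityResult(passed, fraction, n_site, len(theoretical))


@dataclass(frozen=True)
class SiteHit:
    """One methyl mod of one PSM mapped onto protein coordinates."""

    accession: str
    position: int
    residue: str
    degree: int
    peptide_position: int
    alt_positions: tuple[int, ...]


def _occurrences(haystack: str, needle: str) -> list[int]:
    """0-based start indices of every occurrence of ``needle``."""
    out, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return out
        out.append(idx)
        start = idx + 1


def map_psm_sites(
    psm: PSM, proteome: Mapping[str, ProteinEntry]
) -> list[SiteHit]:
    """Map each methyl mod of a PSM to (protein, position, residue) sites.

    The representative accession is the lexicographically smallest matched
    accession whose sequence contains the peptide. If the peptide occurs at
    several positions in that protein, the first occurrence is primary and
    the others are recorded as localization alternatives.
    """
    hits: list[SiteHit] = []
    methyl = [(pos, deg) for pos, deg in psm.peptide.methyl_sites() if pos > 0]
    if not methyl:
        return hits
    for acc in sorted(psm.protein_accessions):
        protein = proteome.get(acc)
        if protein is None:
            continue
        starts = _occurrences(protein.sequence, psm.peptide.sequence)
        if not starts:
            continue
        for pep_pos, degree in methyl:
            positions = [s + pep_pos for s in starts]  # 1-based on protein
            hits.append(
                SiteHit(
                    accession=acc,
                    position=positions[0],
                    residue=psm.peptide.sequence[pep_pos - 1],
                    degree=degree,
                    peptide_position=pep_pos,
                    alt_positions=tuple(positions[1:]),
                )
            )
        break  # one representative protein per PSM
    return hits


def seed_and_corroborate(
    psms: Sequence[PSM],
    spectra: Mapping[str, Spectrum],
    proteome: Mapping[str, ProteinEntry],
    cfg: PipelineConfig | None = None,
) -> tuple[dict[tuple[str, int, str], MethylSiteCandidate], dict]:
    """Steps 1-3: seed sites from high-scoring quality-passing PSMs, then
    attach every PSM above the support floor mapping to the same site.

    Overlapping miscleaved peptides and differing modification patterns pool
    onto one site through protein-coordinate mapping. Returns the candidate
    map and step-count audit entries.
    """
    cfg = cfg or PipelineConfig()
    seeds_checked = 0
    seeds_passed = 0
    candidates: dict[tuple[str, int, str], MethylSiteCandidate] = {}

    # Step 1 + 2: seeds.
    for psm in psms:
        if psm.score < cfg.seed_score or not psm.is_methyl():
            continue
        spec = spectra.get(psm.spectrum_id)
        if spec is None:
            logger.info("seed PSM %s has no spectrum; skipped", psm.spectrum_id)
            continue
        seeds_checked += 1
        quality = assess_spectrum_quality(spec, psm, cfg)
        if not quality.passed:
            continue
        seeds_passed += 1
        for hit in map_psm_sites(psm, proteome):
            key = (hit.accession, hit.position, hit.residue)
            cand = candidates.get(key)
            if cand is None:
                cand = MethylSiteCandidate(
                    accession=hit.accession,
                    position=hit.position,
                    residue=hit.residue,
                    is_decoy=psm.is_decoy,
                )
                candidates[key] = cand
            cand.seed_psms.append(psm)
            if hit.alt_positions:
                cand.localization_ambiguous = True
                cand.alt_positions = tuple(
                    sorted(set(cand.alt_positions) | set(hit.alt_positions))
                )

    # Step 3: corroborating PSMs (seeds included as support).
    for psm in psms:
        if psm.score < cfg.support_score_floor or not psm.is_methyl():
            continue
        for hit in map_psm_sites(psm, proteome):
            cand = candidates.get((hit.accession, hit.position, hit.residue))
            if cand is None:
                continue
            cand.support_psms.append(psm)
            cand.degrees_observed.add(hit.degree)

    audit = {
        "seed_psms_inspected": seeds_checked,
        "seed_psms_quality_passed": seeds_passed,
        "sites_seeded": len(candidates),
        "support_psms_attached": sum(
            len(c.support_psms) for c in candidates.values()
        ),
    }
    return candidates, audit


def apply_min_spectra(
    candidates: Mapping[tuple[str, int, str], MethylSiteCandidate],
    cfg: PipelineConfig | None = None,
) -> dict[tuple[str, int, str], MethylSiteCandidate]:
    """Step 4: drop sites supported by fewer than the minimum spectra."""
    cfg = cfg or PipelineConfig()
    return {
        key: cand
        for key, cand in candidates.items()
        if cand.n_spectra >= cfg.min_spectra_per_site
    }


def _psm_methyl_hits_at(
    psm: PSM, cand: MethylSiteCandidate, proteome: Mapping[str, ProteinEntry]
) -> list[SiteHit]:
    return [
        h
        for h in map_psm_sites(psm, proteome)
        if (h.accession, h.position, h.residue) == cand.key
    ]


def apply_ambiguity_filters(
    candidates: Mapping[tuple[str, int, str], MethylSiteCandidate],
    spectra: Mapping[str, Spectrum],
    calib: CalibrationDistribution,
    proteome: Mapping[str, ProteinEntry],
    cfg: PipelineConfig | None = None,
) -> tuple[dict[tuple[str, int, str], MethylSiteCandidate], dict, dict]:
    """Steps 5-6: substitution and trimethyl/acetyl ambiguity removal.

    A site is removed at step 5 only when *every* supporting PSM admits an
    exact isobaric single-residue substitution (mixed support survives, with
    a flag). Trimethyl sites are adjudicated per supporting trimethyl PSM;
    a site whose evidence resolves to acetyl (and never to trimethyl) is
    removed; unresolved sites are retained with an ambiguity flag.
    """
    cfg = cfg or PipelineConfig()
    kept: dict[tuple[str, int, str], MethylSiteCandidate] = {}
    removed_step5: list[tuple[str, int, str]] = []
    removed_step6: list[tuple[str, int, str]] = []
    evidence_log: dict[str, list[TrimethylAcetylEvidence]] = {}

    # Step 5: exact substitution isobars.
    after_step5: dict[tuple[str, int, str], MethylSiteCandidate] = {}
    for key, cand in candidates.items():
        statuses = []
        for psm in cand.support_psms:
            ambiguous = False
            for hit in _psm_methyl_hits_at(psm, cand, proteome):
                subs = find_isobaric_substitutions(
                    psm.peptide,
                    hit.peptide_position,
                    hit.degree,
                    tol_ppm=cfg.precursor_tol_ppm,
                )
                if any(s.is_exact for s in subs):
                    ambiguous = True
            statuses.append(ambiguous)
        if statuses and all(statuses):
            removed_step5.append(key)
            continue
        if any(statuses):
            cand.ambiguity_flags.add("substitution")
        after_step5[key] = cand

    # Step 6: trimethyl vs acetyl.
    for key, cand in after_step5.items():
        if cand.residue != "K" or 3 not in cand.degrees_observed:
            kept[key] = cand
            continue
        verdicts = []
        site_evidence = []
        for psm in cand.support_psms:
            if not any(
                h.degree == 3 for h in _psm_methyl_hits_at(psm, cand, proteome)
            ):
                continue
            spec = spectra.get(psm.spectrum_id)
            if spec is None:
                logger.info(
                    "no spectrum for trimethyl PSM %s: no neutral-loss evidence",
                    psm.spectrum_id,
                )
            ev = resolve_trimethyl_acetyl(
                psm, spec, calib, cfg.k_spread, cfg.fragment_tol_da
            )
            verdicts.append(ev.verdict)
            site_evidence.append(ev)
        evidence_log[f"{key[0]}:{key[2]}{key[1]}"] = site_evidence
        if "trimethyl" in verdicts:
            kept[key] = cand
        elif "acetyl" in verdicts:
            removed_step6.append(key)
        else:
            cand.ambiguity_flags.add("trimethyl_acetyl")
            kept[key] = cand

    audit = {
        "removed_step5_substitution": sorted(removed_step5),
        "removed_step6_acetyl": sorted(removed_step6),
        "n_removed_step5": len(removed_step5),
        "n_removed_step6": len(removed_step6),
    }
    return kept, audit, evidence_log


def _spectral_counts(
    cand: MethylSiteCandidate,
    psms: Sequence[PSM],
    proteome: Mapping[str, ProteinEntry],
) -> tuple[int, int]:
    """SC_methyl / SC_total for a site. SC_total counts every PSM, methylated
    or not, whose peptide covers the site position on the protein."""
    protein = proteome.get(cand.accession)
    sc_methyl = len(cand.support_psms)
    sc_total = 0
    if protein is None:
        return sc_methyl, sc_methyl
    for psm in psms:
        if cand.accession not in psm.protein_accessions:
            continue
        for start in _occurrences(protein.sequence, psm.peptide.sequence):
            if start + 1 <= cand.position <= start + len(psm.peptide.sequence):
                sc_total += 1
                break
    return sc_methyl, max(sc_total, sc_methyl)


def run_pipeline(
    psms: Sequence[PSM],
    spectra: Mapping[str, Spectrum] | Iterable[Spectrum],
    proteome: Mapping[str, ProteinEntry] | Iterable[ProteinEntry],
    cfg: PipelineConfig | None = None,
    parse_cfg: ParseConfig | None = None,
) -> PipelineResult:
    """Full pipeline: parse filters -> FDR -> steps 1-6 -> site table.

    Decoy PSMs are run through the same site-building machinery against the
    decoy half of the proteome, so the post-filter FDR is computed
    symmetrically; decoy sites are excluded from the returned site list.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(spectra, Mapping):
        spectra = {s.spectrum_id: s for s in spectra}
    if not isinstance(proteome, Mapping):
        proteome = {p.accession: p for p in proteome}

    parsed = parse_filter(list(psms), parse_cfg)
    audit: dict = {
        "n_psms_input": len(psms),
        "n_psms_parsed": len(parsed),
    }
    if not any(p.is_methyl() for p in parsed):
        raise ValueError("no methyl-PSMs after parsing filters")

    fdr_initial = estimate_fdr(parsed, cfg.support_score_floor)
    audit["fdr_initial"] = fdr_initial.fdr

    calib = CalibrationDistribution.from_psms(
        parsed, cfg.calibration_score_floor, cfg.calibration_min_n
    )
    audit["calibration"] = {
        "n": len(calib.errors),
        "center_ppm": calib.center,
        "spread_ppm": calib.spread,
    }

    candidates, seed_audit = seed_and_corroborate(parsed, spectra, proteome, cfg)
    audit.update(seed_audit)

    after4 = apply_min_spectra(candidates, cfg)
    audit["removed_step4_single_psm"] = sorted(
        set(candidates) - set(after4)
    )
    audit["n_removed_step4"] = len(candidates) - len(after4)

    after6, amb_audit, evidence = apply_ambiguity_filters(
        after4, spectra, calib, proteome, cfg
    )
    audit.update(amb_audit)

    validated = []
    n_rev_final = n_real_final = 0
    for cand in after6.values():
        n_psms = len(cand.support_psms)
        if cand.is_decoy:
            n_rev_final += n_psms
            continue
        n_real_final += n_psms
        cand.sc_methyl, cand.sc_total = _spectral_counts(cand, parsed, proteome)
        validated.append(cand)
    validated.sort(key=lambda c: c.key)

    fdr_final = None
    if n_rev_final + n_real_final > 0:
        fdr_final = FdrEstimate(
            n_rev=n_rev_final,
            n_real=n_real_final,
            score_threshold=cfg.support_score_floor,
        )
        audit["fdr_final"] = fdr_final.fdr
    audit["n_sites_validated"] = len(validated)
    return PipelineResult(
        sites=validated, fdr_initial=fdr_initial, fdr_final=fdr_final, audit=audit
    )
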