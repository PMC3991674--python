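"""Chemistry of confusable assignments.

Two ambiguity families threaten methylpeptide calls: a methyl mass shift can
be isobaric with a single amino-acid substitution elsewhere in the peptide,
and the trimethyl shift (+42.04695 Da) is a near-isobar of acetylation
(+42.01056 Da). This module enumerates the former and adjudicates the latter
from precursor mass accuracy and the trimethylamine neutral loss.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dataset_io import PSM, Spectrum
from .masschem import (
    METHYL_MOD_BY_DEGREE,
    RESIDUE_MASS,
    STANDARD_RESIDUES,
    TRIMETHYLAMINE_MASS,
    ModifiedPeptide,
    fragment_ions,
    mod_delta,
    peptide_mass,
    ppm_error,
)

__all__ = [
    "SubstitutionAmbiguity",
    "TrimethylAcetylEvidence",
    "CalibrationDistribution",
    "NeutralLossReport",
    "EXACT_ISOBAR_TOL_DA",
    "find_isobaric_substitutions",
    "separability_mass_limit",
    "detect_neutral_loss",
    "resolve_trimethyl_acetyl",
]

#: Two hypotheses closer than this are treated as exactly isobaric (same
#: elemental composition; any residual difference is float round-off).
EXACT_ISOBAR_TOL_DA = 1e-9


@dataclass(frozen=True)
class SubstitutionAmbiguity:
    """A single-residue substitution whose mass mimics a methyl shift."""

    site_position: int
    degree: int
    substitution_position: int
    from_residue: str
    to_residue: str
    exact_mass_difference: float  # substitution delta minus methyl delta, Da
    within_tolerance: bool
    is_exact: bool


@dataclass(frozen=True)
class CalibrationDistribution:
    """Robust precursor ppm-error distribution from high-scoring PSMs."""

    errors: tuple[float, ...]
    score_floor: float = 40.0
    min_n: int = 20

    def __post_init__(self):
        if len(self.errors) < self.min_n:
            raise ValueError(
                f"calibration needs >= {self.min_n} PSMs with score > "
                f"{self.score_floor}, got {len(self.errors)}"
            )

    @classmethod
    def from_psms(
        cls,
        psms: Iterable[PSM],
        score_floor: float = 40.0,
        min_n: int = 20,
    ) -> "CalibrationDistribution":
        errors = tuple(
            p.precursor_ppm_error for p in psms if p.score > score_floor
        )
        return cls(errors=errors, score_floor=score_floor, min_n=min_n)

    @property
    def center(self) -> float:
        return statistics.median(self.errors)

    @property
    def spread(self) -> float:
        """MAD-based robust standard deviation (1.4826 x MAD) in ppm."""
        med = self.center
        mad = statistics.median(abs(e - med) for e in self.errors)
        return 1.4826 * mad

    def in_band(self, error_ppm: float, k: float = 3.0) -> bool:
        return abs(error_ppm - self.center) <= k * self.spread


@dataclass(frozen=True)
class NeutralLossReport:
    """Outcome of searching a spectrum for the trimethylamine neutral loss."""

    detected: bool
    precursor_matches: tuple[tuple[float, float], ...]  # (expected, observed m/z)
    fragment_matches: tuple[tuple[str, float, float], ...]  # (label, expected, observed)
    loss_mass: float = TRIMETHYLAMINE_MASS

    def __bool__(self) -> bool:
        return self.detected


@dataclass(frozen=True)
class TrimethylAcetylEvidence:
    """Evidence record for one trimethyl-vs-acetyl adjudication."""

    spectrum_id: str
    error_vs_trimethyl: float
    error_vs_acetyl: float
    calibration_center: float
    calibration_spread: float
    neutral_loss_detected: bool
    verdict: str  # "trimethyl" | "acetyl" | "ambiguous"


def find_isobaric_substitutions(
    p: ModifiedPeptide,
    site: int,
    degree: int,
    tol_ppm: float = 10.0,
) -> list[SubstitutionAmbiguity]:
    """Single-residue substitutions whose mass change matches the methyl delta.

    For the methyl hypothesis (degree 1-3 at ``site``), every substitution of
    a residue at another, unmodified position into any standard residue is
    compared against the methyl delta. Matches within ``tol_ppm`` of the
    peptide mass are returned; exact composition matches are flagged.
    """
    methyl_at_site = {pos: deg for pos, deg in p.methyl_sites()}
    if methyl_at_site.get(site) != degree:
        raise ValueError(
            f"position {site} does not carry a degree-{degree} methyl mod"
        )
    methyl_delta = mod_delta(METHYL_MOD_BY_DEGREE[degree])
    tol_da = tol_ppm * 1e-6 * peptide_mass(p)
    modified_positions = {pos for pos, _ in p.mods}
    out: list[SubstitutionAmbiguity] = []
    for pos in range(1, len(p.sequence) + 1):
        if pos == site or pos in modified_positions:
            continue
        fro = p.sequence[pos - 1]
        for to in STANDARD_RESIDUES:
            if to == fro:
                continue
            diff = (RESIDUE_MASS[to] - RESIDUE_MASS[fro]) - methyl_delta
            if abs(diff) <= tol_da:
                out.append(
                    SubstitutionAmbiguity(
                        site_position=site,
                        degree=degree,
                        substitution_position=pos,
                        from_residue=fro,
                        to_residue=to,
                        exact_mass_difference=diff,
                        within_tolerance=True,
                        is_exact=abs(diff) < EXACT_ISOBAR_TOL_DA,
                    )
                )
    return out


def separability_mass_limit(delta: float, tol_ppm: float) -> float:
    """Peptide neutral mass above which two +/- ``tol_ppm`` windows separated
    by ``delta`` Da overlap: delta / (2 * tol_ppm * 1e-6)."""
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be > 0, got {tol_ppm}")
    return delta / (2.0 * tol_ppm * 1e-6)


def detect_neutral_loss(
    spec: Spectrum,
    psm: PSM,
    loss_mass: float = TRIMETHYLAMINE_MASS,
    tol: float = 0.8,
) -> NeutralLossReport:
    """Search for peaks consistent with loss of ``loss_mass`` (trimethylamine).

    Two families of diagnostic peaks are examined: the charge-reduced
    precursor (precursor m/z - loss/charge) and, for each methyl site,
    singly-charged b/y fragments covering the site shifted down by the loss.
    """
    if psm.charge < 1:
        raise ValueError(f"charge must be >= 1, got {psm.charge}")
    peaks = spec.peaks
    if not peaks:
        return NeutralLossReport(False, (), (), loss_mass)

    def nearest(target: float) -> float | None:
        best = None
        for mz, _ in peaks:
            if abs(mz - target) <= tol and (
                best is None or abs(mz - target) < abs(best - target)
            ):
                best = mz
        return best

    precursor_matches = []
    expected = spec.precursor_mz - loss_mass / psm.charge
    hit = nearest(expected)
    if hit is not None:
        precursor_matches.append((expected, hit))

    fragment_matches = []
    n = len(psm.peptide.sequence)
    site_positions = [pos for pos, _ in psm.peptide.methyl_sites() if pos > 0]
    if n >= 2 and site_positions:
        for label, mz in fragment_ions(psm.peptide, ("b", "y"), charge=1):
            idx = int(label.rstrip("+")[1:])
            covers = any(
                (label.startswith("b") and idx >= site)
                or (label.startswith("y") and idx >= n - site + 1)
                for site in site_positions
            )
            if not covers:
                continue
            expected = mz - loss_mass
            hit = nearest(expected)
            if hit is not None:
                fragment_matches.append((label, expected, hit))

    detected = bool(precursor_matches or fragment_matches)
    return NeutralLossReport(
        detected, tuple(precursor_matches), tuple(fragment_matches), loss_mass
    )


def resolve_trimethyl_acetyl(
    psm: PSM,
    spec: Spectrum | None,
    calib: CalibrationDistribution,
    k_spread: float = 3.0,
    fragment_tol: float = 0.8,
) -> TrimethylAcetylEvidence:
    """Adjudicate a trimethyl-Lys hypothesis against the acetyl alternative.

    The precursor error is computed under both hypotheses and compared with
    the calibration band (center +/- k_spread * spread). Verdicts:

    - ``trimethyl`` if the mass evidence favors trimethyl (only it lies in
      the band), or the neutral loss is present and acetyl is not favored;
    - ``acetyl`` if only acetyl lies in the band and no neutral loss;
    - ``ambiguous`` otherwise (e.g. heavy peptides where both hypotheses fit).

    Only the precursor-level loss peak feeds the verdict: acetyl-Lys minus
    trimethylamine is exactly a Glu residue, so fragment-level loss targets
    collide with ordinary b/y peaks of Glu-containing peptides and would
    produce systematic false positives.
    """
    tri_positions = [pos for pos, deg in psm.peptide.methyl_sites() if deg == 3]
    if not tri_positions:
        raise ValueError("PSM does not carry a trimethyl hypothesis")
    pos = tri_positions[0]

    obs = psm.observed_neutral_mass
    err_tri = ppm_error(obs, peptide_mass(psm.peptide))
    acetyl_pep = psm.peptide.with_mod_replaced(pos, "acetyl")
    err_ac = ppm_error(obs, peptide_mass(acetyl_pep))

    tri_in = calib.in_band(err_tri, k_spread)
    ac_in = calib.in_band(err_ac, k_spread)
    mass_favors_tri = tri_in and not ac_in
    mass_favors_ac = ac_in and not tri_in

    loss = False
    if spec is not None:
        report = detect_neutral_loss(spec, psm, tol=fragment_tol)
        loss = bool(report.precursor_matches)

    if mass_favors_tri:
        verdict = "trimethyl"
    elif loss and not ac_in:
        verdict = "trimethyl"
    elif mass_favors_ac and not loss:
        verdict = "acetyl"
    else:
        verdict = "ambiguous"

    return TrimethylAcetylEvidence(
        spectrum_id=psm.spectrum_id,
        error_vs_trimethyl=err_tri,
        error_vs_acetyl=err_ac,
        calibration_center=calib.center,
        calibration_spread=calib.spread,
        neutral_loss_detected=loss,
        verdict=verdict,
    )
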