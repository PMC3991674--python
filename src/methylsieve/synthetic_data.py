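"""Seeded generator of ground-truth datasets with the statistical structure
the filter pipeline assumes.

Planted proteins are built from tryptic segments so that every planted site
sits at a known coordinate with known covering peptides. Besides true methyl
sites the generator plants the confounders the pipeline must reject:
single-PSM spurious sites, acetyl-Lys peptides reported under the trimethyl
hypothesis, and peptides whose methyl mass is exactly explained by a D->E
substitution. Scores are simulated (forward and decoy score models), never
computed from spectra. All randomness flows through one seeded generator in
a fixed draw order, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset_io import PSM, Spectrum, write_mgf, write_psm_table
from .digestion_decoy import (
    DEFAULT_DECOY_PREFIX,
    ProteinEntry,
    build_target_decoy,
    digest,
    write_fasta,
)
from .masschem import (
    METHYL_MOD_BY_DEGREE,
    TRIMETHYLAMINE_MASS,
    ModifiedPeptide,
    fragment_ions,
    mass_to_mz,
    peptide_mass,
)

__all__ = [
    "SimulationConfig",
    "PlantedEvent",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "write_dataset",
    "truth_eval",
]

# Residues that admit no exact single-substitution isobar for methyl deltas
# (avoids accidental step-5 ambiguity on true sites).
_SAFE_RESIDUES = "FYWHPEQTLM"

# (residue, degree) plan cycled over the planted true sites.
_TRUE_SITE_PLAN = [("K", 3), ("K", 1), ("R", 2), ("K", 2), ("R", 1)]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_true_sites: int = 5
    n_spurious_sites: int = 2
    n_acetyl_mimics: int = 1
    n_substitution_mimics: int = 1
    n_background_proteins: int = 4
    n_background_psms: int = 30
    n_decoy_psms: int = 30
    psm_poisson_mean: float = 8.0
    min_methyl_psms: int = 2
    occupancy_range: tuple[float, float] = (0.3, 1.0)
    forward_score_mean: float = 65.0
    forward_score_sd: float = 15.0
    decoy_score_mean: float = 25.0
    decoy_score_sd: float = 8.0
    ppm_bias: float = 0.0
    ppm_sd: float = 1.5
    neutral_loss_probability: float = 1.0
    fragment_detection_probability: float = 0.95
    noise_peaks_per_spectrum: int = 5
    guarantee_seed_psm: bool = True
    seed_score: float = 50.0
    charge: int = 2
    decoy_prefix: str = DEFAULT_DECOY_PREFIX

    def __post_init__(self):
        for name in (
            "neutral_loss_probability",
            "fragment_detection_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.occupancy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"occupancy_range must be within [0, 1], got {lo, hi}")
        for name in (
            "n_true_sites",
            "n_spurious_sites",
            "n_acetyl_mimics",
            "n_substitution_mimics",
            "n_background_proteins",
            "n_background_psms",
            "n_decoy_psms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_methyl_psms < 1:
            raise ValueError("min_methyl_psms must be >= 1")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted site-level event with its provenance type."""

    kind: str  # true_methyl | spurious | acetyl_mimic | substitution_mimic
    accession: str
    position: int
    residue: str
    degree: int
    occupancy: float
    peptide: str  # zero-missed-cleavage covering peptide
    n_methyl_psms: int = 0
    n_total_psms: int = 0

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.residue)


@dataclass
class GroundTruth:
    proteins: list[ProteinEntry]
    events: list[PlantedEvent]
    provenance: dict[str, str]  # spectrum_id -> event kind / background / decoy

    def true_site_keys(self) -> set[tuple[str, int, str]]:
        return {e.site_key for e in self.events if e.kind == "true_methyl"}


@dataclass
class SimulatedDataset:
    proteins: list[ProteinEntry]  # targets followed by decoys
    psms: list[PSM]
    spectra: list[Spectrum]
    truth: GroundTruth


class _Generator:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.scan = 0
        self.psms: list[PSM] = []
        self.spectra: list[Spectrum] = []
        self.provenance: dict[str, str] = {}

    # -- random primitives ------------------------------------------------

    def _letters(self, n: int, alphabet: str = _SAFE_RESIDUES) -> str:
        idx = self.rng.integers(0, len(alphabet), size=n)
        return "".join(alphabet[i] for i in idx)

    def _trunc_normal(self, mean: float, sd: float, low: float = 0.0) -> float:
        # rejection sampling; deterministic given the rng state
        for _ in range(1000):
            x = self.rng.normal(mean, sd)
            if x >= low:
                return float(x)
        return low

    def _next_spectrum_id(self) -> str:
        self.scan += 1
        return f"scan_{self.scan:05d}"

    # -- protein construction --------------------------------------------

    def _segment(self, min_len: int = 5, max_len: int = 10) -> str:
        n = int(self.rng.integers(min_len, max_len + 1))
        return self._letters(n) + ("K" if self.rng.random() < 0.5 else "R")

    def _site_protein(
        self, residue: str, max_peptide_mass: float | None = None, with_d: bool = False
    ) -> tuple[str, str, int]:
        """Build a protein whose planted site terminates a known tryptic
        segment; returns (sequence, site peptide, site position)."""
        while True:
            n = int(self.rng.integers(6, 11))
            peptide = self._letters(n) + residue
            if with_d:
                d_pos = int(self.rng.integers(1, n))
                peptide = peptide[: d_pos - 1] + "D" + peptide[d_pos:]
            mass = peptide_mass(ModifiedPeptide(peptide))
            if max_peptide_mass is None or mass <= max_peptide_mass:
                break
        pre = self._segment()
        post = self._segment() + self._segment()
        sequence = pre + peptide + post
        position = len(pre) + len(peptide)
        return sequence, peptide, position

    # -- spectra ----------------------------------------------------------

    def _spectrum(
        self,
        spectrum_id: str,
        true_peptide: ModifiedPeptide,
        precursor_mz: float,
        charge: int,
        with_neutral_loss: bool,
        noise_only: bool = False,
    ) -> Spectrum:
        peaks: list[tuple[float, float]] = []
        if not noise_only and len(true_peptide.sequence) >= 2:
            for _, mz in fragment_ions(true_peptide, ("b", "y"), charge=1):
                if self.rng.random() < self.cfg.fragment_detection_probability:
                    peaks.append((mz, float(self.rng.uniform(20.0, 100.0))))
        for _ in range(self.cfg.noise_peaks_per_spectrum):
            peaks.append(
                (
                    float(self.rng.uniform(100.0, 1300.0)),
                    float(self.rng.uniform(1.0, 10.0)),
                )
            )
        loss_target = precursor_mz - TRIMETHYLAMINE_MASS / charge
        if with_neutral_loss:
            peaks.append((loss_target, 30.0))
        else:
            # honor the planted "no loss" label: evict chance peaks from the
            # precursor-loss window so provenance stays truthful
            peaks = [p for p in peaks if abs(p[0] - loss_target) > 1.0]
        return Spectrum(spectrum_id, precursor_mz, charge, tuple(peaks))

    # -- PSM emission ------------------------------------------------------

    def _emit_psm(
        self,
        reported: ModifiedPeptide,
        true_mass: float,
        accession: str,
        score: float,
        kind: str,
        run_id: str,
        is_decoy: bool = False,
        true_peptide: ModifiedPeptide | None = None,
        neutral_loss: bool = False,
        noise_only: bool = False,
    ) -> PSM:
        charge = self.cfg.charge
        ppm = self.rng.normal(self.cfg.ppm_bias, self.cfg.ppm_sd)
        observed_mass = true_mass * (1.0 + ppm * 1e-6)
        obs_mz = mass_to_mz(observed_mass, charge)
        spectrum_id = self._next_spectrum_id()
        psm = PSM(
            spectrum_id=spectrum_id,
            run_id=run_id,
            peptide=ModifiedPeptide(reported.sequence, reported.mods, charge),
            observed_precursor_mz=obs_mz,
            charge=charge,
            score=round(score, 2),
            rank=1,
            homology_pass=True,
            protein_accessions=(accession,),
            is_decoy=is_decoy,
        )
        spec = self._spectrum(
            spectrum_id,
            true_peptide if true_peptide is not None else psm.peptide,
            obs_mz,
            charge,
            with_neutral_loss=neutral_loss,
            noise_only=noise_only,
        )
        self.psms.append(psm)
        self.spectra.append(spec)
        self.provenance[spectrum_id] = kind
        return psm

    def _run_id(self) -> str:
        return f"run{1 + self.scan % 2}"

    def _forward_score(self, floor: float | None = None) -> float:
        if floor is not None:
            return self._trunc_normal(
                self.cfg.forward_score_mean, self.cfg.forward_score_sd, low=floor
            )
        return self._trunc_normal(
            self.cfg.forward_score_mean, self.cfg.forward_score_sd
        )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate proteome, PSM table, spectra, and retained ground truth."""
    gen = _Generator(cfg)
    rng = gen.rng
    targets: list[ProteinEntry] = []
    events: list[PlantedEvent] = []
    acc_counter = 0

    def next_accession() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:04d}"

    separability_guard = 1700.0  # keep confusable peptides below the 10 ppm limit

    # --- plant site proteins (draw order: true, spurious, acetyl, subst) --
    plans: list[tuple[str, str, int, bool]] = []
    for i in range(cfg.n_true_sites):
        residue, degree = _TRUE_SITE_PLAN[i % len(_TRUE_SITE_PLAN)]
        plans.append(("true_methyl", residue, degree, False))
    for _ in range(cfg.n_spurious_sites):
        plans.append(("spurious", "K", 1, False))
    for _ in range(cfg.n_acetyl_mimics):
        plans.append(("acetyl_mimic", "K", 3, False))
    for _ in range(cfg.n_substitution_mimics):
        plans.append(("substitution_mimic", "K", 1, True))

    site_info = []  # (kind, accession, peptide, position, residue, degree, next_segment)
    for kind, residue, degree, with_d in plans:
        acc = next_accession()
        guard = separability_guard if degree == 3 or kind == "acetyl_mimic" else None
        sequence, peptide, position = gen._site_protein(
            residue, max_peptide_mass=guard, with_d=with_d
        )
        targets.append(ProteinEntry(acc, f"synthetic {kind}", sequence))
        site_info.append((kind, acc, peptide, position, residue, degree))

    for _ in range(cfg.n_background_proteins):
        acc = next_accession()
        seq = gen._segment() + gen._segment() + gen._segment() + gen._letters(8)
        targets.append(ProteinEntry(acc, "synthetic background", seq))

    proteins = build_target_decoy(targets, cfg.decoy_prefix)
    by_acc = {p.accession: p for p in proteins}

    # --- PSMs per planted event ------------------------------------------
    for kind, acc, peptide, position, residue, degree in site_info:
        protein = by_acc[acc]
        mod_name = METHYL_MOD_BY_DEGREE[degree]
        site_in_pep = len(peptide)  # site terminates its segment
        # the 1-missed-cleavage extension of the covering peptide
        extension = next(
            (
                d.sequence
                for d in digest(protein, max_missed=1)
                if d.start == position - len(peptide) + 1
                and d.missed_cleavages == 1
            ),
            None,
        )

        if kind == "true_methyl":
            occupancy = float(rng.uniform(*cfg.occupancy_range))
            n_total = max(
                cfg.min_methyl_psms, int(rng.poisson(cfg.psm_poisson_mean))
            )
            n_methyl = int(rng.binomial(n_total, occupancy))
            n_methyl = min(max(n_methyl, cfg.min_methyl_psms), n_total)
            for i in range(n_methyl):
                use_ext = extension is not None and i % 2 == 1
                seq = extension if use_ext else peptide
                reported = ModifiedPeptide(seq, ((site_in_pep, mod_name),))
                floor = cfg.seed_score if (cfg.guarantee_seed_psm and i == 0) else None
                loss = degree == 3 and rng.random() < cfg.neutral_loss_probability
                gen._emit_psm(
                    reported,
                    peptide_mass(reported),
                    acc,
                    gen._forward_score(floor),
                    kind,
                    gen._run_id(),
                    neutral_loss=loss,
                )
            for _ in range(n_total - n_methyl):
                unmod = ModifiedPeptide(peptide)
                gen._emit_psm(
                    unmod,
                    peptide_mass(unmod),
                    acc,
                    gen._forward_score(),
                    "unmodified_covering",
                    gen._run_id(),
                )
            events.append(
                PlantedEvent(
                    kind, acc, position, residue, degree, occupancy, peptide,
                    n_methyl_psms=n_methyl, n_total_psms=n_total,
                )
            )

        elif kind == "spurious":
            reported = ModifiedPeptide(peptide, ((site_in_pep, mod_name),))
            gen._emit_psm(
                reported,
                peptide_mass(reported),
                acc,
                gen._forward_score(cfg.seed_score if cfg.guarantee_seed_psm else None),
                kind,
                gen._run_id(),
            )
            events.append(
                PlantedEvent(
                    kind, acc, position, residue, degree, 0.0, peptide,
                    n_methyl_psms=1, n_total_psms=1,
                )
            )

        elif kind == "acetyl_mimic":
            n = max(cfg.min_methyl_psms, int(rng.poisson(3.0)))
            reported = ModifiedPeptide(peptide, ((site_in_pep, "trimethyl"),))
            true_pep = ModifiedPeptide(peptide, ((site_in_pep, "acetyl"),))
            true_mass = peptide_mass(true_pep)
            for i in range(n):
                floor = cfg.seed_score if (cfg.guarantee_seed_psm and i == 0) else None
                gen._emit_psm(
                    reported,
                    true_mass,
                    acc,
                    gen._forward_score(floor),
                    kind,
                    gen._run_id(),
                    true_peptide=true_pep,
                    neutral_loss=False,
                )
            events.append(
                PlantedEvent(
                    kind, acc, position, residue, degree, 0.0, peptide,
                    n_methyl_psms=n, n_total_psms=n,
                )
            )

        elif kind == "substitution_mimic":
            # The reported peptide carries a D whose D->E substitution is
            # exactly isobaric with the claimed monomethyl.
            n = max(cfg.min_methyl_psms, int(rng.poisson(3.0)))
            reported = ModifiedPeptide(peptide, ((site_in_pep, mod_name),))
            for i in range(n):
                floor = cfg.seed_score if (cfg.guarantee_seed_psm and i == 0) else None
                gen._emit_psm(
                    reported,
                    peptide_mass(reported),
                    acc,
                    gen._forward_score(floor),
                    kind,
                    gen._run_id(),
                )
            events.append(
                PlantedEvent(
                    kind, acc, position, residue, degree, 0.0, peptide,
                    n_methyl_psms=n, n_total_psms=n,
                )
            )

    # --- background unmodified PSMs (calibration population) -------------
    background = [p for p in targets if p.description == "synthetic background"]
    if background and cfg.n_background_psms:
        candidates = []
        for protein in background:
            for d in digest(protein, max_missed=0, min_length=6):
                candidates.append((protein.accession, d.sequence))
        for _ in range(cfg.n_background_psms):
            acc, seq = candidates[int(rng.integers(0, len(candidates)))]
            pep = ModifiedPeptide(seq)
            gen._emit_psm(
                pep,
                peptide_mass(pep),
                acc,
                gen._forward_score(),
                "background",
                gen._run_id(),
            )

    # --- decoy methyl PSMs ------------------------------------------------
    decoys = [p for p in proteins if p.is_decoy]
    if decoys and cfg.n_decoy_psms:
        decoy_candidates = []
        for protein in decoys:
            for d in digest(protein, max_missed=0, min_length=6):
                if d.sequence[-1] in "KR":
                    decoy_candidates.append((protein.accession, d.sequence))
        for _ in range(cfg.n_decoy_psms):
            acc, seq = decoy_candidates[int(rng.integers(0, len(decoy_candidates)))]
            pep = ModifiedPeptide(seq, ((len(seq), "monomethyl"),))
            gen._emit_psm(
                pep,
                peptide_mass(pep),
                acc,
                gen._trunc_normal(cfg.decoy_score_mean, cfg.decoy_score_sd),
                "decoy",
                gen._run_id(),
                is_decoy=True,
                noise_only=True,
            )

    truth = GroundTruth(proteins=targets, events=events, provenance=gen.provenance)
    return SimulatedDataset(
        proteins=proteins, psms=gen.psms, spectra=gen.spectra, truth=truth
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / PSM TSV / MGF / truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "psms": outdir / "psms.tsv",
        "mgf": outdir / "spectra.mgf",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.proteins, paths["fasta"])
    write_psm_table(ds.psms, paths["psms"])
    write_mgf(ds.spectra, paths["mgf"])
    truth_doc = {
        "events": [asdict(e) for e in ds.truth.events],
        "provenance": ds.truth.provenance,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True) + "\n")
    return paths


def truth_eval(
    validated_sites: Sequence,
    truth: GroundTruth,
    audit: Mapping | None = None,
) -> dict:
    """Exact set comparison of validated sites against planted true sites.

    ``validated_sites`` may be site keys or objects with a ``key`` attribute.
    When the pipeline audit log is provided, each planted confounder is
    annotated with the step at which it was removed.
    """
    keys = {
        s.key if hasattr(s, "key") else tuple(s) for s in validated_sites
    }
    true_keys = truth.true_site_keys()
    tp = len(keys & true_keys)
    precision = tp / len(keys) if keys else (1.0 if not true_keys else 0.0)
    recall = tp / len(true_keys) if true_keys else 1.0

    outcomes = []
    removed5 = {tuple(k) for k in (audit or {}).get("removed_step5_substitution", [])}
    removed6 = {tuple(k) for k in (audit or {}).get("removed_step6_acetyl", [])}
    removed4 = {tuple(k) for k in (audit or {}).get("removed_step4_single_psm", [])}
    for event in truth.events:
        key = event.site_key
        if key in keys:
            outcome = "validated"
        elif key in removed4:
            outcome = "removed_step4"
        elif key in removed5:
            outcome = "removed_step5"
        elif key in removed6:
            outcome = "removed_step6"
        else:
            outcome = "not_validated"
        outcomes.append({"kind": event.kind, "site": list(key), "outcome": outcome})

    return {
        "precision": precision,
        "recall": recall,
        "n_validated": len(keys),
        "n_true": len(true_keys),
        "outcomes": outcomes,
    }
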