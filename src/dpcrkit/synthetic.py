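"""Synthetic droplet, dilution-series and timeseries data with known truth.

Every input the pipeline consumes can be generated here from a declared
ground truth, so the full stack — Poisson partition inversion, linkage
analysis, double normalisation, detection limits, kinetics fitting — is
testable end to end without any instrument data.

Droplet simulation works at the molecule level: each outcome class at the
locus contributes molecular species to a given assay (e.g. a wildtype locus
carries both edge probe sites on one molecule; an unresolved DSB
contributes independent 5' and 3' flanking fragments), species are loaded
into droplets by independent Poisson placement, and droplets are classified
by their contents. Optional per-molecule shearing between the two probed
sites of a linked species emulates random genomic-DNA fragmentation
(default 0: gDNA preps show minimal fragmentation between ~200 bp probes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assays import AssayPanelConfig
from .detection_limits import DilutionSeries
from .dpcr_core import DropletWellCounts
from .errors import InputError
from .kinetics import STATE_NAMES, RateCoefficients, simulate_model

__all__ = [
    "LocusGroundTruth",
    "simulate_droplet_well",
    "simulate_panel_wells",
    "simulate_timeseries",
    "simulate_dilution_series",
]

OUTCOME_CLASSES = (
    "wt", "indel", "large_del_5", "large_del_3", "dsb", "other_loss", "ti"
)


@dataclass(frozen=True)
class LocusGroundTruth:
    """True outcome-class composition of an edited locus population.

    Class fractions must be non-negative and sum to <= 1; any remainder is
    treated as fully ablated loci (no amplifiable sequence at all).
    ``other_loss`` models aberrations (inversions, large insertions) that
    destroy the cut-site amplicon but leave both flanking amplicons present
    and physically linked. ``aneu_p_factor`` / ``aneu_q_factor`` scale the
    sub-telomeric arm copy numbers (1.0 = euploid).
    """

    wt: float = 1.0
    indel: float = 0.0
    large_del_5: float = 0.0
    large_del_3: float = 0.0
    dsb: float = 0.0
    other_loss: float = 0.0
    ti: float = 0.0
    donor_episomes_per_cell: float = 0.0
    ploidy: int = 2
    cells_assayed: float = 5000.0
    aneu_p_factor: float = 1.0
    aneu_q_factor: float = 1.0
    shear_probability: float = 0.0

    def __post_init__(self) -> None:
        fracs = [getattr(self, c) for c in OUTCOME_CLASSES]
        if any(f < 0 for f in fracs):
            raise InputError("class fractions must be non-negative")
        if sum(fracs) > 1 + 1e-9:
            raise InputError("class fractions must sum to <= 1")
        if self.cells_assayed < 0 or self.donor_episomes_per_cell < 0:
            raise InputError("cells and donor copies must be non-negative")
        if not 0 <= self.shear_probability <= 1:
            raise InputError("shear_probability must lie in [0, 1]")

    @property
    def locus_copies(self) -> float:
        return self.ploidy * self.cells_assayed

    def mock(self) -> "LocusGroundTruth":
        """The matched unedited control: all-wildtype, no donor."""
        return replace(
            self, wt=1.0, indel=0.0, large_del_5=0.0, large_del_3=0.0,
            dsb=0.0, other_loss=0.0, ti=0.0, donor_episomes_per_cell=0.0,
            aneu_p_factor=1.0, aneu_q_factor=1.0,
        )


def _species_lambdas(truth: LocusGroundTruth, assay_role: str,
                     n_droplets: int) -> tuple[float, float, float]:
    """(linked, FAM-only, HEX-only) mean molecules per droplet for a role."""
    lam_locus = truth.locus_copies / n_droplets

    if assay_role == "edge":
        # FAM = cleavage probe (wildtype only); HEX = distal probe
        # (wildtype + indel); other classes abolish the amplicon.
        linked = truth.wt * lam_locus
        fam = 0.0
        hex_ = truth.indel * lam_locus
    elif assay_role == "flanking":
        # FAM = 5' amplicon, HEX = 3' amplicon. Intact or internally
        # rearranged loci keep both sides on one molecule; a DSB yields two
        # independent fragments; one-sided large deletions drop a side.
        intact = truth.wt + truth.indel + truth.other_loss + truth.ti
        linked = intact * lam_locus
        fam = (truth.dsb + truth.large_del_3) * lam_locus
        hex_ = (truth.dsb + truth.large_del_5) * lam_locus
    elif assay_role == "reference":
        linked, fam, hex_ = 0.0, lam_locus, 0.0
    elif assay_role == "aneuploidy":
        # p and q sub-telomeric fragments are megabases apart: never on one
        # extracted gDNA molecule.
        linked = 0.0
        fam = truth.aneu_p_factor * lam_locus
        hex_ = truth.aneu_q_factor * lam_locus
    elif assay_role == "ti_junction":
        linked, fam, hex_ = 0.0, truth.ti * lam_locus, 0.0
    elif assay_role in ("donor_total", "donor_total_digested"):
        donor = (
            truth.ti * lam_locus
            + truth.donor_episomes_per_cell * truth.cells_assayed / n_droplets
        )
        linked, fam, hex_ = 0.0, donor, 0.0
    else:
        raise InputError(f"unknown assay role {assay_role!r}")

    if truth.shear_probability > 0 and linked > 0:
        sheared = linked * truth.shear_probability
        fam += sheared
        hex_ += sheared
        linked -= sheared
    return linked, fam, hex_


def simulate_droplet_well(
    truth: LocusGroundTruth,
    assay_role: str,
    n_droplets: int = 20000,
    seed: int | np.random.Generator = 0,
    well_id: str = "",
    sample_id: str = "",
    assay_id: str = "",
) -> DropletWellCounts:
    """Simulate one classified droplet well for an assay role.

    Molecular species implied by the ground truth are loaded by independent
    Poisson placement; each droplet is classified by whether it received at
    least one FAM-bearing and/or HEX-bearing molecule. Deterministic given
    ``seed``.
    """
    if n_droplets < 100:
        raise InputError("n_droplets must be >= 100")
    lam_l, lam_f, lam_h = _species_lambdas(truth, assay_role, n_droplets)

    # class probabilities follow from Poisson presence/absence
    p_neg = math.exp(-(lam_l + lam_f + lam_h))
    p_fam_only = math.exp(-(lam_l + lam_h)) - p_neg
    p_hex_only = math.exp(-(lam_l + lam_f)) - p_neg
    p_double = 1.0 - p_neg - p_fam_only - p_hex_only

    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_double, n_fam, n_hex, n_neg = rng.multinomial(
        n_droplets, [p_double, p_fam_only, p_hex_only, p_neg]
    )
    return DropletWellCounts(
        n_total=n_droplets,
        n_double=int(n_double),
        n_fam_only=int(n_fam),
        n_hex_only=int(n_hex),
        n_negative=int(n_neg),
        well_id=well_id,
        sample_id=sample_id,
        assay_id=assay_id,
    )


def simulate_panel_wells(
    truth: LocusGroundTruth,
    panel: AssayPanelConfig,
    sample_id: str,
    n_droplets: int = 20000,
    n_replicates: int = 3,
    seed: int = 0,
    include_mock: bool = True,
) -> list[DropletWellCounts]:
    """Simulate replicate wells for every assay in a panel, plus the mock.

    Donor-specific assays are skipped for the mock sample (it carries no
    donor). Well seeds are spawned from ``seed`` so each well is
    independent yet the whole set is reproducible.
    """
    rng = np.random.default_rng(seed)
    wells: list[DropletWellCounts] = []
    jobs = [(sample_id, truth)]
    if include_mock:
        jobs.append((panel.mock_sample_id, truth.mock()))
    for sid, tr in jobs:
        for assay in panel.assays:
            if sid == panel.mock_sample_id and assay.role in (
                "ti_junction", "donor_total", "donor_total_digested"
            ):
                continue
            for rep in range(1, n_replicates + 1):
                wells.append(
                    simulate_droplet_well(
                        tr, assay.role, n_droplets, rng,
                        well_id=f"{sid}:{assay.id}:r{rep}",
                        sample_id=sid,
                        assay_id=assay.id,
                    )
                )
    return wells


def simulate_timeseries(
    coeffs: RateCoefficients,
    timepoints,
    n_replicates: int = 3,
    noise_sd: float = 2.0,
    seed: int = 0,
    states=STATE_NAMES,
    delay_form: str = "exponential",
) -> pd.DataFrame:
    """Replicate editing-outcome timeseries from the kinetics model.

    Evaluates the model at ``timepoints`` for every condition in ``coeffs``
    and adds independent Gaussian observation noise (sd in percentage
    points, clipped at 0) per replicate. Returns the tidy frame
    ``condition, timepoint_h, replicate, state, percent``.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for cond in sorted(coeffs.conditions):
        traj = simulate_model(coeffs.condition(cond), t, delay_form=delay_form)
        for state in states:
            clean = traj.state(state)
            for rep in range(1, n_replicates + 1):
                noisy = clean + rng.normal(0.0, noise_sd, size=t.size) \
                    if noise_sd > 0 else clean.copy()
                noisy = np.clip(noisy, 0.0, None)
                for ti, tp in enumerate(t):
                    rows.append(
                        {
                            "condition": cond,
                            "timepoint_h": float(tp),
                            "replicate": rep,
                            "state": state,
                            "percent": float(noisy[ti]),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_dilution_series(
    levels,
    noise_sd: float = 0.005,
    n_replicates: int = 4,
    seed: int = 0,
) -> DilutionSeries:
    """Synthetic mutant-fraction dilution series with Gaussian noise.

    ``levels`` are true mutant fractions in [0, 1]; observed replicate
    values are level + N(0, noise_sd), floored at 0 — emulating reference-
    normalised, dilution-corrected measurements of a synthetic mutant
    cassette diluted into wildtype.
    """
    levels = sorted((float(x) for x in levels), reverse=True)
    if any(not 0 <= x <= 1 for x in levels):
        raise InputError("levels must lie in [0, 1]")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    observed = []
    for lv in levels:
        vals = lv + rng.normal(0.0, noise_sd, size=n_replicates) \
            if noise_sd > 0 else np.full(n_replicates, lv)
        observed.append(tuple(np.clip(vals, 0.0, None)))
    return DilutionSeries(
        expected_fraction=tuple(levels), observed=tuple(observed)
    )
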