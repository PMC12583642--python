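"""Editing-outcome assay logic and the double normalisation.

Four duplex droplet-PCR assay families, each read against one or more
reference assays and an unedited mock control, decompose the edited locus
into absolute outcome classes:

* **edge** — one amplicon spanning the cut site with a cleavage-site probe
  (FAM) directly over the expected cut and a distal probe (HEX) ~25 bp away.
  Indels abolish FAM binding but keep HEX; larger aberrations abolish the
  whole amplicon. Yields wildtype / indel / total-copy-loss fractions.
* **flanking** — two amplicons on either side of the cut site (FAM = 5',
  HEX = 3') in one well. Loss of physical linkage between the two probed
  sequences marks an unresolved double-strand break; loss of one side's
  copies marks end trimming, labelled a large deletion once the processing
  reaches beyond the configured primer/probe distance (20-30 bp).
* **aneuploidy** — sub-telomeric p-arm (FAM) and q-arm (HEX) copy assays
  reporting signed arm copy-number change.
* **targeted integration / episomal** — a junction assay (genome primer +
  donor primer) counts on-target integrations; a donor-internal assay counts
  every donor copy, integrated or episomal; optional single-cut digestion
  resolves concatemers.

Double normalisation: each assay's copies are first divided by the mean of
the reference-assay copies in the same well set, then that ratio is divided
by the same ratio measured in the unedited mock. The second step cancels
per-assay efficiency differences so the result is an absolute fraction of
loci. Donor-specific assays skip the mock term (the mock carries no donor)
and are normalised to references only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dpcr_core import DropletWellCounts, estimate_lambda, estimate_linkage
from .errors import ConfigurationError, InputError

__all__ = [
    "AssayPanelConfig",
    "AssayEntry",
    "SampleMeta",
    "NormalisedFraction",
    "LocusIntegritySummary",
    "double_normalise",
    "edge_from_fractions",
    "flanking_from_fractions",
    "edge_summary",
    "flanking_summary",
    "aneuploidy_summary",
    "ti_summary",
    "combine_summary",
    "well_copies",
    "mean_reference_copies",
]

logger = logging.getLogger(__name__)

VALID_ROLES = {
    "edge",
    "flanking",
    "reference",
    "aneuploidy",
    "ti_junction",
    "donor_total",
    "donor_total_digested",
}

#: End processing beyond this primer/probe distance from the cut site is
#: labelled a large deletion rather than trimming.
DEFAULT_LARGE_DELETION_THRESHOLD_BP = 25


# ---------------------------------------------------------------------------
# panel configuration


@dataclass(frozen=True)
class AssayEntry:
    id: str
    role: str
    channels: Mapping[str, str] = field(default_factory=dict)
    distance_bp: float | None = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ConfigurationError(
                f"assay {self.id!r}: unknown role {self.role!r}; "
                f"valid roles: {sorted(VALID_ROLES)}"
            )


@dataclass(frozen=True)
class SampleMeta:
    id: str
    condition: str = ""
    timepoint_h: float | None = None


@dataclass
class AssayPanelConfig:
    """Declarative map from assays to roles and channel semantics.

    Duplex channel conventions: edge FAM = cleavage probe, HEX = distal
    probe; flanking FAM = 5' amplicon, HEX = 3' amplicon; aneuploidy
    FAM = p arm, HEX = q arm. Single-target assays (reference, junction,
    donor) are read on FAM.
    """

    locus: str
    assays: list[AssayEntry]
    mock_sample_id: str = "mock"
    ploidy: int = 2
    dsb_statistic: str = "copresent"
    flanking_valid: bool = True
    large_deletion_threshold_bp: float = DEFAULT_LARGE_DELETION_THRESHOLD_BP
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not any(a.role == "reference" for a in self.assays):
            raise ConfigurationError("panel needs at least one reference assay")
        for a in self.assays:
            if a.role == "edge" and not (
                a.channels.get("fam") and a.channels.get("hex")
            ):
                raise ConfigurationError(
                    f"edge assay {a.id!r} must define both FAM and HEX semantics"
                )
        if self.dsb_statistic not in {"copresent", "mean", "min"}:
            raise ConfigurationError(
                f"unknown dsb_statistic {self.dsb_statistic!r}"
            )
        if self.ploidy < 1:
            raise ConfigurationError("ploidy must be >= 1")

    def by_role(self, role: str) -> list[AssayEntry]:
        return [a for a in self.assays if a.role == role]

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.id == sample_id:
                return s
        return SampleMeta(id=sample_id)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssayPanelConfig":
        try:
            assays = [
                AssayEntry(
                    id=str(a["id"]),
                    role=str(a["role"]),
                    channels=dict(a.get("channels", {})),
                    distance_bp=a.get("distance_bp"),
                )
                for a in d["assays"]
            ]
            samples = [
                SampleMeta(
                    id=str(s["id"]),
                    condition=str(s.get("condition", "")),
                    timepoint_h=s.get("timepoint_h"),
                )
                for s in d.get("samples", [])
            ]
            return cls(
                locus=str(d["locus"]),
                assays=assays,
                mock_sample_id=str(d.get("mock_sample_id", "mock")),
                ploidy=int(d.get("ploidy", 2)),
                dsb_statistic=str(d.get("dsb_statistic", "copresent")),
                flanking_valid=bool(d.get("flanking_valid", True)),
                large_deletion_threshold_bp=float(
                    d.get("large_deletion_threshold_bp", DEFAULT_LARGE_DELETION_THRESHOLD_BP)
                ),
                samples=samples,
            )
        except KeyError as exc:
            raise ConfigurationError(f"panel config missing key: {exc}") from exc


# ---------------------------------------------------------------------------
# normalisation primitives


@dataclass(frozen=True)
class NormalisedFraction:
    """A double-normalised fraction of loci (dimensionless, >= 0)."""

    value: float
    sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.value < 0 or self.sd < 0:
            raise InputError("normalised fraction and sd must be non-negative")

    @classmethod
    def from_replicates(cls, values: Sequence[float]) -> "NormalisedFraction":
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(value=float(arr.mean()), sd=sd, n_replicates=arr.size)


def double_normalise(
    assay_copies: float,
    ref_copies: Sequence[float],
    mock_assay_copies: float,
    mock_ref_copies: Sequence[float],
) -> NormalisedFraction:
    """Normalise assay copies against references, then against the mock.

    value = (assay / mean(refs)) / (mock_assay / mean(mock_refs)).
    """
    ref_copies = list(ref_copies)
    mock_ref_copies = list(mock_ref_copies)
    if not ref_copies or not mock_ref_copies:
        raise InputError("reference copy lists must be non-empty")
    mean_ref = float(np.mean(ref_copies))
    mean_mock_ref = float(np.mean(mock_ref_copies))
    if mean_ref <= 0 or mean_mock_ref <= 0 or mock_assay_copies <= 0:
        raise InputError("reference and mock copies must be positive")
    if assay_copies < 0:
        raise InputError("assay copies must be non-negative")
    value = (assay_copies / mean_ref) / (mock_assay_copies / mean_mock_ref)
    return NormalisedFraction(value=value)


def well_copies(well: DropletWellCounts, channel: str = "fam") -> float:
    """Absolute copies in one channel of a well (lambda * n_total)."""
    if channel == "fam":
        lam = estimate_lambda(well.n_fam_negative, well.n_total)
    elif channel == "hex":
        lam = estimate_lambda(well.n_hex_negative, well.n_total)
    else:
        raise InputError(f"unknown channel {channel!r}")
    return lam * well.n_total


def mean_reference_copies(
    ref_wells: Sequence[DropletWellCounts], channel: str = "fam"
) -> float:
    if not ref_wells:
        raise InputError("at least one reference well is required")
    return float(np.mean([well_copies(w, channel) for w in ref_wells]))


def _dn(
    copies: float,
    ref_wells: Sequence[DropletWellCounts],
    mock_copies: float,
    mock_ref_wells: Sequence[DropletWellCounts],
) -> float:
    return double_normalise(
        copies,
        [mean_reference_copies(ref_wells)],
        mock_copies,
        [mean_reference_copies(mock_ref_wells)],
    ).value


# ---------------------------------------------------------------------------
# per-assay summaries (single replicate, well level)


def edge_from_fractions(f_fam: float, f_hex: float) -> dict[str, float]:
    """Edge-assay class percentages from double-normalised channel fractions."""
    return {
        "wt": 100.0 * f_fam,
        "indel": 100.0 * max(0.0, f_hex - f_fam),
        "other": 100.0 * max(0.0, 1.0 - f_hex),
        "f_fam": f_fam,
        "f_hex": f_hex,
    }


def edge_summary(
    edge_well: DropletWellCounts,
    ref_wells: Sequence[DropletWellCounts],
    mock_edge_well: DropletWellCounts,
    mock_ref_wells: Sequence[DropletWellCounts],
) -> dict[str, float]:
    """Wildtype / indel / other-aberration percentages from the edge assay.

    FAM (cleavage probe) survives only on wildtype sequence; HEX (distal
    probe) survives wildtype and indels; larger aberrations abolish both.
    """
    f_fam = _dn(
        well_copies(edge_well, "fam"), ref_wells,
        well_copies(mock_edge_well, "fam"), mock_ref_wells,
    )
    f_hex = _dn(
        well_copies(edge_well, "hex"), ref_wells,
        well_copies(mock_edge_well, "hex"), mock_ref_wells,
    )
    return edge_from_fractions(f_fam, f_hex)


def _dsb_from_fractions(
    f5: float, f3: float, f_linked: float, statistic: str
) -> float:
    """Unresolved-DSB fraction from flanking side and linkage fractions.

    ``copresent`` (default) compares the fraction of loci with *both* sides
    present (f5 + f3 - 1) against the linked fraction, so one-sided copy
    loss does not inflate the DSB estimate. ``mean`` and ``min`` compare the
    averaged or the smaller side fraction instead.
    """
    if statistic == "copresent":
        both = f5 + f3 - 1.0
    elif statistic == "mean":
        both = 0.5 * (f5 + f3)
    elif statistic == "min":
        both = min(f5, f3)
    else:
        raise ConfigurationError(f"unknown dsb_statistic {statistic!r}")
    return max(0.0, both - f_linked)


def flanking_from_fractions(
    f5: float, f3: float, f_linked: float, dsb_statistic: str = "copresent"
) -> dict[str, float]:
    """Flanking-assay percentages from double-normalised fractions."""
    dsb = _dsb_from_fractions(f5, f3, f_linked, dsb_statistic)
    return {
        "trim5": 100.0 * max(0.0, 1.0 - f5),
        "trim3": 100.0 * max(0.0, 1.0 - f3),
        "dsb": 100.0 * dsb,
        "linked": 100.0 * f_linked,
        "f5": f5,
        "f3": f3,
    }


def flanking_summary(
    f5_well: DropletWellCounts,
    f3_well: DropletWellCounts,
    ref_wells: Sequence[DropletWellCounts],
    mock_f5_well: DropletWellCounts,
    mock_f3_well: DropletWellCounts,
    mock_ref_wells: Sequence[DropletWellCounts],
    dsb_statistic: str = "copresent",
) -> dict[str, float]:
    """Trimming / large-deletion / unresolved-DSB percentages.

    The default physical layout carries both flanking amplicons in one
    duplex well (FAM = 5', HEX = 3'), which is required for the linkage
    (DSB) readout; pass the same well as ``f5_well`` and ``f3_well``.
    """
    duplex = f5_well is f3_well or (
        f5_well.well_id == f3_well.well_id and f5_well.well_id != ""
    )
    if not duplex:
        raise ConfigurationError(
            "flanking DSB readout requires both probes in one duplex well"
        )
    f5 = _dn(
        well_copies(f5_well, "fam"), ref_wells,
        well_copies(mock_f5_well, "fam"), mock_ref_wells,
    )
    f3 = _dn(
        well_copies(f3_well, "hex"), ref_wells,
        well_copies(mock_f3_well, "hex"), mock_ref_wells,
    )
    link = estimate_linkage(f5_well).lambda_link * f5_well.n_total
    mock_link = estimate_linkage(mock_f5_well).lambda_link * mock_f5_well.n_total
    f_linked = _dn(link, ref_wells, mock_link, mock_ref_wells)
    return flanking_from_fractions(f5, f3, f_linked, dsb_statistic)


def aneuploidy_summary(
    aneu_well: DropletWellCounts,
    ref_wells: Sequence[DropletWellCounts],
    mock_aneu_well: DropletWellCounts,
    mock_ref_wells: Sequence[DropletWellCounts],
) -> dict[str, float]:
    """Signed percent copy-number change of the p (FAM) and q (HEX) arms.

    Negative = arm loss, positive = gain (balanced segregated translocations
    appear as a gain).
    """
    f_p = _dn(
        well_copies(aneu_well, "fam"), ref_wells,
        well_copies(mock_aneu_well, "fam"), mock_ref_wells,
    )
    f_q = _dn(
        well_copies(aneu_well, "hex"), ref_wells,
        well_copies(mock_aneu_well, "hex"), mock_ref_wells,
    )
    return {
        "aneu_p_change": 100.0 * (f_p - 1.0),
        "aneu_q_change": 100.0 * (f_q - 1.0),
    }


def ti_summary(
    ti_well: DropletWellCounts,
    donor_total_well: DropletWellCounts,
    ref_wells: Sequence[DropletWellCounts],
    ploidy: int = 2,
    digested_donor_well: DropletWellCounts | None = None,
) -> dict[str, float]:
    """Targeted-integration, episomal-donor and vector-copy-number metrics.

    Donor-specific assays have no counterpart in the unedited mock, so they
    are normalised against the reference assays only. ``concatemer_ratio``
    compares vector copy number after a single-cut digestion inside the
    donor with the undigested value; ~1 means no concatemers.
    """
    ref = mean_reference_copies(ref_wells)
    if ref <= 0:
        raise InputError("reference copies must be positive")
    junction = well_copies(ti_well, "fam")
    donor_total = well_copies(donor_total_well, "fam")
    ti_fraction = junction / ref
    vcn = ploidy * donor_total / ref
    episomal = max(0.0, donor_total - junction)
    out = {
        "targeted_integration": 100.0 * ti_fraction,
        "episomal_copies": episomal,
        "vcn": vcn,
        "concatemer_ratio": float("nan"),
    }
    if digested_donor_well is not None:
        vcn_dig = ploidy * well_copies(digested_donor_well, "fam") / ref
        out["concatemer_ratio"] = vcn_dig / vcn if vcn > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# combined locus summary


@dataclass
class LocusIntegritySummary:
    """Absolute genome-copy percentages of each outcome class for one sample.

    ``total`` sums the six stacked classes; accumulated assay error can push
    it off 100, and ``flag`` is set when it leaves [90, 110]. Trimming is
    reported alongside the large-deletion class it feeds (the stacked
    summary uses ``large_del`` only).
    """

    sample_id: str
    condition: str = ""
    timepoint_h: float | None = None
    wt: float = 0.0
    indel: float = 0.0
    large_del: float = 0.0
    dsb: float = 0.0
    other_aberration: float = 0.0
    targeted_integration: float = 0.0
    trim5: float = 0.0
    trim3: float = 0.0
    aneu_p_change: float = 0.0
    aneu_q_change: float = 0.0
    vcn: float = float("nan")
    episomal_copies: float = float("nan")
    concatemer_ratio: float = float("nan")
    total: float = 0.0
    flag: bool = False
    sd: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 1

    STATE_FIELDS = ("wt", "indel", "large_del", "dsb", "other_aberration",
                    "targeted_integration")

    def as_tidy_rows(self) -> list[dict]:
        rows = []
        for state in self.STATE_FIELDS:
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "condition": self.condition,
                    "timepoint_h": self.timepoint_h,
                    "state": state,
                    "percent": getattr(self, state),
                    "sd": self.sd.get(state, 0.0),
                    "flag": self.flag,
                }
            )
        return rows


def combine_summary(
    edge: Mapping[str, float],
    flanking: Mapping[str, float] | None,
    aneuploidy: Mapping[str, float] | None = None,
    ti: Mapping[str, float] | None = None,
    *,
    sample_id: str = "",
    condition: str = "",
    timepoint_h: float | None = None,
    distance_bp: float | None = None,
    large_deletion_threshold_bp: float = DEFAULT_LARGE_DELETION_THRESHOLD_BP,
) -> LocusIntegritySummary:
    """Merge per-assay outputs into one stacked locus-integrity summary.

    The edge assay's total copy loss ("other") subsumes the unresolved DSBs
    and large deletions that the flanking assay resolves; those are
    subtracted (clamped at zero, with a log record when clamping bites) so
    the stacked classes are disjoint. One-sided flanking copy loss is
    labelled a large deletion when the assay's primer/probe distance exceeds
    the configured threshold, otherwise it stays trimming only.
    """
    wt = float(edge["wt"])
    indel = float(edge["indel"])
    edge_other = float(edge["other"])

    trim5 = trim3 = dsb = 0.0
    large_del = 0.0
    if flanking is not None:
        trim5 = float(flanking["trim5"])
        trim3 = float(flanking["trim3"])
        dsb = float(flanking["dsb"])
        is_large = (
            distance_bp is None or distance_bp >= large_deletion_threshold_bp
        )
        if is_large:
            large_del = max(trim5, trim3)

    raw_other = edge_other - large_del - dsb
    other = max(0.0, raw_other)
    if raw_other < -1e-9:
        logger.info(
            "sample %s: other-aberration clamped to 0 (raw %.3f%%)",
            sample_id, raw_other,
        )

    ti_pct = float(ti["targeted_integration"]) if ti else 0.0
    total = wt + indel + large_del + dsb + other + ti_pct
    flag = not (90.0 <= total <= 110.0)

    return LocusIntegritySummary(
        sample_id=sample_id,
        condition=condition,
        timepoint_h=timepoint_h,
        wt=wt,
        indel=indel,
        large_del=large_del,
        dsb=dsb,
        other_aberration=other,
        targeted_integration=ti_pct,
        trim5=trim5,
        trim3=trim3,
        aneu_p_change=float(aneuploidy["aneu_p_change"]) if aneuploidy else 0.0,
        aneu_q_change=float(aneuploidy["aneu_q_change"]) if aneuploidy else 0.0,
        vcn=float(ti["vcn"]) if ti else float("nan"),
        episomal_copies=float(ti["episomal_copies"]) if ti else float("nan"),
        concatemer_ratio=float(ti["concatemer_ratio"]) if ti else float("nan"),
        total=total,
        flag=flag,
    )
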