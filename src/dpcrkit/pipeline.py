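"""Well-level orchestration: classified droplet counts -> locus summaries.

Groups wells by sample, pairs technical replicates across assays, applies
the double normalisation against the replicate-averaged mock ratios, runs
the per-assay logic and combines everything into one
:class:`~dpcrkit.assays.LocusIntegritySummary` per sample (mean +- sd
across replicates).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .assays import (
    AssayPanelConfig,
    LocusIntegritySummary,
    combine_summary,
    edge_from_fractions,
    flanking_from_fractions,
    mean_reference_copies,
    well_copies,
)
from .dpcr_core import DropletWellCounts, estimate_linkage
from .errors import ConfigurationError, InputError

__all__ = ["quantify", "summaries_to_frame"]

logger = logging.getLogger(__name__)

_MEAN_SD_FIELDS = (
    "wt", "indel", "large_del", "dsb", "other_aberration",
    "targeted_integration", "trim5", "trim3", "aneu_p_change",
    "aneu_q_change", "vcn", "episomal_copies", "concatemer_ratio", "total",
)


def _group_wells(
    wells: Sequence[DropletWellCounts],
) -> dict[str, dict[str, list[DropletWellCounts]]]:
    grouped: dict[str, dict[str, list[DropletWellCounts]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for w in wells:
        grouped[w.sample_id][w.assay_id].append(w)
    for sample in grouped.values():
        for lst in sample.values():
            lst.sort(key=lambda w: w.well_id)
    return grouped


def _mock_ratios(
    mock: dict[str, list[DropletWellCounts]],
    panel: AssayPanelConfig,
) -> dict[tuple[str, str], float]:
    """Replicate-averaged (assay copies / mean reference copies) in the mock."""
    ref_ids = [a.id for a in panel.by_role("reference")]
    n_rep = min(len(mock[r]) for r in ref_ids if r in mock)
    ratios: dict[tuple[str, str], list[float]] = defaultdict(list)
    for rep in range(n_rep):
        ref_mean = float(
            np.mean([well_copies(mock[r][rep], "fam") for r in ref_ids])
        )
        for assay in panel.assays:
            if assay.id not in mock:
                continue
            w = mock[assay.id][rep] if rep < len(mock[assay.id]) else None
            if w is None:
                continue
            for ch in ("fam", "hex"):
                ratios[(assay.id, ch)].append(well_copies(w, ch) / ref_mean)
            if assay.role == "flanking":
                link = estimate_linkage(w).lambda_link * w.n_total
                ratios[(assay.id, "link")].append(link / ref_mean)
    return {k: float(np.mean(v)) for k, v in ratios.items()}


def quantify(
    wells: Sequence[DropletWellCounts],
    panel: AssayPanelConfig,
) -> list[LocusIntegritySummary]:
    """Quantify every non-mock sample in a set of classified droplet wells."""
    grouped = _group_wells(wells)
    if panel.mock_sample_id not in grouped:
        raise InputError(
            f"mock sample {panel.mock_sample_id!r} not present in the data"
        )
    mock = grouped[panel.mock_sample_id]
    ref_ids = [a.id for a in panel.by_role("reference")]
    for rid in ref_ids:
        if rid not in mock:
            raise ConfigurationError(
                f"reference assay {rid!r} missing from the mock sample"
            )
    mock_ratio = _mock_ratios(mock, panel)

    donor_roles = {"ti_junction", "donor_total", "donor_total_digested"}
    for assay in panel.assays:
        if assay.role in donor_roles and assay.id in mock:
            logger.warning(
                "donor assay %s present in mock sample: possible contamination",
                assay.id,
            )

    summaries = []
    for sample_id in sorted(grouped):
        if sample_id == panel.mock_sample_id:
            continue
        summaries.append(
            _quantify_sample(sample_id, grouped[sample_id], panel, mock_ratio)
        )
    return summaries


def _replicate_count(
    sample: dict[str, list[DropletWellCounts]], assay_ids: Sequence[str]
) -> int:
    counts = [len(sample[a]) for a in assay_ids if a in sample]
    if not counts:
        raise InputError("sample has no wells for required assays")
    if len(set(counts)) > 1:
        logger.warning("unequal replicate counts %s; using the minimum", counts)
    return min(counts)


def _quantify_sample(
    sample_id: str,
    sample: dict[str, list[DropletWellCounts]],
    panel: AssayPanelConfig,
    mock_ratio: dict[tuple[str, str], float],
) -> LocusIntegritySummary:
    ref_ids = [a.id for a in panel.by_role("reference")]
    for rid in ref_ids:
        if rid not in sample:
            raise ConfigurationError(
                f"sample {sample_id!r}: reference assay {rid!r} missing"
            )
    edge_assays = panel.by_role("edge")
    if not edge_assays:
        raise ConfigurationError("panel defines no edge assay")
    edge_id = edge_assays[0].id
    if edge_id not in sample:
        raise InputError(f"sample {sample_id!r}: edge assay wells missing")

    flank = panel.by_role("flanking")
    flank_id = flank[0].id if flank and panel.flanking_valid else None
    aneu = panel.by_role("aneuploidy")
    aneu_id = aneu[0].id if aneu else None
    ti = panel.by_role("ti_junction")
    ti_id = ti[0].id if ti else None
    donor = panel.by_role("donor_total")
    donor_id = donor[0].id if donor else None
    dig = panel.by_role("donor_total_digested")
    dig_id = dig[0].id if dig else None

    core_ids = [edge_id] + ref_ids + ([flank_id] if flank_id else [])
    n_rep = _replicate_count(sample, core_ids)

    def dn(assay_id: str, ch: str, copies: float, ref_mean: float) -> float:
        mock = mock_ratio.get((assay_id, ch))
        if mock is None or mock <= 0:
            raise InputError(
                f"no positive mock ratio for assay {assay_id!r} channel {ch!r}"
            )
        return (copies / ref_mean) / mock

    rep_summaries: list[LocusIntegritySummary] = []
    for rep in range(n_rep):
        ref_wells = [sample[r][rep] for r in ref_ids]
        ref_mean = mean_reference_copies(ref_wells)

        ew = sample[edge_id][rep]
        edge = edge_from_fractions(
            dn(edge_id, "fam", well_copies(ew, "fam"), ref_mean),
            dn(edge_id, "hex", well_copies(ew, "hex"), ref_mean),
        )

        flanking = None
        distance_bp = None
        if flank_id is not None:
            fw = sample[flank_id][rep]
            link = estimate_linkage(fw).lambda_link * fw.n_total
            flanking = flanking_from_fractions(
                dn(flank_id, "fam", well_copies(fw, "fam"), ref_mean),
                dn(flank_id, "hex", well_copies(fw, "hex"), ref_mean),
                dn(flank_id, "link", link, ref_mean),
                panel.dsb_statistic,
            )
            distance_bp = panel.by_role("flanking")[0].distance_bp

        aneu_out = None
        if aneu_id is not None and aneu_id in sample:
            aw = sample[aneu_id][rep] if rep < len(sample[aneu_id]) else None
            if aw is not None:
                aneu_out = {
                    "aneu_p_change": 100.0 * (
                        dn(aneu_id, "fam", well_copies(aw, "fam"), ref_mean) - 1.0
                    ),
                    "aneu_q_change": 100.0 * (
                        dn(aneu_id, "hex", well_copies(aw, "hex"), ref_mean) - 1.0
                    ),
                }

        ti_out = None
        if ti_id is not None and ti_id in sample:
            # donor assays: reference-only normalisation (mock has no donor)
            jw = sample[ti_id][rep] if rep < len(sample[ti_id]) else None
            if jw is not None:
                junction = well_copies(jw, "fam")
                ti_out = {
                    "targeted_integration": 100.0 * junction / ref_mean,
                    "vcn": float("nan"),
                    "episomal_copies": float("nan"),
                    "concatemer_ratio": float("nan"),
                }
                if donor_id is not None and donor_id in sample and \
                        rep < len(sample[donor_id]):
                    donor_copies = well_copies(sample[donor_id][rep], "fam")
                    vcn = panel.ploidy * donor_copies / ref_mean
                    ti_out["vcn"] = vcn
                    ti_out["episomal_copies"] = max(0.0, donor_copies - junction)
                    if dig_id is not None and dig_id in sample and \
                            rep < len(sample[dig_id]):
                        dig_copies = well_copies(sample[dig_id][rep], "fam")
                        vcn_dig = panel.ploidy * dig_copies / ref_mean
                        ti_out["concatemer_ratio"] = (
                            vcn_dig / vcn if vcn > 0 else float("nan")
                        )

        meta = panel.sample_meta(sample_id)
        rep_summaries.append(
            combine_summary(
                edge, flanking, aneu_out, ti_out,
                sample_id=sample_id,
                condition=meta.condition,
                timepoint_h=meta.timepoint_h,
                distance_bp=distance_bp,
                large_deletion_threshold_bp=panel.large_deletion_threshold_bp,
            )
        )

    return _aggregate_replicates(rep_summaries)


def _aggregate_replicates(
    reps: list[LocusIntegritySummary],
) -> LocusIntegritySummary:
    first = reps[0]
    if len(reps) == 1:
        first.n_replicates = 1
        return first
    agg = LocusIntegritySummary(
        sample_id=first.sample_id,
        condition=first.condition,
        timepoint_h=first.timepoint_h,
    )
    sd: dict[str, float] = {}
    for name in _MEAN_SD_FIELDS:
        vals = np.array([getattr(r, name) for r in reps], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        setattr(agg, name, float(vals.mean()))
        sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    agg.sd = sd
    agg.n_replicates = len(reps)
    agg.flag = not (90.0 <= agg.total <= 110.0)
    return agg


def summaries_to_frame(
    summaries: Sequence[LocusIntegritySummary],
) -> pd.DataFrame:
    """Tidy frame: one row per sample x state, with sd and range flag."""
    rows = []
    for s in summaries:
        rows.extend(s.as_tidy_rows())
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "timepoint_h", "state",
                 "percent", "sd", "flag"],
    )
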