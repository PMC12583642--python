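"""Poisson partition statistics for two-colour droplet digital PCR.

A droplet PCR well partitions the sample into ~10^4--10^5 droplets; each
droplet is scored positive or negative in the FAM and HEX channels. Under
independent Poisson loading the mean number of target molecules per droplet
(lambda) is recovered from the fraction of negative droplets,

    lambda = ln(n_total / n_negative_in_channel),

and "absolute copies" in the analysed partition set is lambda * n_total.

When two probed sequences reside on the *same* physical DNA molecule they
always co-occupy a droplet, producing an excess of double-positive droplets
over the rate expected by chance. The linked concentration is recovered in
closed form from the three negative fractions (see :func:`estimate_linkage`).

All concentrations are kept on the per-droplet lambda scale; every
downstream quantity in this package is a ratio, which is volume-invariant.
A helper converting to copies/uL via the partition volume is provided for
reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SaturationError

__all__ = [
    "DropletWellCounts",
    "ChannelConcentration",
    "LinkageEstimate",
    "estimate_lambda",
    "estimate_linkage",
    "copies_with_ci",
    "copies_per_microlitre",
]

#: Default droplet (partition) volume in nanolitres, used only for the
#: optional copies/uL conversion.
DEFAULT_PARTITION_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DropletWellCounts:
    """Classified droplet tally for one well.

    Counts may be floats so that exact expected-count wells (useful for
    closed-form checks) are representable; real wells carry integers.
    """

    n_total: float
    n_double: float
    n_fam_only: float
    n_hex_only: float
    n_negative: float
    well_id: str = ""
    sample_id: str = ""
    assay_id: str = ""

    def __post_init__(self) -> None:
        counts = (self.n_double, self.n_fam_only, self.n_hex_only, self.n_negative)
        if any(c < 0 for c in counts) or self.n_total < 1:
            raise InputError(
                f"well {self.well_id!r}: negative counts or n_total < 1"
            )
        if not math.isclose(sum(counts), self.n_total, rel_tol=1e-9, abs_tol=1e-6):
            raise InputError(
                f"well {self.well_id!r}: droplet classes sum to {sum(counts)}, "
                f"expected n_total={self.n_total}"
            )

    # channel-negative counts: a droplet is FAM-negative iff it is neither
    # double-positive nor FAM-only positive.
    @property
    def n_fam_negative(self) -> float:
        return self.n_hex_only + self.n_negative

    @property
    def n_hex_negative(self) -> float:
        return self.n_fam_only + self.n_negative


@dataclass(frozen=True)
class ChannelConcentration:
    """Per-channel concentration estimates for one well."""

    lambda_fam: float
    lambda_hex: float
    copies_fam: float
    copies_hex: float
    ci_low_fam: float = 0.0
    ci_high_fam: float = 0.0
    ci_low_hex: float = 0.0
    ci_high_hex: float = 0.0


@dataclass(frozen=True)
class LinkageEstimate:
    """Decomposition of a two-channel well into linked and free molecules.

    ``lambda_link`` is the mean number of physically linked probe pairs per
    droplet; ``lambda_*_free`` are the channel concentrations after the
    linked contribution is removed. Raw (pre-flooring) values are kept for
    diagnostics: sampling noise can push them slightly negative.
    """

    lambda_link: float
    lambda_fam_free: float
    lambda_hex_free: float
    linked_fraction: float
    raw_lambda_link: float = field(default=0.0, repr=False)
    raw_lambda_fam_free: float = field(default=0.0, repr=False)
    raw_lambda_hex_free: float = field(default=0.0, repr=False)


def estimate_lambda(n_negative_in_channel: float, n_total: float) -> float:
    """Mean molecules per droplet from the negative-droplet fraction.

    Parameters
    ----------
    n_negative_in_channel
        Droplets negative in the channel of interest (for FAM this is
        ``n_hex_only + n_negative``).
    n_total
        Accepted droplets in the well.

    Raises
    ------
    SaturationError
        If no droplet is negative — the estimator diverges.
    InputError
        If the counts are inconsistent.
    """
    if n_total < 1 or n_negative_in_channel > n_total or n_negative_in_channel < 0:
        raise InputError(
            f"invalid counts: n_negative={n_negative_in_channel}, n_total={n_total}"
        )
    if n_negative_in_channel == 0:
        raise SaturationError(
            "all droplets positive: concentration unquantifiable at this dilution"
        )
    return math.log(n_total / n_negative_in_channel)


def estimate_linkage(well: DropletWellCounts) -> LinkageEstimate:
    """Linked and free molecule concentrations from a two-channel well.

    With independent Poisson loading of free FAM molecules (lambda_F), free
    HEX molecules (lambda_H) and linked pairs (lambda_L), the negative
    fractions satisfy

        f_neg  = exp(-(lambda_F + lambda_H + lambda_L))
        f_FAM- = exp(-(lambda_F + lambda_L))
        f_HEX- = exp(-(lambda_H + lambda_L))

    so ``lambda_L = ln f_neg - ln f_FAM- - ln f_HEX-``: the observed
    double-positive excess over the frequency expected by chance. Estimates
    are floored at zero (concentrations are physical non-negatives); the raw
    values are retained on the result.
    """
    if well.n_negative < 1:
        raise SaturationError("no double-negative droplets: linkage unquantifiable")
    if well.n_fam_negative < 1 or well.n_hex_negative < 1:
        raise SaturationError("a channel is saturated: linkage unquantifiable")

    n = well.n_total
    raw_link = (
        math.log(well.n_negative / n)
        - math.log(well.n_fam_negative / n)
        - math.log(well.n_hex_negative / n)
    )
    lam_fam = estimate_lambda(well.n_fam_negative, n)
    lam_hex = estimate_lambda(well.n_hex_negative, n)

    link = max(0.0, raw_link)
    raw_fam_free = lam_fam - link
    raw_hex_free = lam_hex - link
    fam_free = max(0.0, raw_fam_free)
    hex_free = max(0.0, raw_hex_free)

    denom = max(lam_fam, lam_hex)
    linked_fraction = min(1.0, link / denom) if denom > 0 else 0.0

    return LinkageEstimate(
        lambda_link=link,
        lambda_fam_free=fam_free,
        lambda_hex_free=hex_free,
        linked_fraction=linked_fraction,
        raw_lambda_link=raw_link,
        raw_lambda_fam_free=raw_fam_free,
        raw_lambda_hex_free=raw_hex_free,
    )


def copies_with_ci(
    well: DropletWellCounts, n_boot: int = 1000, seed: int = 0
) -> ChannelConcentration:
    """Per-channel copies with 95% bootstrap confidence intervals.

    The four droplet classes are resampled as a multinomial with the
    observed class probabilities; each resample is re-inverted through the
    Poisson estimator. Resamples that saturate a channel (zero negatives)
    are continuity-corrected with half a droplet. Deterministic given
    ``seed``.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    n = int(round(well.n_total))
    lam_fam = estimate_lambda(well.n_fam_negative, well.n_total)
    lam_hex = estimate_lambda(well.n_hex_negative, well.n_total)

    p = (
        np.array(
            [well.n_double, well.n_fam_only, well.n_hex_only, well.n_negative],
            dtype=float,
        )
        / well.n_total
    )
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, p, size=n_boot).astype(float)
    fam_neg = np.maximum(draws[:, 2] + draws[:, 3], 0.5)  # half-count correction
    hex_neg = np.maximum(draws[:, 1] + draws[:, 3], 0.5)
    lam_fam_b = np.log(n / fam_neg)
    lam_hex_b = np.log(n / hex_neg)

    lo_f, hi_f = np.percentile(lam_fam_b, [2.5, 97.5])
    lo_h, hi_h = np.percentile(lam_hex_b, [2.5, 97.5])

    return ChannelConcentration(
        lambda_fam=lam_fam,
        lambda_hex=lam_hex,
        copies_fam=lam_fam * well.n_total,
        copies_hex=lam_hex * well.n_total,
        ci_low_fam=float(min(lo_f, lam_fam)),
        ci_high_fam=float(max(hi_f, lam_fam)),
        ci_low_hex=float(min(lo_h, lam_hex)),
        ci_high_hex=float(max(hi_h, lam_hex)),
    )


def copies_per_microlitre(
    lam: float, partition_volume_nl: float = DEFAULT_PARTITION_VOLUME_NL
) -> float:
    """Convert a per-droplet lambda to copies per microlitre of reaction."""
    if partition_volume_nl <= 0:
        raise InputError("partition volume must be positive")
    return lam / (partition_volume_nl * 1e-3)
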