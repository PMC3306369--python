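"""Morphometric summaries: neck:trunk proportions, per-bin size ranges,
and isometric mass-scaling factors.

Trunk length (first dorsal-ribbed to last sacral vertebra, mm) is the
body-size proxy; the neck:trunk ratio is the body-proportion proxy.
Under isometry a linear-size ratio r implies a mass factor r³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import TaxonRecord

__all__ = [
    "BodyProportion",
    "proportion_table",
    "range_by_bin",
    "isometric_mass_factor",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BodyProportion:
    taxon: str
    trunk_length: float
    neck_length: float
    ratio: float            # neck / trunk
    bin_label: str | None = None
    underestimate: bool = False  # e.g. incomplete cervical series


def proportion_table(records: Sequence[TaxonRecord],
                     underestimates: Sequence[str] = ()
                     ) -> list[BodyProportion]:
    """Neck:trunk ratios for every record with both measurements.

    Records missing either length are skipped (and logged); taxa listed
    in ``underestimates`` are flagged but their numbers are untouched.
    """
    flagged = set(underestimates)
    out = []
    for r in records:
        if r.trunk_length is None or r.neck_length is None:
            log.info("skipping %s: missing trunk or neck length", r.name)
            continue
        if r.trunk_length <= 0 or r.neck_length <= 0:
            raise ValueError(f"{r.name}: lengths must be positive")
        out.append(BodyProportion(
            taxon=r.name,
            trunk_length=r.trunk_length,
            neck_length=r.neck_length,
            ratio=r.neck_length / r.trunk_length,
            bin_label=r.bin_label,
            underestimate=r.name in flagged,
        ))
    return out


def range_by_bin(values: Sequence[tuple[str, float]]
                 ) -> dict[str, tuple[float, float]]:
    """(min, max) of a measurement per bin label; empty bins are absent.

    ``values`` is a sequence of (bin_label, value) pairs."""
    out: dict[str, tuple[float, float]] = {}
    for bin_label, v in values:
        if bin_label is None:
            continue
        if bin_label in out:
            lo, hi = out[bin_label]
            out[bin_label] = (min(lo, v), max(hi, v))
        else:
            out[bin_label] = (v, v)
    return out


def isometric_mass_factor(length_a: float, length_b: float) -> float:
    """Mass factor implied by isometric scaling: (b/a)³."""
    if length_a <= 0 or length_b <= 0:
        raise ValueError("lengths must be positive")
    return (length_b / length_a) ** 3
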