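"""Ki67 field-sampling plan for a tumor section.

The number of 400x image fields captured depends on the section's long
axis: <10 mm -> 5 fields, 10-15 mm -> 10, 15-20 mm -> 15, >=20 mm -> 20.
Hotspot regions (intensely stained areas) receive a share of fields
proportional to their approximate percent area, with fractional field
counts always rounded up; remaining fields come from typical regions.
Example: a 12 mm section with 30% hotspot area gets 10 fields, 3 from
hotspots and 7 typical.

The category table leaves exactly 20.0 mm unassigned ("<20" vs ">20"); this
implementation assigns it to the 20-field category so coverage of the axis
is monotone and gap-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_CATEGORY_TABLE = (
    (10.0, 5),
    (15.0, 10),
    (20.0, 15),
    (math.inf, 20),
)


@dataclass(frozen=True)
class SamplingPlan:
    long_axis_mm: float
    hotspot_percent: float
    total_fields: int
    hotspot_fields: int
    typical_fields: int


def total_fields_for_axis(long_axis_mm: float) -> int:
    """Total field count for a section's long axis (mm)."""
    if long_axis_mm <= 0:
        raise ValueError("long_axis_mm must be > 0")
    for upper, n_fields in _CATEGORY_TABLE:
        if long_axis_mm < upper:
            return n_fields
    return _CATEGORY_TABLE[-1][1]


def plan_fields(long_axis_mm: float, hotspot_percent: float) -> SamplingPlan:
    """Allocate total/hotspot/typical field counts for one section."""
    if not 0.0 <= hotspot_percent <= 100.0:
        raise ValueError("hotspot_percent must lie in [0, 100]")
    total = total_fields_for_axis(long_axis_mm)
    hotspot = math.ceil(total * hotspot_percent / 100.0)
    return SamplingPlan(
        long_axis_mm=float(long_axis_mm),
        hotspot_percent=float(hotspot_percent),
        total_fields=total,
        hotspot_fields=hotspot,
        typical_fields=total - hotspot,
    )
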