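"""Dosing protocols, including the split-dose oral absorption protocol.

The population analysis of rosuvastatin absorption assigns 63.4% of an oral
dose to an immediate release and the remaining 36.6% to a second release
delayed by 2.3 h; this is the default oral protocol.  During rifampicin or
probenecid co-treatment the whole dose is released at once (see
:func:`rosupbpk.ddi.absorption_variant`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SPLIT_FIRST_FRACTION = 0.634
SPLIT_SECOND_FRACTION = 0.366
SPLIT_LAG_H = 2.3

ROUTES = ("oral", "iv_bolus", "iv_infusion")


@dataclass(frozen=True)
class DoseEvent:
    start_time_h: float
    dose_fraction: float
    infusion_duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.start_time_h < 0:
            raise ValueError("dose times must be non-negative")
        if not 0 < self.dose_fraction <= 1:
            raise ValueError("dose fractions must lie in (0, 1]")
        if self.infusion_duration_h < 0:
            raise ValueError("infusion duration must be non-negative")


@dataclass(frozen=True)
class DosingProtocol:
    route: str
    total_dose_mg: float
    events: tuple = (DoseEvent(0.0, 1.0),)
    repeat_interval_h: float | None = None
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.total_dose_mg < 0:
            raise ValueError("total_dose must be non-negative")
        frac = sum(e.dose_fraction for e in self.events)
        if abs(frac - 1.0) > 1e-9:
            raise ValueError("dose fractions must sum to 1 per administration")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_repeats > 1 and not self.repeat_interval_h:
            raise ValueError("repeat_interval_h required when n_repeats > 1")

    def administrations(self):
        """All (absolute_start_h, dose_mg, infusion_duration_h) across repeats."""
        out = []
        for r in range(self.n_repeats):
            offset = r * (self.repeat_interval_h or 0.0)
            for e in self.events:
                out.append(
                    (
                        offset + e.start_time_h,
                        self.total_dose_mg * e.dose_fraction,
                        e.infusion_duration_h,
                    )
                )
        return sorted(out)

    @property
    def last_event_time_h(self) -> float:
        return max(t + d for t, _, d in self.administrations())


def oral_split(dose_mg: float, repeat_interval_h=None, n_repeats=1) -> DosingProtocol:
    """Oral administration with the delayed second-release protocol."""
    return DosingProtocol(
        route="oral",
        total_dose_mg=dose_mg,
        events=(
            DoseEvent(0.0, SPLIT_FIRST_FRACTION),
            DoseEvent(SPLIT_LAG_H, SPLIT_SECOND_FRACTION),
        ),
        repeat_interval_h=repeat_interval_h,
        n_repeats=n_repeats,
    )


def oral_single(dose_mg: float, repeat_interval_h=None, n_repeats=1) -> DosingProtocol:
    """Oral administration released at once (rifampicin/probenecid arms)."""
    return DosingProtocol(
        route="oral",
        total_dose_mg=dose_mg,
        repeat_interval_h=repeat_interval_h,
        n_repeats=n_repeats,
    )


def iv_bolus(dose_mg: float) -> DosingProtocol:
    return DosingProtocol(route="iv_bolus", total_dose_mg=dose_mg)


def iv_infusion(dose_mg: float, duration_h: float) -> DosingProtocol:
    return DosingProtocol(
        route="iv_infusion",
        total_dose_mg=dose_mg,
        events=(DoseEvent(0.0, 1.0, duration_h),),
    )
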