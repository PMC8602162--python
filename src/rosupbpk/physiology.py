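"""Virtual-individual physiology for the reduced whole-body model.

The model collapses full anatomy to the organs where rosuvastatin transport
processes act (gut lumen / enterocyte / portal vein / liver / gallbladder /
kidney) plus a lumped central ("plasma") and a lumped peripheral compartment.
Reference organ volumes and blood flows follow an ICRP-style reference adult
European male (30 y, 73 kg, 176 cm) and are all overridable through the model
configuration file.  Volumes and flows scale linearly with body weight
relative to the 73 kg reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


REFERENCE_WEIGHT_KG = 73.0


@dataclass(frozen=True)
class Demographics:
    """Study-population descriptors of a virtual mean individual."""

    ethnicity: str = "European"
    sex: str = "male"
    age_years: float = 30.0
    weight_kg: float = 73.0
    height_cm: float = 176.0

    def __post_init__(self) -> None:
        if self.age_years <= 0 or self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("age, weight and height must be positive")


#: The default virtual mean individual used when a study reports no demographics.
REFERENCE_DEMOGRAPHICS = Demographics()


@dataclass(frozen=True)
class Physiology:
    """Organ volumes (L), plasma/blood flows (L/h) and elimination physiology.

    ``blood_flows`` are whole-blood flows; the drug distributes almost
    exclusively into plasma (blood/plasma ratio 0.56 ≈ 1 − hematocrit), so
    convective transport uses the plasma flow ``blood_flow × (1 − hematocrit)``
    with all concentrations expressed on plasma.
    """

    body_weight_kg: float = REFERENCE_WEIGHT_KG
    lumen_volumes_l: tuple = (0.35, 0.35, 0.35)
    organ_volumes_l: dict = field(
        default_factory=lambda: {
            "enterocyte": 0.5,
            "portal_vein": 1.0,
            "liver": 1.8,
            "gallbladder_bile": 0.05,
            "kidney": 0.31,
            "plasma_central": 30.0,
            "peripheral": 35.0,
        }
    )
    blood_flows_l_per_h: dict = field(
        default_factory=lambda: {
            "liver": 100.0,
            "kidney": 60.0,
            "peripheral": 36.4,
        }
    )
    portal_flow_fraction: float = 0.75
    gfr_l_per_h: float = 7.2
    hematocrit: float = 0.45
    bile_flow_l_per_h: float = 0.02
    intestinal_transit_rates_per_h: tuple = (0.85, 0.85, 0.85)

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.gfr_l_per_h <= 0:
            raise ValueError("gfr must be positive")
        if self.bile_flow_l_per_h <= 0:
            raise ValueError("bile_flow must be positive")
        if len(self.lumen_volumes_l) != len(self.intestinal_transit_rates_per_h):
            raise ValueError("one transit rate per lumen segment is required")
        for v in list(self.lumen_volumes_l) + list(self.organ_volumes_l.values()):
            if v <= 0:
                raise ValueError("all volumes must be positive")
        for q in self.blood_flows_l_per_h.values():
            if q <= 0:
                raise ValueError("all blood flows must be positive")
        if not 0 < self.portal_flow_fraction < 1:
            raise ValueError("portal_flow_fraction must lie in (0, 1)")
        for k in self.intestinal_transit_rates_per_h:
            if k <= 0:
                raise ValueError("transit rates must be positive")

    # -- derived plasma flows -------------------------------------------------
    def plasma_flow(self, organ: str) -> float:
        return self.blood_flows_l_per_h[organ] * (1.0 - self.hematocrit)

    @property
    def hepatic_plasma_flow(self) -> float:
        return self.plasma_flow("liver")

    @property
    def portal_plasma_flow(self) -> float:
        return self.hepatic_plasma_flow * self.portal_flow_fraction

    @property
    def arterial_plasma_flow(self) -> float:
        return self.hepatic_plasma_flow * (1.0 - self.portal_flow_fraction)

    @property
    def n_lumen_segments(self) -> int:
        return len(self.lumen_volumes_l)


#: Shipped reference physiology of the 73 kg virtual mean individual.
REFERENCE_PHYSIOLOGY = Physiology()


def build_physiology(
    demographics: Demographics,
    reference: Physiology = REFERENCE_PHYSIOLOGY,
) -> Physiology:
    """Scale the reference physiology to a virtual individual's body weight.

    All volumes and flows (including GFR and bile flow) scale linearly with
    ``weight / 73 kg``; first-order transit rates are size-invariant.  For the
    default 73 kg European male this returns the shipped reference physiology
    unchanged.
    """
    if demographics.weight_kg <= 0:
        raise ValueError("weight must be positive")
    s = demographics.weight_kg / REFERENCE_WEIGHT_KG
    return replace(
        reference,
        body_weight_kg=demographics.weight_kg,
        lumen_volumes_l=tuple(v * s for v in reference.lumen_volumes_l),
        organ_volumes_l={k: v * s for k, v in reference.organ_volumes_l.items()},
        blood_flows_l_per_h={k: q * s for k, q in reference.blood_flows_l_per_h.items()},
        gfr_l_per_h=reference.gfr_l_per_h * s,
        bile_flow_l_per_h=reference.bile_flow_l_per_h * s,
    )
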