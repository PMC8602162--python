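"""Compound parameters and active transport / metabolism processes."""

from __future__ import annotations

from dataclasses import dataclass, field

PROCESS_NAMES = ("OATP1B1_1B3", "OATP2B1", "OAT3", "BCRP", "Pgp", "CYP2C9")
PROCESS_KINDS = ("influx", "efflux", "metabolism")

#: Organ sites at which a process can be placed, and the membrane it acts on.
ORGAN_SITES = (
    "gut_apical",          # lumen <-> enterocyte apical membrane
    "liver_basolateral",   # sinusoidal uptake into hepatocytes
    "liver_canalicular",   # hepatocyte -> bile efflux
    "liver_intracellular", # metabolism inside hepatocytes
    "kidney_basolateral",  # plasma -> proximal tubule cell uptake
    "kidney_apical",       # tubule cell -> urine efflux
)


@dataclass(frozen=True)
class CompoundParams:
    """Rosuvastatin physicochemistry and lumped passive permeation terms.

    ``intestinal_permeability_l_per_h`` is a per-lumen-segment passive
    absorption clearance (the carrier-mediated part of absorption is an
    :class:`ActiveProcess`).  ``enterocyte_basolateral_clearance_l_per_h`` is
    the fitted passive permeability out of the enterocytes into portal blood —
    the rate-limiting step that produces the characteristically slow
    absorption of rosuvastatin.  Liver/kidney backflux clearances return
    tissue drug to plasma; the peripheral partition coefficient sets the
    effective volume of the lumped deep-distribution compartment.
    """

    molecular_weight_g_per_mol: float = 481.54
    lipophilicity_log_units: float = 0.13
    fraction_unbound_plasma: float = 0.115
    blood_plasma_ratio: float = 0.56
    intestinal_permeability_l_per_h: tuple = (0.004, 0.004, 0.004)
    enterocyte_basolateral_clearance_l_per_h: float = 0.25
    liver_backflux_clearance_l_per_h: float = 0.09
    kidney_backflux_clearance_l_per_h: float = 0.26
    peripheral_partition_coefficient: float = 9.2

    def __post_init__(self) -> None:
        if not 0 < self.fraction_unbound_plasma <= 1:
            raise ValueError("fraction_unbound_plasma must lie in (0, 1]")
        if self.blood_plasma_ratio <= 0:
            raise ValueError("blood_plasma_ratio must be positive")
        if self.molecular_weight_g_per_mol <= 0:
            raise ValueError("molecular_weight must be positive")
        for p in self.intestinal_permeability_l_per_h:
            if p < 0:
                raise ValueError("permeabilities must be non-negative")
        for name in (
            "enterocyte_basolateral_clearance_l_per_h",
            "liver_backflux_clearance_l_per_h",
            "kidney_backflux_clearance_l_per_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peripheral_partition_coefficient <= 0:
            raise ValueError("peripheral_partition_coefficient must be positive")


@dataclass(frozen=True)
class ActiveProcess:
    """A saturable transport or metabolism process at one organ site.

    ``vmax_scaled_umol_per_h`` lumps kcat × reference expression at the site;
    relative organ expression is absorbed into this per-site maximum rate.
    """

    name: str
    kind: str
    organ_site: str
    km_umol_per_l: float
    vmax_scaled_umol_per_h: float

    def __post_init__(self) -> None:
        if self.name not in PROCESS_NAMES:
            raise ValueError(f"unknown process name {self.name!r}")
        if self.kind not in PROCESS_KINDS:
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.organ_site not in ORGAN_SITES:
            raise ValueError(f"unknown organ site {self.organ_site!r}")
        if self.km_umol_per_l <= 0:
            raise ValueError("km must be positive")
        if self.vmax_scaled_umol_per_h < 0:
            raise ValueError("vmax_scaled must be non-negative")

    @property
    def key(self) -> str:
        return f"{self.name}@{self.organ_site}"


def validate_processes(processes) -> None:
    """Each process name may appear at most once per organ site."""
    seen = set()
    for p in processes:
        if p.key in seen:
            raise ValueError(f"duplicate process {p.key}")
        seen.add(p.key)
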