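"""Reference data shipped with the package.

Per-species mercury concentrations in muscle tissue (mg/kg wet weight) for
the four Gadiformes species used in the two-week fried-fish intervention,
in both raw and fried state, together with typical portion masses (kg).
Twelve tissue samples per species/state underlie the published descriptive
statistics reproduced here.

Also holds regulatory limits and a documented table of published weekly
mercury intakes in other populations, shipped for context only — their
underlying consumption data are not available, so they are never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

RAW = "raw"
FRIED = "fried"
STATES = (RAW, FRIED)


@dataclass(frozen=True)
class SpeciesReference:
    """Published descriptive statistics for one species in one state."""

    species_id: str
    academic_name: str
    common_name: str
    state: str
    n: int
    mean: float          # mg/kg wet weight
    sd: float
    conc_min: float
    conc_max: float
    median: float
    p95: float
    portion_mean: float  # kg
    portion_sd: float


SPECIES_REFERENCE: tuple[SpeciesReference, ...] = (
    SpeciesReference("m_magellanicus", "Macruronus magellanicus", "hoki",
                     RAW, 12, 0.105, 0.015, 0.075, 0.130, 0.11, 0.12, 0.175, 0.015),
    SpeciesReference("m_magellanicus", "Macruronus magellanicus", "hoki",
                     FRIED, 12, 0.109, 0.015, 0.052, 0.139, 0.11, 0.13, 0.150, 0.014),
    SpeciesReference("g_chalcogrammus", "Gadus chalcogrammus", "pollock",
                     RAW, 12, 0.018, 0.006, 0.010, 0.028, 0.02, 0.03, 0.166, 0.020),
    SpeciesReference("g_chalcogrammus", "Gadus chalcogrammus", "pollock",
                     FRIED, 12, 0.023, 0.009, 0.009, 0.033, 0.02, 0.03, 0.147, 0.019),
    SpeciesReference("g_morhua", "Gadus morhua", "cod",
                     RAW, 12, 0.049, 0.006, 0.041, 0.060, 0.05, 0.06, 0.189, 0.025),
    SpeciesReference("g_morhua", "Gadus morhua", "cod",
                     FRIED, 12, 0.060, 0.009, 0.049, 0.072, 0.06, 0.07, 0.173, 0.026),
    SpeciesReference("p_virens", "Pollachius virens", "coalfish",
                     RAW, 12, 0.041, 0.005, 0.027, 0.046, 0.04, 0.05, 0.189, 0.023),
    SpeciesReference("p_virens", "Pollachius virens", "coalfish",
                     FRIED, 12, 0.055, 0.019, 0.035, 0.090, 0.05, 0.09, 0.166, 0.021),
)

SPECIES_IDS = ("m_magellanicus", "g_chalcogrammus", "g_morhua", "p_virens")

#: (species_id, state) -> mean tissue Hg, mg/kg wet weight
CONC_MG_PER_KG: dict[tuple[str, str], float] = {
    (r.species_id, r.state): r.mean for r in SPECIES_REFERENCE
}

#: (species_id, state) -> mean portion mass, kg
PORTION_KG: dict[tuple[str, str], float] = {
    (r.species_id, r.state): r.portion_mean for r in SPECIES_REFERENCE
}


def species_reference_file():
    """Path to the shipped CSV mirror of :data:`SPECIES_REFERENCE`."""
    from importlib.resources import files
    return files("hgintake.data").joinpath("species_reference.csv")


def species_reference(species_id: str, state: str) -> SpeciesReference:
    for rec in SPECIES_REFERENCE:
        if rec.species_id == species_id and rec.state == state:
            return rec
    raise KeyError(f"no reference data for species {species_id!r} state {state!r}")


# --- Regulatory limits -----------------------------------------------------

#: JECFA provisional tolerable weekly intake for MeHg, μg/kg bw/week
PTWI_MEHG = 1.6
#: JECFA PTWI for total mercury, μg/kg bw/week
PTWI_THG = 4.0
#: US National Research Council weekly intake limit, μg/kg bw/week
NRC_LIMIT = 0.7
#: Japanese PTWI for MeHg, μg/kg bw/week
PTWI_JAPAN = 3.4
#: EC 1881/2006 maximum permitted concentration for most fish, mg/kg wet weight
MPC_MG_PER_KG = 0.5

#: Mean cohort body weight in kg, *inferred* by inverting the published mean
#: EWI (0.62 μg/kg bw/week) against the computed weekly intake (52.6 μg/week).
#: The study never prints body weight; this is a back-derived fixture
#: constant, not measured data.
INFERRED_MEAN_BODY_WEIGHT_KG = 85.0


# --- Published weekly Hg intakes elsewhere (context only, never recomputed) --

#: population -> (EWI μg/kg bw/week, note). Inputs behind these figures are
#: not available, so the package ships them as documentation only.
LITERATURE_EWI: dict[str, tuple[float, str]] = {
    "Netherlands": (0.1, "MeHg, mean, upper bound '<0.1', 60 kg adult assumed"),
    "France": (0.43, "MeHg, adult mean; median 0.30; P97.5 1.78"),
    "Portugal": (1.6, "MeHg, mean, 60 kg adult assumed"),
    "Catalonia": (0.78, "THg, mean"),
    "Italy": (0.88, "μg/week for a 65 kg median consumer; 55% of PTWI"),
    "Hong Kong (average consumer)": (0.45, "MeHg, median band 0.4-0.5"),
    "Hong Kong (high consumer)": (1.3, "MeHg, median band 1.2-1.4"),
    "Nepal (visitors)": (0.05, "MeHg, minimum intake category"),
    "Nepal (hotel owners)": (3.71, "MeHg, maximum intake category"),
}
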