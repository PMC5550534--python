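"""Fish-tissue mercury summaries, raw-vs-fried comparison, MPC compliance, QC.

Concentrations are total mercury in muscle tissue, mg/kg wet weight.
Descriptive statistics use the package-wide percentile convention
(type 7 linear interpolation) and the sample (n-1) standard deviation.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._stats import percentile, sample_sd
from .constants import STATES


@dataclass(frozen=True)
class FishSample:
    """One tissue Hg measurement: ``conc`` in mg/kg wet weight."""

    species_id: str
    state: str
    conc: float
    sample_index: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.conc < 0:
            raise ValueError(f"negative concentration {self.conc}")


@dataclass(frozen=True)
class SpeciesSummary:
    """Descriptive statistics for one species/state group (mg/kg wet weight)."""

    species_id: str
    state: str
    n: int
    mean: float
    sd: float
    median: float
    p95: float
    min: float
    max: float
    portion_mass_mean: float | None = None
    portion_mass_sd: float | None = None


@dataclass(frozen=True)
class QCResult:
    """Analyzer QC: limits in ng absolute Hg mass, recoveries in percent."""

    detection_limit: float
    quantification_limit: float
    recoveries: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.detection_limit < 0 or self.quantification_limit < 0:
            raise ValueError("QC limits must be non-negative")


@dataclass(frozen=True)
class RawFriedDifference:
    """Raw-vs-fried mean Hg comparison for one species.

    ``study_pct`` reproduces the idiosyncratic percent notation used in the
    source study's raw/fried comparison: the absolute mg/kg difference
    multiplied by 100 (0.060 - 0.049 = 0.011 mg/kg is reported as "1.1%").
    ``rel_pct`` is the conventional relative change against the raw mean.
    """

    species_id: str
    abs_diff: float   # fried mean - raw mean, mg/kg (signed)
    study_pct: float  # abs_diff * 100
    rel_pct: float    # 100 * abs_diff / raw mean


def summarize_samples(samples: Sequence[FishSample],
                      portion_masses: Sequence[float] = ()) -> SpeciesSummary:
    """Descriptive statistics for one species/state sample group.

    Parameters
    ----------
    samples
        Tissue measurements, all from the same species and state.
    portion_masses
        Optional edible-portion masses (kg) for the same group; summarised
        into ``portion_mass_mean``/``portion_mass_sd``.
    """
    if not samples:
        raise ValueError("no samples")
    species = {s.species_id for s in samples}
    states = {s.state for s in samples}
    if len(species) > 1 or len(states) > 1:
        raise ValueError("heterogeneous group: "
                         f"species={sorted(species)}, states={sorted(states)}")
    conc = np.array([s.conc for s in samples], dtype=float)
    masses = np.asarray(portion_masses, dtype=float)
    return SpeciesSummary(
        species_id=samples[0].species_id,
        state=samples[0].state,
        n=len(samples),
        mean=float(conc.mean()),
        sd=sample_sd(conc),
        median=float(np.median(conc)),
        p95=percentile(conc, 95.0),
        min=float(conc.min()),
        max=float(conc.max()),
        portion_mass_mean=float(masses.mean()) if masses.size else None,
        portion_mass_sd=sample_sd(masses) if masses.size else None,
    )


def raw_fried_difference(raw: SpeciesSummary,
                         fried: SpeciesSummary) -> RawFriedDifference:
    """Signed mean difference between fried and raw tissue Hg, both notations."""
    if raw.species_id != fried.species_id:
        raise ValueError(f"species mismatch: {raw.species_id!r} vs {fried.species_id!r}")
    if raw.state != "raw" or fried.state != "fried":
        raise ValueError("arguments must be the raw and the fried summary, in that order")
    diff = fried.mean - raw.mean
    rel = 100.0 * diff / raw.mean if raw.mean != 0 else float("nan")
    return RawFriedDifference(species_id=raw.species_id, abs_diff=diff,
                              study_pct=diff * 100.0, rel_pct=rel)


def mpc_check(summary: SpeciesSummary, mpc: float, *,
              strict: bool = False) -> dict[str, float | bool]:
    """Compliance of a species' tissue Hg against a maximum permitted concentration.

    The comparison is on the species *mean* (boundary inclusive); with
    ``strict=True`` the per-sample maximum is compared instead. ``margin``
    is ``mpc`` minus the compared statistic (negative when non-compliant).
    """
    if mpc <= 0:
        raise ValueError(f"mpc must be positive, got {mpc}")
    stat = summary.max if strict else summary.mean
    return {"compliant": bool(stat <= mpc), "margin": mpc - stat}


def qc_limits(blank_sd: float) -> QCResult:
    """Detection and quantification limits from the blank's standard deviation.

    DL = 3 x blank SD, QL = 6 x blank SD (both in ng absolute Hg mass),
    so QL/DL = 2 by construction.
    """
    if blank_sd < 0:
        raise ValueError(f"blank_sd must be non-negative, got {blank_sd}")
    return QCResult(detection_limit=3.0 * blank_sd,
                    quantification_limit=6.0 * blank_sd)


def recovery(measured: float, certified: float) -> float:
    """Certified-reference-material recovery, percent: 100 x measured/certified."""
    if certified <= 0:
        raise ValueError(f"certified value must be positive, got {certified}")
    return 100.0 * measured / certified


def recoveries(measured: Iterable[float], certified: float) -> list[float]:
    """Recoveries for a batch of replicate CRM measurements."""
    return [recovery(m, certified) for m in measured]
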