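"""Quantification arithmetic: protein lowering, qPCR, permeability, Kp,uu.

These are the study-style derived quantities around the splicing analysis:

* ECL protein lowering: per animal, ratio = mean(target signal) /
  mean(normaliser signal) x 1000; fold change vs the vehicle-group grand
  mean of ratios; percent lowering = (1 - fold) x 100.  The white-blood-cell
  variant has no normaliser and uses raw target means.
* qPCR abundance: (1 + E)^(-Ct) per amplicon with efficiency E, normalised
  target/housekeeping, expressed as percent of the vehicle-group mean
  (efficiency-corrected ddCt).
* Transwell permeability: Papp = (dCr/dt) * Vr / (A * C0) in cm/s, with
  dCr/dt the least-squares slope of receiver concentration vs time.  The
  efflux metric is emitted both as the difference Papp(B->A) - Papp(A->B)
  (as printed) and as the conventional ratio Papp(B->A)/Papp(A->B).
* Unbound brain partition: Kp,uu = Cbrain * fu,b / (Cplasma * fu,p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EclRecord",
    "LoweringResult",
    "ecl_lowering",
    "QpcrRecord",
    "qpcr_percent",
    "estimate_efficiency",
    "PermeabilityRecord",
    "papp",
    "efflux_metrics",
    "kpuu",
]


@dataclass
class EclRecord:
    animal_id: str
    tissue: str
    group: str
    target_signals: list[float]  # duplicate target (e.g. hHTT) readouts
    normaliser_signals: list[float] | None = None  # e.g. KRAS; None in WBC mode

    def __post_init__(self) -> None:
        if not self.target_signals:
            raise ValueError(f"{self.animal_id}: no target signals")
        if any(x < 0 for x in self.target_signals):
            raise ValueError(f"{self.animal_id}: negative target signal")
        if self.normaliser_signals is not None and any(
            x < 0 for x in self.normaliser_signals
        ):
            raise ValueError(f"{self.animal_id}: negative normaliser signal")


@dataclass
class LoweringResult:
    animal_id: str
    group: str
    ratio: float
    fold_change: float
    percent_lowering: float


def ecl_lowering(
    records: Sequence[EclRecord],
    vehicle_group: str,
    wbc_mode: bool = False,
) -> tuple[list[LoweringResult], pd.DataFrame]:
    """Per-animal percent lowering vs the vehicle grand mean, plus group summary.

    ratio = mean(target)/mean(normaliser) x 1000 (or the raw target mean in
    WBC mode); fold = ratio / vehicle grand mean; lowering = (1 - fold) x 100.
    Animals with a zero normaliser mean are excluded with a reason; the group
    summary reports mean +/- SEM of percent lowering.
    """
    per_animal: list[LoweringResult] = []
    ratios: dict[str, float] = {}
    for r in records:
        if wbc_mode or r.normaliser_signals is None:
            ratios[r.animal_id] = float(np.mean(r.target_signals))
        else:
            norm = float(np.mean(r.normaliser_signals))
            if norm == 0:
                continue  # excluded: zero normaliser mean
            ratios[r.animal_id] = 1000.0 * float(np.mean(r.target_signals)) / norm

    vehicle = [
        ratios[r.animal_id]
        for r in records
        if r.group == vehicle_group and r.animal_id in ratios
    ]
    if not vehicle:
        raise ValueError(f"no usable vehicle animals in group {vehicle_group!r}")
    grand = float(np.mean(vehicle))

    for r in records:
        if r.animal_id not in ratios:
            continue
        fold = ratios[r.animal_id] / grand
        per_animal.append(
            LoweringResult(
                animal_id=r.animal_id,
                group=r.group,
                ratio=ratios[r.animal_id],
                fold_change=fold,
                percent_lowering=(1.0 - fold) * 100.0,
            )
        )

    rows = []
    for group in dict.fromkeys(r.group for r in records):
        vals = [a.percent_lowering for a in per_animal if a.group == group]
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "mean_lowering": float(np.mean(vals)) if vals else np.nan,
                "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else np.nan,
            }
        )
    return per_animal, pd.DataFrame(rows)


@dataclass
class QpcrRecord:
    sample_id: str
    group: str
    target_ct: float
    normaliser_ct: float
    target_efficiency: float = 1.0
    normaliser_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name, ct in (("target", self.target_ct), ("normaliser", self.normaliser_ct)):
            if ct <= 0:
                raise ValueError(f"{self.sample_id}: {name} Ct must be > 0")
        for name, e in (
            ("target", self.target_efficiency),
            ("normaliser", self.normaliser_efficiency),
        ):
            if not 0 < e <= 1.2:
                raise ValueError(
                    f"{self.sample_id}: {name} efficiency {e} outside (0, 1.2]"
                )


def estimate_efficiency(log10_input: Sequence[float], ct: Sequence[float]) -> float:
    """Amplification efficiency from a dilution series: E = 10^(-1/slope) - 1."""
    slope = float(np.polyfit(np.asarray(log10_input, float), np.asarray(ct, float), 1)[0])
    return 10.0 ** (-1.0 / slope) - 1.0


def qpcr_percent(
    records: Sequence[QpcrRecord], vehicle_group: str
) -> pd.DataFrame:
    """Efficiency-corrected relative abundance as percent of the vehicle mean.

    abundance = (1+E)^(-Ct) per amplicon; normalised = target / normaliser;
    percent = 100 * normalised / mean(normalised over vehicle samples).
    """
    rows = []
    for r in records:
        target = (1.0 + r.target_efficiency) ** (-r.target_ct)
        norm = (1.0 + r.normaliser_efficiency) ** (-r.normaliser_ct)
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "target_abundance": target,
                "normaliser_abundance": norm,
                "normalised": target / norm,
            }
        )
    df = pd.DataFrame(rows)
    vehicle_mean = df.loc[df["group"] == vehicle_group, "normalised"].mean()
    if not np.isfinite(vehicle_mean) or vehicle_mean == 0:
        raise ValueError(f"vehicle group {vehicle_group!r} unusable")
    df["percent_of_vehicle"] = 100.0 * df["normalised"] / vehicle_mean
    return df


@dataclass
class PermeabilityRecord:
    direction: str  # "A->B" or "B->A"
    times_s: list[float]
    receiver_uM: list[float]
    vr_cm3: float
    a_cm2: float
    c0_uM: float
    vd_cm3: float | None = None  # carried for user-supplied recovery formulas

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.receiver_uM):
            raise ValueError("times and concentrations differ in length")
        if len(self.times_s) < 2:
            raise ValueError("need >= 2 receiver timepoints")
        if self.c0_uM <= 0:
            raise ValueError("C0 must be positive")


def papp(record: PermeabilityRecord) -> float:
    """Apparent permeability in cm/s: least-squares receiver slope * Vr / (A*C0)."""
    slope = float(
        np.polyfit(np.asarray(record.times_s, float), np.asarray(record.receiver_uM, float), 1)[0]
    )
    return slope * record.vr_cm3 / (record.a_cm2 * record.c0_uM)


def efflux_metrics(papp_ab: float, papp_ba: float) -> dict:
    """Both efflux summaries, labelled: the printed difference and the ratio.

    ``as_printed`` = Papp(B->A) - Papp(A->B); ``conventional_ratio`` =
    Papp(B->A) / Papp(A->B), None when Papp(A->B) = 0.
    """
    if papp_ab < 0 or papp_ba < 0:
        raise ValueError("Papp values must be non-negative")
    return {
        "as_printed": papp_ba - papp_ab,
        "conventional_ratio": (papp_ba / papp_ab) if papp_ab > 0 else None,
    }


def kpuu(c_brain: float, c_plasma: float, fu_b: float, fu_p: float) -> float:
    """Unbound brain partition coefficient Cbrain*fu,b / (Cplasma*fu,p)."""
    if c_brain <= 0 or c_plasma <= 0:
        raise ValueError("concentrations must be positive")
    for name, f in (("fu_b", fu_b), ("fu_p", fu_p)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    denom = c_plasma * fu_p
    if denom == 0:
        raise ValueError("zero plasma term")
    return c_brain * fu_b / denom
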