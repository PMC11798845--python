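"""Cardiac-output and Doppler summary variables.

Derives the hemodynamic covariates used alongside the CEUS perfusion
parameters: combined cardiac output (CCO = LVCO + RVCO), the LVCO:RVCO
ratio, the oxygenator shunt fraction (circuit flow / CCO), and the middle
cerebral artery pulsatility index PI = (PSV - EDV) / TAMV computed from a
maximum-velocity envelope over an integer number of cardiac cycles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["CardiacRecord", "DopplerTrace", "derive_cardiac", "compute_pi", "join_cardiac_perfusion"]

logger = logging.getLogger(__name__)


@dataclass
class CardiacRecord:
    """Per-animal-day cardiac flows, all indexed to body weight (mL/kg/min)."""

    animal_id: str
    day: int
    lvco: float
    rvco: float
    circuit_flow: float
    cco: float
    lv_rv_ratio: float
    shunt_fraction: float
    oxygen_delivery: float = float("nan")
    group: str = ""


@dataclass
class DopplerTrace:
    """Sampled maximum-velocity envelope spanning whole cardiac cycles.

    PSV/EDV/TAMV are the per-trace maximum, minimum and time average of the
    envelope; they are meaningful only when the trace covers an integer
    number of cycles (guaranteed by the synthetic generator).
    """

    times_s: np.ndarray
    envelope_velocity: np.ndarray
    n_cycles: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.envelope_velocity = np.asarray(self.envelope_velocity, dtype=float)
        if self.times_s.shape != self.envelope_velocity.shape or self.times_s.ndim != 1:
            raise InputError("times and envelope must be equal-length 1-D arrays")
        if np.any(self.envelope_velocity < 0):
            raise InputError("envelope velocities must be nonnegative")
        if self.n_cycles < 1:
            raise InputError("trace must span at least one full cycle")

    @property
    def psv(self) -> float:
        """Peak systolic velocity (envelope maximum)."""
        return float(self.envelope_velocity.max())

    @property
    def edv(self) -> float:
        """End-diastolic velocity (envelope minimum)."""
        return float(self.envelope_velocity.min())

    @property
    def tamv(self) -> float:
        """Time-averaged maximum velocity."""
        return float(self.envelope_velocity.mean())


def derive_cardiac(
    lvco: float,
    rvco: float,
    circuit_flow: float,
    animal_id: str = "",
    day: int = 0,
    oxygen_delivery: float = float("nan"),
    group: str = "",
) -> CardiacRecord:
    """Combine raw flows into a :class:`CardiacRecord`.

    CCO = LVCO + RVCO; LVCO:RVCO requires RVCO > 0 (flagged NaN otherwise);
    shunt fraction = circuit flow / CCO, clipped to 1 with a warning if the
    measured circuit flow exceeds the combined output.
    """
    if lvco < 0 or rvco < 0 or circuit_flow < 0:
        raise InputError("flows must be nonnegative")
    cco = lvco + rvco
    if rvco > 0:
        ratio = lvco / rvco
    else:
        warnings.warn("RVCO is zero; LVCO:RVCO undefined", RuntimeWarning, stacklevel=2)
        ratio = float("nan")
    if cco > 0:
        shunt = circuit_flow / cco
        if shunt > 1:
            warnings.warn(
                f"circuit flow {circuit_flow:.1f} exceeds CCO {cco:.1f}; "
                "shunt fraction clipped to 1",
                RuntimeWarning,
                stacklevel=2,
            )
            shunt = 1.0
    else:
        shunt = float("nan")
    return CardiacRecord(
        animal_id=animal_id,
        day=day,
        lvco=lvco,
        rvco=rvco,
        circuit_flow=circuit_flow,
        cco=cco,
        lv_rv_ratio=ratio,
        shunt_fraction=shunt,
        oxygen_delivery=oxygen_delivery,
        group=group,
    )


def compute_pi(trace: DopplerTrace) -> float:
    """Pulsatility index PI = (PSV - EDV) / TAMV of a Doppler envelope."""
    tamv = trace.tamv
    if tamv <= 0:
        raise InputError("TAMV is zero; pulsatility index undefined")
    return (trace.psv - trace.edv) / tamv


def join_cardiac_perfusion(cardiac: pd.DataFrame, perfusion: pd.DataFrame) -> pd.DataFrame:
    """Pair each CEUS exam with the same-day cardiac record.

    Both tables must carry ``animal_id`` and ``day`` columns.  Exams with
    no same-day cardiac row are dropped (counted in the log).  Raises if no
    keys overlap at all.
    """
    for name, df in (("cardiac", cardiac), ("perfusion", perfusion)):
        missing = {"animal_id", "day"} - set(df.columns)
        if missing:
            raise InputError(f"{name} table lacks key columns {sorted(missing)}")
    joined = perfusion.merge(cardiac, on=["animal_id", "day"], how="inner", suffixes=("", "_cardiac"))
    if joined.empty:
        raise InputError("no overlapping (animal_id, day) keys between tables")
    n_exams = len(perfusion.drop_duplicates(subset=["animal_id", "day"]))
    n_joined = len(joined.drop_duplicates(subset=["animal_id", "day"]))
    dropped = n_exams - n_joined
    if dropped:
        logger.info("join_cardiac_perfusion: dropped %d exams without same-day cardiac data", dropped)
    return joined
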