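"""Control-range exceedance calling of per-patient miRNA dysregulation.

The central classification rule of the pipeline: for each panel miRNA the
control cohort defines a reference range [lo, hi] (its minimum and maximum
copies/µL); a patient's value is called UP when it strictly exceeds hi,
DOWN when it falls strictly below lo, and NORMAL otherwise — a value equal
to a bound is NORMAL, since exceedance means "higher/lower than" the
extremes. Per-patient dysregulation counts and >=k signature coverage
summarize how informative a panel is across a cohort.

Under an exchangeable continuous null (a new sample drawn from the same
distribution as n controls), the probability of a non-NORMAL call is
2/(n+1): the new value is equally likely to fall in any of the n+1 rank
gaps, and only the two outer gaps trigger a call. With 6 controls this is
2/7 ≈ 0.286 per miRNA — the rule is a screening heuristic, not a
calibrated test, and the package exposes a Monte-Carlo check of exactly
this rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RangeError
from .screen import CASE, CONTROL


class CallStatus(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NORMAL = "NORMAL"
    MISSING = "MISSING"


class DirectionFilter(str, Enum):
    ANY = "ANY"
    UP_ONLY = "UP_ONLY"
    DOWN_ONLY = "DOWN_ONLY"


@dataclass(frozen=True)
class ControlRange:
    """Reference interval of one miRNA over the control cohort."""

    mirna_id: str
    lo: float
    hi: float
    mean: float
    n_controls: int

    def __post_init__(self) -> None:
        if not self.lo <= self.mean <= self.hi:
            raise ConfigurationError("require lo <= mean <= hi")
        if self.n_controls < 2:
            raise RangeError(
                f"control range for {self.mirna_id} needs >= 2 controls"
            )


@dataclass(frozen=True)
class Call:
    sample_id: str
    mirna_id: str
    value: float
    status: CallStatus


@dataclass
class CallTable:
    """UP/DOWN/NORMAL grid over (patient, panel miRNA) plus per-patient counts.

    ``per_patient_count`` counts non-NORMAL, non-MISSING calls; MISSING
    assays shrink neither the numerator nor are they imputed.
    """

    calls: pd.DataFrame  # columns: sample_id, mirna_id, value, status
    panel: list[str]

    @property
    def per_patient_count(self) -> pd.Series:
        flagged = self.calls["status"].isin([CallStatus.UP.value, CallStatus.DOWN.value])
        counts = (
            self.calls.assign(flagged=flagged)
            .groupby("sample_id", sort=False)["flagged"]
            .sum()
            .astype(int)
        )
        return counts.rename("n_dysregulated")

    def status_grid(self) -> pd.DataFrame:
        """Patients x panel miRNAs status matrix (the tabular-figure layout)."""
        return self.calls.pivot(index="sample_id", columns="mirna_id", values="status")

    def counts_for(
        self, direction: DirectionFilter = DirectionFilter.ANY
    ) -> pd.Series:
        wanted = {
            DirectionFilter.ANY: [CallStatus.UP.value, CallStatus.DOWN.value],
            DirectionFilter.UP_ONLY: [CallStatus.UP.value],
            DirectionFilter.DOWN_ONLY: [CallStatus.DOWN.value],
        }[DirectionFilter(direction)]
        flagged = self.calls["status"].isin(wanted)
        return (
            self.calls.assign(flagged=flagged)
            .groupby("sample_id", sort=False)["flagged"]
            .sum()
            .astype(int)
        )


@dataclass(frozen=True)
class CoverageResult:
    """Fraction of patients with at least k dysregulated panel miRNAs."""

    k: int
    n_flagged: int
    n_patients: int
    fraction: float
    direction_filter: DirectionFilter = DirectionFilter.ANY


def control_ranges(
    ddpcr: pd.DataFrame, meta: pd.DataFrame, panel: Sequence[str] | None = None
) -> dict[str, ControlRange]:
    """Per-miRNA [min, max] (and mean) copies/µL over control samples only."""
    controls = meta.index[meta["group"] == CONTROL]
    sub = ddpcr[ddpcr["sample_id"].isin(controls)]
    if panel is None:
        panel = sorted(sub["mirna_id"].unique())
    ranges: dict[str, ControlRange] = {}
    for mirna in panel:
        vals = sub.loc[sub["mirna_id"] == mirna, "copies_per_ul"].dropna()
        if len(vals) < 2:
            raise RangeError(
                f"miRNA {mirna}: {len(vals)} control value(s); need >= 2"
            )
        ranges[mirna] = ControlRange(
            mirna_id=mirna,
            lo=float(vals.min()),
            hi=float(vals.max()),
            mean=float(vals.mean()),
            n_controls=int(len(vals)),
        )
    return ranges


def _classify(value: float, lo: float, hi: float) -> CallStatus:
    if np.isnan(value):
        return CallStatus.MISSING
    if value > hi:
        return CallStatus.UP
    if value < lo:
        return CallStatus.DOWN
    return CallStatus.NORMAL


def call_patients(
    ddpcr: pd.DataFrame,
    ranges: dict[str, ControlRange],
    panel: Sequence[str],
    meta: pd.DataFrame | None = None,
) -> CallTable:
    """Classify every patient's panel miRNAs against the control ranges.

    Patients are the CASE samples of ``meta`` (every sample in ``ddpcr``
    if no metadata is given). A panel miRNA without a measurement for a
    patient yields a MISSING call, excluded from dysregulation counts.
    """
    missing_ranges = [m for m in panel if m not in ranges]
    if missing_ranges:
        raise RangeError(f"no control range for panel miRNA(s): {missing_ranges}")
    if meta is not None:
        patients = [s for s in meta.index if meta.loc[s, "group"] == CASE]
    else:
        patients = list(dict.fromkeys(ddpcr["sample_id"]))
    wide = ddpcr.pivot(index="sample_id", columns="mirna_id", values="copies_per_ul")
    rows = []
    for patient in patients:
        seen_any = False
        for mirna in panel:
            value = np.nan
            if patient in wide.index and mirna in wide.columns:
                value = wide.loc[patient, mirna]
            status = _classify(value, ranges[mirna].lo, ranges[mirna].hi)
            if status is not CallStatus.MISSING:
                seen_any = True
            rows.append(
                {
                    "sample_id": patient,
                    "mirna_id": mirna,
                    "value": value,
                    "status": status.value,
                }
            )
        if not seen_any:
            warnings.warn(
                f"patient {patient} has no panel measurement; count undefined",
                stacklevel=2,
            )
    return CallTable(calls=pd.DataFrame(rows), panel=list(panel))


def coverage(
    table: CallTable,
    k: int,
    direction_filter: DirectionFilter = DirectionFilter.ANY,
) -> CoverageResult:
    """How many patients show >= k dysregulated miRNAs in the panel."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(table.panel):
        warnings.warn(
            f"k={k} exceeds panel size {len(table.panel)}; no patient can qualify",
            stacklevel=2,
        )
    counts = table.counts_for(direction_filter)
    n_patients = len(counts)
    n_flagged = int((counts >= k).sum())
    fraction = n_flagged / n_patients if n_patients else float("nan")
    return CoverageResult(
        k=k,
        n_flagged=n_flagged,
        n_patients=n_patients,
        fraction=fraction,
        direction_filter=DirectionFilter(direction_filter),
    )


def mean_reference_calls(
    ddpcr: pd.DataFrame,
    ranges: dict[str, ControlRange],
    panel: Sequence[str],
    fold_margin: float = 2.0,
    meta: pd.DataFrame | None = None,
) -> CallTable:
    """Alternative caller against the control mean with a fold margin.

    UP when value > mean x fold_margin, DOWN when value < mean / fold_margin;
    ``fold_margin=1`` degenerates to a strict comparison against the mean
    itself (every off-mean value is called). When a control mean is zero no
    DOWN call is possible; a warning flags the affected miRNA.
    """
    if fold_margin < 1:
        raise ConfigurationError("fold_margin must be >= 1")
    synth = {}
    for mirna in panel:
        mean = ranges[mirna].mean
        if mean == 0 and fold_margin > 1:
            warnings.warn(
                f"miRNA {mirna}: control mean 0, DOWN calls impossible",
                stacklevel=2,
            )
        synth[mirna] = ControlRange(
            mirna_id=mirna,
            lo=mean / fold_margin,
            hi=mean * fold_margin,
            mean=mean,
            n_controls=ranges[mirna].n_controls,
        )
    return call_patients(ddpcr, synth, panel, meta)


def null_specificity(
    n_controls: int, reps: int = 100_000, seed: int | None = None
) -> float:
    """Monte-Carlo per-miRNA non-NORMAL call rate under an exchangeable null.

    Draws ``n_controls`` + 1 iid continuous values per replicate and asks
    whether the held-out value escapes the controls' [min, max]. The
    analytic expectation is 2/(n_controls + 1); the simulation exists to
    validate the calling rule's implementation against that closed form.
    """
    if n_controls < 2:
        raise ConfigurationError("n_controls must be >= 2")
    if reps < 10_000:
        raise ConfigurationError("reps must be >= 10,000 for a stable estimate")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((reps, n_controls + 1))
    controls, new = draws[:, :-1], draws[:, -1]
    called = (new > controls.max(axis=1)) | (new < controls.min(axis=1))
    return float(called.mean())
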