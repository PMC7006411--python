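"""Cohort construction for therapy-cycle analyses in relapsing-remitting MS.

A *therapy cycle* is one continuous episode on an index disease-modifying
therapy (DMT) and is the unit of observation.  This module turns raw cycle
and EDSS tables into the analysis cohort:

* confirmed disability progression (CDP) detection on EDSS trajectories,
* baseline-EDSS selection with the post-relapse validity rule,
* quality filters (complete predictors, documented pre-index relapse and
  EDSS, annualized relapse rate at most 12/year),
* inclusion filters (adults, baseline EDSS <= 6, the six index DMTs,
  no first-line starts within 6 months of diagnosis, one randomly chosen
  cycle per patient, sites with at least two patients),
* a patient-level train/test split.

Time is measured in days since an arbitrary per-registry epoch.  Calendar
phrases are fixed day constants used consistently everywhere:
3 months = 91 d, 6 months = 183 d, 12 months = 365 d; an EDSS measurement is
*valid* if taken at least 84 days after every preceding relapse; a CDP must
be sustained for at least 91 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: the six index DMTs compared throughout: Dimethylfumarat, Fingolimod,
#: Glatirameracetat, Interferon-ss1, Natalizumab, Teriflunomide
INDEX_DMTS = ("DMF", "FTY", "GA", "IF", "NA", "TERI")
#: levels of the therapy taken before the cycle; NONE = treatment-naive/other
CURRENT_DMTS = INDEX_DMTS + ("NONE",)

DAYS_3_MONTHS = 91
DAYS_6_MONTHS = 183
DAYS_12_MONTHS = 365
#: EDSS validity: minimum days after a relapse for a measurement to count
EDSS_VALID_AFTER_RELAPSE = 84
#: minimum sustainment of an EDSS worsening for confirmed progression
CDP_SUSTAIN_DAYS = 91
#: cycles with an annualized relapse rate above this are excluded
MAX_ANNUALIZED_RELAPSE_RATE = 12.0

#: predictor columns that must be non-missing for a cycle to be usable
PREDICTOR_COLUMNS = (
    "site_id",
    "index_dmt",
    "current_dmt",
    "age",
    "gender",
    "diagnosis_distance",
    "relapse_distance",
    "relapses_count",
    "dmts_count",
    "second_line",
    "current_duration",
    "index_duration",
)


class BaselineUnavailableError(ValueError):
    """No valid reference EDSS exists for the cycle; CDP is undeterminable."""


class CohortExhaustedError(ValueError):
    """A filter removed every remaining cycle."""


@dataclass(frozen=True)
class EdssTrajectory:
    """Timestamped EDSS series plus relapse dates for one patient.

    Measurement times are strictly increasing; EDSS scores lie on the
    half-point grid in [0, 10].
    """

    patient_id: str
    times: np.ndarray  # days, strictly increasing
    edss: np.ndarray
    relapse_days: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        edss = np.asarray(self.edss, dtype=float)
        relapses = np.sort(np.asarray(self.relapse_days, dtype=float))
        if times.shape != edss.shape:
            raise ValueError("times and edss must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if edss.size and (
            np.any(edss < 0) or np.any(edss > 10) or np.any(edss * 2 != np.round(edss * 2))
        ):
            raise ValueError("EDSS values must lie on the half-point grid in [0, 10]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "edss", edss)
        object.__setattr__(self, "relapse_days", relapses)

    def valid_mask(self) -> np.ndarray:
        """Measurements taken >= 84 days after every preceding relapse."""
        if self.relapse_days.size == 0:
            return np.ones(self.times.size, dtype=bool)
        # last relapse strictly before each measurement
        idx = np.searchsorted(self.relapse_days, self.times, side="left")
        last = np.where(idx > 0, self.relapse_days[np.maximum(idx - 1, 0)], -np.inf)
        return self.times - last >= EDSS_VALID_AFTER_RELAPSE


@dataclass
class FilterReport:
    """Per-criterion removal counts, in application order."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def record(self, criterion: str, n: int) -> None:
        self.removed[criterion] = self.removed.get(criterion, 0) + int(n)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_output": self.n_output,
        }


def baseline_edss(
    traj: EdssTrajectory, cycle_start: float, *, return_time: bool = False
):
    """Reference EDSS for a cycle starting at ``cycle_start`` (days).

    The baseline is the valid measurement closest to the cycle start within
    [start - 183 d, start + 91 d]; a measurement is valid if it is at least
    84 days after every preceding relapse.  Returns ``None`` when no
    measurement qualifies.  Ties in distance resolve to the earlier
    measurement.
    """
    valid = traj.valid_mask()
    in_window = (traj.times >= cycle_start - DAYS_6_MONTHS) & (
        traj.times <= cycle_start + DAYS_3_MONTHS
    )
    mask = valid & in_window
    if not mask.any():
        return None
    cand_times = traj.times[mask]
    cand_edss = traj.edss[mask]
    dist = np.abs(cand_times - cycle_start)
    best = int(np.argmin(dist))  # argmin takes the first = earliest on ties
    if return_time:
        return float(cand_edss[best]), float(cand_times[best])
    return float(cand_edss[best])


def detect_cdp(
    traj: EdssTrajectory, cycle_start: float, cycle_end: float
) -> tuple[bool, float | None]:
    """Detect a confirmed disability progression within a therapy cycle.

    A CDP is a worsening relative to the reference (baseline) EDSS of at
    least 1.0 point when the reference is 5.5 or lower and 0.5 point
    otherwise.  The worsening must be sustained for at least 91 days — no
    valid measurement within that period may fall back below the progressed
    threshold — and must be confirmed by at least one additional valid
    measurement at or above the threshold taken >= 91 days after onset.

    Returns ``(occurred, onset_day)``; ``onset_day`` is the first qualifying
    measurement time, or ``None`` when no CDP occurred.

    Raises
    ------
    BaselineUnavailableError
        If no valid reference EDSS exists for the cycle.
    """
    ref = baseline_edss(traj, cycle_start)
    if ref is None:
        raise BaselineUnavailableError(
            f"no valid baseline EDSS for patient {traj.patient_id!r} "
            f"at cycle start {cycle_start}"
        )
    threshold = ref + (1.0 if ref <= 5.5 else 0.5)
    valid = traj.valid_mask()
    in_cycle = (traj.times > cycle_start) & (traj.times <= cycle_end)
    times = traj.times[valid & in_cycle]
    edss = traj.edss[valid & in_cycle]

    for onset, score in zip(times, edss):
        if score < threshold:
            continue
        window = (times > onset) & (times <= onset + CDP_SUSTAIN_DAYS)
        if np.any(edss[window] < threshold):
            continue  # worsening not sustained from this onset
        confirm = (times >= onset + CDP_SUSTAIN_DAYS) & (edss >= threshold)
        if confirm.any():
            return True, float(onset)
    return False, None


def derive_endpoints(
    cycles: pd.DataFrame, trajectories: Mapping[str, EdssTrajectory]
) -> pd.DataFrame:
    """Attach ``edss_baseline``, ``cdp`` and ``n_relapses`` from trajectories.

    Requires ``cycle_start_day`` and ``cycle_end_day`` columns.  Cycles whose
    patient has no trajectory, or no valid baseline EDSS, get missing values
    (they are removed later by the quality filter).
    """
    out = cycles.copy()
    baselines, cdps, counts = [], [], []
    for row in out.itertuples(index=False):
        traj = trajectories.get(row.patient_id)
        start, end = row.cycle_start_day, row.cycle_end_day
        if traj is None:
            baselines.append(np.nan)
            cdps.append(np.nan)
            counts.append(np.nan)
            continue
        base = baseline_edss(traj, start)
        baselines.append(np.nan if base is None else base)
        if base is None:
            cdps.append(np.nan)
        else:
            occurred, _ = detect_cdp(traj, start, end)
            cdps.append(occurred)
        counts.append(
            int(np.sum((traj.relapse_days > start) & (traj.relapse_days <= end)))
        )
    out["edss_baseline"] = baselines
    out["cdp"] = cdps
    out["n_relapses"] = counts
    return out


def apply_quality_criteria(cycles: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Sequential data-quality filters; removal counts itemized in order.

    Criteria: every predictor available; at least one documented relapse
    before the index start (non-missing ``relapse_distance``); a documented
    pre-index EDSS (non-missing ``edss_baseline``); annualized relapse rate
    ``n_relapses / index_duration`` at most 12 per year (exactly 12 is kept).
    """
    report = FilterReport(n_input=len(cycles))
    df = cycles

    missing_pred = df[list(PREDICTOR_COLUMNS)].isna().any(axis=1)
    report.record("missing_predictor", missing_pred.sum())
    df = df[~missing_pred]

    # redundant with predictor completeness when relapse_distance is listed
    # there, but kept as its own named criterion for reporting
    no_relapse = df["relapse_distance"].isna()
    report.record("no_preindex_relapse", no_relapse.sum())
    df = df[~no_relapse]

    no_edss = df["edss_baseline"].isna()
    report.record("no_preindex_edss", no_edss.sum())
    df = df[~no_edss]

    arr = df["n_relapses"] / df["index_duration"]
    extreme = arr > MAX_ANNUALIZED_RELAPSE_RATE
    report.record("annualized_relapse_rate_above_12", extreme.sum())
    df = df[~extreme]

    if len(df) == 0:
        raise CohortExhaustedError("quality criteria removed every cycle")
    return df.copy(), report


def apply_inclusion_criteria(
    cycles: pd.DataFrame, rng_seed: int
) -> tuple[pd.DataFrame, FilterReport]:
    """Population-selection filters, then one cycle per patient, then site pruning.

    Retains cycles with age >= 18, baseline EDSS <= 6 and an index DMT among
    the six studied.  Cycles started within 6 months (0.5 y) of MS diagnosis
    without a previous treatment failure (operationalized as
    ``dmts_count == 0``) are removed: they are not therapy switches.  One
    cycle per patient is then chosen uniformly at random (seeded), and sites
    with fewer than two remaining patients are dropped, iterated to a fixed
    point.
    """
    report = FilterReport(n_input=len(cycles))
    df = cycles

    underage = df["age"] < 18
    report.record("age_below_18", underage.sum())
    df = df[~underage]

    high_edss = df["edss_baseline"] > 6
    report.record("edss_above_6", high_edss.sum())
    df = df[~high_edss]

    bad_dmt = ~df["index_dmt"].isin(INDEX_DMTS)
    report.record("index_dmt_not_studied", bad_dmt.sum())
    df = df[~bad_dmt]

    early = (df["diagnosis_distance"] <= 0.5) & (df["dmts_count"] == 0)
    report.record("early_start_without_failure", early.sum())
    df = df[~early]

    # one uniformly chosen cycle per patient, reproducible: operate on a
    # patient-sorted, stably ordered frame so the draw depends only on content
    df = df.sort_values("patient_id", kind="mergesort")
    rng = np.random.default_rng(rng_seed)
    keep_idx = []
    for _, group in df.groupby("patient_id", sort=True):
        keep_idx.append(group.index[rng.integers(len(group))])
    n_dropped = len(df) - len(keep_idx)
    report.record("extra_cycles_per_patient", n_dropped)
    df = df.loc[keep_idx]

    # prune sites with < 2 patients; iterate to a fixed point
    n_site_removed = 0
    while True:
        patients_per_site = df.groupby("site_id")["patient_id"].nunique()
        lonely = patients_per_site[patients_per_site < 2].index
        if len(lonely) == 0:
            break
        mask = df["site_id"].isin(lonely)
        n_site_removed += int(mask.sum())
        df = df[~mask]
    report.record("single_patient_site", n_site_removed)

    if len(df) == 0:
        raise CohortExhaustedError("inclusion criteria removed every cycle")
    return df.copy(), report


def split_test(
    cycles: pd.DataFrame, fraction: float, rng_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level train/test split with ``round(n_patients * fraction)``
    patients in the test set (banker's rounding, documented convention)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    patients = np.sort(cycles["patient_id"].unique())
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(patients)
    n_test = int(round(len(patients) * fraction))
    test_patients = set(patients[:n_test])
    mask = cycles["patient_id"].isin(test_patients)
    return cycles[~mask].copy(), cycles[mask].copy()


# ---------------------------------------------------------------------------
# CSV interfaces


def read_cycles(path) -> pd.DataFrame:
    """Read a therapy-cycle table (one row per cycle, documented columns)."""
    df = pd.read_csv(path)
    if "second_line" in df:
        df["second_line"] = df["second_line"].astype(bool)
    if "cdp" in df:
        df["cdp"] = df["cdp"].astype(bool)
    return df


def read_trajectories(edss_path, relapse_path=None) -> dict[str, EdssTrajectory]:
    """Read EDSS (patient_id, day, edss) and relapse (patient_id, day) tables."""
    edss = pd.read_csv(edss_path)
    relapses: dict[str, np.ndarray] = {}
    if relapse_path is not None:
        rel = pd.read_csv(relapse_path)
        relapses = {
            pid: grp["day"].to_numpy(float) for pid, grp in rel.groupby("patient_id")
        }
    out = {}
    for pid, grp in edss.groupby("patient_id"):
        grp = grp.sort_values("day")
        out[pid] = EdssTrajectory(
            patient_id=str(pid),
            times=grp["day"].to_numpy(float),
            edss=grp["edss"].to_numpy(float),
            relapse_days=relapses.get(pid, np.empty(0)),
        )
    return out


def write_cohort(cycles: pd.DataFrame, path) -> None:
    cycles.to_csv(path, index=False)
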