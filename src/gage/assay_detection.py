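"""Detection calling on replicate fluorescence time series.

A Cas12a collateral-cleavage assay reports target presence as fluorescence
from an FQ reporter.  A group (one DNA-substrate concentration or sample) is
*detected* when its replicate readings at a chosen timepoint are
significantly higher than the no-template control: a two-sided Welch t-test
at ``alpha`` (default 0.01) combined with a mean-direction guard, which
together implement the one-sided "significantly higher than control" call.

Scanning a dilution ladder gives the limit of detection (LOD): the smallest
concentration called detected.  The default test timepoint is 25 min, where
the reaction signal typically plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluorescenceSeries",
    "DetectionResult",
    "LodResult",
    "detection_call",
    "lod_scan",
    "read_plate_tsv",
    "write_calls_tsv",
]

#: Measurement grid (minutes) used by the reference assay protocol.
DEFAULT_TIMEPOINTS_MIN = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 25.0, 35.0, 45.0, 60.0)

DEFAULT_TEST_TIMEPOINT_MIN = 25.0


@dataclass
class FluorescenceSeries:
    """Replicate fluorescence readings for one group on a shared time grid.

    ``readings`` is (n_replicates, n_timepoints) in arbitrary fluorescence
    units; at least two replicates are required and readings must be
    non-negative.  ``concentration`` (ng/uL) is optional and used only by
    :func:`lod_scan`.
    """

    group_label: str
    timepoints_min: tuple[float, ...]
    readings: np.ndarray
    concentration: float | None = None

    def __post_init__(self) -> None:
        self.timepoints_min = tuple(float(t) for t in self.timepoints_min)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 2:
            raise ValueError("readings must be a replicate x timepoint matrix")
        if self.readings.shape[0] < 2:
            raise ValueError(
                f"group {self.group_label!r}: at least 2 replicates required"
            )
        if self.readings.shape[1] != len(self.timepoints_min):
            raise ValueError(
                f"group {self.group_label!r}: readings have "
                f"{self.readings.shape[1]} timepoints, grid has "
                f"{len(self.timepoints_min)}"
            )
        if np.any(self.readings < 0):
            raise ValueError(f"group {self.group_label!r}: negative readings")
        diffs = np.diff(self.timepoints_min)
        if len(diffs) and np.any(diffs <= 0):
            raise ValueError(
                f"group {self.group_label!r}: timepoints must be strictly increasing"
            )

    @property
    def n_replicates(self) -> int:
        return int(self.readings.shape[0])

    def reading_at(self, at_min: float) -> np.ndarray:
        """Replicate readings at timepoint ``at_min`` (must be on the grid)."""
        matches = [
            i
            for i, t in enumerate(self.timepoints_min)
            if np.isclose(t, at_min)
        ]
        if not matches:
            raise ValueError(
                f"timepoint {at_min} min not in grid {self.timepoints_min}"
            )
        return self.readings[:, matches[0]]


@dataclass
class DetectionResult:
    """Verdict for one group vs the negative control at one timepoint."""

    group_label: str
    p_value: float
    alpha: float
    detected: bool
    test_timepoint_min: float
    group_mean: float
    control_mean: float
    concentration: float | None = None


@dataclass
class LodResult:
    """Per-concentration calls and the limit of detection.

    ``lod`` is the smallest detected concentration, or None if no group was
    detected.  ``monotonic`` is False when some undetected concentration lies
    above a detected one (an inconsistent ladder worth inspecting).
    """

    results: list[DetectionResult]
    lod: float | None
    monotonic: bool


def detection_call(
    group: FluorescenceSeries,
    control: FluorescenceSeries,
    alpha: float = 0.01,
    at_min: float = DEFAULT_TEST_TIMEPOINT_MIN,
    equal_var: bool = False,
) -> DetectionResult:
    """Welch t-test of group vs control replicates at one timepoint.

    ``detected`` requires both ``p < alpha`` and group mean above control
    mean, so a significantly *lower* group is never called detected.  With
    zero variance in both groups the p-value degenerates to 1.0 for equal
    means and 0.0 otherwise.
    """
    g = group.reading_at(at_min)
    c = control.reading_at(at_min)
    with warnings.catch_warnings():
        # near-constant inputs trip scipy's precision warning; the nan
        # fallback below handles the truly degenerate case explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_value = stats.ttest_ind(g, c, equal_var=equal_var)
    if np.isnan(p_value):
        p_value = 1.0 if np.isclose(g.mean(), c.mean()) else 0.0
    p_value = float(p_value)
    g_mean, c_mean = float(g.mean()), float(c.mean())
    return DetectionResult(
        group_label=group.group_label,
        p_value=p_value,
        alpha=alpha,
        detected=bool(p_value < alpha and g_mean > c_mean),
        test_timepoint_min=float(at_min),
        group_mean=g_mean,
        control_mean=c_mean,
        concentration=group.concentration,
    )


def lod_scan(
    groups: Sequence[FluorescenceSeries],
    control: FluorescenceSeries,
    alpha: float = 0.01,
    at_min: float = DEFAULT_TEST_TIMEPOINT_MIN,
    equal_var: bool = False,
) -> LodResult:
    """Call every concentration of a dilution ladder and find the LOD."""
    if not groups:
        raise ValueError("at least one concentration group is required")
    concs = [g.concentration for g in groups]
    if any(c is None for c in concs):
        raise ValueError("every ladder group needs a numeric concentration")
    if len(set(concs)) != len(concs):
        raise ValueError("ladder concentrations must be distinct")
    ordered = sorted(groups, key=lambda g: -g.concentration)
    results = [
        detection_call(g, control, alpha=alpha, at_min=at_min, equal_var=equal_var)
        for g in ordered
    ]
    detected = [r.concentration for r in results if r.detected]
    lod = min(detected) if detected else None
    monotonic = True
    if lod is not None:
        monotonic = all(
            r.detected for r in results if r.concentration > lod
        ) and all(
            not r.detected for r in results if r.concentration < lod
        )
    return LodResult(results=results, lod=lod, monotonic=monotonic)


def read_plate_tsv(path) -> dict[str, FluorescenceSeries]:
    """Read long-format replicate readings.

    Columns: ``group``, ``replicate``, ``timepoint_min``, ``reading``
    (tab-separated, ``#`` comments allowed).  Returns one series per group,
    in file order.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        names = first.lstrip("#").split("\t")
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    else:
        df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip() for c in df.columns]
    required = {"group", "replicate", "timepoint_min", "reading"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate TSV is missing columns: {sorted(missing)}")
    series: dict[str, FluorescenceSeries] = {}
    for label in df["group"].drop_duplicates():
        sub = df[df["group"] == label]
        pivot = sub.pivot_table(
            index="replicate", columns="timepoint_min", values="reading"
        ).sort_index(axis=1)
        if pivot.isna().any().any():
            raise ValueError(
                f"group {label!r}: incomplete replicate x timepoint grid"
            )
        series[str(label)] = FluorescenceSeries(
            group_label=str(label),
            timepoints_min=tuple(float(t) for t in pivot.columns),
            readings=pivot.to_numpy(),
        )
    return series


def write_calls_tsv(results: Sequence[DetectionResult], path) -> None:
    with open(path, "wt") as fh:
        fh.write(
            "#group\tconcentration\tp_value\talpha\tgroup_mean\t"
            "control_mean\ttimepoint_min\tdetected\n"
        )
        for r in results:
            conc = "" if r.concentration is None else f"{r.concentration:g}"
            fh.write(
                f"{r.group_label}\t{conc}\t{r.p_value:.6g}\t{r.alpha:g}\t"
                f"{r.group_mean:.6g}\t{r.control_mean:.6g}\t"
                f"{r.test_timepoint_min:g}\t{str(r.detected).lower()}\n"
            )
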