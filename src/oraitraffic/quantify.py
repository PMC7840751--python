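"""Marker-peak percent-PM statistic and PM-plane colocalization.

The statistic: locate the PM by the z slice with maximal summed marker
fluorescence, split the stack into a "surface" and a "cytoplasm" compartment
at that peak, and report 100 × surface / (surface + cytoplasm) of the cargo
channel. Marker roles:

* ``pm_marker`` (TMEM16A-like): surface runs from the outermost slice through
  the peak (default ``through_peak`` convention; ``past_peak`` additionally
  assigns the first sub-peak slice to surface).
* ``cytoplasmic_marker`` (Rab5-like): the peak itself is cytoplasmic, so
  surface stops one slice above it.
* ``caveolin_pm_above``: surface is everything above the caveolin peak.

Every slice belongs to exactly one compartment under every convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simulate import TwoChannelStack

MARKER_ROLES = ("pm_marker", "cytoplasmic_marker", "caveolin_pm_above")
CONVENTIONS = ("through_peak", "past_peak")


class QuantifyError(ValueError):
    """Raised for unquantifiable stacks (all-zero marker, empty groups...)."""


@dataclass(frozen=True)
class PMQuantResult:
    """Outcome of the percent-PM statistic on one stack."""

    peak_slice: int
    surface_sum: float
    cytoplasm_sum: float
    percent_pm: float
    convention: str
    marker_role: str
    degenerate: bool = False  # one compartment empty (peak at a stack edge)


def find_marker_peak(stack: TwoChannelStack, channel: str = "marker") -> int:
    """z index of the slice with maximal summed intensity in ``channel``.

    Ties break toward the outermost slice (lowest index).
    """
    img = getattr(stack, channel)
    sums = img.reshape(img.shape[0], -1).sum(axis=1)
    if not sums.any():
        raise QuantifyError(f"all-zero {channel} channel; no peak")
    return int(np.argmax(sums))


def _partition(nz: int, peak: int, marker_role: str, convention: str
               ) -> tuple[slice, slice]:
    """(surface, cytoplasm) slice ranges; exhaustive and non-overlapping."""
    if marker_role == "pm_marker":
        split = peak + 1 if convention == "through_peak" else peak + 2
    elif marker_role in ("cytoplasmic_marker", "caveolin_pm_above"):
        split = peak
    else:
        raise QuantifyError(f"unknown marker_role {marker_role!r}")
    split = min(max(split, 0), nz)
    return slice(0, split), slice(split, nz)


def percent_pm(stack: TwoChannelStack, marker_role: str = "pm_marker",
               convention: str = "through_peak",
               background: float | None = None) -> PMQuantResult:
    """Percent of cargo fluorescence in the surface compartment.

    ``background``, when given, is a constant subtracted from the cargo
    channel before summing (off by default; clipped at zero).
    """
    if convention not in CONVENTIONS:
        raise QuantifyError(f"unknown convention {convention!r}")
    peak = find_marker_peak(stack)
    surface, cytoplasm = _partition(stack.nz, peak, marker_role, convention)
    cargo = stack.cargo
    if background is not None:
        cargo = np.maximum(cargo - background, 0.0)
    s = float(cargo[surface].sum())
    c = float(cargo[cytoplasm].sum())
    if s + c <= 0:
        raise QuantifyError("no cargo signal in the stack")
    degenerate = surface.stop - surface.start == 0 or cytoplasm.stop - cytoplasm.start == 0
    return PMQuantResult(
        peak_slice=peak,
        surface_sum=s,
        cytoplasm_sum=c,
        percent_pm=100.0 * s / (s + c),
        convention=convention,
        marker_role=marker_role,
        degenerate=degenerate,
    )


def pearson_colocalization(stack: TwoChannelStack,
                           slice_index: int | None = None) -> float:
    """Pixelwise Pearson coefficient between the channels on one focal plane.

    Defaults to the marker-peak (PM) plane. A constant channel on the chosen
    slice makes the coefficient undefined and raises, never returns 0.
    """
    idx = find_marker_peak(stack) if slice_index is None else slice_index
    if not 0 <= idx < stack.nz:
        raise QuantifyError(f"slice {idx} outside [0, {stack.nz - 1}]")
    return stats.pearson_r(stack.marker[idx], stack.cargo[idx])


def batch_quantify(stacks: list[TwoChannelStack], grouping: list[str],
                   marker_role: str = "pm_marker",
                   convention: str = "through_peak",
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stack results plus per-group mean ± SEM.

    Returns (per-stack table, group summary). Groups of size 1 get a NaN SEM
    and are flagged. Group comparison (t test / one-way ANOVA) is available
    via :func:`oraitraffic.stats.compare_groups` on the returned table.
    """
    if len(stacks) != len(grouping):
        raise QuantifyError("grouping must label every stack")
    if not stacks:
        raise QuantifyError("no stacks supplied")
    rows = []
    for label, stack in zip(grouping, stacks):
        res = percent_pm(stack, marker_role=marker_role, convention=convention)
        rows.append(
            {
                "group": label,
                "peak_slice": res.peak_slice,
                "surface_sum": res.surface_sum,
                "cytoplasm_sum": res.cytoplasm_sum,
                "percent_pm": res.percent_pm,
                "convention": res.convention,
                "marker_role": res.marker_role,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(rows)
    summaries = []
    for label, sub in table.groupby("group", sort=False):
        vals = sub["percent_pm"].to_numpy()
        summaries.append(
            {
                "group": label,
                "n": len(vals),
                "mean_percent_pm": float(vals.mean()),
                "sem_percent_pm": stats.sem(vals),
                "single_stack": len(vals) == 1,
            }
        )
    return table, pd.DataFrame(summaries)
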