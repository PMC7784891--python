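"""Scalar quantifiers for immunofluorescence and behavior.

* CTCF — corrected total cell fluorescence, the standard ImageJ-style
  measure: integrated density minus (ROI area x mean background).
* Normalized fluorescence — per-cell CTCF as a percentage of the mean
  CTCF of a reference group (non-PV neurons of control animals), so the
  reference group averages exactly 100 %.
* Y-maze spontaneous alternation index — percentage of overlapping
  triplets of consecutive arm entries that visit three distinct arms;
  with three arms and no immediate re-entries, chance level is 50 %.
* %PPI — percent prepulse inhibition of acoustic startle per prepulse
  intensity, from per-intensity trial means.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import CellFluorescence


def ctcf(cell: CellFluorescence) -> float:
    """Corrected total cell fluorescence of one ROI measurement.

    CTCF = integrated_density - area * background_mean.  A negative
    result (cell dimmer than background) is returned as-is.
    """
    for v in (cell.integrated_density, cell.area, cell.background_mean):
        if not np.isfinite(v):
            raise ValueError("CTCF inputs must be finite")
    return float(cell.integrated_density - cell.area * cell.background_mean)


def normalized_fluorescence(
    cells: Sequence[CellFluorescence],
    reference: Callable[[CellFluorescence], bool] | tuple[str, str],
) -> np.ndarray:
    """Per-cell CTCF as % of the reference group's mean CTCF.

    ``reference`` is either a predicate over cells or a
    ``(group, genotype)`` pair, e.g. ``("non-PV", "control")``.
    """
    if isinstance(reference, tuple):
        group, genotype = reference
        pred = lambda c: c.group == group and c.genotype == genotype
    else:
        pred = reference
    values = np.array([ctcf(c) for c in cells])
    ref = np.array([v for c, v in zip(cells, values) if pred(c)])
    if ref.size == 0:
        raise ValueError("reference group is empty")
    ref_mean = ref.mean()
    if ref_mean <= 0:
        raise ValueError(f"reference group mean CTCF must be positive, got {ref_mean:g}")
    return 100.0 * values / ref_mean


def alternation_index(entries: Iterable[str]) -> float:
    """Y-maze spontaneous alternation index (%).

    100 x (number of overlapping windows of three consecutive entries
    containing three distinct arms) / (n_entries - 2).
    """
    seq = list(entries)
    if len(seq) < 3:
        raise ValueError("need >= 3 arm entries")
    for prev, cur in zip(seq, seq[1:]):
        if prev == cur:
            raise ValueError("invalid transition log: consecutive entries equal")
    wins = sum(
        1 for i in range(len(seq) - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    return 100.0 * wins / (len(seq) - 2)


def ppi_percent(startle_table: pd.DataFrame) -> dict[str, float]:
    """Percent prepulse inhibition per prepulse trial type.

    %PPI(i) = 100 x (mean pulse-alone - mean prepulse(i)+pulse) / mean
    pulse-alone.  Facilitation yields a negative value, returned
    unclipped.
    """
    required = {"trial_type", "amplitude"}
    if not required.issubset(startle_table.columns):
        raise ValueError(f"startle table needs columns {sorted(required)}")
    pulse = startle_table.loc[startle_table["trial_type"] == "pulse_alone", "amplitude"]
    if pulse.empty:
        raise ValueError("need >= 1 pulse_alone trial")
    pa = pulse.mean()
    if pa == 0:
        raise ValueError("mean pulse-alone startle is zero; %PPI undefined")
    out: dict[str, float] = {}
    for ttype, grp in startle_table.groupby("trial_type", sort=True):
        if ttype == "pulse_alone":
            continue
        if grp.empty:
            raise ValueError(f"no trials for {ttype}")
        out[str(ttype)] = float(100.0 * (pa - grp["amplitude"].mean()) / pa)
    return out
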