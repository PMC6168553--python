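"""Immuno-gold filament-polarity statistics.

Gold-particle annotations (off filament, on filament body, on a filament end)
summarize where an end-labelling probe binds.  A strong excess of end-bound
particles over the fraction expected under uniform binding supports polar,
single-end nucleation; the excess is tested with a one-sided exact binomial
test.  The expected end fraction under no preference (rho0) depends on what
the annotator counts as an "end" and must be supplied by the caller, e.g.
2 × (end window length) / (mean filament length).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import binomtest

__all__ = ["GoldSummary", "gold_summary", "end_preference_test"]

LOCATIONS = {"off", "on_body", "on_end"}


@dataclass(frozen=True)
class GoldSummary:
    n_total: int
    n_on_filament: int
    n_on_end: int
    fraction_on_filament: float
    fraction_at_end: float | None  # None when no particle is on a filament
    filaments_with_both_ends: int | None  # None without filament ids


def gold_summary(table: pd.DataFrame) -> GoldSummary:
    """Summarize a gold-particle annotation table.

    Expects columns image_id, particle_id, location (off/on_body/on_end) and
    optionally filament_id.  The both-ends count requires filament ids and is
    the number of filaments carrying two or more end-bound particles (a
    conservative stand-in for "both ends" when end identity is not annotated).
    """
    if len(table) == 0:
        raise ValueError("empty annotation table")
    bad = set(table["location"]) - LOCATIONS
    if bad:
        raise ValueError(f"unknown location labels: {sorted(bad)}")
    if table.duplicated(["image_id", "particle_id"]).any():
        raise ValueError("particle ids are not unique within images")
    n = len(table)
    n_end = int((table["location"] == "on_end").sum())
    n_body = int((table["location"] == "on_body").sum())
    n_fil = n_end + n_body
    both = None
    if "filament_id" in table.columns:
        ends = table[(table["location"] == "on_end") & (table["filament_id"] != "")]
        per_fil = ends.groupby("filament_id").size()
        both = int((per_fil >= 2).sum())
    return GoldSummary(
        n_total=n,
        n_on_filament=n_fil,
        n_on_end=n_end,
        fraction_on_filament=n_fil / n,
        fraction_at_end=(n_end / n_fil) if n_fil else None,
        filaments_with_both_ends=both,
    )


def end_preference_test(n_end: int, n_body: int, rho0: float) -> float:
    """One-sided exact binomial p-value for end-binding preference.

    P[X >= n_end] for X ~ Binomial(n_end + n_body, rho0): the probability,
    under uniform binding with expected end fraction rho0, of seeing at least
    as many end-bound particles as observed.
    """
    if n_end < 0 or n_body < 0 or n_end + n_body < 1:
        raise ValueError("need at least one on-filament particle")
    if not 0 < rho0 < 1:
        raise ValueError("rho0 must be strictly between 0 and 1")
    return float(binomtest(n_end, n_end + n_body, rho0, alternative="greater").pvalue)
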