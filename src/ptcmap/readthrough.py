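"""Premature-stop-codon readthrough, relative to wild type and to activity.

The readthrough assay places a premature stop codon (UAG, UGA or UAA) at a
chosen amino-acid position of the sfGFP reporter; any fluorescence requires
the ribosome to read through it. For each construct, mutant endpoint signal
is divided by the wild-type signal on the same construct (wild type ≡ 1),
then normalized by the mutant's translation activity so that a weakly
translating mutant is not mistaken for a low-readthrough one.

Below an activity floor (default 2% of wild type) the normalization
amplifies noise without bound, so those records are flagged undefined (NaN)
while the raw relative readthrough is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

STOP_CODONS = ("UAG", "UGA", "UAA")
DEFAULT_STOP_POSITIONS = (50, 100, 116, 216)
DEFAULT_ACTIVITY_FLOOR = 0.02


@dataclass(frozen=True)
class ReadthroughConstruct:
    """A reporter with a premature stop codon at a given amino-acid index."""

    stop_codon: str
    position: int

    def __post_init__(self) -> None:
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"not a stop codon: {self.stop_codon!r}")
        if self.position < 1:
            raise ValueError("stop position must be ≥ 1")

    @property
    def label(self) -> str:
        return f"{self.stop_codon}@{self.position}"


def relative_readthrough(mutant_signal: float, wt_signal: float) -> float:
    """Mutant / wild-type endpoint signal on the same construct."""
    if not wt_signal > 0:
        raise ValueError("wild-type readthrough signal must be positive")
    if mutant_signal < 0:
        raise ValueError("signals cannot be negative")
    return mutant_signal / wt_signal


def normalize_by_activity(
    rel_readthrough: float,
    rel_activity: float,
    floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> float:
    """Relative readthrough divided by the mutant's relative activity.

    Returns NaN (an explicit undefined marker, never infinity) when the
    activity lies below the floor.
    """
    if rel_activity < 0:
        raise ValueError("relative activity cannot be negative")
    if rel_activity < floor:
        return math.nan
    return rel_readthrough / rel_activity


def readthrough_table(
    signals_df: pd.DataFrame,
    activity_df: pd.DataFrame,
    wt_id: str = "WT",
    floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> pd.DataFrame:
    """Per-mutant, per-construct readthrough records.

    ``signals_df`` columns: sample_id, stop_codon, aa_position, replicate,
    signal. Replicates are averaged before ratios; the wild-type mean is
    computed independently per construct. ``activity_df`` is the activity
    module's record table (sample_id, relative_activity).
    """
    required = {"sample_id", "stop_codon", "aa_position", "replicate", "signal"}
    missing = required - set(signals_df.columns)
    if missing:
        raise ValueError(f"signal table lacks columns {sorted(missing)}")

    means = (
        signals_df.groupby(["sample_id", "stop_codon", "aa_position"], sort=True)["signal"]
        .mean()
        .reset_index()
    )
    wt = means[means["sample_id"] == wt_id].set_index(["stop_codon", "aa_position"])
    if wt.empty:
        raise ValueError(f"no wild-type ({wt_id!r}) signals in table")
    activity = activity_df.set_index("sample_id")["relative_activity"]

    rows = []
    for _, rec in means.iterrows():
        construct = (rec["stop_codon"], rec["aa_position"])
        if construct not in wt.index:
            raise ValueError(f"no wild-type signal for construct {construct}")
        rel = relative_readthrough(rec["signal"], float(wt.loc[construct, "signal"]))
        sample = rec["sample_id"]
        act = 1.0 if sample == wt_id else float(activity.get(sample, math.nan))
        if math.isnan(act):
            raise ValueError(f"no activity record for {sample!r}")
        norm = normalize_by_activity(rel, act, floor=floor)
        rows.append(
            {
                "sample_id": sample,
                "stop_codon": rec["stop_codon"],
                "aa_position": int(rec["aa_position"]),
                "relative_readthrough": rel,
                "relative_activity": act,
                "normalized_readthrough": norm,
                "defined": not math.isnan(norm),
            }
        )
    return pd.DataFrame(rows)
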