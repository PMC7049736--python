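"""End-to-end analysis over a panel bundle (real or synthetic).

Chains the stage modules in study order: standard-curve fit → activity
records → flexibility scores; entropy profile of the alignment at the
study positions; readthrough table; gradient species areas; structure
distances and shells; and the flexibility-vs-entropy / -vs-distance
regressions. Used by the numbered analysis drivers, the tests and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import conservation, readthrough, sedimentation, stats, structure
from .activity import activity_records, fit_standard_curve, flexibility_scores
from .regions import default_regions, enumerate_positions
from .synth import PanelBundle


@dataclass
class PanelResults:
    activity: pd.DataFrame
    flexibility: pd.DataFrame
    entropy: pd.DataFrame
    readthrough: pd.DataFrame
    species_areas: dict[str, sedimentation.SpeciesAreas]
    distances: pd.DataFrame
    shells: pd.DataFrame
    regressions: dict[str, stats.RegressionResult]


def score_panel(bundle: PanelBundle, regions=None) -> PanelResults:
    """Run every analysis stage of the study over one input bundle."""
    if regions is None:
        regions = default_regions()

    curve = fit_standard_curve(
        list(zip(bundle.standard_curve_points["rfu"], bundle.standard_curve_points["uM"]))
    )
    activity = activity_records(bundle.traces, curve, wt_id=bundle.wt_id)
    flexibility = flexibility_scores(activity, wt_id=bundle.wt_id)

    # The bundle's alignment covers the study columns only, in the order of
    # the truth's column table; ungapped reference position i+1 is column i's
    # 23S position. Relabel the profile accordingly.
    study_positions = list(bundle.truth.column_frequencies.index)
    entropy = conservation.entropy_profile(
        bundle.alignment, bundle.reference_id, range(1, len(study_positions) + 1)
    )
    entropy["position"] = study_positions

    rt = readthrough.readthrough_table(
        bundle.readthrough_signals, activity, wt_id=bundle.wt_id
    )

    species_areas = {}
    for sample_id, trs in bundle.gradient_traces.items():
        corrected = sedimentation.correct_trace(
            trs["sample"], trs["blank"], trs["background"]
        )
        species_areas[sample_id] = sedimentation.integrate_species(corrected)

    residues = structure.load_structure_from_gemmi(bundle.structure)
    ref_a = structure.reference_point(
        "A-site", [r for r in residues if r.chain == "A"]
    )
    ref_p = structure.reference_point(
        "P-site", [r for r in residues if r.chain == "P"]
    )
    nucleotides = {r.number: r for r in residues if r.chain == "B"}
    distances, _missing = structure.nucleotide_distances(nucleotides, ref_a, ref_p)

    shells = structure.assign_shells(
        flexibility.set_index("position")["score"]
    )

    merged = flexibility.merge(entropy, on="position").merge(distances, on="position")
    loop_positions = set(
        enumerate_positions(regions["A-loop"]) + enumerate_positions(regions["P-loop"])
    ) & set(merged["position"])
    ring = merged[~merged["position"].isin(loop_positions)]
    loops = merged[merged["position"].isin(loop_positions)]
    regressions = {
        "ring_flexibility_vs_entropy": stats.linear_regression(
            ring["entropy_nats"], ring["score"]
        ),
        "loops_flexibility_vs_entropy": stats.linear_regression(
            loops["entropy_nats"], loops["score"]
        ),
        "loops_flexibility_vs_P_distance": stats.linear_regression(
            loops["distance_to_P_site"], loops["score"]
        ),
        "loops_flexibility_vs_A_distance": stats.linear_regression(
            loops["distance_to_A_site"], loops["score"]
        ),
    }

    return PanelResults(
        activity=activity,
        flexibility=flexibility,
        entropy=entropy,
        readthrough=rt,
        species_areas=species_areas,
        distances=distances,
        shells=shells,
        regressions=regressions,
    )
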