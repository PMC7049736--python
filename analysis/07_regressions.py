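"""Regressions of mutational flexibility on conservation and tRNA distance.

Merges the flexibility scores with the entropy profile and the structure
distances, then fits simple linear regressions separately for the
PTC-ring and the A/P-loops: flexibility vs Shannon entropy, and
flexibility vs distance to each tRNA reference point.
"""

import argparse
from pathlib import Path

import pandas as pd

from ptcmap.regions import default_regions, enumerate_positions
from ptcmap.stats import linear_regression


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--flexibility", type=Path,
                    default=Path("results/flexibility_scores.tsv"))
    ap.add_argument("--entropy", type=Path, default=Path("results/entropy_profile.tsv"))
    ap.add_argument("--distances", type=Path, default=Path("results/distances.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/regressions.tsv"))
    args = ap.parse_args(argv)

    flexibility = pd.read_csv(args.flexibility, sep="\t")
    entropy = pd.read_csv(args.entropy, sep="\t")
    distances = pd.read_csv(args.distances, sep="\t")
    merged = flexibility.merge(entropy, on="position").merge(distances, on="position")

    regions = default_regions()
    loops = set(enumerate_positions(regions["A-loop"])) | set(
        enumerate_positions(regions["P-loop"])
    )
    groups = {
        "PTC-ring": merged[~merged["position"].isin(loops)],
        "A/P-loops": merged[merged["position"].isin(loops)],
    }
    predictors = {
        "entropy_nats": "Shannon entropy",
        "distance_to_A_site": "distance to A-site tRNA",
        "distance_to_P_site": "distance to P-site tRNA",
    }

    rows = []
    print("flexibility regressions:")
    for group_name, frame in groups.items():
        for col, label in predictors.items():
            res = linear_regression(frame[col], frame["score"])
            rows.append(
                {"group": group_name, "predictor": col, "slope": res.slope,
                 "r_squared": res.r_squared, "p_value": res.p_value, "n": res.n}
            )
            print(f"  {group_name} vs {label}: R^2 = {res.r_squared:.3f}, "
                  f"P = {res.p_value:.3g} (n = {res.n})")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
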