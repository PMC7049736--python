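"""Distance mapping and flexibility shells on the 3D structure.

Computes each study nucleotide's geometric-center distance to the A-site
and P-site tRNA reference points (A76 heavy atoms), bins the flexibility
scores into four shells, and writes a B-factor-annotated PDB for heat-map
rendering in any viewer.

By default runs on the panel's toy structure (chains A/P = tRNA reference
clusters, chain B = nucleotides). Given real coordinate files via
--ribosome/--trna (e.g. the 4YBB ribosome with 1VY4 tRNAs), the tRNA
structure is first placed into the ribosome frame by Kabsch superposition
on phosphorus atoms of shared residues of the named rRNA chains.
"""

import argparse
from pathlib import Path

import pandas as pd

from ptcmap.structure import (
    assign_shells,
    export_attribute_map,
    load_structure,
    nucleotide_distances,
    reference_point,
    superpose,
)


def toy_references(residues):
    ref_a = reference_point("A-site", [r for r in residues if r.chain == "A"])
    ref_p = reference_point("P-site", [r for r in residues if r.chain == "P"])
    nucleotides = {r.number: r for r in residues if r.chain == "B"}
    return ref_a, ref_p, nucleotides


def real_references(args):
    ribosome = load_structure(args.ribosome)
    trna = load_structure(args.trna)
    shared_rrna = [r for r in trna if r.chain == args.trna_rrna_chain]
    fixed_rrna = [r for r in ribosome if r.chain == args.rrna_chain]
    tf = superpose(shared_rrna, fixed_rrna)
    print(f"  tRNA frame placed on shared phosphates, RMSD {tf.rmsd:.2f} A")
    moved = tf.apply_residues(trna)
    ref_a = reference_point(
        "A-site", [r for r in moved if r.chain == args.a_trna_chain and r.number == 76]
    )
    ref_p = reference_point(
        "P-site", [r for r in moved if r.chain == args.p_trna_chain and r.number == 76]
    )
    nucleotides = {r.number: r for r in ribosome if r.chain == args.rrna_chain}
    return ref_a, ref_p, nucleotides


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--flexibility", type=Path,
                    default=Path("results/flexibility_scores.tsv"))
    ap.add_argument("--ribosome", type=Path, help="real ribosome PDB/mmCIF")
    ap.add_argument("--trna", type=Path, help="real tRNA-bearing PDB/mmCIF")
    ap.add_argument("--rrna-chain", default="DA", help="23S chain in the ribosome file")
    ap.add_argument("--trna-rrna-chain", default="A", help="23S chain in the tRNA file")
    ap.add_argument("--a-trna-chain", default="W", help="A-site tRNA chain")
    ap.add_argument("--p-trna-chain", default="V", help="P-site tRNA chain")
    ap.add_argument("--out-distances", type=Path, default=Path("results/distances.tsv"))
    ap.add_argument("--out-shells", type=Path, default=Path("results/shells.tsv"))
    ap.add_argument("--out-pdb", type=Path, default=Path("results/flexibility_map.pdb"))
    args = ap.parse_args(argv)

    if args.ribosome and args.trna:
        structure_path = args.ribosome
        score_chain = args.rrna_chain
        ref_a, ref_p, nucleotides = real_references(args)
    else:
        structure_path = args.panel / "toy_structure.pdb"
        score_chain = "B"
        ref_a, ref_p, nucleotides = toy_references(load_structure(structure_path))

    flexibility = pd.read_csv(args.flexibility, sep="\t")
    positions = sorted(flexibility["position"])
    distances, missing = nucleotide_distances(nucleotides, ref_a, ref_p, positions)
    shells = assign_shells(flexibility.set_index("position")["score"])

    args.out_distances.parent.mkdir(parents=True, exist_ok=True)
    distances.to_csv(args.out_distances, sep="\t", index=False)
    shells.to_csv(args.out_shells, sep="\t", index=False)
    export_attribute_map(
        structure_path,
        {(score_chain, int(p)): float(s)
         for p, s in flexibility.set_index("position")["score"].items()
         if int(p) in nucleotides},
        args.out_pdb,
    )

    print(f"distances for {len(distances)} positions -> {args.out_distances}"
          + (f" ({len(missing)} missing from structure)" if missing else ""))
    print(f"  P-site distance span: {distances['distance_to_P_site'].min():.1f}"
          f"-{distances['distance_to_P_site'].max():.1f} A")
    print(f"shell assignments -> {args.out_shells}")
    print(f"B-factor flexibility map -> {args.out_pdb}")


if __name__ == "__main__":
    main()
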