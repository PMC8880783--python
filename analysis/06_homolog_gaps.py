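#!/usr/bin/env python
"""The B1/C1-equivalent FeS gap in nonbifurcating homologs.

The published edge-to-edge distances between the FMN-proximal [4Fe-4S] and
the accessory [2Fe-2S] cluster are 19.4 Å in respiratory complex I (entry
3IAM) and 19.5 Å in formate dehydrogenase (entry 6TGA) — both far beyond
electron-transfer range, mirroring the >22 Å B1-C1 exclusion in the
bifurcating enzyme.

This driver measures those gaps on synthetic stand-ins that encode the
printed values (the deposited entries are not bundled); pass paths to
downloaded mmCIF/PDB files as arguments to measure the real entries with
the same code path.

Found: the detect/measure pipeline reproduces 19.4 and 19.5 Å at 0.1 Å
rounding on the stand-ins.
"""

import sys
from itertools import combinations
from pathlib import Path

import cofnet as cn

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"
PRINTED = {"complex-I (3IAM analog)": 19.4, "FDH (6TGA analog)": 19.5}


def measure_fes_pair(structure: cn.Structure) -> float:
    """Edge distance between the [4Fe-4S] / [2Fe-2S] pair of interest."""
    cofs = cn.detect_cofactors(structure)
    fes4 = [c for c in cofs if c.type.code == "FES4"]
    fes2 = [c for c in cofs if c.type.code == "FES2"]
    return min(cn.edge_distance(a, b)[0] for a in fes4 for b in fes2)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, printed in PRINTED.items():
        st = cn.make_synthetic_homolog(printed, seed=SEED, name=name)
        got = measure_fes_pair(st)
        lines.append(f"{name}\tsynthetic stand-in\t{got:.1f}")
        print(f"{name}: measured {got:.1f} Å (printed {printed})")
    for arg in sys.argv[1:]:
        st = cn.read_structure(arg)
        got = measure_fes_pair(st)
        lines.append(f"{Path(arg).name}\tdownloaded entry\t{got:.1f}")
        print(f"{arg}: closest [4Fe-4S]-[2Fe-2S] edge distance {got:.1f} Å")
    (OUT / "homolog_gaps.tsv").write_text(
        "system\tsource\tedge_distance_A\n" + "\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
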